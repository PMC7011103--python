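# Methods

This note records the scientific and numerical choices behind `oxlip`:
what is computed, under which assumptions, and what the synthetic-data
tests do and do not establish.

## Mass and formula conventions

All masses are monoisotopic, from a fixed atomic-mass table
(C 12.000000, H 1.00782503, N 14.00307401, O 15.99491462, P 30.97376151;
¹³C–¹²C spacing 1.0033548 Da). Anion m/z is computed as the neutral
formula arithmetic result with **no electron-mass correction**: the
curated reference fragment values (255.232 for palmitate, 293.212 for the
18:3-O anion, 291.196 for 18:4-O) match neutral-minus-H arithmetic only
without the ~0.549 mDa electron term, so adding it would shift every
3-decimal value off the reference. Display rounding is round-half-up to
3 decimals; matching always uses unrounded values with ppm tolerances so
rounding can never change a match decision. Only singly charged
negative-mode species are supported — the entire identification workflow
runs in negative ESI.

## Candidate chemistry

The diacyl core is glycerol esterified with two free fatty acids, losing
one water per ester bond. Head-group increments (water of condensation
already netted out): PC +C5H12NO3P, PE +C2H6NO3P, PG +C3H7O5P,
PI +C6H11O8P, PS +C3H6NO5P, MGDG +C6H10O5, DGDG +C12H20O10. These
reproduce the curated detected precursors to ≈1 mDa for 37 of 38 species;
the one exception (PI(36:5)-O, printed 871.487) is inconsistent with its
own homologous series (one double bond below PI(36:4)-O at 873.515 must
sit near 871.499) and is treated as a transcription error in the source
table.

Adduct assignment per class — acetate adducts for PC and the
galactolipids, deprotonation for PE/PG/PI, deprotonation plus serine head
loss (C3H5NO2, 87.032 Da) for PS — was **inferred** by reconciling the
curated masses; it is the only assignment that reproduces all classes,
but it is an inference of this package, not a stated fact of the source
workflow.

The default oxylipin chain set is 18:2-O, 18:3-O, 18:4-O, 18:2-2O,
18:3-2O **plus 18:4-2O**. The five canonical types cover 37 confirmed
species; the confirmed species PS(34:4)-2O (monitored ion 699.424) is
only reachable as 16:0/18:4-2O (computed 699.4237, <1 mDa), and a
targeted library that cannot express a confirmed species would be
defective, so the sixth chain is included. The canonical five remain
available as `CORE_OX_CHAINS`. Enumeration pairs every normal FA with
every oxylipin and every unordered oxylipin pair including self-pairs,
keeps totals of 1–4 extra oxygens ("oxygen atoms in acyl chains range
from one to four" is read as oxygens beyond the carboxyl pair — the only
reading consistent with the -O/-2O naming), and yields 273 candidates
over the seven classes (210 with the canonical five chains). One species
label can map to two chain compositions (PE(36:5)-O is both
18:2-O/18:3 and 18:3-O/18:2); both are kept, since MS/MS distinguishes
them while the precursor does not.

Dehydration: di-oxygenated chains are predicted as the anion of the
(d+1, 1-oxygen) chain, e.g. 18:3-2O → 291.196. Applied uniformly, this
predicts the 18:5-O anion (289.180) for 18:4-2O; the source table instead
prints 291.196 for PS(34:4)-2O's oxidized fragment, which equals the
18:4-O anion and is inconsistent with that species' own precursor mass.
The library keeps the uniform computed rule.

## Annotation

Tolerances default to the instrument's stated accuracy: 5 ppm MS1,
10 ppm MS/MS. MS/MS spectra are associated to a feature when their
precursor is within the MS1 tolerance and their RT within ±0.2 min (the
source is silent on this window; it is configurable). Verification
minimally requires the **oxidized-chain** fragment: the normal-chain
fragment and head-group diagnostics improve ranking but are not required,
mirroring a presence-based manual check. Ranking is by |ppm error|, then
more fragments, then lower precursor m/z, then label — fully
deterministic.

The retention-time rules are ordinal constraints, not an RT prediction
model. Rule A: an oxidized species must elute before its non-oxidized
parent. Rule B: within one class and one extra-oxygen count, species are
compared under a **dominance partial order** — a species with no more
carbons and no fewer double bonds must elute no later. A blanket
"fewer carbons ⇒ earlier" ordering is refuted by the curated data itself
(PE(34:3)-O at 7.16 min elutes after PE(36:6)-O at 5.98 min: the three
extra double bonds outweigh the two extra carbons), while the dominance
order holds on every curated class series. Violations flag the match
(both members of a violating pair); nothing is dropped, and only
violation-free MS/MS-verified matches reach the top tier.

Isotope-partner detection defines a partner as a co-eluting feature
(|ΔRT| ≤ 0.1 min) one ¹³C spacing away (±0.01 Da), flagging both members
of a pair under the singly-charged assumption. Cross-run alignment
groups features at |Δm/z| ≤ 0.01 Da and ≤5% relative RT difference after
a single-point internal-standard shift, resolving ambiguity by nearest
m/z then nearest RT.

## Quantification

Extraction windows are 100 ppm wide (±50 ppm). "Gaussian smooth width,
2 points" is implemented as a Gaussian kernel with σ = 2 sample
intervals; vendor semantics are not public, and area is nearly invariant
to the exact kernel since convolution preserves the integral. The
"noise percentage" baseline is threshold = pct% of the trace's robust
background (the median of the smoothed trace): 0% integrates the whole
trace, the parameter is monotone, and large values restrict integration
to the apex region. This contract is the documented stand-in for a
proprietary vendor algorithm; absolute areas are therefore comparable
within `oxlip` but not bit-identical to vendor software. Integration is
per-fragment-then-sum (the alternative, sum-traces-then-integrate, is
equivalent for co-eluting fragments of one species but less robust to
interference); fragment sets follow the class rules: all chain
carboxylates for diacyl GP/GL/CL, FA-neutral-loss products for DAG, the
long-chain base plus its first three dehydration products for Cer/HexCer,
the single dehydrated backbone for ST.

Normalization: value = raw × (reference IS / sample IS) × (250 / weight
mg), with the batch **median** internal-standard response as reference
(the source describes a "manual scale factor" without a formula; the
median is robust to single-sample IS failures). PBQC CV uses the sample
standard deviation (ddof = 1); lipids at CV ≥ 25% are removed and the
median CV of retained lipids is reported.

## Statistics

Fold changes are log2 ratios of group **means** (matching
ratio-of-responses semantics); a non-positive control mean yields a
missing value with a recorded reason rather than an error. t-tests are
two-sided Student (pooled variance) by default — the source does not
state its variance assumption; Welch is available by flag. BH adjustment
is applied within each variety's family of contrasts, implemented via
`statsmodels.multipletests` and cross-checked in the test suite against
an independent step-up implementation. Zero-variance identical groups
return p = 1 by convention.

## Synthetic data: what it emulates, what it does not

The generators state the design of the emulated experiment: 4 varieties ×
2 treatments × 5 biological replicates, 5 pooled-QC injections, mass
errors Normal(0, 2 ppm) truncated to the instrument's <5 ppm accuracy
envelope, decoys offset ≥ 20 ppm, multiplicative lognormal abundance
noise at 10% CV, lognormal IS drift and 250–300 mg sample weights. The
RT model is linear and qualitative only (rt = a0 + a1·C − a2·DB − a3·Ox
with positive a2, a3, placing species at realistic 4–8 min values);
it reproduces elution-order *patterns*, not retention physics.
Simulated spectra contain exactly the predicted fragments plus optional
random contaminants — no chimeras, no isotope envelopes in MS2, no peak
tailing, no batch drift. A green end-to-end test therefore establishes
correctness of the matching, tiering, normalization and testing logic
under the stated error model; it does not establish performance on real
chromatographic interference or co-isolation.

Experiment-level fold-change recovery is assessed per lipid by averaging
the four per-variety contrast estimates, since the planted effect is
common to all varieties: a single n = 5 vs 5 contrast at 10% CV has
SE(log2 FC) ≈ 0.09, so only ~90% of single contrasts land within ±0.15,
while the pooled estimator (SE ≈ 0.046) does so for >95% of lipids. The
per-variety estimates remain available in the results table.

## Known limitations

- Structural isomers of an oxylipin (hydroxy vs keto vs hydroperoxy) and
  sn-positions are indistinguishable by mass; labels encode composition
  only.
- Lyso (monoacyl) oxidized species and triacyl galactolipids are out of
  scope, as are positive-mode identifications and multiply charged ions.
- The integration baseline is a documented stand-in for proprietary
  vendor behaviour (see above).
- mzML support covers the minimal centroided MS2 subset the pipeline
  writes and reads; profile-mode data and vendor raw files are not
  handled.
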