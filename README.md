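# oxlip

Targeted identification and profiling of **oxidized diacyl membrane
lipids** from negative-mode LC-MS/MS data.

Reactive oxygen species produced under abiotic stress (salinity, drought,
wounding) peroxidize the polyunsaturated acyl chains of membrane
glycerophospholipids (PC, PE, PG, PI, PS) and plastid galactolipids
(MGDG, DGDG). The resulting esterified oxylipins — hydroxy, keto and
dihydroxy 18-carbon chains such as 18:3-O or 18:2-2O — are low-abundance
markers of membrane oxidation that untargeted pipelines routinely miss.
`oxlip` implements the targeted alternative: enumerate every plausible
oxidized species *in silico*, compute its exact precursor and fragment
m/z, and hunt for those ions in MS1 feature tables and MS/MS spectra.
It is written for analytical lipidomics groups profiling plant (or other)
tissue on accurate-mass QTOF instruments with scheduled MRM/PRM assays.

## The method

**Candidate enumeration.** A candidate is a lipid class plus two acyl
chains: one of the abundant normal fatty acids (16:0, 18:2, 18:3) paired
with an 18-carbon oxylipin (18:2-O, 18:3-O, 18:4-O, 18:2-2O, 18:3-2O,
18:4-2O), or two oxylipins. The neutral formula is constructive:

```
M = glycerol (C3H8O3) + RCOOH(chain1) + RCOOH(chain2) − 2 H2O + head increment
```

where a chain `n:d` with `x` extra oxygens has free-acid formula
C(n)H(2n−2d)O(2+x). Negative-mode precursors follow per-class adduct
rules: `[M+OAc]−` for PC/MGDG/DGDG, `[M−H]−` for PE/PG/PI, and the
serine-loss ion `[M−H−C3H5NO2]−` (−88.040) for PS. No electron-mass
correction is applied; m/z values are reported to 3 decimals
(round-half-up) while all matching uses unrounded values.

**Fragments.** Collision-induced dissociation releases each chain as its
carboxylate anion (free acid − H). Di-oxygenated chains dehydrate and are
detected as the anion of the chain with one more double bond and one less
oxygen (18:2-2O → the 18:3-O anion at 293.212; 18:3-2O → the 18:4-O anion
at 291.196).

**Annotation.** MS1 features are filtered (m/z 100–1600, RT 0.5–16 min,
intensity ≥ 300 in ≥ 3 samples of a group, ¹³C isotope partner required),
matched to candidates within 5 ppm, verified by the presence of the
oxidized-chain fragment within 10 ppm in a co-eluting MS/MS spectrum, and
screened by elution-order rules (oxidized species elute before their
non-oxidized parents; within a class, shorter and more unsaturated
species elute earlier). Matches are tiered MS1_ONLY → MS1_MS2 →
MS1_MS2_RT; rule violations are flagged, never silently dropped.

**Quantification and statistics.** Species are quantified as the summed
trapezoidal areas of their fragment-ion chromatograms (100 ppm extraction
width, Gaussian smoothing, 40% noise baseline), normalized by internal
standard and fresh weight to a 250 mg equivalent, filtered at a pooled-QC
CV < 25%, and tested per variety with two-sided Student t-tests,
log2 fold changes of group means, and Benjamini–Hochberg FDR.

## Worked example

```python
from oxlip import AcylChain
from oxlip.chem import round_mz
from oxlip.library import LIPID_CLASSES, OxLipidCandidate

cand = OxLipidCandidate.build(
    LIPID_CLASSES["PE"], AcylChain.parse("18:2-O"), AcylChain.parse("18:3")
)
```

prints, via the obvious formatting:

```
PE(36:5)-O  (18:2-O/18:3)
  neutral formula : C41H72NO9P
  adduct          : [M-H]-
  precursor m/z   : 752.487
  product 18:2-O : 295.227
  product 18:3   : 277.217
library size      : 273 candidates
```

i.e. the deprotonated PE(36:5)-O precursor at m/z 752.487 fragments into
the 18:2-O carboxylate (295.227) and the linolenate anion (277.217); the
same species label is also reachable as 18:3-O/18:2 (fragments 293.212 /
279.232), and both compositions are kept as distinct candidates.

End to end on synthetic data from the shell:

```
$ oxlip --output-dir run --seed 7 simulate
simulated 566 features, 273 spectra, 175 lipids into run
$ oxlip --output-dir run annotate --features run/features.csv \
        --spectra run/spectra.mgf --manifest run/feature_manifest.csv
wrote 540 matches to run/matches.tsv
recall: 100.0% of planted features; decoy matches: 0
```

Every feature planted within the 5 ppm mass-accuracy envelope is
recovered and MS/MS-verified; decoys offset by ≥ 20 ppm are never
accepted. `quantify` and `stats` continue the pipeline to normalized,
QC-filtered differential-abundance tables.

## Acceptance script

`scripts/acceptance.py` rebuilds the candidate library from scratch and
reports the computed negative-mode precursor m/z for six benchmark
species — PC(34:3)-O, PE(36:5)-O, PS(36:5)-O, PI(36:4)-O, MGDG(34:4)-O
and DGDG(36:6)-O — each assembled from its chains via the constructive
formula and class adduct rule:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `oxlip.chem` — elemental-formula arithmetic, monoisotopic masses, ppm error
- `oxlip.library` — candidate enumeration, adduct rules, transition lists
- `oxlip.annotate` — feature filtering/alignment, matching, MS/MS and RT rules
- `oxlip.quantify` — EICC extraction, peak integration, normalization, QC
- `oxlip.stats` — fold changes, t-tests, BH-FDR (`DifferentialAbundance` model)
- `oxlip.simulate` — synthetic fixtures with ground-truth manifests
- `oxlip.io` / `oxlip.cli` — CSV/MGF/mzML codecs, config, `oxlip` CLI

See `docs/methods.md` for modelling assumptions and numerical choices.
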