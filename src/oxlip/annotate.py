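"""MS1 feature filtering, alignment, accurate-mass matching and MS/MS
verification of oxidized-lipid candidates.

The annotation contract mirrors a targeted manual-verification workflow:
a feature matches a candidate by precursor m/z within a 5 ppm MS1
tolerance; the match is *verified* when an associated MS/MS spectrum
contains at least one predicted oxidized-chain carboxylate fragment within
10 ppm; and retention-time plausibility rules (oxidized species elute
before their non-oxidized parents; within a class, chain length and
unsaturation order elution) flag — never silently drop — implausible
matches. Tiers encode how far a match got: MS1_ONLY < MS1_MS2 < MS1_MS2_RT.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable, Mapping, Sequence

from .chem import DEFAULT_ISOTOPES, ppm_error
from .library import OxLipidCandidate

logger = logging.getLogger(__name__)

__all__ = [
    "MS1Feature",
    "MsmsSpectrum",
    "AnnotationMatch",
    "MatchTier",
    "RuleOutcome",
    "FilterParams",
    "filter_features",
    "detect_isotope_partner",
    "align_features",
    "match_and_verify",
    "apply_rt_rules",
    "parent_label",
]


@dataclass(frozen=True)
class MS1Feature:
    """One aligned MS1 feature: centroid m/z, RT in minutes, per-sample
    intensities, and whether a 13C isotopic partner feature was seen."""

    feature_id: str
    mz: float
    rt: float
    intensities: Mapping[str, float] = field(default_factory=dict)
    has_isotope_partner: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensities", dict(self.intensities))


@dataclass(frozen=True)
class MsmsSpectrum:
    """A centroided MS2 scan: precursor m/z, RT (minutes), peak list
    sorted by m/z."""

    precursor_mz: float
    rt: float
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise ValueError("negative peak intensity")
        object.__setattr__(self, "peaks", pk)

    def intensity_near(self, mz: float, tol_ppm: float) -> float:
        """Summed intensity of peaks within ±tol_ppm of ``mz``."""
        half = mz * tol_ppm * 1e-6
        return sum(i for m, i in self.peaks if abs(m - mz) <= half)


class MatchTier(enum.Enum):
    MS1_ONLY = "MS1_ONLY"
    MS1_MS2 = "MS1_MS2"
    MS1_MS2_RT = "MS1_MS2_RT"

    def __lt__(self, other: "MatchTier") -> bool:  # ordering for ranking
        order = [MatchTier.MS1_ONLY, MatchTier.MS1_MS2, MatchTier.MS1_MS2_RT]
        return order.index(self) < order.index(other)


@dataclass(frozen=True)
class RuleOutcome:
    rule: str  # "A" (earlier than parent) or "B" (within-class order)
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class AnnotationMatch:
    candidate: OxLipidCandidate
    feature: MS1Feature
    ppm_error: float
    #: (fragment label, theoretical m/z, observed ppm) for found products.
    fragments_found: tuple[tuple[str, float, float], ...] = ()
    rt_checks: tuple[RuleOutcome, ...] = ()
    tier: MatchTier = MatchTier.MS1_ONLY

    @property
    def n_fragments(self) -> int:
        return len(self.fragments_found)


@dataclass(frozen=True)
class FilterParams:
    """Feature-table filter settings (defaults follow the workflow)."""

    mz_range: tuple[float, float] = (100.0, 1600.0)
    rt_range: tuple[float, float] = (0.5, 16.0)
    noise_threshold: float = 300.0
    min_samples_per_group: int = 3
    require_isotope_partner: bool = True


def filter_features(
    raw: Sequence[MS1Feature],
    groups: Mapping[str, str],
    params: FilterParams = FilterParams(),
) -> list[MS1Feature]:
    """Keep features inside the m/z and RT windows, above the noise
    threshold in at least ``min_samples_per_group`` samples of at least one
    group, and (optionally) carrying an isotopic partner. Order preserved.
    """
    by_group: dict[str, list[str]] = {}
    for sample, grp in groups.items():
        by_group.setdefault(grp, []).append(sample)

    kept = []
    for feat in raw:
        missing = set(feat.intensities) - set(groups)
        if missing:
            raise KeyError(f"samples without group labels: {sorted(missing)}")
        if not params.mz_range[0] <= feat.mz <= params.mz_range[1]:
            continue
        if not params.rt_range[0] <= feat.rt <= params.rt_range[1]:
            continue
        ok = False
        for members in by_group.values():
            n = sum(
                1
                for s in members
                if feat.intensities.get(s, 0.0) >= params.noise_threshold
            )
            if n >= params.min_samples_per_group:
                ok = True
                break
        if not ok:
            continue
        if params.require_isotope_partner and not feat.has_isotope_partner:
            continue
        kept.append(feat)
    return kept


def detect_isotope_partner(
    features: Sequence[MS1Feature],
    mz_tol: float = 0.01,
    rt_tol: float = 0.1,
    spacing: float = DEFAULT_ISOTOPES.isotope_spacing,
) -> list[MS1Feature]:
    """Flag features that have a co-eluting 13C isotopic partner.

    A feature has a partner iff another feature lies one 13C-12C spacing
    above or below it (±mz_tol Da) with |ΔRT| ≤ rt_tol min. Both members of
    a pair are flagged (singly charged assumption).
    """
    out = []
    for feat in features:
        has = any(
            other is not feat
            and abs(abs(other.mz - feat.mz) - spacing) <= mz_tol
            and abs(other.rt - feat.rt) <= rt_tol
            for other in features
        )
        out.append(replace(feat, has_isotope_partner=has))
    return out


def _anchor_shift(
    table: Sequence[MS1Feature], anchor: tuple[float, float] | None
) -> float:
    """RT shift from a single internal-standard anchor (observed, reference)."""
    if anchor is None:
        return 0.0
    observed_rt, reference_rt = anchor
    return reference_rt - observed_rt


def align_features(
    tables: Sequence[Sequence[MS1Feature]],
    anchors: Sequence[tuple[float, float] | None] | None = None,
    mz_tol: float = 0.01,
    rt_rel_tol: float = 0.05,
) -> list[MS1Feature]:
    """Group features across tables into consensus features.

    Each table may carry an internal-standard anchor ``(observed RT,
    reference RT)``; RTs are shifted by the single-point anchor offset
    before grouping. Features group when |Δmz| ≤ mz_tol and the relative RT
    difference ≤ rt_rel_tol. Ambiguity is resolved by nearest m/z then
    nearest RT (logged). Consensus: median m/z, median RT, union of sample
    intensities.
    """
    if not tables:
        raise ValueError("need at least one feature table")
    if anchors is None:
        anchors = [None] * len(tables)
    if len(anchors) != len(tables):
        raise ValueError("one anchor (or None) per table required")

    groups: list[list[MS1Feature]] = []
    for table, anchor in zip(tables, anchors):
        shift = _anchor_shift(table, anchor)
        for feat in table:
            shifted = replace(feat, rt=feat.rt + shift) if shift else feat
            cands = []
            for gi, grp in enumerate(groups):
                ref_mz = median(f.mz for f in grp)
                ref_rt = median(f.rt for f in grp)
                dmz = abs(shifted.mz - ref_mz)
                denom = max(abs(ref_rt), abs(shifted.rt), 1e-9)
                drel = abs(shifted.rt - ref_rt) / denom
                if dmz <= mz_tol and drel <= rt_rel_tol:
                    cands.append((dmz, abs(shifted.rt - ref_rt), gi))
            if cands:
                cands.sort()
                if len(cands) > 1:
                    logger.debug(
                        "feature %s matched %d groups; keeping nearest",
                        shifted.feature_id,
                        len(cands),
                    )
                groups[cands[0][2]].append(shifted)
            else:
                groups.append([shifted])

    consensus = []
    for i, grp in enumerate(groups):
        intensities: dict[str, float] = {}
        for f in grp:
            intensities.update(f.intensities)
        partner_flags = [f.has_isotope_partner for f in grp if f.has_isotope_partner is not None]
        consensus.append(
            MS1Feature(
                feature_id=grp[0].feature_id,
                mz=median(f.mz for f in grp),
                rt=median(f.rt for f in grp),
                intensities=intensities,
                has_isotope_partner=any(partner_flags) if partner_flags else None,
            )
        )
    return consensus


def match_and_verify(
    features: Sequence[MS1Feature],
    spectra: Sequence[MsmsSpectrum],
    candidates: Sequence[OxLipidCandidate],
    ms1_tol_ppm: float = 5.0,
    ms2_tol_ppm: float = 10.0,
    rt_window: float = 0.2,
) -> list[AnnotationMatch]:
    """Match features to candidates by accurate mass and verify by MS/MS.

    Every feature-candidate pair within ``ms1_tol_ppm`` yields a match.
    MS/MS spectra whose precursor lies within the same tolerance of the
    feature m/z and within ±``rt_window`` min of the feature RT are searched
    for each predicted product within ``ms2_tol_ppm``; the tier is upgraded
    to MS1_MS2 when at least one oxidized-chain fragment is found. All
    matches are returned ranked per feature by (|ppm|, more fragments
    first, lower precursor m/z, label).
    """
    matches: list[AnnotationMatch] = []
    for feat in features:
        feat_matches = []
        for cand in candidates:
            err = ppm_error(feat.mz, cand.precursor_mz)
            if abs(err) > ms1_tol_ppm:
                continue
            found: list[tuple[str, float, float]] = []
            for spec in spectra:
                if abs(ppm_error(spec.precursor_mz, feat.mz)) > ms1_tol_ppm:
                    continue
                if abs(spec.rt - feat.rt) > rt_window:
                    continue
                for frag_label, frag_mz in cand.products:
                    if any(f[0] == frag_label for f in found):
                        continue
                    half = frag_mz * ms2_tol_ppm * 1e-6
                    hits = [m for m, inten in spec.peaks if abs(m - frag_mz) <= half and inten > 0]
                    if hits:
                        best = min(hits, key=lambda m: abs(m - frag_mz))
                        found.append((frag_label, frag_mz, ppm_error(best, frag_mz)))
            ox_labels = {lbl for lbl, _ in cand.oxidized_products}
            tier = (
                MatchTier.MS1_MS2
                if any(lbl in ox_labels for lbl, _, _ in found)
                else MatchTier.MS1_ONLY
            )
            feat_matches.append(
                AnnotationMatch(
                    candidate=cand,
                    feature=feat,
                    ppm_error=err,
                    fragments_found=tuple(found),
                    tier=tier,
                )
            )
        feat_matches.sort(
            key=lambda m: (
                abs(m.ppm_error),
                -m.n_fragments,
                m.candidate.precursor_mz,
                m.candidate.label,
                m.candidate.chain_composition,
            )
        )
        matches.extend(feat_matches)
    return matches


_SUFFIX = re.compile(r"-\d?O$")


def parent_label(species_label: str) -> str:
    """Label of the non-oxidized parent: strip the ``-O``/``-nO`` suffix."""
    return _SUFFIX.sub("", species_label)


def _dominates(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True if species a must elute no later than species b.

    a = (carbons, double bonds). Comparable only when a has <= carbons AND
    >= double bonds (not both equal): shorter chains and higher unsaturation
    both pull elution earlier on reversed phase, so only pairs where the two
    effects agree are ordered.
    """
    (ca, da), (cb, db) = a, b
    return ca <= cb and da >= db and (ca, da) != (cb, db)


def apply_rt_rules(
    matches: Sequence[AnnotationMatch],
    parent_rts: Mapping[str, float] | None = None,
) -> list[AnnotationMatch]:
    """Attach retention-time plausibility checks and upgrade tiers.

    Rule A (when the non-oxidized parent is annotated): an oxidized species
    must elute earlier than its parent. Rule B (within one class and one
    extra-oxygen count): the dominance partial order — fewer carbons with
    equal-or-more double bonds implies earlier-or-equal elution — must hold
    over the matched set. Violations are flagged in ``rt_checks``;
    violation-free MS1_MS2 matches are upgraded to MS1_MS2_RT.
    """
    parent_rts = parent_rts or {}

    # one representative RT per species label for rule B
    label_rt: dict[tuple[str, int, str], float] = {}
    label_cd: dict[tuple[str, int, str], tuple[int, int]] = {}
    for m in matches:
        c = m.candidate
        key = (c.lipid_class.name, c.total_extra_oxygens, c.label)
        label_rt.setdefault(key, m.feature.rt)
        carbons = c.chain1.carbons + c.chain2.carbons
        dbs = c.chain1.double_bonds + c.chain2.double_bonds
        label_cd[key] = (carbons, dbs)

    out = []
    for m in matches:
        checks: list[RuleOutcome] = []
        c = m.candidate
        parent = parent_label(c.label)
        if parent in parent_rts:
            ok = m.feature.rt < parent_rts[parent]
            checks.append(
                RuleOutcome(
                    "A",
                    ok,
                    f"{c.label} at {m.feature.rt:.2f} vs parent {parent} at "
                    f"{parent_rts[parent]:.2f}",
                )
            )
        key = (c.lipid_class.name, c.total_extra_oxygens, c.label)
        my_cd = label_cd[key]
        my_rt = label_rt[key]
        for other_key, other_cd in label_cd.items():
            if other_key[:2] != key[:2] or other_key == key:
                continue
            other_rt = label_rt[other_key]
            if _dominates(my_cd, other_cd) and my_rt > other_rt:
                checks.append(
                    RuleOutcome(
                        "B",
                        False,
                        f"{c.label} ({my_rt:.2f}) should elute before "
                        f"{other_key[2]} ({other_rt:.2f})",
                    )
                )
            elif _dominates(other_cd, my_cd) and other_rt > my_rt:
                checks.append(
                    RuleOutcome(
                        "B",
                        False,
                        f"{other_key[2]} ({other_rt:.2f}) should elute before "
                        f"{c.label} ({my_rt:.2f})",
                    )
                )
        if not any(o.rule == "B" and not o.passed for o in checks):
            checks.append(RuleOutcome("B", True, "within-class elution order consistent"))
        tier = m.tier
        if tier == MatchTier.MS1_MS2 and all(o.passed for o in checks):
            tier = MatchTier.MS1_MS2_RT
        out.append(replace(m, rt_checks=tuple(checks), tier=tier))
    return out


def matches_to_records(matches: Iterable[AnnotationMatch]) -> list[dict]:
    """Flatten matches for TSV reporting."""
    rows = []
    for m in matches:
        rows.append(
            {
                "feature_id": m.feature.feature_id,
                "feature_mz": round(m.feature.mz, 4),
                "feature_rt_min": round(m.feature.rt, 3),
                "species": m.candidate.label,
                "chain_composition": m.candidate.chain_composition,
                "precursor_mz": round(m.candidate.precursor_mz, 4),
                "ppm_error": round(m.ppm_error, 3),
                "n_fragments_found": m.n_fragments,
                "fragments_found": ";".join(lbl for lbl, _, _ in m.fragments_found),
                "rt_violations": ";".join(
                    o.detail for o in m.rt_checks if not o.passed
                ),
                "tier": m.tier.value,
            }
        )
    return rows
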