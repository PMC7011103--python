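"""Synthetic LC-MS fixtures with known ground truth.

Generates MS1 feature tables (planted candidates with controlled ppm
error, isotopic partners and far-off decoys), MS/MS spectra built from the
candidates' predicted product ions, and full multi-group quantitative
experiments with planted log2 fold changes — everything the annotation,
quantification and statistics layers need, without any instrument data.

The stated world mirrors the barley-root design: four varieties, two
treatments, five biological replicates, MS1 mass errors below 5 ppm,
decoys at >= 20 ppm, per-lipid abundance noise around a 10% CV, and a
linear qualitative RT model in which longer chains elute later while extra
double bonds and extra oxygens pull elution earlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import MS1Feature, MsmsSpectrum
from .chem import DEFAULT_ISOTOPES
from .library import OxLipidCandidate, enumerate_candidates
from .quantify import QuantTable, SampleMeta, normalize_table

__all__ = [
    "SimulationDesign",
    "candidate_rt",
    "simulate_features",
    "simulate_msms",
    "simulate_experiment",
]

DEFAULT_VARIETIES = ("Gairdner", "Keel", "Mundah", "Vlamingh")


@dataclass(frozen=True)
class SimulationDesign:
    """Ground-truth parameters for all simulators.

    RT model: rt = a0 + a1*carbons - a2*double_bonds - a3*extra_oxygens
    with a2, a3 > 0, so elution order is consistent with reversed-phase
    behaviour. Defaults put the curated species between ~4 and ~8 min.
    """

    candidates: tuple[OxLipidCandidate, ...] | None = None
    ppm_error_mean: float = 0.0
    ppm_error_sd: float = 2.0  # well below the 5 ppm MS1 tolerance
    #: instrument MS1 mass-accuracy bound: planted errors are truncated
    #: Normal draws with |eps| below this (the stated accuracy is <5 ppm)
    max_abs_ppm: float = 5.0
    rt_coeffs: tuple[float, float, float, float] = (0.0, 0.22, 0.30, 0.20)
    n_decoys: int = 20
    decoy_ppm_offset: float = 25.0  # >= 20 ppm: outside any match window
    varieties: tuple[str, ...] = DEFAULT_VARIETIES
    treatments: tuple[str, str] = ("control", "salt")
    replicates: int = 5
    n_pbqc: int = 5
    planted_log2_fc: Mapping[str, float] | float = 0.0
    cv: float = 0.10
    seed: int = 0

    def resolve_candidates(self) -> tuple[OxLipidCandidate, ...]:
        if self.candidates is not None:
            return self.candidates
        return tuple(enumerate_candidates())

    def planted_fc(self, lipid: str) -> float:
        if isinstance(self.planted_log2_fc, Mapping):
            return float(self.planted_log2_fc.get(lipid, 0.0))
        return float(self.planted_log2_fc)


def candidate_rt(candidate: OxLipidCandidate, coeffs: Sequence[float]) -> float:
    a0, a1, a2, a3 = coeffs
    carbons = candidate.chain1.carbons + candidate.chain2.carbons
    dbs = candidate.chain1.double_bonds + candidate.chain2.double_bonds
    return a0 + a1 * carbons - a2 * dbs - a3 * candidate.total_extra_oxygens


def _sample_names(design: SimulationDesign) -> list[str]:
    return [
        f"{v}_{t}_{r + 1}"
        for v in design.varieties
        for t in design.treatments
        for r in range(design.replicates)
    ]


def simulate_features(
    design: SimulationDesign,
) -> tuple[list[MS1Feature], pd.DataFrame]:
    """Feature table with one planted feature per candidate plus decoys.

    Planted features sit at mz*(1+eps), eps ~ Normal(mean, sd) in ppm, each
    with a 13C isotope partner at +1.0033548 Da; decoys are offset by at
    least ``decoy_ppm_offset`` ppm. The manifest records every feature's
    kind, species and applied error. Byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    candidates = design.resolve_candidates()
    samples = _sample_names(design)
    spacing = DEFAULT_ISOTOPES.isotope_spacing

    features: list[MS1Feature] = []
    manifest_rows = []

    def intensities(base: float) -> dict[str, float]:
        return {
            s: float(base * rng.lognormal(0.0, design.cv))
            for s in samples
        }

    def truncated_ppm() -> float:
        while True:
            eps = float(rng.normal(design.ppm_error_mean, design.ppm_error_sd))
            if abs(eps) < design.max_abs_ppm:
                return eps

    for i, cand in enumerate(candidates):
        eps = truncated_ppm()
        mz = cand.precursor_mz * (1.0 + eps * 1e-6)
        rt = candidate_rt(cand, design.rt_coeffs)
        base = 10_000.0 * float(rng.lognormal(0.0, 0.3))
        fid = f"F{i:04d}"
        features.append(MS1Feature(fid, mz, rt, intensities(base)))
        features.append(
            MS1Feature(f"{fid}_iso", mz + spacing, rt, intensities(0.3 * base))
        )
        manifest_rows.append(
            {
                "feature_id": fid,
                "kind": "planted",
                "species": cand.label,
                "chain_composition": cand.chain_composition,
                "true_mz": cand.precursor_mz,
                "ppm_applied": eps,
                "rt_min": rt,
            }
        )
        manifest_rows.append(
            {
                "feature_id": f"{fid}_iso",
                "kind": "isotope_partner",
                "species": cand.label,
                "chain_composition": cand.chain_composition,
                "true_mz": cand.precursor_mz + spacing,
                "ppm_applied": eps,
                "rt_min": rt,
            }
        )

    decoy_src = rng.choice(len(candidates), size=design.n_decoys, replace=True)
    for j, k in enumerate(decoy_src):
        cand = candidates[int(k)]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        eps = sign * (design.decoy_ppm_offset + float(rng.exponential(5.0)))
        mz = cand.precursor_mz * (1.0 + eps * 1e-6)
        rt = candidate_rt(cand, design.rt_coeffs) + float(rng.normal(0.0, 0.5))
        fid = f"D{j:04d}"
        features.append(MS1Feature(fid, mz, rt, intensities(3_000.0)))
        manifest_rows.append(
            {
                "feature_id": fid,
                "kind": "decoy",
                "species": cand.label,
                "chain_composition": cand.chain_composition,
                "true_mz": cand.precursor_mz,
                "ppm_applied": eps,
                "rt_min": rt,
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    return features, manifest


def simulate_msms(
    candidate: OxLipidCandidate,
    seed: int = 0,
    rt: float | None = None,
    rt_coeffs: Sequence[float] = SimulationDesign.rt_coeffs,
    base_intensity: float = 1000.0,
    n_contaminants: int = 0,
    ms2_ppm_sd: float = 0.0,
) -> MsmsSpectrum:
    """One MS/MS spectrum of a candidate: peaks at every predicted product
    m/z (optionally jittered in ppm) plus random contaminant peaks."""
    rng = np.random.default_rng(seed)
    if rt is None:
        rt = candidate_rt(candidate, rt_coeffs)
    peaks = []
    for _, frag_mz in candidate.products:
        jitter = rng.normal(0.0, ms2_ppm_sd) if ms2_ppm_sd else 0.0
        peaks.append(
            (frag_mz * (1.0 + jitter * 1e-6), base_intensity * float(rng.uniform(0.5, 1.0)))
        )
    for _ in range(n_contaminants):
        peaks.append((float(rng.uniform(100.0, 1000.0)), float(rng.uniform(10.0, 200.0))))
    return MsmsSpectrum(
        precursor_mz=candidate.precursor_mz, rt=float(rt), peaks=tuple(peaks)
    )


def simulate_experiment(
    design: SimulationDesign,
) -> tuple[QuantTable, pd.DataFrame]:
    """Multi-group quantitative experiment with planted effects.

    Per lipid: a lognormal baseline; treated group means are baseline x
    2^(planted log2 FC); replicate values are lognormal around the group
    mean with the designed CV. PBQC injections are drawn around the
    all-sample pool mean with the same CV. Sample weights and IS
    intensities are jittered, and the returned table is produced by raw
    areas passed through the package's own normalization — so the
    normalization path is exercised, not bypassed.
    """
    rng = np.random.default_rng(design.seed)
    lipids = [c.label for c in design.resolve_candidates()]
    # one label can appear twice (two chain compositions); quantify by label
    lipids = list(dict.fromkeys(lipids))
    sigma = float(np.sqrt(np.log1p(design.cv**2)))

    samples = _sample_names(design)
    pbqc_samples = [f"PBQC_{i + 1}" for i in range(design.n_pbqc)]
    metas: list[SampleMeta] = []
    nominal_is = 50_000.0
    for s in samples:
        variety, treatment = s.split("_")[0], s.split("_")[1]
        metas.append(
            SampleMeta(
                sample_id=s,
                group=f"{variety}:{treatment}",
                weight_mg=float(rng.uniform(250.0, 300.0)),
                is_intensity=nominal_is * float(rng.lognormal(0.0, 0.1)),
            )
        )
    for s in pbqc_samples:
        metas.append(
            SampleMeta(
                sample_id=s,
                group="PBQC",
                weight_mg=275.0,
                is_intensity=nominal_is * float(rng.lognormal(0.0, 0.1)),
                is_pbqc=True,
            )
        )
    meta_map = {m.sample_id: m for m in metas}
    ref_is = float(np.median([m.is_intensity for m in metas]))

    manifest_rows = []
    values = np.empty((len(lipids), len(samples) + len(pbqc_samples)))
    for li, lipid in enumerate(lipids):
        baseline = float(rng.lognormal(np.log(5_000.0), 0.5))
        fc = design.planted_fc(lipid)
        group_means = {}
        for v in design.varieties:
            group_means[(v, design.treatments[0])] = baseline
            group_means[(v, design.treatments[1])] = baseline * 2.0**fc
        row = []
        for s in samples:
            v, t = s.split("_")[0], s.split("_")[1]
            mu = group_means[(v, t)]
            row.append(mu * float(rng.lognormal(-(sigma**2) / 2.0, sigma)))
        pool_mean = float(np.mean(row))
        for _ in pbqc_samples:
            row.append(pool_mean * float(rng.lognormal(-(sigma**2) / 2.0, sigma)))
        values[li] = row
        manifest_rows.append(
            {"lipid": lipid, "planted_log2_fc": fc, "baseline": baseline, "cv": design.cv}
        )

    normalized = pd.DataFrame(values, index=lipids, columns=samples + pbqc_samples)
    # invert the normalization so normalize_table reproduces the planted values
    raw = normalized.copy()
    for s in raw.columns:
        m = meta_map[s]
        raw[s] = raw[s] * (m.is_intensity / ref_is) * (m.weight_mg / 250.0)
    table = normalize_table(raw, metas)
    manifest = pd.DataFrame(manifest_rows)
    return table, manifest
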