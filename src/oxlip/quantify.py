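"""Fragment-ion chromatogram extraction, peak integration, class-specific
quantification rules, normalization and pooled-QC filtering.

Quantification is fragment-based: for each targeted species the extracted
ion count chromatograms (EICCs) of its class-prescribed fragment ions are
integrated separately and summed (per-fragment-then-sum). Raw areas are
scaled by internal-standard response and fresh sample weight to the value
equivalent to 250 mg of tissue, and analytes whose pooled-QC coefficient of
variation is 25% or more are removed before statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .annotate import MsmsSpectrum
from .chem import monoisotopic_mass, WATER

__all__ = [
    "ChromatogramTrace",
    "IntegrationParams",
    "ClassQuantRule",
    "QuantSpecies",
    "SampleMeta",
    "QuantTable",
    "DEFAULT_QUANT_RULES",
    "extract_eicc",
    "integrate_peak",
    "class_quantify",
    "normalize",
    "reference_is_intensity",
    "normalize_table",
    "pbqc_filter",
]

_WATER_MASS = monoisotopic_mass(WATER)


@dataclass(frozen=True)
class ChromatogramTrace:
    """An EICC: strictly increasing times (minutes) and intensities."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("negative intensity in trace")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.times.size


def extract_eicc(
    spectra: Sequence[MsmsSpectrum], target_mz: float, width_ppm: float = 100.0
) -> ChromatogramTrace:
    """Per-scan summed intensity within a ±width_ppm/2 window around
    ``target_mz``; zero where no peaks fall in the window. Scans sharing a
    retention time (e.g. interleaved PRM transitions) are merged by sum.
    """
    half = target_mz * (width_ppm / 2.0) * 1e-6
    by_time: dict[float, float] = {}
    for s in spectra:
        value = sum(i for m, i in s.peaks if abs(m - target_mz) <= half)
        by_time[s.rt] = by_time.get(s.rt, 0.0) + value
    times = np.array(sorted(by_time), dtype=float)
    intens = np.array([by_time[t] for t in times], dtype=float)
    return ChromatogramTrace(times, intens)


@dataclass(frozen=True)
class IntegrationParams:
    """Vendor-style integration settings.

    ``smooth_points`` is the Gaussian kernel sigma in sample intervals.
    ``noise_pct`` sets the baseline threshold as that percentage of the
    trace's robust background (the median intensity): 0 keeps the whole
    trace, larger values keep a progressively tighter region around the
    apex, and the threshold is monotone in the parameter.
    """

    noise_pct: float = 40.0
    smooth_points: float = 2.0


def integrate_peak(
    trace: ChromatogramTrace, params: IntegrationParams = IntegrationParams()
) -> float:
    """Area of the apex peak: Gaussian-smooth, threshold at
    noise_pct% of the background, trapezoid-integrate the contiguous
    above-threshold region containing the apex (raw intensities)."""
    if len(trace) == 0:
        raise ValueError("cannot integrate an empty trace")
    y = trace.intensities
    if not np.any(y > 0):
        return 0.0
    smoothed = gaussian_filter1d(y, sigma=params.smooth_points, mode="nearest")
    background = float(np.median(smoothed))
    threshold = (params.noise_pct / 100.0) * background
    apex = int(np.argmax(smoothed))
    if threshold <= 0:
        lo, hi = 0, len(y) - 1
    else:
        mask = smoothed > threshold
        if not mask[apex]:
            return 0.0
        lo = apex
        while lo > 0 and mask[lo - 1]:
            lo -= 1
        hi = apex
        while hi < len(y) - 1 and mask[hi + 1]:
            hi += 1
    if hi == lo:
        return 0.0
    return float(np.trapezoid(y[lo : hi + 1], trace.times[lo : hi + 1]))


@dataclass(frozen=True)
class QuantSpecies:
    """A species to quantify: name, rule category, and its base ions.

    ``ions`` meaning depends on the category: chain carboxylate anions for
    diacyl GP/GL/CL, FA-neutral-loss products for DAG, the LCB ion for
    Cer/HexCer, the dehydrated backbone ion for ST.
    """

    name: str
    category: str
    ions: tuple[float, ...]


def _chain_fragments(sp: QuantSpecies) -> tuple[float, ...]:
    return sp.ions


def _lcb_ladder(sp: QuantSpecies) -> tuple[float, ...]:
    lcb = sp.ions[0]
    return (lcb, lcb - _WATER_MASS, lcb - 2 * _WATER_MASS, lcb - 3 * _WATER_MASS)


def _single_backbone(sp: QuantSpecies) -> tuple[float, ...]:
    return (sp.ions[0],)


@dataclass(frozen=True)
class ClassQuantRule:
    """Which fragment EICCs are integrated and summed for a category."""

    category: str
    polarity: str
    fragment_selector: Callable[[QuantSpecies], tuple[float, ...]]


#: One rule per quantified category.
DEFAULT_QUANT_RULES: dict[str, ClassQuantRule] = {
    "GP": ClassQuantRule("GP", "negative", _chain_fragments),
    "GL": ClassQuantRule("GL", "negative", _chain_fragments),
    "CL": ClassQuantRule("CL", "negative", _chain_fragments),
    "DAG": ClassQuantRule("DAG", "positive", _chain_fragments),
    "Cer": ClassQuantRule("Cer", "positive", _lcb_ladder),
    "HexCer": ClassQuantRule("HexCer", "positive", _lcb_ladder),
    "ST": ClassQuantRule("ST", "positive", _single_backbone),
}


def class_quantify(
    species: QuantSpecies,
    spectra: Sequence[MsmsSpectrum],
    rule: ClassQuantRule | None = None,
    width_ppm: float = 100.0,
    params: IntegrationParams = IntegrationParams(),
) -> float:
    """Raw area for one species: sum of the integrated EICC of every
    fragment the class rule prescribes (order-independent)."""
    if rule is None:
        try:
            rule = DEFAULT_QUANT_RULES[species.category]
        except KeyError:
            raise KeyError(f"no quantification rule for category {species.category!r}") from None
    elif rule.category != species.category:
        raise KeyError(
            f"rule for {rule.category!r} applied to species of category {species.category!r}"
        )
    total = 0.0
    for frag_mz in rule.fragment_selector(species):
        trace = extract_eicc(spectra, frag_mz, width_ppm)
        if len(trace):
            total += integrate_peak(trace, params)
    return total


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata used for normalization and QC."""

    sample_id: str
    group: str  # variety x treatment, e.g. "Keel:salt"
    weight_mg: float
    is_intensity: float  # internal-standard observed response
    is_pbqc: bool = False

    def __post_init__(self) -> None:
        if self.weight_mg <= 0:
            raise ValueError(f"sample {self.sample_id}: weight must be positive")
        if self.is_intensity <= 0:
            raise ValueError(f"sample {self.sample_id}: IS intensity must be positive")


def reference_is_intensity(metas: Sequence[SampleMeta]) -> float:
    """Batch reference internal-standard response: the batch median."""
    if not metas:
        raise ValueError("no sample metadata")
    return float(np.median([m.is_intensity for m in metas]))


def normalize(raw_area: float, meta: SampleMeta, reference_is: float) -> float:
    """Scale a raw area to the 250 mg-equivalent, IS-corrected value:
    raw x (reference_is / is_intensity) x (250 / weight_mg)."""
    if reference_is <= 0:
        raise ValueError("reference IS intensity must be positive")
    return raw_area * (reference_is / meta.is_intensity) * (250.0 / meta.weight_mg)


@dataclass
class QuantTable:
    """Lipid x sample matrix of normalized abundances plus metadata.

    ``values`` is a DataFrame indexed by lipid with one column per sample;
    ``metas`` maps sample id -> :class:`SampleMeta`. ``pbqc_cv`` is filled
    by :func:`pbqc_filter`.
    """

    values: pd.DataFrame
    metas: dict[str, SampleMeta]
    pbqc_cv: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.metas)
        if missing:
            raise KeyError(f"samples without metadata: {sorted(missing)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalized abundances must be non-negative")

    @property
    def pbqc_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.metas[s].is_pbqc]

    @property
    def biological_samples(self) -> list[str]:
        return [s for s in self.values.columns if not self.metas[s].is_pbqc]


def normalize_table(
    raw_areas: pd.DataFrame, metas: Sequence[SampleMeta]
) -> QuantTable:
    """Normalize a lipid x sample raw-area table sample-by-sample."""
    meta_map = {m.sample_id: m for m in metas}
    ref = reference_is_intensity(list(meta_map.values()))
    out = raw_areas.copy().astype(float)
    for sample in out.columns:
        if sample not in meta_map:
            raise KeyError(f"no metadata for sample {sample!r}")
        m = meta_map[sample]
        out[sample] = out[sample] * (ref / m.is_intensity) * (250.0 / m.weight_mg)
    return QuantTable(values=out, metas=meta_map)


def pbqc_filter(
    table: QuantTable, cv_max: float = 25.0
) -> tuple[QuantTable, pd.DataFrame]:
    """Remove lipids whose pooled-QC CV is >= cv_max percent.

    CV = 100 x sd / mean over the PBQC injections (sample sd, ddof=1),
    defined only where the PBQC mean is positive; lipids with zero PBQC
    mean are removed with CV reported as NaN. Returns the filtered table
    and a report with per-lipid CV, the retained flag, and the median CV of
    retained lipids in ``report.attrs['median_cv_retained']``.
    """
    pbqc = table.pbqc_samples
    if len(pbqc) < 2:
        raise ValueError("PBQC CV needs at least 2 PBQC injections")
    sub = table.values[pbqc]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    cv = pd.Series(np.where(mean > 0, 100.0 * sd / mean, np.nan), index=sub.index, name="cv_pct")
    retained = cv.notna() & (cv < cv_max)
    report = pd.DataFrame({"cv_pct": cv, "retained": retained})
    report.attrs["median_cv_retained"] = float(cv[retained].median()) if retained.any() else np.nan
    filtered = QuantTable(
        values=table.values.loc[retained],
        metas=table.metas,
        pbqc_cv=cv[retained],
    )
    return filtered, report
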