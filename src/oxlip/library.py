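"""In-silico library of candidate oxidized diacyl membrane lipids.

Candidates are assembled constructively: a glycerol backbone is esterified
with two fatty acyl chains (losing one water per ester bond) and a
class-specific head-group increment is added. Seven diacyl classes are
covered — the glycerophospholipids PC, PE, PG, PI, PS and the plastid
galactolipids MGDG, DGDG. Negative-mode precursor ions are the acetate
adduct for PC and the galactolipids, the deprotonated molecule for PE, PG
and PI, and the serine-loss ion [M-H-87.032]- for PS; this per-class
assignment was inferred by reconciling the curated reference masses, the
source data do not state it explicitly.

Each candidate predicts one carboxylate-anion product per chain, with the
dehydration rule applied to di-oxygenated chains (see
:func:`oxlip.chem.carboxylate_fragment_mz`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import (
    ACETATE,
    DEFAULT_ISOTOPES,
    GLYCEROL,
    PROTON,
    SERINE_HEAD_LOSS,
    WATER,
    AcylChain,
    AdductSpec,
    ElementalFormula,
    IsotopeTable,
    monoisotopic_mass,
)

__all__ = [
    "LipidClassSpec",
    "OxLipidCandidate",
    "LIPID_CLASSES",
    "DEFAULT_NORMAL_FAS",
    "DEFAULT_OX_CHAINS",
    "CORE_OX_CHAINS",
    "neutral_formula",
    "precursor_mz",
    "enumerate_candidates",
    "export_transitions",
    "read_transitions",
    "load_curated_reference",
]


@dataclass(frozen=True)
class LipidClassSpec:
    """A diacyl lipid class: head-group increment plus adduct rule.

    ``head_increment`` is added to the diacylglycerol core with the water
    of condensation already netted out.
    """

    name: str
    head_increment: ElementalFormula
    adduct: AdductSpec
    diagnostic_head_fragments: tuple[float, ...] = ()


_ADDUCT_ACETATE = AdductSpec("[M+OAc]-", gains=ACETATE)
_ADDUCT_DEPROT = AdductSpec("[M-H]-", losses=PROTON)
_ADDUCT_SERINE_LOSS = AdductSpec("[M-H-C3H5NO2]-", losses=PROTON + SERINE_HEAD_LOSS)

#: The seven supported diacyl classes, in reporting order.
LIPID_CLASSES: dict[str, LipidClassSpec] = {
    "PC": LipidClassSpec("PC", ElementalFormula.parse("C5H12NO3P"), _ADDUCT_ACETATE),
    "PE": LipidClassSpec("PE", ElementalFormula.parse("C2H6NO3P"), _ADDUCT_DEPROT),
    "PG": LipidClassSpec("PG", ElementalFormula.parse("C3H7O5P"), _ADDUCT_DEPROT),
    "PI": LipidClassSpec("PI", ElementalFormula.parse("C6H11O8P"), _ADDUCT_DEPROT),
    "PS": LipidClassSpec("PS", ElementalFormula.parse("C3H6NO5P"), _ADDUCT_SERINE_LOSS),
    "MGDG": LipidClassSpec("MGDG", ElementalFormula.parse("C6H10O5"), _ADDUCT_ACETATE),
    "DGDG": LipidClassSpec("DGDG", ElementalFormula.parse("C12H20O10"), _ADDUCT_ACETATE),
}

#: The three most abundant normal fatty acids in barley-root membrane lipids.
DEFAULT_NORMAL_FAS: tuple[AcylChain, ...] = (
    AcylChain(16, 0),
    AcylChain(18, 2),
    AcylChain(18, 3),
)

#: Default 18-carbon oxylipin chain types. The canonical five are 18:2-O,
#: 18:3-O, 18:4-O, 18:2-2O and 18:3-2O; 18:4-2O is additionally included
#: because the confirmed barley-root set contains PS(34:4)-2O (monitored ion
#: 699.424, which only a 16:0/18:4-2O composition reproduces to <1 mDa) and a
#: targeted library that cannot express a confirmed species is defective.
DEFAULT_OX_CHAINS: tuple[AcylChain, ...] = (
    AcylChain(18, 2, 1),
    AcylChain(18, 3, 1),
    AcylChain(18, 4, 1),
    AcylChain(18, 2, 2),
    AcylChain(18, 3, 2),
    AcylChain(18, 4, 2),
)

#: The five oxylipin types explicitly named in the source workflow text.
CORE_OX_CHAINS: tuple[AcylChain, ...] = DEFAULT_OX_CHAINS[:5]


def neutral_formula(
    lipid_class: LipidClassSpec, chain1: AcylChain, chain2: AcylChain
) -> ElementalFormula:
    """Neutral molecular formula of a diacyl species.

    glycerol + free acid(chain1) + free acid(chain2) - 2 H2O + head increment;
    symmetric under chain swap.
    """
    core = GLYCEROL + chain1.free_acid_formula() + chain2.free_acid_formula()
    core = (core - WATER) - WATER
    return core + lipid_class.head_increment


def _species_label(class_name: str, chain1: AcylChain, chain2: AcylChain) -> str:
    carbons = chain1.carbons + chain2.carbons
    dbs = chain1.double_bonds + chain2.double_bonds
    extra = chain1.extra_oxygens + chain2.extra_oxygens
    label = f"{class_name}({carbons}:{dbs})"
    if extra == 1:
        label += "-O"
    elif extra > 1:
        label += f"-{extra}O"
    return label


def _observed_fragment_chain(chain: AcylChain) -> AcylChain:
    """Chain identity of the observed carboxylate anion after dehydration."""
    if chain.extra_oxygens == 2:
        return AcylChain(chain.carbons, chain.double_bonds + 1, 1)
    return chain


@dataclass(frozen=True)
class OxLipidCandidate:
    """One candidate species, keyed by exact chain composition.

    Two chain compositions can share a species label (e.g. PE(18:2-O/18:3)
    and PE(18:3-O/18:2) are both PE(36:5)-O); both are kept as distinct
    candidates and reporting may aggregate by label.
    """

    lipid_class: LipidClassSpec
    chain1: AcylChain
    chain2: AcylChain
    neutral: ElementalFormula = field(compare=False)
    precursor_mz: float = field(compare=False)
    #: (fragment label, m/z) — one entry per chain, dehydration applied.
    products: tuple[tuple[str, float], ...] = field(compare=False)

    @property
    def label(self) -> str:
        return _species_label(self.lipid_class.name, self.chain1, self.chain2)

    @property
    def chain_composition(self) -> str:
        a, b = sorted((self.chain1, self.chain2))
        return f"{a.label()}/{b.label()}"

    @property
    def total_extra_oxygens(self) -> int:
        return self.chain1.extra_oxygens + self.chain2.extra_oxygens

    @property
    def oxidized_products(self) -> tuple[tuple[str, float], ...]:
        """Products arising from oxidized chains (required for MS/MS tiering)."""
        return tuple(
            p
            for p, chain in zip(self.products, (self.chain1, self.chain2))
            if chain.is_oxidized
        )

    @classmethod
    def build(
        cls,
        lipid_class: LipidClassSpec,
        chain1: AcylChain,
        chain2: AcylChain,
        iso: IsotopeTable = DEFAULT_ISOTOPES,
    ) -> "OxLipidCandidate":
        neutral = neutral_formula(lipid_class, chain1, chain2)
        products = []
        for chain in (chain1, chain2):
            obs = _observed_fragment_chain(chain)
            frag = obs.free_acid_formula() - PROTON
            products.append((obs.label(), monoisotopic_mass(frag, iso)))
        return cls(
            lipid_class=lipid_class,
            chain1=chain1,
            chain2=chain2,
            neutral=neutral,
            precursor_mz=lipid_class.adduct.mz(neutral, iso),
            products=tuple(products),
        )


def precursor_mz(candidate: OxLipidCandidate) -> float:
    """Negative-mode precursor m/z under the candidate's class adduct rule."""
    return candidate.lipid_class.adduct.mz(candidate.neutral)


def enumerate_candidates(
    classes: Iterable[LipidClassSpec] | None = None,
    normal_fas: Sequence[AcylChain] = DEFAULT_NORMAL_FAS,
    ox_chains: Sequence[AcylChain] = DEFAULT_OX_CHAINS,
    iso: IsotopeTable = DEFAULT_ISOTOPES,
) -> list[OxLipidCandidate]:
    """Enumerate all candidate oxidized diacyl species.

    Every unordered (normal FA, oxylipin) and (oxylipin, oxylipin) pairing —
    self-pairings included — is generated for every class, keeping only
    combinations whose total extra-oxygen count lies in 1..4. Output order
    is deterministic: class order as given, then total carbons, double
    bonds, extra oxygens, then chain composition.
    """
    if classes is None:
        classes = LIPID_CLASSES.values()
    classes = list(classes)
    if not classes or not list(normal_fas) or not list(ox_chains):
        raise ValueError("classes, normal_fas and ox_chains must all be non-empty")

    pairs: set[tuple[AcylChain, AcylChain]] = set()
    for normal in normal_fas:
        for ox in ox_chains:
            pairs.add(tuple(sorted((normal, ox))))  # type: ignore[arg-type]
    for i, ox1 in enumerate(ox_chains):
        for ox2 in ox_chains[i:]:
            pairs.add(tuple(sorted((ox1, ox2))))  # type: ignore[arg-type]

    out: list[OxLipidCandidate] = []
    for order, cls_spec in enumerate(classes):
        for c1, c2 in pairs:
            total_extra = c1.extra_oxygens + c2.extra_oxygens
            if not 1 <= total_extra <= 4:
                continue
            out.append(OxLipidCandidate.build(cls_spec, c1, c2, iso))
    class_order = {cls_spec.name: i for i, cls_spec in enumerate(classes)}
    out.sort(
        key=lambda c: (
            class_order[c.lipid_class.name],
            c.chain1.carbons + c.chain2.carbons,
            c.chain1.double_bonds + c.chain2.double_bonds,
            c.total_extra_oxygens,
            c.chain_composition,
        )
    )
    return out


_TRANSITION_COLUMNS = [
    "species",
    "chain_composition",
    "precursor_mz",
    "product_label",
    "product_mz",
    "rt_window_start_min",
    "rt_window_end_min",
    "polarity",
]


def export_transitions(
    candidates: Sequence[OxLipidCandidate],
    rt_windows: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Scheduled-MRM transition list: one row per (candidate, product ion).

    ``rt_windows`` maps species label -> (start, end) in minutes; species
    without a window are scheduled unbounded (empty cells). Row order
    follows candidate order, products in chain order.
    """
    if not candidates:
        raise ValueError("no candidates to export")
    rt_windows = rt_windows or {}
    rows = []
    for cand in candidates:
        window = rt_windows.get(cand.label)
        for frag_label, frag_mz in cand.products:
            rows.append(
                {
                    "species": cand.label,
                    "chain_composition": cand.chain_composition,
                    "precursor_mz": round(cand.precursor_mz, 4),
                    "product_label": frag_label,
                    "product_mz": round(frag_mz, 4),
                    "rt_window_start_min": window[0] if window else None,
                    "rt_window_end_min": window[1] if window else None,
                    "polarity": "negative",
                }
            )
    return pd.DataFrame(rows, columns=_TRANSITION_COLUMNS)


def read_transitions(path) -> pd.DataFrame:
    """Read back a transition list written with ``DataFrame.to_csv(index=False)``."""
    df = pd.read_csv(path)
    missing = set(_TRANSITION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transition list missing columns: {sorted(missing)}")
    return df[_TRANSITION_COLUMNS]


def load_curated_reference() -> pd.DataFrame:
    """Packaged curated list of the 38 oxidized diacyl species confirmed in
    barley roots (label-level; rows suffixed a/b are alternative chain
    compositions of one species).

    Columns: no, lipid_class, species, precursor_detected,
    precursor_theoretical, ox_fa_fragment, fa_fragment, rt_min,
    precursor_mass_error_ppm. Printed fragment values are transcribed as
    printed; matching elsewhere in the package always uses computed values.
    """
    ref = resources.files("oxlip.data").joinpath("curated_ox_lipids.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"no": str})
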