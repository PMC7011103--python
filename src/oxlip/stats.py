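"""Differential abundance of lipids between treatments.

Per lipid and variety: log2 fold change of group means, a two-sample
Student t-test (equal-variance by default; Welch by flag), and
Benjamini-Hochberg FDR adjustment within each variety's family of tests.
Class-level summaries aggregate member abundances before the log
transform. The model surface follows statsmodels conventions:
``DifferentialAbundance(...).fit()`` returns a results object carrying the
per-lipid table, class summaries and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log2_fold_change",
    "t_test",
    "bh_adjust",
    "summarize_classes",
    "ContrastResult",
    "DifferentialAbundance",
    "DifferentialAbundanceResults",
]


def log2_fold_change(treated: Sequence[float], control: Sequence[float]) -> float:
    """log2 of the ratio of group means; NaN when the control mean is not
    positive (undefined ratio, reported as missing downstream)."""
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    mc = control.mean()
    mt = treated.mean()
    if mc <= 0 or mt <= 0:
        return float("nan")
    return float(np.log2(mt / mc))


def t_test(
    treated: Sequence[float], control: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test; Student (pooled variance) by default.

    Degenerate input with zero variance in both groups and equal means is
    reported as (t=0, p=1) by convention.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size < 2 or control.size < 2:
        raise ValueError("t-test needs n >= 2 per group")
    if treated.std(ddof=1) == 0 and control.std(ddof=1) == 0:
        if treated.mean() == control.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(treated.mean() - control.mean()), 0.0
    t, p = sps.ttest_ind(treated, control, equal_var=equal_var)
    return float(t), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, aligned to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ContrastResult:
    lipid: str
    group_pair: tuple[str, str]
    log2_fc: float
    t_statistic: float
    p_value: float
    adjusted_p: float


def summarize_classes(
    quant: pd.DataFrame,
    design: pd.DataFrame,
    lipid_classes: Mapping[str, str],
    treatment: str = "salt",
    control: str = "control",
    standardize: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class totals and a heatmap-ready matrix of group means.

    ``quant``: lipid x sample abundances. ``design``: one row per sample
    with columns sample, variety, treatment. Returns (class_fc, matrix):
    class_fc has one row per (class, variety) with the log2 FC of the class
    total; matrix is lipid x "variety:treatment" group means, optionally
    row-standardized (mean 0, sd 1). Classes with no members are omitted.
    """
    design = design.set_index("sample") if "sample" in design.columns else design
    missing = set(quant.columns) - set(design.index)
    if missing:
        raise KeyError(f"samples missing from design: {sorted(missing)}")

    cls = pd.Series({lip: lipid_classes.get(lip) for lip in quant.index})
    known = cls.dropna()
    class_rows = []
    for class_name, members in known.groupby(known).groups.items():
        totals = quant.loc[list(members)].sum(axis=0)
        for variety, dsub in design.groupby("variety"):
            t_samples = dsub.index[dsub["treatment"] == treatment]
            c_samples = dsub.index[dsub["treatment"] == control]
            if len(t_samples) == 0 or len(c_samples) == 0:
                continue
            class_rows.append(
                {
                    "lipid_class": class_name,
                    "variety": variety,
                    "log2_fc": log2_fold_change(totals[t_samples], totals[c_samples]),
                }
            )
    class_fc = pd.DataFrame(class_rows, columns=["lipid_class", "variety", "log2_fc"])

    cols = {}
    for (variety, treat), dsub in design.groupby(["variety", "treatment"]):
        cols[f"{variety}:{treat}"] = quant[dsub.index].mean(axis=1)
    matrix = pd.DataFrame(cols)
    if standardize:
        mu = matrix.mean(axis=1)
        sd = matrix.std(axis=1, ddof=1).replace(0, np.nan)
        matrix = matrix.sub(mu, axis=0).div(sd, axis=0)
    return class_fc, matrix


class DifferentialAbundance:
    """Per-lipid treated-vs-control contrasts within each variety.

    Parameters
    ----------
    quant : DataFrame
        Lipid x sample normalized abundances.
    design : DataFrame
        One row per sample with columns ``sample``, ``variety``,
        ``treatment``.
    lipid_classes : mapping, optional
        Lipid -> class label, used for class summaries.
    """

    def __init__(
        self,
        quant: pd.DataFrame,
        design: pd.DataFrame,
        lipid_classes: Mapping[str, str] | None = None,
    ) -> None:
        if "sample" in design.columns:
            design = design.set_index("sample")
        for col in ("variety", "treatment"):
            if col not in design.columns:
                raise KeyError(f"design is missing the {col!r} column")
        missing = set(quant.columns) - set(design.index)
        if missing:
            raise KeyError(f"samples missing from design: {sorted(missing)}")
        self.quant = quant
        self.design = design.loc[list(quant.columns)]
        self.lipid_classes = dict(lipid_classes or {})

    @classmethod
    def from_quant_table(cls, table, lipid_classes=None) -> "DifferentialAbundance":
        """Build from a :class:`oxlip.quantify.QuantTable`, using only
        biological (non-PBQC) samples and ``group`` labels of the form
        ``variety:treatment``."""
        samples = table.biological_samples
        rows = []
        for s in samples:
            variety, _, treatment = table.metas[s].group.partition(":")
            rows.append({"sample": s, "variety": variety, "treatment": treatment})
        return cls(table.values[samples], pd.DataFrame(rows), lipid_classes)

    def fit(
        self,
        treatment: str = "salt",
        control: str = "control",
        equal_var: bool = True,
        alpha: float = 0.05,
    ) -> "DifferentialAbundanceResults":
        rows = []
        for variety, dsub in self.design.groupby("variety"):
            t_samples = dsub.index[dsub["treatment"] == treatment]
            c_samples = dsub.index[dsub["treatment"] == control]
            if len(t_samples) < 2 or len(c_samples) < 2:
                raise ValueError(
                    f"variety {variety!r} needs >= 2 samples per treatment arm"
                )
            for lipid in self.quant.index:
                tv = self.quant.loc[lipid, t_samples].to_numpy(dtype=float)
                cv = self.quant.loc[lipid, c_samples].to_numpy(dtype=float)
                fc = log2_fold_change(tv, cv)
                t, p = t_test(tv, cv, equal_var=equal_var)
                rows.append(
                    {
                        "lipid": lipid,
                        "lipid_class": self.lipid_classes.get(lipid, ""),
                        "variety": variety,
                        "log2_fc": fc,
                        "t": t,
                        "p": p,
                        "n_treated": len(t_samples),
                        "n_control": len(c_samples),
                        "note": "" if np.isfinite(fc) else "undefined FC: non-positive group mean",
                    }
                )
        table = pd.DataFrame(rows)
        # FDR within each variety's contrast family
        table["p_adj"] = np.nan
        for variety, idx in table.groupby("variety").groups.items():
            table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p"].to_numpy())
        table = table[
            [
                "lipid",
                "lipid_class",
                "variety",
                "log2_fc",
                "t",
                "p",
                "p_adj",
                "n_treated",
                "n_control",
                "note",
            ]
        ]
        return DifferentialAbundanceResults(
            model=self,
            table=table,
            treatment=treatment,
            control=control,
            equal_var=equal_var,
            alpha=alpha,
        )


class DifferentialAbundanceResults:
    """Fitted contrasts: per-lipid table, class summaries, heatmap matrix."""

    def __init__(self, model, table, treatment, control, equal_var, alpha) -> None:
        self.model = model
        self.table = table
        self.treatment = treatment
        self.control = control
        self.equal_var = equal_var
        self.alpha = alpha

    @property
    def n_significant(self) -> pd.Series:
        """Number of FDR-significant lipids per variety."""
        sig = self.table[self.table["p_adj"] < self.alpha]
        return sig.groupby("variety").size().reindex(
            sorted(self.table["variety"].unique()), fill_value=0
        )

    def class_summary(self) -> pd.DataFrame:
        fc, _ = summarize_classes(
            self.model.quant,
            self.model.design.reset_index(names="sample"),
            self.model.lipid_classes,
            treatment=self.treatment,
            control=self.control,
        )
        return fc

    def heatmap_matrix(self, standardize: bool = True) -> pd.DataFrame:
        _, matrix = summarize_classes(
            self.model.quant,
            self.model.design.reset_index(names="sample"),
            self.model.lipid_classes,
            treatment=self.treatment,
            control=self.control,
            standardize=standardize,
        )
        return matrix

    def contrasts(self) -> list[ContrastResult]:
        return [
            ContrastResult(
                lipid=r.lipid,
                group_pair=(self.treatment, self.control),
                log2_fc=r.log2_fc,
                t_statistic=r.t,
                p_value=r.p,
                adjusted_p=r.p_adj,
            )
            for r in self.table.itertuples()
        ]

    def summary(self) -> str:
        test_name = "Student t (pooled)" if self.equal_var else "Welch t"
        lines = [
            "Differential lipid abundance",
            "=" * 60,
            f"contrast:     {self.treatment} vs {self.control}",
            f"test:         {test_name}, two-sided",
            f"adjustment:   Benjamini-Hochberg within each variety",
            f"lipids:       {self.table['lipid'].nunique()}",
            f"varieties:    {', '.join(sorted(self.table['variety'].unique()))}",
            "",
            f"FDR-significant lipids (q < {self.alpha:g}) per variety:",
        ]
        for variety, n in self.n_significant.items():
            lines.append(f"  {variety:<12} {n}")
        return "\n".join(lines)
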