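"""Per-CpG methylation tables: variability classification and phenotyping.

A methylation table holds bisulphite-pyrosequencing measurements as tidy
records (locus, individual, CpG index, percent).  Downstream decisions are
made on per-individual means across a locus's CpGs: loci whose individual
means span more than a threshold (default 10 percentage points) are called
variably methylated; individuals are dichotomised into high/low phenotype
classes at a cutoff (default 60%, strictly-greater rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds

__all__ = [
    "MethylationTable",
    "individual_means",
    "classify_variability",
    "threshold_classify",
    "distribution_summary",
    "DistributionSummary",
]

_COLUMNS = ["locus", "individual", "cpg_index", "percent"]


class MethylationTable:
    """Tidy container of per-CpG methylation percentages."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"methylation table missing columns: {missing}")
        df = df.loc[:, _COLUMNS].copy()
        df["percent"] = df["percent"].astype(float)
        if ((df["percent"] < 0) | (df["percent"] > 100)).any():
            raise ValueError("methylation percentages must lie in [0, 100]")
        self._df = df

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def loci(self) -> List[str]:
        return sorted(self._df["locus"].unique())

    @property
    def individuals(self) -> List[str]:
        return sorted(self._df["individual"].unique())

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "MethylationTable":
        return cls(pd.DataFrame(list(records)))

    @classmethod
    def from_csv(cls, path) -> "MethylationTable":
        return cls(pd.read_csv(path, dtype={"locus": str, "individual": str}))

    @classmethod
    def from_wide(cls, df: pd.DataFrame, locus: str) -> "MethylationTable":
        """Wide per-locus layout: rows = individuals, columns = CpGs."""
        records = []
        for ind, row in df.iterrows():
            for j, v in enumerate(row.values):
                records.append(
                    {"locus": locus, "individual": str(ind), "cpg_index": j, "percent": float(v)}
                )
        return cls(pd.DataFrame(records))

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)

    def individual_means(self, locus: str) -> pd.Series:
        return individual_means(self, locus)


def individual_means(table: MethylationTable, locus: str) -> pd.Series:
    """Arithmetic mean across a locus's CpGs, one value per individual,
    index sorted by individual id."""
    sub = table.df[table.df["locus"] == locus]
    if sub.empty:
        raise KeyError(f"unknown locus {locus!r}")
    means = sub.groupby("individual")["percent"].mean()
    return means.sort_index()


def classify_variability(means: Sequence[float], thresholds: Thresholds = Thresholds()) -> str:
    """Variable / hypermethylated / hypomethylated / intermediate-nonvariable.

    A locus is *variable* when the spread of its per-individual means
    exceeds ``thresholds.variability_spread`` (interpreted as the range
    max-min by default, or as the variance when
    ``thresholds.variability_mode == "variance"``).  Non-variable loci are
    subtyped by their group mean.
    """
    x = np.asarray(list(means), dtype=float)
    if x.size < 2:
        raise ValueError("classify_variability requires >= 2 individuals")
    if thresholds.variability_mode == "range":
        spread = float(x.max() - x.min())
    else:
        spread = float(np.var(x, ddof=1))
    if spread > thresholds.variability_spread:
        return "variable"
    m = float(x.mean())
    if m >= thresholds.hyper_bound:
        return "hypermethylated"
    if m <= thresholds.hypo_bound:
        return "hypomethylated"
    return "intermediate-nonvariable"


def threshold_classify(value: float, thresholds: Thresholds = Thresholds()) -> str:
    """High/low phenotype call: high iff strictly above the cutoff
    (a value exactly at the cutoff is low)."""
    if not 0 <= value <= 100:
        raise ValueError("methylation value outside [0, 100]")
    return "high" if value > thresholds.high_low_cutoff else "low"


@dataclass(frozen=True)
class DistributionSummary:
    median: float
    q1: float
    q3: float
    skewness: float
    normal: bool
    shapiro_p: float


def distribution_summary(means: Sequence[float], alpha: float = 0.05) -> DistributionSummary:
    """Median, quartiles (linear interpolation), adjusted Fisher-Pearson
    skewness, and a Shapiro-Wilk normality flag."""
    x = np.asarray(list(means), dtype=float)
    if x.size < 3:
        raise ValueError("distribution_summary requires n >= 3")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    skew = float(stats.skew(x, bias=False))  # n/((n-1)(n-2)) adjusted form
    if np.allclose(x, x[0]):
        sh_p = 1.0
    else:
        sh_p = float(stats.shapiro(x).pvalue)
    return DistributionSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        skewness=skew, normal=sh_p >= alpha, shapiro_p=sh_p,
    )
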