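"""Backcross modifier-locus mapping by phenotype-stratified SNP intersection.

The mapping rule: a marker is a *candidate* iff it is heterozygous in all
highly methylated individuals and homozygous-B6 in all lowly methylated
individuals.  Candidate positions per chromosome define an inner interval
(candidate span) and an outer interval extending to the nearest flanking
informative markers that failed the filter (exclusive bounds).  Two
independent mapping experiments are combined by interval intersection.

Coordinates are 0-based half-open internally; printed-style 1-based
inclusive at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .sim.pedigree import Individual, Pedigree

__all__ = [
    "CALL_HOM_B6",
    "CALL_HET",
    "CALL_HOM_CAST",
    "CALL_MISSING",
    "GenotypeMatrix",
    "GenomicInterval",
    "SegregationResult",
    "candidate_snps",
    "assemble_interval",
    "combine_experiments",
    "interval_length_mb",
    "segregation_test",
    "pedigree_consistency",
    "PedigreeConsistency",
]

CALL_HOM_B6 = 0
CALL_HET = 1
CALL_HOM_CAST = 2
CALL_MISSING = -1

_CALL_CODES = {"BB": CALL_HOM_B6, "BC": CALL_HET, "CC": CALL_HOM_CAST, "NA": CALL_MISSING}
_CALL_NAMES = {v: k for k, v in _CALL_CODES.items()}


class GenotypeMatrix:
    """Biallelic SNP calls over a sorted marker map.

    Stored as an int8 array (markers x individuals) with codes
    0=homozygous-B6, 1=heterozygous, 2=homozygous-CAST, -1=missing, plus a
    marker map DataFrame with columns chrom, pos, marker.
    """

    def __init__(self, markers: pd.DataFrame, calls: np.ndarray, individuals: Sequence[str]):
        markers = markers.reset_index(drop=True)
        if list(markers.columns[:3]) != ["chrom", "pos", "marker"]:
            raise ValueError("marker map must have columns chrom, pos, marker")
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(markers), len(individuals)):
            raise ValueError("calls shape does not match markers x individuals")
        for chrom, grp in markers.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"marker positions not sorted within {chrom}")
        self.markers = markers
        self.calls = calls
        self.individuals = list(individuals)
        self._col = {ind: i for i, ind in enumerate(self.individuals)}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        """From the genotype CSV layout (chrom,pos,marker,<individuals...>)."""
        markers = df[["chrom", "pos", "marker"]].copy()
        inds = [c for c in df.columns if c not in ("chrom", "pos", "marker")]
        calls = np.empty((len(df), len(inds)), dtype=np.int8)
        for j, ind in enumerate(inds):
            calls[:, j] = [_CALL_CODES[str(v)] for v in df[ind]]
        return cls(markers, calls, inds)

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, dtype={"chrom": str, "marker": str}, keep_default_na=False)
        return cls.from_frame(df)

    def to_frame(self) -> pd.DataFrame:
        df = self.markers.copy()
        for j, ind in enumerate(self.individuals):
            df[ind] = [_CALL_NAMES[int(v)] for v in self.calls[:, j]]
        return df

    def columns_for(self, individuals: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._col[i] for i in individuals]
        except KeyError as e:
            raise KeyError(f"individual {e.args[0]!r} absent from genotype matrix") from None
        return self.calls[:, idx]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open internally; ``bounds_kind`` records whether the
    bounds are the candidate span (inner) or the flanking-marker bound
    (outer, exclusive)."""

    chrom: str
    start: int
    end: int
    bounds_kind: str = "inner"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("interval start must be < end")

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def to_printed(self) -> str:
        """Genome-browser style: 1-based inclusive."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    @classmethod
    def from_printed(cls, text: str, bounds_kind: str = "inner") -> "GenomicInterval":
        chrom, span = text.split(":")
        lo, hi = span.replace("–", "-").split("-")
        return cls(chrom, int(lo) - 1, int(hi), bounds_kind)


@dataclass(frozen=True)
class SegregationResult:
    n_high: int
    n_low: int
    p_value: float
    consistent: bool


class MappingConflictError(ValueError):
    """Two mapping experiments produced disjoint intervals."""


def candidate_snps(
    matrix: GenotypeMatrix, labels: Mapping[str, str]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype-stratified SNP intersection filter.

    Returns ``(candidates, report)``: candidate markers (heterozygous in
    every high individual, homozygous-B6 in every low individual, no
    missing calls among labelled individuals) and a per-marker report with
    boolean columns ``candidate``, ``has_missing`` and ``genotyping_error``
    (homozygous-CAST calls, impossible in a B6 backcross).
    """
    high = [i for i, c in labels.items() if c == "high"]
    low = [i for i, c in labels.items() if c == "low"]
    if not high or not low:
        raise ValueError("both high and low phenotype groups must be non-empty")
    hi_calls = matrix.columns_for(high)
    lo_calls = matrix.columns_for(low)
    labelled = np.concatenate([hi_calls, lo_calls], axis=1)
    has_missing = (labelled == CALL_MISSING).any(axis=1)
    geno_error = (labelled == CALL_HOM_CAST).any(axis=1)
    ok = (hi_calls == CALL_HET).all(axis=1) & (lo_calls == CALL_HOM_B6).all(axis=1)
    cand_mask = ok & ~has_missing
    # a marker is a usable outer bound only if its NON-missing calls
    # already violate the filter (missingness alone is not evidence)
    ok_nonmissing = (
        ((hi_calls == CALL_HET) | (hi_calls == CALL_MISSING)).all(axis=1)
        & ((lo_calls == CALL_HOM_B6) | (lo_calls == CALL_MISSING)).all(axis=1)
    )
    report = matrix.markers.copy()
    report["candidate"] = cand_mask
    report["bound_failing"] = ~ok_nonmissing
    report["has_missing"] = has_missing
    report["genotyping_error"] = geno_error
    return matrix.markers[cand_mask].reset_index(drop=True), report


def assemble_interval(
    candidates: pd.DataFrame, marker_report: pd.DataFrame
) -> Dict[str, Dict[str, GenomicInterval]]:
    """Inner/outer mapped interval per chromosome carrying candidates.

    Inner bounds span the candidate positions (a single candidate is
    widened to 1 bp).  Outer bounds extend to the nearest flanking
    *failing* marker on each side (exclusive); a marker with missing calls
    only bounds the interval if its non-missing calls already violate the
    filter.  When candidates occur on more than one chromosome each gets
    an interval and the result is flagged multi-locus by its length.
    """
    if candidates.empty:
        raise ValueError("no candidate markers to assemble an interval from")
    out: Dict[str, Dict[str, GenomicInterval]] = {}
    for chrom, cand in candidates.groupby("chrom", sort=False):
        pos = np.sort(cand["pos"].to_numpy())
        inner = GenomicInterval(chrom, int(pos[0]), int(max(pos[-1], pos[0] + 1)), "inner")
        chrom_report = marker_report[marker_report["chrom"] == chrom]
        fail_col = "bound_failing" if "bound_failing" in chrom_report else "candidate"
        failing = (
            chrom_report[chrom_report["bound_failing"]]
            if fail_col == "bound_failing"
            else chrom_report[~chrom_report["candidate"]]
        )
        left = failing[failing["pos"] < pos[0]]["pos"]
        right = failing[failing["pos"] > pos[-1]]["pos"]
        lo = int(left.max()) if len(left) else 0
        hi = int(right.min()) if len(right) else int(chrom_report["pos"].max()) + 1
        outer = GenomicInterval(chrom, lo, hi, "outer")
        out[chrom] = {"inner": inner, "outer": outer}
    return out


def combine_experiments(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval:
    """Intersection of two mapped intervals from independent experiments."""
    if a.chrom != b.chrom:
        raise MappingConflictError(
            f"mapping experiments disagree on chromosome: {a.chrom} vs {b.chrom}"
        )
    start, end = max(a.start, b.start), min(a.end, b.end)
    if start >= end:
        raise MappingConflictError(f"disjoint mapped intervals: {a} vs {b}")
    kind = a.bounds_kind if a.bounds_kind == b.bounds_kind else "combined"
    return GenomicInterval(a.chrom, start, end, kind)


def interval_length_mb(interval: GenomicInterval) -> float:
    """(end - start) in Mb, rounded half-up to one decimal."""
    mb = Decimal(interval.end - interval.start) / Decimal(10**6)
    return float(mb.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def segregation_test(n_high: int, n_low: int, alpha: float = 0.05) -> SegregationResult:
    """Exact two-sided binomial test of the observed high:low split
    against the 1:1 Mendelian expectation for a dominant single locus."""
    n = n_high + n_low
    if n < 1:
        raise ValueError("need at least one phenotyped individual")
    p = float(stats.binomtest(n_high, n, 0.5, alternative="two-sided").pvalue)
    return SegregationResult(n_high, n_low, p, consistent=p >= alpha)


@dataclass(frozen=True)
class FamilyCheck:
    sire: str
    sire_class: str
    n_high: int
    n_low: int
    p_value: Optional[float]
    passed: bool


@dataclass(frozen=True)
class PedigreeConsistency:
    consistent: bool
    families: Tuple[FamilyCheck, ...]
    excluded: Tuple[str, ...]  # phenotyped ids without a phenotyped parent


def pedigree_consistency(
    pedigree: Pedigree,
    classes: Mapping[str, str],
    alpha: float = 0.05,
) -> PedigreeConsistency:
    """Check the single-dominant-locus inheritance rules on a phenotyped
    backcross pedigree.

    For every sire with phenotyped offspring from B6 dams: a *high* sire's
    offspring must segregate ~1:1 (binomial test), a *low* sire's
    offspring must all be low, and the rule is applied uniformly across
    generations.  The family-wise error of the overall verdict is held at
    ``alpha`` by Bonferroni-correcting the per-family binomial tests.
    Phenotyped individuals whose sire is untyped are excluded and
    reported.
    """
    families: Dict[str, List[str]] = {}
    excluded: List[str] = []
    for ind in pedigree:
        if ind.id not in classes or ind.sire_id is None:
            continue
        if ind.sire_id in classes:
            families.setdefault(ind.sire_id, []).append(ind.id)
        else:
            excluded.append(ind.id)
    n_binomial = sum(1 for s in families if classes[s] == "high")
    family_alpha = alpha / max(1, n_binomial)
    checks: List[FamilyCheck] = []
    for sire, kids in sorted(families.items()):
        sire_class = classes[sire]
        n_high = sum(classes[k] == "high" for k in kids)
        n_low = len(kids) - n_high
        if n_high + n_low == 0:
            continue
        if sire_class == "high":
            res = segregation_test(n_high, n_low, family_alpha)
            checks.append(FamilyCheck(sire, "high", n_high, n_low, res.p_value, res.consistent))
        else:
            checks.append(FamilyCheck(sire, "low", n_high, n_low, None, n_high == 0))
    consistent = all(c.passed for c in checks) if checks else True
    return PedigreeConsistency(consistent, tuple(checks), tuple(sorted(excluded)))
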