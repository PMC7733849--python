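"""Anchored, strand-aware coverage matrices and metaprofiles.

Each element's body is rescaled to a fixed pseudolength by area-weighted
binning of the coverage step function (so total signal is conserved
exactly), flanks are copied at 1-bp resolution, and minus-strand rows are
reversed so the column axis always reads 5' to 3'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import Thresholds
from .sim.coverage import BedElement

__all__ = [
    "CoverageTrack",
    "AnchoredMatrix",
    "anchored_matrix",
    "mean_profile",
    "ProfileStats",
    "group_compare",
]


class CoverageTrack:
    """Step-wise coverage with bedGraph semantics.

    Per chromosome: sorted, non-overlapping (start, end, value) runs;
    positions not covered by any run have value 0.
    """

    def __init__(self, intervals: Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._iv: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError("starts/ends/values length mismatch")
            if np.any(ends <= starts):
                raise ValueError("intervals must have positive width")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping or unsorted intervals on {chrom}")
            if not np.all(np.isfinite(values)):
                raise ValueError("coverage values must be finite")
            self._iv[chrom] = (starts, ends, values)

    @classmethod
    def from_bedgraph_frame(cls, df: pd.DataFrame) -> "CoverageTrack":
        iv = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            grp = grp.sort_values("start")
            iv[chrom] = (
                grp["start"].to_numpy(),
                grp["end"].to_numpy(),
                grp["value"].to_numpy(),
            )
        return cls(iv)

    @classmethod
    def from_bedgraph(cls, path) -> "CoverageTrack":
        from .sim.io import read_bedgraph

        return cls.from_bedgraph_frame(read_bedgraph(path))

    @classmethod
    def from_dense(cls, dense: Mapping[str, np.ndarray]) -> "CoverageTrack":
        iv = {}
        for chrom, v in dense.items():
            v = np.asarray(v, dtype=float)
            change = np.nonzero(np.diff(v))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            iv[chrom] = (starts, ends, v[starts])
        return cls(iv)

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._iv)

    def per_bp(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-bp values over [start, end); uncovered positions are 0.
        Positions before 0 are also reported as 0."""
        if end <= start:
            raise ValueError("query end must exceed start")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._iv:
            return out
        starts, ends, values = self._iv[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            a = max(int(s), start) - start
            b = min(int(e), end) - start
            if b > a:
                out[a:b] = v
        return out


@dataclass(frozen=True)
class AnchoredMatrix:
    """Rows = elements (5'->3'), columns = flank + pseudolength + flank."""

    values: np.ndarray
    element_names: Tuple[str, ...]
    flank: int
    pseudolength: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.element_names), 2 * self.flank + self.pseudolength):
            raise ValueError("matrix shape inconsistent with flank/pseudolength")

    @property
    def n_columns(self) -> int:
        return 2 * self.flank + self.pseudolength

    def body(self) -> np.ndarray:
        return self.values[:, self.flank : self.flank + self.pseudolength]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.element_names))


def _rescale_body(per_bp: np.ndarray, pseudolength: int) -> np.ndarray:
    """Area-weighted rebinning of a per-bp step function to a fixed number
    of bins; conserves the mean exactly."""
    length = per_bp.size
    if length == pseudolength:
        return per_bp.astype(float)
    cum = np.concatenate(([0.0], np.cumsum(per_bp, dtype=float)))
    edges = np.linspace(0.0, length, pseudolength + 1)
    integral = np.interp(edges, np.arange(length + 1), cum)
    return np.diff(integral) / (length / pseudolength)


def anchored_matrix(
    track: CoverageTrack,
    elements: Sequence[BedElement],
    thresholds: Thresholds = Thresholds(),
) -> AnchoredMatrix:
    """Anchored coverage matrix: each element body rescaled to
    ``thresholds.pseudolength`` bins, with ``thresholds.flank`` bp of
    unscaled flank on each side; minus-strand rows reversed."""
    flank, pseudo = thresholds.flank, thresholds.pseudolength
    rows = []
    names = []
    for el in elements:
        if el.length < 2:
            raise ValueError(f"element {el.name!r} shorter than 2 bp")
        up = track.per_bp(el.chrom, el.start - flank, el.start)
        body = _rescale_body(track.per_bp(el.chrom, el.start, el.end), pseudo)
        down = track.per_bp(el.chrom, el.end, el.end + flank)
        row = np.concatenate([up, body, down])
        if el.strand == "-":
            row = row[::-1]
        rows.append(row)
        names.append(el.name)
    return AnchoredMatrix(np.vstack(rows), tuple(names), flank, pseudo)


@dataclass(frozen=True)
class ProfileStats:
    mean: np.ndarray
    se: np.ndarray | None
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    n: int


def mean_profile(matrix: AnchoredMatrix | np.ndarray) -> ProfileStats:
    """Column mean, standard error and normal 95% CI (1.96 x SE)."""
    values = matrix.values if isinstance(matrix, AnchoredMatrix) else np.asarray(matrix)
    n = values.shape[0]
    mean = values.mean(axis=0)
    if n < 2:
        return ProfileStats(mean, None, None, None, n)
    se = values.std(axis=0, ddof=1) / np.sqrt(n)
    return ProfileStats(mean, se, mean - 1.96 * se, mean + 1.96 * se, n)


def group_compare(
    matrix: AnchoredMatrix,
    groups: Mapping[str, Sequence[str]],
    difference: Tuple[str, str] | None = None,
) -> Dict[str, ProfileStats | np.ndarray]:
    """Per-group mean profiles over a partition of the rows, plus an
    optional difference profile between two named groups."""
    name_to_row = {n: i for i, n in enumerate(matrix.element_names)}
    out: Dict[str, ProfileStats | np.ndarray] = {}
    for gname, members in groups.items():
        if not members:
            raise ValueError(f"group {gname!r} is empty")
        try:
            idx = [name_to_row[m] for m in members]
        except KeyError as e:
            raise KeyError(f"unknown element {e.args[0]!r} in group {gname!r}") from None
        out[gname] = mean_profile(matrix.values[idx])
    if difference is not None:
        a, b = difference
        if a not in out or b not in out:
            raise KeyError(f"difference groups {difference} not among {sorted(groups)}")
        out["difference"] = out[a].mean - out[b].mean
    return out


def plot_profile(stats: ProfileStats, path, title: str = "") -> None:
    """Write a mean-profile PNG with the SE band shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(stats.mean.size)
    ax.plot(x, stats.mean, lw=1, label=f"mean (n={stats.n})")
    if stats.ci_low is not None:
        ax.fill_between(x, stats.ci_low, stats.ci_high, alpha=0.3, label="95% CI")
    ax.set_xlabel("position (bins, 5'->3')")
    ax.set_ylabel("coverage")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_heatmap(matrix: AnchoredMatrix, path, title: str = "") -> None:
    """Write an anchored-coverage heatmap PNG (rows ordered as given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(matrix.values, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.axvline(matrix.flank, color="w", lw=0.5)
    ax.axvline(matrix.flank + matrix.pseudolength, color="w", lw=0.5)
    ax.set_xlabel("position (bins, 5'->3')")
    ax.set_ylabel("elements")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="coverage")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
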