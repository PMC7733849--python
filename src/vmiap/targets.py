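"""Sequence-based prediction of additional modifier targets.

Stages: orientation normalisation (reverse complement), global percent
identity to the index LTR, deterministic progressive multiple alignment,
scanning the alignment for the window that discriminates target from
nontarget rows (the putative KZFP recognition segment), high/low
methylation concordance with the index locus, and per-locus unpaired t
tests with two-stage step-up FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from Bio import Align
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "reverse_complement",
    "percent_identity",
    "LabelledAlignment",
    "align_multiple",
    "DivergentWindow",
    "divergent_window_scan",
    "concordance",
    "ConcordanceResult",
    "ttest_bky",
    "TTestResult",
]

_ALPHABET = set("ACGTN-")
_COMP = str.maketrans("ACGTN", "TGCAN")

# char -> profile code
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
_CHR = np.array(list("ACGT-N"))


def reverse_complement(seq: str) -> str:
    """Reverse complement; N maps to N."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)}")
    return seq.translate(_COMP)[::-1]


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity under a fixed global alignment scheme
    (match +1, mismatch -1, gap open -2, extend -1): identities over
    aligned columns, reported to one decimal."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    # canonical argument order: co-optimal alignments can differ in column
    # count, so align the lexicographically smaller sequence first to make
    # the reported identity symmetric and deterministic
    seq_a, seq_b = sorted((seq_a, seq_b))
    aln = _aligner().align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = aln.length
    return round(100.0 * counts.identities / columns, 1)


@dataclass
class LabelledAlignment:
    """Equal-length gapped rows with optional target/nontarget labels."""

    ids: List[str]
    rows: List[str]
    labels: Dict[str, str] = field(default_factory=dict)
    orientation: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")
        for r in self.rows:
            bad = set(r) - _ALPHABET
            if bad:
                raise ValueError(f"invalid alignment characters: {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, ident: str) -> str:
        return self.rows[self.ids.index(ident)]

    def matrix(self) -> np.ndarray:
        return np.array([[_CODE[c] for c in r] for r in self.rows], dtype=np.int8)

    def rows_with_label(self, label: str) -> List[int]:
        return [i for i, ident in enumerate(self.ids) if self.labels.get(ident) == label]


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

_GAP_OPEN = -12.0  # affine gap opening cost per merged column
_GAP_EXTEND = -0.5  # affine gap extension cost (favors contiguous gap blocks)


def _profile_counts(rows: np.ndarray) -> np.ndarray:
    """(columns x 6) count matrix of A,C,G,T,-,N per alignment column."""
    n_rows, n_cols = rows.shape
    counts = np.zeros((n_cols, 6), dtype=np.float64)
    for code in range(6):
        counts[:, code] = (rows == code).sum(axis=0)
    return counts


def _column_scores(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """Mean pair score between every column of profile A and of profile B.

    Base/base same +1, base/base different -1, base/gap -1, gap/gap and
    anything involving N scores 0.
    """
    base_a = ca[:, :4]
    base_b = cb[:, :4]
    ta = ca.sum(axis=1)
    tb = cb.sum(axis=1)
    matches = base_a @ base_b.T
    nbase_a = base_a.sum(axis=1)
    nbase_b = base_b.sum(axis=1)
    base_pairs = np.outer(nbase_a, nbase_b)
    mismatches = base_pairs - matches
    gap_base = np.outer(ca[:, 4], nbase_b) + np.outer(nbase_a, cb[:, 4])
    return (matches - mismatches - gap_base) / np.outer(ta, tb)


def _align_profiles(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Needleman-Wunsch on two profiles with affine gap cost.

    Three-state DP (match, gap-in-B, gap-in-A); the horizontal gap state
    is vectorised per row with a prefix-max scan.  Returns gapped index
    arrays (-1 marks an inserted gap column) mapping merged columns back
    into each profile.
    """
    ca, cb = _profile_counts(a), _profile_counts(b)
    m, n = ca.shape[0], cb.shape[0]
    s = _column_scores(ca, cb)
    go, ge = _GAP_OPEN, _GAP_EXTEND
    neg = -1e30
    M = np.full((m + 1, n + 1), neg)
    Ix = np.full((m + 1, n + 1), neg)  # gap in B: consumes a column of A
    Iy = np.full((m + 1, n + 1), neg)  # gap in A: consumes a column of B
    M[0, 0] = 0.0
    if m:
        Ix[1:, 0] = go + ge * np.arange(m)
    if n:
        Iy[0, 1:] = go + ge * np.arange(n)
    idx = np.arange(1, n + 1)
    for i in range(1, m + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = s[i - 1] + best_prev[:-1]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] + go, Ix[i - 1, 1:] + ge)
        Ix[i, 0] = go + ge * (i - 1)
        # Iy[i, j] = max(M[i, j-1] + go, Iy[i, j-1] + ge): prefix-max scan
        c = M[i, :-1] + go
        scan = np.maximum.accumulate(c - ge * np.arange(n))
        Iy[i, 1:] = scan + ge * (idx - 1)
    # traceback with deterministic state preference M > Ix > Iy
    out_a: List[int] = []
    out_b: List[int] = []
    i, j = m, n
    eps = 1e-6
    state = max(("M", "Ix", "Iy"), key=lambda st: {"M": M, "Ix": Ix, "Iy": Iy}[st][m, n])
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(i - 1)
            out_b.append(j - 1)
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            target = M[i, j] - s[i - 1, j - 1]
            i, j = i - 1, j - 1
            if abs(prev[0] - target) < eps:
                state = "M"
            elif abs(prev[1] - target) < eps:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            out_a.append(i - 1)
            out_b.append(-1)
            opened = abs(Ix[i, j] - (M[i - 1, j] + go)) < eps
            i -= 1
            state = "M" if opened else "Ix"
        else:
            out_a.append(-1)
            out_b.append(j - 1)
            opened = abs(Iy[i, j] - (M[i, j - 1] + go)) < eps
            j -= 1
            state = "M" if opened else "Iy"
        if i == 0 and j > 0 and state in ("M", "Ix"):
            state = "Iy"
        if j == 0 and i > 0 and state in ("M", "Iy"):
            state = "Ix"
    return np.array(out_a[::-1]), np.array(out_b[::-1])


def _merge(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ia, ib = _align_profiles(a, b)
    n_cols = len(ia)
    out = np.full((a.shape[0] + b.shape[0], n_cols), _CODE["-"], dtype=np.int8)
    mask_a = ia >= 0
    mask_b = ib >= 0
    out[: a.shape[0], mask_a] = a[:, ia[mask_a]]
    out[a.shape[0] :, mask_b] = b[:, ib[mask_b]]
    return out


def align_multiple(
    seqs: Mapping[str, str],
    labels: Mapping[str, str] | None = None,
    orientation: Mapping[str, str] | None = None,
) -> LabelledAlignment:
    """Deterministic progressive alignment.

    Pairwise percent identities (same scoring scheme as
    :func:`percent_identity`) feed a UPGMA guide tree; profiles are merged
    bottom-up with a profile-profile Needleman-Wunsch.  Sequences are
    processed in lexicographic id order, making the result independent of
    input order.  Orientation must be normalised by the caller
    (contraoriented records reverse-complemented first).
    """
    if len(seqs) < 2:
        raise ValueError("align_multiple needs >= 2 sequences")
    ids = sorted(seqs)
    arrays = {
        i: np.array([[_CODE[c] for c in seqs[i]]], dtype=np.int8) for i in ids
    }
    n = len(ids)
    if n == 2:
        merged = _merge(arrays[ids[0]], arrays[ids[1]])
        order = list(ids)
    else:
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 100.0 - percent_identity(seqs[ids[i]], seqs[ids[j]])
                dist[i, j] = dist[j, i] = d
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        # progressive merge following the linkage join order
        clusters: Dict[int, Tuple[np.ndarray, List[str]]] = {
            i: (arrays[ids[i]], [ids[i]]) for i in range(n)
        }
        for k, (ia, ib, _, _) in enumerate(link):
            a_arr, a_ids = clusters.pop(int(ia))
            b_arr, b_ids = clusters.pop(int(ib))
            clusters[n + k] = (_merge(a_arr, b_arr), a_ids + b_ids)
        merged, order = clusters[n + len(link) - 1]
    rows = {ident: "".join(_CHR[merged[i]]) for i, ident in enumerate(order)}
    ids_sorted = sorted(order)
    return LabelledAlignment(
        ids=ids_sorted,
        rows=[rows[i] for i in ids_sorted],
        labels=dict(labels or {}),
        orientation=dict(orientation or {}),
    )


# ---------------------------------------------------------------------------
# Divergent window scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DivergentWindow:
    start: int  # alignment column, inclusive
    end: int  # alignment column, exclusive
    length_bp: int  # ungapped consensus-frame length
    score: float  # mean column discrimination score in [0, 1]

    @property
    def rank_key(self) -> float:
        return self.length_bp * self.score


def _column_discrimination(tchars: np.ndarray, nchars: np.ndarray) -> np.ndarray:
    """Per-column discrimination scores for target rows vs nontarget rows.

    A column scores 1 when all targets share one state and every
    nontarget differs from it; otherwise the clamped difference between
    the between-group and within-group mismatch rates.
    """
    n_cols = tchars.shape[1]
    scores = np.empty(n_cols)
    nt, nn = tchars.shape[0], nchars.shape[0]
    for c in range(n_cols):
        t = tchars[:, c]
        n = nchars[:, c]
        if (t == t[0]).all() and (n != t[0]).all():
            scores[c] = 1.0
            continue
        between = (t[:, None] != n[None, :]).mean()
        within_pairs = 0
        within_mis = 0
        for grp in (t, n):
            k = grp.size
            if k > 1:
                within_pairs += k * (k - 1) // 2
                within_mis += int(np.sum(grp[:, None] != grp[None, :])) // 2
        within = within_mis / within_pairs if within_pairs else 0.0
        scores[c] = min(1.0, max(0.0, between - within))
    return scores


def divergent_window_scan(
    alignment: LabelledAlignment,
    min_score: float = 0.35,
    min_len: int = 8,
    merge_gap: int = 6,
    seed_score: float = 0.55,
    target_label: str = "VM",
    nontarget_label: str = "nontarget",
) -> List[DivergentWindow]:
    """Maximal divergent windows between the labelled groups, ranked by
    length x score.

    Strongly discriminating columns (score >= ``seed_score``) seed the
    windows; seeds separated by fewer than ``merge_gap`` low-scoring
    columns merge into one window, which prevents fragmentation by
    isolated noisy or conserved columns inside a divergent segment.  A
    merged window is reported when its mean column score reaches
    ``min_score`` and its length reaches ``min_len``.  Window length is
    measured in the consensus frame: columns where more than half of the
    target rows are ungapped.
    """
    t_rows = alignment.rows_with_label(target_label)
    n_rows = alignment.rows_with_label(nontarget_label)
    if not t_rows or not n_rows:
        raise ValueError("both target and nontarget labels must be present")
    mat = alignment.matrix()
    scores = _column_discrimination(mat[t_rows], mat[n_rows])
    consensus_frame = (mat[t_rows] != _CODE["-"]).mean(axis=0) > 0.5
    high = np.nonzero(scores >= seed_score)[0]
    if high.size == 0:
        return []
    runs: List[List[int]] = [[int(high[0]), int(high[0])]]
    for c in high[1:]:
        if c - runs[-1][1] - 1 < merge_gap:
            runs[-1][1] = int(c)
        else:
            runs.append([int(c), int(c)])
    windows = []
    for lo, hi in runs:
        span = slice(lo, hi + 1)
        mean_score = float(scores[span].mean())
        length = int(consensus_frame[span].sum())
        if mean_score >= min_score and length >= min_len:
            windows.append(DivergentWindow(lo, hi + 1, length, mean_score))
    windows.sort(key=lambda w: (-w.rank_key, w.start))
    return windows


# ---------------------------------------------------------------------------
# Concordance and group testing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceResult:
    locus: str
    fraction: float
    n_shared: int
    verdict: str  # 'target' | 'nontarget'


def concordance(
    index_classes: Mapping[str, str],
    candidate_classes: Mapping[str, Mapping[str, str]],
    min_concordance: float = 0.9,
) -> List[ConcordanceResult]:
    """Fraction of individuals whose high/low call at each candidate locus
    matches their call at the index locus; ``target`` verdict at or above
    ``min_concordance``."""
    out: List[ConcordanceResult] = []
    for locus in sorted(candidate_classes):
        cand = candidate_classes[locus]
        shared = sorted(set(index_classes) & set(cand))
        if not shared:
            raise ValueError(f"no shared individuals between index and {locus!r}")
        frac = float(np.mean([index_classes[i] == cand[i] for i in shared]))
        verdict = "target" if frac >= min_concordance else "nontarget"
        out.append(ConcordanceResult(locus, frac, len(shared), verdict))
    return out


@dataclass(frozen=True)
class TTestResult:
    locus: str
    t: float
    p: float
    discovery: bool


def ttest_bky(
    group_pairs: Mapping[str, Tuple[Sequence[float], Sequence[float]]],
    q: float = 0.05,
    equal_var: bool = True,
) -> List[TTestResult]:
    """Unpaired two-sample t test per locus with two-stage step-up FDR.

    Default is the classic pooled-variance t (configurable to Welch via
    ``equal_var=False``).  Discoveries are flagged by the adaptive
    two-stage Benjamini-Krieger-Yekutieli step-up at level ``q``:
    stage 1 runs a linear step-up at q' = q/(1+q) to estimate the number
    of true nulls, stage 2 a linear step-up at level q * m / m0.
    Degenerate zero-variance comparisons with equal means give p = 1.
    """
    loci = sorted(group_pairs)
    if len(loci) < 2:
        raise ValueError("ttest_bky needs >= 2 loci")
    ts, ps = [], []
    for locus in loci:
        a = np.asarray(group_pairs[locus][0], dtype=float)
        b = np.asarray(group_pairs[locus][1], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"locus {locus!r}: each group needs n >= 2")
        if np.var(a) == 0 and np.var(b) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        ts.append(float(t))
        ps.append(float(p))
    reject, _, _, _ = multipletests(ps, alpha=q, method="fdr_tsbky")
    return [
        TTestResult(locus, t, p, bool(r)) for locus, t, p, r in zip(loci, ts, ps, reject)
    ]
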