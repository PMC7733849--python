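"""Synthetic solo-LTR sequence families with a planted discriminative motif.

The generator emulates the sequence structure the target-prediction and
phylogeny stages rely on: a family of near-identical LTRs descended from a
common VM-clade ancestor, split into *targets* (intact 28-bp recognition
segment), *nontargets* (segment disrupted by an insertion plus spread
substitutions), and a more divergent *background* set drawn directly from
the subclass consensus.  A random subset of records is emitted
reverse-complemented with an orientation flag, as solo LTRs occur on both
strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["MotifSpec", "LtrRecord", "evolve_ltr_family", "random_consensus"]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class LtrRecord:
    id: str
    seq: str
    label: str  # 'VM' (modifier target), 'nontarget', 'background'
    orientation: str  # '+' or '-' ('-' means emitted reverse-complemented)


@dataclass(frozen=True)
class MotifSpec:
    """Geometry of the planted discriminative segment.

    ``segment_start``/``segment_length`` place the recognition segment on
    the consensus.  Nontargets receive ``insertion_length`` extra bases at
    ``insertion_offset`` within the segment plus substitutions at
    ``substitution_offsets`` (relative to segment start).  The default
    substitutions are spaced every third base across the full segment so
    the disrupted region is divergent along its whole length, emulating a
    segment carrying an insertion and numerous SNPs.
    """

    consensus_length: int = 420
    segment_start: int = 150
    segment_length: int = 28
    insertion_offset: int = 12
    insertion_length: int = 4
    substitution_offsets: Tuple[int, ...] = tuple(range(0, 28, 3))
    clade_divergence: float = 0.02  # subs/bp on the VM-clade ancestor branch
    leaf_divergence: float = 0.005  # subs/bp on each terminal branch
    background_divergence: float = 0.15  # subs/bp for background leaves
    revcomp_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.segment_start + self.segment_length > self.consensus_length:
            raise ValueError("planted segment does not fit within the consensus")
        if not 0 <= self.insertion_offset <= self.segment_length:
            raise ValueError("insertion offset outside segment")
        offs = self.substitution_offsets
        if self.insertion_length + len(offs) >= 1 and not (
            len(offs) == 0 or (min(offs) >= 0 and max(offs) < self.segment_length)
        ):
            raise ValueError("substitution offsets outside segment")
        if self.insertion_length == 0 and len(offs) == 0:
            raise ValueError("disruption must change at least one position in the segment")


def random_consensus(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(seq_arr: np.ndarray, rate: float, rng: np.random.Generator,
            protect: slice | None = None) -> np.ndarray:
    """Substitute bases iid at ``rate``; positions in ``protect`` untouched."""
    out = seq_arr.copy()
    hit = rng.random(out.size) < rate
    if protect is not None:
        hit[protect] = False
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _disrupt(seq_arr: np.ndarray, spec: MotifSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.segment_start
    out = seq_arr.copy()
    for off in sorted(set(spec.substitution_offsets)):
        i = s + off
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    if spec.insertion_length:
        ins = _BASES[rng.integers(0, 4, size=spec.insertion_length)]
        out = np.concatenate([out[: s + spec.insertion_offset], ins, out[s + spec.insertion_offset:]])
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def evolve_ltr_family(
    n_targets: int,
    n_nontargets: int,
    n_background: int,
    motif_spec: MotifSpec = MotifSpec(),
    rng: np.random.Generator | None = None,
    consensus: str | None = None,
) -> List[LtrRecord]:
    """Generate a labelled LTR family.

    Targets and nontargets share the VM-clade ancestor (consensus plus
    clade-level substitutions outside the planted segment) and are
    therefore mutually closer than either is to the background leaves,
    which diverge independently from the consensus.
    """
    if min(n_targets, n_nontargets, n_background) < 0:
        raise ValueError("counts must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    spec = motif_spec
    if consensus is None:
        consensus = random_consensus(spec.consensus_length, rng)
    elif len(consensus) != spec.consensus_length:
        raise ValueError("consensus length does not match MotifSpec")
    cons = np.array(list(consensus))
    segment = slice(spec.segment_start, spec.segment_start + spec.segment_length)
    vm_ancestor = _mutate(cons, spec.clade_divergence, rng, protect=segment)
    nontarget_ancestor = _disrupt(vm_ancestor, spec, rng)

    records: List[LtrRecord] = []

    def emit(ident: str, arr: np.ndarray, label: str) -> None:
        seq = "".join(arr)
        orientation = "+"
        if rng.random() < spec.revcomp_prob:
            seq = reverse_complement(seq)
            orientation = "-"
        records.append(LtrRecord(ident, seq, label, orientation))

    for k in range(n_targets):
        emit(f"VM_{k:03d}", _mutate(vm_ancestor, spec.leaf_divergence, rng), "VM")
    for k in range(n_nontargets):
        emit(f"NT_{k:03d}", _mutate(nontarget_ancestor, spec.leaf_divergence, rng), "nontarget")
    for k in range(n_background):
        emit(f"BG_{k:03d}", _mutate(cons, spec.background_divergence, rng), "background")
    return records
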