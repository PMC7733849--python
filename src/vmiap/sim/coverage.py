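"""Synthetic coverage tracks with strand-aware 3'-biased enrichment.

Emulates the chromatin-signal structure seen at modifier-target elements:
Poisson background everywhere, plus an additive enrichment block over the
3'-proximal fraction of each enriched element (so on the minus strand the
block abuts the element's lower-coordinate end).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = ["EnrichmentSpec", "BedElement", "synth_coverage"]


@dataclass(frozen=True)
class BedElement:
    """BED6-style stranded interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("element start must be < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EnrichmentSpec:
    """Background Poisson mean and the additive 3' enrichment block."""

    background_mean: float = 5.0
    enrichment_height: float = 20.0
    three_prime_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.background_mean < 0 or self.enrichment_height < 0:
            raise ValueError("means/heights must be >= 0")
        if not 0 <= self.three_prime_fraction <= 1:
            raise ValueError("three_prime_fraction must lie in [0, 1]")


def enrichment_block(el: BedElement, fraction: float) -> Tuple[int, int]:
    """Coordinates of the 3'-proximal block of ``el`` covering ``fraction``
    of its length, respecting strand."""
    w = max(1, int(round(el.length * fraction))) if fraction > 0 else 0
    if w == 0:
        return el.start, el.start
    if el.strand == "+":
        return el.end - w, el.end
    return el.start, el.start + w


def synth_coverage(
    elements: Sequence[BedElement],
    chrom_sizes: Dict[str, int],
    spec: EnrichmentSpec,
    rng: np.random.Generator,
    enriched: Iterable[str] | None = None,
) -> Dict[str, np.ndarray]:
    """Per-chromosome per-bp coverage arrays.

    ``enriched`` selects element names receiving the 3' block (default:
    all).  Overlapping enrichment blocks sum.
    """
    enriched_set = set(enriched) if enriched is not None else {e.name for e in elements}
    track = {
        chrom: rng.poisson(spec.background_mean, size=size).astype(float)
        for chrom, size in chrom_sizes.items()
    }
    for el in elements:
        if el.name not in enriched_set or spec.enrichment_height == 0:
            continue
        if el.chrom not in track:
            raise KeyError(f"element chromosome {el.chrom!r} missing from chrom_sizes")
        lo, hi = enrichment_block(el, spec.three_prime_fraction)
        track[el.chrom][lo:hi] += spec.enrichment_height
    return track
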