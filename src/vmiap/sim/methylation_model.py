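"""Locus-specific methylation phenotype model.

Each locus has a variable baseline distribution (a Beta shape rescaled to
0-100%) and a modifier-induced high state.  Whether an individual expresses
the high state depends on the locus's effect mode:

* ``zygotic`` — high iff the individual carries >= 1 modifier allele;
* ``maternal`` — high iff its dam is of the modifier strain;
* ``maternal+zygotic`` — high under either condition, with an extra
  maternal boost when both hold (so reciprocal hybrid cohorts remain
  statistically distinguishable);
* ``none`` — always baseline.

Per-CpG measurements are the locus draw plus independent Gaussian
pyrosequencing noise, clamped to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .pedigree import Individual

__all__ = ["MethylationModel", "assign_methylation", "EFFECT_MODES"]

EFFECT_MODES = ("zygotic", "maternal", "maternal+zygotic", "none")


@dataclass(frozen=True)
class MethylationModel:
    """Distributional parameters for one locus.

    Defaults give a baseline mean of 45% (Beta(9, 11)) and a high-state
    mean of 80% (Beta(24, 6)), which a 60% cutoff separates essentially
    without overlap, mirroring a locus with non-overlapping baseline and
    hybrid methylation distributions.
    """

    baseline: Tuple[float, float] = (9.0, 11.0)
    high_state: Tuple[float, float] = (24.0, 6.0)
    effect_mode: str = "zygotic"
    modifier_strain: str = "CAST"
    maternal_boost: float = 8.0
    measurement_noise_sd: float = 2.0
    n_cpgs: int = 6

    def __post_init__(self) -> None:
        if self.effect_mode not in EFFECT_MODES:
            raise ValueError(
                f"unknown effect mode {self.effect_mode!r}; expected one of {EFFECT_MODES}"
            )
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement noise sd must be >= 0")
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")


def _is_high_state(ind: Individual, model: MethylationModel) -> Tuple[bool, bool]:
    zyg = ind.modifier_alleles >= 1
    mat = ind.dam_strain == model.modifier_strain
    if model.effect_mode == "zygotic":
        return zyg, False
    if model.effect_mode == "maternal":
        return mat, False
    if model.effect_mode == "maternal+zygotic":
        return (zyg or mat), (zyg and mat)
    return False, False  # 'none'


def assign_methylation(
    ind: Individual, model: MethylationModel, rng: np.random.Generator
) -> np.ndarray:
    """Per-CpG methylation percentages for one individual at one locus."""
    high, boosted = _is_high_state(ind, model)
    a, b = model.high_state if high else model.baseline
    level = 100.0 * rng.beta(a, b)
    if boosted:
        level += model.maternal_boost
    noise = rng.normal(0.0, model.measurement_noise_sd, size=model.n_cpgs) \
        if model.measurement_noise_sd > 0 else np.zeros(model.n_cpgs)
    return np.clip(level + noise, 0.0, 100.0)
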