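"""Numeric thresholds shared across the analysis stages.

All of the decision rules in the package (variability calls, high/low
phenotype calls, identity filters, FDR level, tree length filter,
metaprofile geometry) are driven by a single :class:`Thresholds` object so
that a complete analysis is reproducible from one configuration record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

__all__ = ["Thresholds"]


@dataclass(frozen=True)
class Thresholds:
    """Bundle of the numeric cut-offs used throughout the pipeline.

    Parameters
    ----------
    variability_spread:
        Minimum spread (max - min, percentage points) of per-individual
        methylation means for a locus to be called variably methylated.
    high_low_cutoff:
        Methylation percentage separating the "high" from the "low"
        phenotype; values strictly above the cutoff are "high".
    identity_min:
        Minimum percent sequence identity to the index locus for a
        candidate modifier target.
    fdr_q:
        False-discovery-rate level for the two-stage step-up procedure.
    nj_len_min, nj_len_max:
        Inclusive length bounds (bp) on solo-LTR sequences admitted to the
        neighbor-joining tree.
    pseudolength:
        Number of bins each element body is rescaled to in anchored
        coverage matrices.
    flank:
        Width (bp) of the unscaled up/downstream flanks in anchored
        matrices.
    alpha:
        Significance level for hypothesis tests (Kruskal-Wallis, Dunn,
        binomial segregation checks).
    variability_mode:
        "range" interprets ``variability_spread`` as max-min of individual
        means; "variance" as the statistical variance of the means.
    hyper_bound, hypo_bound:
        Group-mean boundaries used to subtype non-variable loci.
    concordance_min:
        Minimum high/low concordance fraction with the index locus for a
        "target" verdict.
    """

    variability_spread: float = 10.0
    high_low_cutoff: float = 60.0
    identity_min: float = 90.0
    fdr_q: float = 0.05
    nj_len_min: int = 200
    nj_len_max: int = 800
    pseudolength: int = 500
    flank: int = 500
    alpha: float = 0.05
    variability_mode: str = "range"
    hyper_bound: float = 80.0
    hypo_bound: float = 20.0
    concordance_min: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.high_low_cutoff < 100:
            raise ValueError("high_low_cutoff must lie in (0, 100)")
        for name in (
            "variability_spread",
            "identity_min",
            "fdr_q",
            "nj_len_min",
            "nj_len_max",
            "pseudolength",
            "flank",
            "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nj_len_min > self.nj_len_max:
            raise ValueError("nj_len_min must not exceed nj_len_max")
        if self.variability_mode not in ("range", "variance"):
            raise ValueError("variability_mode must be 'range' or 'variance'")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Thresholds":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)
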