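"""HER2 positivity cutoff and EMT-index.

The cutoff separating HER2-negative from HER2-positive CTCs is derived from
two control cell-line populations modeled as Gaussians: a HER2-negative line
(KATOIII, mean 50, SD 23.7) and a weakly HER2-positive line (NUGC4, mean 76,
SD 46.1).  The published decision rule takes the inverse-variance-weighted
mean of the two control means,

    T = (mu1 * sigma2**2 + mu2 * sigma1**2) / (sigma1**2 + sigma2**2),

and calls a CTC HER2-positive when its mean membrane fluorescence strictly
exceeds the next integer above T (56 for the reference parameters).  Note
this weighted mean is *not* the exact density-intersection point of two
unequal-variance Gaussians (which solves a quadratic); the weighted-mean rule
is implemented as published and the discrepancy documented, never silently
"corrected".

The EMT-index quantifies epithelial-mesenchymal transition as
``vim / (ck + vim)``: 0 is fully epithelial (cytokeratin only), 1 fully
mesenchymal (vimentin only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ctcflow.errors import ValidationError

__all__ = [
    "CELL_LINE_REFERENCES",
    "CellLineReference",
    "ThresholdModel",
    "classify_her2",
    "emt_index",
    "intersection_threshold",
    "positivity_cutoff",
]


def intersection_threshold(
    mu1: float, sigma1: float, mu2: float, sigma2: float
) -> float:
    """Variance-weighted crossover between two control Gaussians.

    Parameters are the mean and SD of the HER2-negative (``mu1, sigma1``)
    and HER2-positive (``mu2, sigma2``) control populations, in arbitrary
    fluorescence units.  Returns a value strictly between ``mu1`` and
    ``mu2``: each mean is weighted by the *other* population's variance, so
    the cut sits closer to the tighter population.
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValidationError(f"sigmas must be > 0, got {sigma1}, {sigma2}")
    if mu1 >= mu2:
        raise ValidationError(
            f"negative-control mean must lie below positive-control mean "
            f"(got mu1={mu1}, mu2={mu2})"
        )
    v1, v2 = sigma1 * sigma1, sigma2 * sigma2
    return (mu1 * v2 + mu2 * v1) / (v1 + v2)


def positivity_cutoff(t_raw: float) -> int:
    """Integer cutoff: the smallest integer >= ``t_raw``.

    The decision rule operates on an integer boundary with a strict ``>``
    comparison; rounding the raw crossover up (never down) keeps every
    intensity at or below the crossover on the negative side.
    """
    if not math.isfinite(t_raw):
        raise ValidationError(f"t_raw must be finite, got {t_raw}")
    return math.ceil(t_raw)


def classify_her2(mean_intensity: float, cutoff: int) -> str:
    """Classify a patient's mean CTC HER2 intensity: ``intensity > cutoff``.

    Strict inequality — a value exactly at the cutoff is negative.
    """
    if mean_intensity < 0:
        raise ValidationError(
            f"intensity must be >= 0, got {mean_intensity}"
        )
    return "positive" if mean_intensity > cutoff else "negative"


def emt_index(ck: float, vim: float) -> float:
    """EMT-index ``vim / (ck + vim)`` in [0, 1].

    Scale-invariant in the pair (so unit choice does not matter), strictly
    increasing in vimentin and decreasing in cytokeratin.
    """
    if ck < 0 or vim < 0:
        raise ValidationError(f"signals must be >= 0, got ck={ck}, vim={vim}")
    total = ck + vim
    if total == 0:
        raise ValidationError("EMT-index undefined when ck + vim == 0")
    return vim / total


@dataclass(frozen=True)
class ThresholdModel:
    """Two control Gaussians and the positivity cutoff they induce.

    Defaults are the reference control parameters (negative control mean 50
    SD 23.7; positive control mean 76 SD 46.1), which give t_raw = 55.435
    and cutoff 56.
    """

    mu_neg: float = 50.0
    sigma_neg: float = 23.7
    mu_pos: float = 76.0
    sigma_pos: float = 46.1
    t_raw: float = field(init=False)
    cutoff: int = field(init=False)

    def __post_init__(self) -> None:
        t = intersection_threshold(
            self.mu_neg, self.sigma_neg, self.mu_pos, self.sigma_pos
        )
        object.__setattr__(self, "t_raw", t)
        object.__setattr__(self, "cutoff", positivity_cutoff(t))

    def classify(self, mean_intensity: float) -> str:
        return classify_her2(mean_intensity, self.cutoff)


@dataclass(frozen=True)
class CellLineReference:
    """A gastric cell line used as a HER2 staining control."""

    name: str
    mean_her2_intensity: float
    her2_class: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.mean_her2_intensity <= 0:
            raise ValidationError("reference intensity must be > 0")
        if self.her2_class not in ("positive", "negative"):
            raise ValidationError(f"bad her2_class {self.her2_class!r}")


#: Gastric cell lines with their measured mean HER2 membrane fluorescence.
CELL_LINE_REFERENCES: tuple[CellLineReference, ...] = (
    CellLineReference("MKN7", 489.0, "positive"),
    CellLineReference("GSU", 200.0, "positive"),
    CellLineReference("NUGC4", 76.0, "positive"),
    CellLineReference("KATOIII", 50.0, "negative"),
)
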