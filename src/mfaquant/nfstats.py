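"""Per-pad NF statistics: Gaussian histogram fits, zero rule, error overlap.

Each pad aggregates millions of single-molecule competitions; its valid NF
pixels are histogrammed and the histogram is fitted with a Gaussian, whose
mean and standard deviation are the pad's read-out.  Pads whose transfer
signal never rises above the camera background carry no ratio information
and are assigned NF = 0 by convention (the zero rule).  Two pads are
"equal within errors" when their mean difference does not exceed the sum
of their fitted SDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import curve_fit

from .errors import ComparisonUndefinedError

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import Background, NFImage

__all__ = [
    "NFEstimate",
    "fit_nf_histogram",
    "apply_zero_rule",
    "equal_within_errors",
]


@dataclass
class NFEstimate:
    """Gaussian-fit summary of one pad's NF distribution.

    ``status`` is "fitted" (nf_mean/nf_sd from the Gaussian fit), "zeroed"
    (no transfer signal above background; nf_mean = 0, nf_sd absent) or
    "failed" (too few valid pixels or non-converging fit).
    """

    pad_id: tuple[int, int]
    motif_label: str
    reference_n_bp: int
    nf_mean: float
    nf_sd: float | None
    n_pixels: int
    status: str
    histogram: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.status not in ("fitted", "zeroed", "failed"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "zeroed" and self.nf_mean != 0.0:
            raise ValueError("zeroed estimates must have nf_mean == 0")


def _gaussian(x: np.ndarray, amplitude: float, mean: float, sd: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((x - mean) / sd) ** 2)


def fit_nf_histogram(
    nf_image: "NFImage",
    pad_mask: np.ndarray,
    bins: int = 100,
    min_pixels: int = 500,
    pad_id: tuple[int, int] = (0, 0),
    motif_label: str = "",
    reference_n_bp: int = 0,
) -> NFEstimate:
    """Least-squares Gaussian fit to the binned valid NF pixels of one pad.

    Bins span [min, max] of the pad's valid pixels; the fit is initialized
    from the sample moments.  Returns a "failed" estimate (never raises)
    when fewer than ``min_pixels`` valid pixels are available, the fit does
    not converge, or the fitted width is not positive.
    """
    vals = nf_image.values[pad_mask & nf_image.valid_mask]
    n = int(vals.size)

    def failed() -> NFEstimate:
        return NFEstimate(pad_id, motif_label, reference_n_bp,
                          float("nan"), None, n, "failed")

    if n < min_pixels:
        return failed()
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        # degenerate single-valued pad: the histogram is one spike, the width
        # is below any bin resolution
        return NFEstimate(pad_id, motif_label, reference_n_bp,
                          lo, 1e-6, n, "fitted")
    counts, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(vals.mean()), max(float(vals.std()), 1e-6))
    try:
        popt, _ = curve_fit(_gaussian, centers, counts.astype(float), p0=p0, maxfev=20000)
    except RuntimeError:
        return failed()
    mean, sd = float(popt[1]), abs(float(popt[2]))
    if not (np.isfinite(mean) and sd > 0):
        return failed()
    return NFEstimate(pad_id, motif_label, reference_n_bp, mean, sd, n, "fitted",
                      histogram=(edges, counts))


def apply_zero_rule(
    transfer_image: np.ndarray,
    background: "Background",
    pad_mask: np.ndarray,
    k_sigma: float = 3.0,
) -> bool:
    """True when the pad should be zeroed (no transfer signal above background).

    A pad is zeroed when the median raw transfer signal over the pad does
    not exceed ``background.mean + k_sigma * background.sd`` (inclusive at
    the threshold); no Gaussian fit is attempted for such pads and their NF
    is reported as exactly 0.
    """
    median = float(np.median(transfer_image[pad_mask]))
    return median <= background.mean + k_sigma * background.sd


def equal_within_errors(a: NFEstimate, b: NFEstimate) -> bool:
    """Whether two fitted pads agree: |mean_a - mean_b| <= sd_a + sd_b."""
    for est in (a, b):
        if est.status != "fitted":
            raise ComparisonUndefinedError(
                f"pad {est.pad_id} has status {est.status!r}; "
                "equality within errors needs two fitted estimates"
            )
    return abs(a.nf_mean - b.nf_mean) <= a.nf_sd + b.nf_sd
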