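"""From image pair to per-pixel normalized fluorescence (NF).

The NF of a pixel is the background-subtracted transfer signal divided by
the background-subtracted saturation signal: the fraction of constructs at
that position whose reference bond ruptured, normalized to the functional
protein actually present there.  Because both channels image the same
surface, any multiplicative inhomogeneity cancels in the ratio.

Stages: estimate a scalar background from the inter-pad region (robust
median / MAD), subtract it from both channels (clipping at zero), divide
pixel-by-pixel wherever the denominator is trustworthy, and segment the
known pad rectangles for per-pad statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import NoBackgroundRegionError
from .imaging import ImageSet, PadLayout
from . import nfstats

__all__ = [
    "Background",
    "NFImage",
    "estimate_background",
    "estimate_background_field",
    "subtract_background",
    "compute_nf_image",
    "segment_pads",
    "default_min_denominator",
    "quantify_image_set",
]

_MAD_TO_SD = 1.4826  # consistency factor for a normal distribution


@dataclass(frozen=True)
class Background:
    """Robust location/scale of the camera background, in counts."""

    mean: float
    sd: float


def estimate_background(image: np.ndarray, layout: PadLayout) -> Background:
    """Median and 1.4826*MAD of all pixels outside the pad rectangles."""
    outside = ~layout.pad_mask()
    if outside.shape != image.shape:
        raise ValueError(f"layout {outside.shape} does not match image {image.shape}")
    pixels = image[outside]
    if pixels.size == 0:
        raise NoBackgroundRegionError("pad layout covers the entire image")
    med = float(np.median(pixels))
    sd = _MAD_TO_SD * float(np.median(np.abs(pixels - med)))
    return Background(mean=med, sd=sd)


def estimate_background_field(
    image: np.ndarray, layout: PadLayout, smooth_px: float = 50.0
) -> np.ndarray:
    """Optional smoothly varying background estimate (counts per pixel).

    Pad regions are in-painted with the global inter-pad median before
    Gaussian smoothing, so pad signal does not leak into the field.  The
    default pipeline uses the scalar estimate; this is for strongly
    non-uniform illumination.
    """
    bg = estimate_background(image, layout)
    filled = np.where(layout.pad_mask(), bg.mean, image.astype(float))
    return ndimage.gaussian_filter(filled, smooth_px, mode="reflect")


def subtract_background(image: np.ndarray, background: Background | np.ndarray) -> np.ndarray:
    """Subtract a scalar or per-pixel background, clipping negatives to zero."""
    level = background.mean if isinstance(background, Background) else background
    if isinstance(background, Background) and background.mean < 0:
        raise ValueError("background mean must be >= 0")
    return np.clip(image.astype(float) - level, 0.0, None)


@dataclass
class NFImage:
    """Per-pixel NF values with a validity mask.

    ``values`` is NaN wherever ``valid_mask`` is False (denominator too
    small to divide by).  Values above 1 are retained: clipping would skew
    the per-pad histogram that is later fitted with a Gaussian.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def default_min_denominator(background: Background, k: float = 5.0) -> float:
    """Denominator threshold: k robust-SDs of background noise, floor 1 count."""
    return max(k * background.sd, 1.0)


def compute_nf_image(
    transfer_corrected: np.ndarray,
    saturation_corrected: np.ndarray,
    min_denominator: float,
) -> NFImage:
    """Pixel-by-pixel division of corrected transfer by corrected saturation.

    Pixels whose corrected saturation signal falls below ``min_denominator``
    are marked invalid instead of producing blown-up ratios.
    """
    if transfer_corrected.shape != saturation_corrected.shape:
        raise ValueError(
            f"shape mismatch: {transfer_corrected.shape} vs {saturation_corrected.shape}"
        )
    if not min_denominator > 0:
        raise ValueError(f"min_denominator must be > 0, got {min_denominator}")
    valid = saturation_corrected >= min_denominator
    values = np.full(transfer_corrected.shape, np.nan)
    values[valid] = transfer_corrected[valid] / saturation_corrected[valid]
    return NFImage(
        values=values,
        valid_mask=valid,
        provenance={"min_denominator": float(min_denominator)},
    )


def segment_pads(layout: PadLayout, margin: int = 2) -> dict[tuple[int, int], np.ndarray]:
    """Disjoint boolean masks of the pad interiors, eroded by ``margin`` px.

    A margin of at least half the pad size leaves an empty mask; the caller
    reports such pads as failed rather than erroring out.
    """
    masks: dict[tuple[int, int], np.ndarray] = {}
    for r, c, _ in layout.iter_pads():
        mask = np.zeros(layout.image_shape, dtype=bool)
        sl = layout.pad_slice(r, c, margin=margin)
        if sl[0].stop > sl[0].start and sl[1].stop > sl[1].start:
            mask[sl] = True
        masks[(r, c)] = mask
    return masks


def quantify_image_set(
    image_set: ImageSet,
    layout: PadLayout,
    *,
    min_denominator: float | None = None,
    k_sigma: float = 3.0,
    bins: int = 100,
    min_pixels: int = 500,
    margin: int = 2,
) -> tuple[list["nfstats.NFEstimate"], NFImage]:
    """Run the full per-pad quantification on one image pair.

    Backgrounds are estimated per channel from the inter-pad region and
    subtracted; the NF image is formed pixel-by-pixel; each pad is either
    zeroed (transfer signal indistinguishable from background within
    ``k_sigma`` robust SDs), fitted with a Gaussian, or marked failed.
    """
    transfer = image_set.transfer_image
    saturation = image_set.saturation_image
    bg_transfer = estimate_background(transfer, layout)
    bg_saturation = estimate_background(saturation, layout)
    if min_denominator is None:
        min_denominator = default_min_denominator(bg_saturation)

    nf = compute_nf_image(
        subtract_background(transfer, bg_transfer),
        subtract_background(saturation, bg_saturation),
        min_denominator,
    )
    nf.provenance.update(
        {
            "background_transfer": {"mean": bg_transfer.mean, "sd": bg_transfer.sd},
            "background_saturation": {"mean": bg_saturation.mean, "sd": bg_saturation.sd},
            "k_sigma": float(k_sigma),
        }
    )

    estimates: list[nfstats.NFEstimate] = []
    for (r, c), mask in segment_pads(layout, margin=margin).items():
        cond = layout.pad_conditions[(r, c)]
        if not mask.any():
            estimates.append(
                nfstats.NFEstimate(
                    pad_id=(r, c),
                    motif_label=cond.motif_label,
                    reference_n_bp=cond.reference_n_bp,
                    nf_mean=float("nan"),
                    nf_sd=None,
                    n_pixels=0,
                    status="failed",
                )
            )
            continue
        if nfstats.apply_zero_rule(transfer, bg_transfer, mask, k_sigma=k_sigma):
            estimates.append(
                nfstats.NFEstimate(
                    pad_id=(r, c),
                    motif_label=cond.motif_label,
                    reference_n_bp=cond.reference_n_bp,
                    nf_mean=0.0,
                    nf_sd=None,
                    n_pixels=int((mask & nf.valid_mask).sum()),
                    status="zeroed",
                )
            )
            continue
        estimates.append(
            nfstats.fit_nf_histogram(
                nf,
                mask,
                bins=bins,
                min_pixels=min_pixels,
                pad_id=(r, c),
                motif_label=cond.motif_label,
                reference_n_bp=cond.reference_n_bp,
            )
        )
    return estimates, nf
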