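"""Synthetic transfer/saturation fluorescence image pairs on a pad grid.

The assay read-out is a pair of 16-bit images of the same protein surface:
the *transfer* image taken right after surface separation (Cy5 label left
behind where the reference bond broke) and the *saturation* image taken
after flooding the surface with labelled high-affinity duplex so every
functional protein carries a fluorophore.  The generator renders both
images from a known ground truth — per-pad protein density, per-pad
transfer probability, background level and channel noise — so the whole
downstream pipeline can be tested against exact expectations.

Model per pixel (counts):

    saturation = bg + density * field * (1 + cv*g_s) + read noise
    transfer   = bg + density * field * p_transfer * (1 + cv*g_t) + read noise

where ``field`` is a smooth multiplicative inhomogeneity shared between the
two channels (the same immobilized proteins are imaged twice, so surface
density fluctuations are common-mode and cancel in the ratio), while
background fluctuation, multiplicative noise ``g`` and read noise are drawn
independently per pixel and per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
from scipy import ndimage

from .errors import LayoutError

__all__ = [
    "PadCondition",
    "PadLayout",
    "GroundTruth",
    "ImageSet",
    "REPORTED_MEAN_NF",
    "default_conditions",
    "default_ground_truth",
    "make_inhomogeneity_field",
    "render_image_set",
]

UINT16_MAX = 65535.0

# Measured mean NF of the zinc-finger proof-of-principle conditions
# (motif, reference duplex length in bp) -> mean normalized fluorescence.
# Used as the default ground-truth transfer probabilities so that synthetic
# data reproduces the published study conditions.
REPORTED_MEAN_NF: Mapping[tuple[str, int], float] = {
    ("high_affinity", 20): 0.65,
    ("high_affinity", 40): 0.32,
    ("low_affinity", 20): 0.39,
    ("low_affinity", 40): 0.20,
    ("no_binding", 20): 0.0,
    ("no_binding", 40): 0.0,
}

REPORTED_SD_NF: Mapping[tuple[str, int], float] = {
    ("high_affinity", 20): 0.07,
    ("high_affinity", 40): 0.01,
    ("low_affinity", 20): 0.15,
    ("low_affinity", 40): 0.02,
}

_MOTIF_CYCLE = ("no_binding", "low_affinity", "high_affinity")


@dataclass(frozen=True)
class PadCondition:
    """The (DNA motif, reference duplex length) condition printed on one pad."""

    motif_label: str
    reference_n_bp: int


def default_conditions(rows: int = 4, cols: int = 4) -> dict[tuple[int, int], PadCondition]:
    """Condition grid cycling the three motifs over rows and 20/40 bp over columns."""
    return {
        (r, c): PadCondition(_MOTIF_CYCLE[r % 3], 20 if c % 2 == 0 else 40)
        for r in range(rows)
        for c in range(cols)
    }


@dataclass
class PadLayout:
    """Geometry of the pad grid stamped onto the image.

    Pads are axis-aligned squares of ``pad_size_px`` on a ``grid_rows`` x
    ``grid_cols`` grid with centre-to-centre ``pitch_px``, centred in
    ``image_shape``.  Pixel coordinates are 0-based, row-major; pad
    rectangles are half-open.
    """

    grid_rows: int = 4
    grid_cols: int = 4
    pad_size_px: int = 48
    pitch_px: int = 96
    image_shape: tuple[int, int] = (420, 420)
    pad_conditions: dict[tuple[int, int], PadCondition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pad_conditions:
            self.pad_conditions = default_conditions(self.grid_rows, self.grid_cols)
        self.validate()

    def validate(self) -> None:
        if min(self.grid_rows, self.grid_cols, self.pad_size_px) < 1:
            raise LayoutError("grid dimensions and pad size must be >= 1")
        if self.grid_rows > 1 or self.grid_cols > 1:
            if self.pitch_px < self.pad_size_px:
                raise LayoutError(
                    f"pads overlap: pitch {self.pitch_px} < pad size {self.pad_size_px}"
                )
        h, w = self.image_shape
        span_r = (self.grid_rows - 1) * self.pitch_px + self.pad_size_px
        span_c = (self.grid_cols - 1) * self.pitch_px + self.pad_size_px
        if span_r > h or span_c > w:
            raise LayoutError(
                f"pad grid ({span_r}x{span_c} px) does not fit image {self.image_shape}"
            )

    @property
    def n_pads(self) -> int:
        return self.grid_rows * self.grid_cols

    def pad_origin(self, row: int, col: int) -> tuple[int, int]:
        h, w = self.image_shape
        span_r = (self.grid_rows - 1) * self.pitch_px + self.pad_size_px
        span_c = (self.grid_cols - 1) * self.pitch_px + self.pad_size_px
        return ((h - span_r) // 2 + row * self.pitch_px, (w - span_c) // 2 + col * self.pitch_px)

    def pad_slice(self, row: int, col: int, margin: int = 0) -> tuple[slice, slice]:
        """Half-open slices of the pad interior, optionally eroded by ``margin``."""
        y0, x0 = self.pad_origin(row, col)
        s = self.pad_size_px
        return (
            slice(y0 + margin, y0 + s - margin),
            slice(x0 + margin, x0 + s - margin),
        )

    def iter_pads(self) -> Iterator[tuple[int, int, PadCondition]]:
        for r in range(self.grid_rows):
            for c in range(self.grid_cols):
                yield r, c, self.pad_conditions[(r, c)]

    def pad_mask(self) -> np.ndarray:
        """Boolean image, True inside any pad."""
        mask = np.zeros(self.image_shape, dtype=bool)
        for r, c, _ in self.iter_pads():
            mask[self.pad_slice(r, c)] = True
        return mask

    def to_dict(self) -> dict:
        return {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "pad_size_px": self.pad_size_px,
            "pitch_px": self.pitch_px,
            "image_shape": list(self.image_shape),
            "pad_conditions": [
                {"row": r, "col": c, "motif_label": cond.motif_label,
                 "reference_n_bp": cond.reference_n_bp}
                for r, c, cond in self.iter_pads()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PadLayout":
        conditions = {
            (int(p["row"]), int(p["col"])): PadCondition(
                p["motif_label"], int(p["reference_n_bp"])
            )
            for p in d.get("pad_conditions", [])
        }
        return cls(
            grid_rows=int(d["grid_rows"]),
            grid_cols=int(d["grid_cols"]),
            pad_size_px=int(d["pad_size_px"]),
            pitch_px=int(d["pitch_px"]),
            image_shape=tuple(int(x) for x in d["image_shape"]),
            pad_conditions=conditions,
        )


@dataclass
class GroundTruth:
    """True parameters behind one synthetic image pair.

    ``protein_density`` and ``transfer_probability`` are (grid_rows,
    grid_cols) arrays: mean saturation signal of each pad in counts above
    background, and the true fraction of constructs whose reference bond
    ruptures.  Default count scales follow the published images: background
    ~1500 counts, strong-pad saturation 15500 counts so a fully transferred
    pad reads 17000 counts.
    """

    protein_density: np.ndarray
    transfer_probability: np.ndarray
    transfer_probability_sd: np.ndarray | None = None
    background_mean: float = 1500.0
    background_sd: float = 30.0
    multiplicative_noise_cv: float = 0.02
    read_noise_sd: float = 100.0
    inhomogeneity_amplitude: float = 0.2
    inhomogeneity_corr_px: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.protein_density = np.atleast_2d(np.asarray(self.protein_density, float))
        self.transfer_probability = np.atleast_2d(
            np.asarray(self.transfer_probability, float)
        )
        if self.transfer_probability_sd is None:
            self.transfer_probability_sd = np.zeros_like(self.transfer_probability)
        else:
            self.transfer_probability_sd = np.atleast_2d(
                np.asarray(self.transfer_probability_sd, float)
            )
        if self.protein_density.shape != self.transfer_probability.shape:
            raise ValueError("protein_density and transfer_probability shapes differ")
        if self.transfer_probability_sd.shape != self.transfer_probability.shape:
            raise ValueError("transfer_probability_sd shape differs from transfer_probability")
        if np.any(self.transfer_probability_sd < 0):
            raise ValueError("transfer_probability_sd must be >= 0")
        p = self.transfer_probability
        if np.any((p < 0) | (p > 1)):
            raise ValueError("transfer_probability must lie in [0, 1]")
        if self.background_mean < 0:
            raise ValueError("background_mean must be >= 0")
        for name in ("background_sd", "multiplicative_noise_cv", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def summary(self) -> dict:
        return {
            "protein_density": self.protein_density.tolist(),
            "transfer_probability": self.transfer_probability.tolist(),
            "transfer_probability_sd": self.transfer_probability_sd.tolist(),
            "background_mean": self.background_mean,
            "background_sd": self.background_sd,
            "multiplicative_noise_cv": self.multiplicative_noise_cv,
            "read_noise_sd": self.read_noise_sd,
            "inhomogeneity_amplitude": self.inhomogeneity_amplitude,
            "inhomogeneity_corr_px": self.inhomogeneity_corr_px,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            protein_density=np.asarray(d["protein_density"], float),
            transfer_probability=np.asarray(d["transfer_probability"], float),
            transfer_probability_sd=(
                np.asarray(d["transfer_probability_sd"], float)
                if "transfer_probability_sd" in d
                else None
            ),
            background_mean=float(d["background_mean"]),
            background_sd=float(d["background_sd"]),
            multiplicative_noise_cv=float(d["multiplicative_noise_cv"]),
            read_noise_sd=float(d["read_noise_sd"]),
            inhomogeneity_amplitude=float(d["inhomogeneity_amplitude"]),
            inhomogeneity_corr_px=float(d["inhomogeneity_corr_px"]),
            seed=int(d["seed"]),
        )


@dataclass
class ImageSet:
    """Transfer + saturation image pair for one field of view.

    Arrays are float64 counts clipped to the 16-bit range [0, 65535];
    quantization to uint16 happens only on TIFF export.
    """

    transfer_image: np.ndarray
    saturation_image: np.ndarray
    metadata: dict

    def __post_init__(self) -> None:
        if self.transfer_image.shape != self.saturation_image.shape:
            raise ValueError("transfer and saturation images must share a shape")


def default_ground_truth(
    layout: PadLayout,
    seed: int = 0,
    nf_table: Mapping[tuple[str, int], float] = REPORTED_MEAN_NF,
    sd_table: Mapping[tuple[str, int], float] = REPORTED_SD_NF,
    **kwargs,
) -> GroundTruth:
    """Ground truth whose per-pad transfer probabilities follow ``nf_table``.

    Per-pad transfer-ratio spreads default to the measured histogram SDs of
    the same conditions, so default synthetic pads reproduce both the mean
    and the width of the published NF distributions.
    """
    p = np.zeros((layout.grid_rows, layout.grid_cols))
    p_sd = np.zeros_like(p)
    for r, c, cond in layout.iter_pads():
        key = (cond.motif_label, cond.reference_n_bp)
        p[r, c] = nf_table[key]
        p_sd[r, c] = sd_table.get(key, 0.0)
    density = np.full_like(p, 15500.0)
    return GroundTruth(
        protein_density=density,
        transfer_probability=p,
        transfer_probability_sd=p_sd,
        seed=seed,
        **kwargs,
    )


def make_inhomogeneity_field(
    image_shape: tuple[int, int],
    amplitude: float,
    correlation_length_px: float,
    seed: int,
) -> np.ndarray:
    """Smooth positive multiplicative field of mean exactly 1.

    Gaussian-filtered white noise, standardized, clipped at +/-3.5 sigma and
    scaled so excursions stay within ``amplitude`` of 1 (hence strictly
    positive for amplitude < 1), then renormalized to unit mean.  Models the
    per-pad protein-density inhomogeneity that the pixel-wise NF ratio is
    designed to cancel.
    """
    if not 0.0 <= amplitude < 1.0:
        raise ValueError(f"amplitude must be in [0, 1), got {amplitude}")
    if correlation_length_px < 1:
        raise ValueError(f"correlation_length_px must be >= 1, got {correlation_length_px}")
    if amplitude == 0.0:
        return np.ones(image_shape)
    rng = np.random.default_rng(seed)
    g = ndimage.gaussian_filter(rng.standard_normal(image_shape), correlation_length_px,
                                mode="reflect")
    sd = g.std()
    if sd == 0:  # pragma: no cover - constant noise field
        return np.ones(image_shape)
    z = np.clip((g - g.mean()) / sd, -3.5, 3.5)
    field = 1.0 + amplitude * z / 3.5
    return field / field.mean()


def render_image_set(layout: PadLayout, truth: GroundTruth, seed: int | None = None) -> ImageSet:
    """Render a transfer/saturation pair from a layout and ground truth.

    The density field (pad density times the shared inhomogeneity field) is
    identical in both channels; every noise term is drawn independently per
    pixel and per channel.  Bit-identical for identical seeds.
    """
    if truth.protein_density.shape != (layout.grid_rows, layout.grid_cols):
        raise ValueError(
            "ground-truth arrays must have shape (grid_rows, grid_cols) = "
            f"{(layout.grid_rows, layout.grid_cols)}, got {truth.protein_density.shape}"
        )
    if seed is None:
        seed = truth.seed
    ss = np.random.SeedSequence(seed)
    field_seed, noise_seed = ss.spawn(2)
    rng = np.random.default_rng(noise_seed)

    shape = layout.image_shape
    inhom = make_inhomogeneity_field(
        shape,
        truth.inhomogeneity_amplitude,
        truth.inhomogeneity_corr_px,
        int(field_seed.generate_state(1)[0] % 2**31),
    )

    density = np.zeros(shape)
    p_map = np.zeros(shape)
    p_sd_map = np.zeros(shape)
    for r, c, _ in layout.iter_pads():
        sl = layout.pad_slice(r, c)
        density[sl] = truth.protein_density[r, c]
        p_map[sl] = truth.transfer_probability[r, c]
        p_sd_map[sl] = truth.transfer_probability_sd[r, c]
    density = density * inhom  # shared between channels
    # per-pixel transfer-ratio heterogeneity: each pixel's construct
    # population has its own transferred fraction, giving the pad NF
    # histogram its finite width
    p_map = np.clip(p_map + p_sd_map * rng.standard_normal(shape), 0.0, 1.0)

    def channel(signal: np.ndarray) -> np.ndarray:
        bg = truth.background_mean + rng.normal(0.0, truth.background_sd, shape)
        mult = 1.0 + truth.multiplicative_noise_cv * rng.standard_normal(shape)
        read = rng.normal(0.0, truth.read_noise_sd, shape)
        return np.clip(bg + signal * mult + read, 0.0, UINT16_MAX)

    saturation = channel(density)
    transfer = channel(density * p_map)
    metadata = {
        "seed": int(seed),
        "channel": "Cy5",
        "layout": layout.to_dict(),
        "truth": truth.summary(),
    }
    return ImageSet(transfer_image=transfer, saturation_image=saturation, metadata=metadata)
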