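"""Run configuration: one YAML file drives simulate/quantify/calibrate."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .imaging import GroundTruth, PadLayout, default_ground_truth

__all__ = ["LayoutConfig", "ImagingConfig", "RuptureConfig", "PipelineConfig", "RunConfig"]


@dataclass
class LayoutConfig:
    grid_rows: int = 4
    grid_cols: int = 4
    pad_size_px: int = 48
    pitch_px: int = 96
    image_height: int = 420
    image_width: int = 420
    # optional explicit condition list [{row, col, motif_label, reference_n_bp}]
    conditions: list = field(default_factory=list)

    def build(self) -> PadLayout:
        d = {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "pad_size_px": self.pad_size_px,
            "pitch_px": self.pitch_px,
            "image_shape": (self.image_height, self.image_width),
            "pad_conditions": self.conditions,
        }
        return PadLayout.from_dict(d)


@dataclass
class RuptureConfig:
    """Bell-model simulator parameters (section ``rupture`` of the YAML)."""

    loading_rate_pn_per_s: float = 100.0
    f_max_pn: float | None = None
    k0_1_per_s: float = 30.0
    delta_g_per_bp: float = 0.6
    f_beta_pn: float = 8.0

    def per_bp_params(self) -> dict:
        return {
            "k0_1": self.k0_1_per_s,
            "delta_g_per_bp": self.delta_g_per_bp,
            "f_beta": self.f_beta_pn,
        }


@dataclass
class ImagingConfig:
    protein_density_counts: float = 15500.0
    background_mean: float = 1500.0
    background_sd: float = 30.0
    multiplicative_noise_cv: float = 0.02
    read_noise_sd: float = 100.0
    inhomogeneity_amplitude: float = 0.2
    inhomogeneity_corr_px: float = 20.0

    def build_truth(self, layout: PadLayout, seed: int) -> GroundTruth:
        truth = default_ground_truth(
            layout,
            seed=seed,
            background_mean=self.background_mean,
            background_sd=self.background_sd,
            multiplicative_noise_cv=self.multiplicative_noise_cv,
            read_noise_sd=self.read_noise_sd,
            inhomogeneity_amplitude=self.inhomogeneity_amplitude,
            inhomogeneity_corr_px=self.inhomogeneity_corr_px,
        )
        truth.protein_density[:] = self.protein_density_counts
        return truth


@dataclass
class PipelineConfig:
    min_denominator: float | None = None  # None -> 5 robust SDs of background
    k_sigma: float = 3.0
    bins: int = 100
    min_pixels: int = 500
    margin_px: int = 2


@dataclass
class RunConfig:
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    rupture: RuptureConfig = field(default_factory=RuptureConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0
    outdir: str = "mfa_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        for section, sub_cls in (
            ("layout", LayoutConfig),
            ("rupture", RuptureConfig),
            ("imaging", ImagingConfig),
            ("pipeline", PipelineConfig),
        ):
            if section in d:
                known = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(d[section]) - known
                if unknown:
                    raise ValueError(f"unknown keys in config section {section}: {sorted(unknown)}")
                setattr(cfg, section, sub_cls(**d[section]))
        if "seed" in d:
            cfg.seed = int(d["seed"])
        if "outdir" in d:
            cfg.outdir = str(d["outdir"])
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
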