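"""File I/O: 16-bit TIFF image pairs with JSON sidecars, NF TIFFs, CSV tables.

All JSON is written with sorted keys and no timestamps so reruns with the
same seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .imaging import GroundTruth, ImageSet, PadLayout
from .nfstats import NFEstimate
from .pipeline import NFImage

__all__ = [
    "write_image_set",
    "read_image_set",
    "write_nf_image",
    "read_nf_image",
    "estimates_to_frame",
    "write_estimates_csv",
    "read_estimates_csv",
    "write_json",
]

TRANSFER_TIF = "transfer.tif"
SATURATION_TIF = "saturation.tif"
SIDECAR_JSON = "imageset.json"


def write_json(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_image_set(outdir: str | Path, image_set: ImageSet) -> dict[str, Path]:
    """Write the pair as 16-bit grayscale TIFFs plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transfer": outdir / TRANSFER_TIF,
        "saturation": outdir / SATURATION_TIF,
        "sidecar": outdir / SIDECAR_JSON,
    }
    for key, img in (("transfer", image_set.transfer_image),
                     ("saturation", image_set.saturation_image)):
        tifffile.imwrite(paths[key], np.round(img).clip(0, 65535).astype(np.uint16))
    write_json(paths["sidecar"], image_set.metadata)
    return paths


def read_image_set(indir: str | Path) -> tuple[ImageSet, PadLayout, GroundTruth | None]:
    """Read a TIFF pair + sidecar back into an ImageSet and its layout."""
    indir = Path(indir)
    with open(indir / SIDECAR_JSON) as fh:
        metadata = json.load(fh)
    transfer = tifffile.imread(indir / TRANSFER_TIF).astype(float)
    saturation = tifffile.imread(indir / SATURATION_TIF).astype(float)
    layout = PadLayout.from_dict(metadata["layout"])
    truth = GroundTruth.from_dict(metadata["truth"]) if "truth" in metadata else None
    return ImageSet(transfer, saturation, metadata), layout, truth


def write_nf_image(outdir: str | Path, nf: NFImage, stem: str = "nf") -> dict[str, Path]:
    """NF values as 32-bit float TIFF, validity mask as 8-bit TIFF."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"values": outdir / f"{stem}.tif", "mask": outdir / f"{stem}_mask.tif"}
    tifffile.imwrite(paths["values"], nf.values.astype(np.float32))
    tifffile.imwrite(paths["mask"], nf.valid_mask.astype(np.uint8))
    return paths


def read_nf_image(outdir: str | Path, stem: str = "nf") -> NFImage:
    outdir = Path(outdir)
    values = tifffile.imread(outdir / f"{stem}.tif").astype(float)
    mask = tifffile.imread(outdir / f"{stem}_mask.tif").astype(bool)
    return NFImage(values=values, valid_mask=mask)


def estimates_to_frame(estimates: Sequence[NFEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pad_row": [e.pad_id[0] for e in estimates],
            "pad_col": [e.pad_id[1] for e in estimates],
            "motif_label": [e.motif_label for e in estimates],
            "reference_n_bp": [e.reference_n_bp for e in estimates],
            "nf_mean": [e.nf_mean for e in estimates],
            "nf_sd": [np.nan if e.nf_sd is None else e.nf_sd for e in estimates],
            "n_pixels": [e.n_pixels for e in estimates],
            "status": [e.status for e in estimates],
        }
    )


def write_estimates_csv(path: str | Path, estimates: Sequence[NFEstimate]) -> None:
    estimates_to_frame(estimates).to_csv(path, index=False, float_format="%.6g")


def read_estimates_csv(path: str | Path) -> list[NFEstimate]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        sd = None if pd.isna(row.nf_sd) else float(row.nf_sd)
        out.append(
            NFEstimate(
                pad_id=(int(row.pad_row), int(row.pad_col)),
                motif_label=str(row.motif_label),
                reference_n_bp=int(row.reference_n_bp),
                nf_mean=float(row.nf_mean),
                nf_sd=sd,
                n_pixels=int(row.n_pixels),
                status=str(row.status),
            )
        )
    return out
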