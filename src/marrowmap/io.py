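"""Reading and writing of micrograph sets, tables and configs.

Images travel as one single-channel 16-bit grayscale TIFF per channel
(``<set>_<channel>.tif``), label masks as 16-bit label TIFFs, tables as
CSV, configs as JSON or YAML.  Coordinates are 0-based (row, col) pixel
indices throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fixtures import CHANNELS, GroundTruth, MicrographSet


def save_micrograph_set(mset: MicrographSet, outdir: Union[str, Path]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ch in CHANNELS:
        tifffile.imwrite(
            outdir / f"{mset.name}_{ch}.tif", mset.channels[ch].astype(np.uint16)
        )
    tifffile.imwrite(outdir / f"{mset.name}_lumen.tif", mset.lumen_labels)
    tifffile.imwrite(outdir / f"{mset.name}_wall.tif", mset.wall_labels)
    tifffile.imwrite(
        outdir / f"{mset.name}_bone.tif", mset.bone_mask.astype(np.uint16)
    )
    (outdir / f"{mset.name}_meta.json").write_text(
        json.dumps({"um_per_px": mset.um_per_px, "name": mset.name})
    )


def load_micrograph_set(outdir: Union[str, Path], name: str) -> MicrographSet:
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{name}_meta.json").read_text())
    channels = {
        ch: tifffile.imread(outdir / f"{name}_{ch}.tif") for ch in CHANNELS
    }
    return MicrographSet(
        name=name,
        channels=channels,
        lumen_labels=tifffile.imread(outdir / f"{name}_lumen.tif"),
        wall_labels=tifffile.imread(outdir / f"{name}_wall.tif"),
        bone_mask=tifffile.imread(outdir / f"{name}_bone.tif").astype(bool),
        um_per_px=float(meta["um_per_px"]),
    )


def save_ground_truth(truth: GroundTruth, outdir: Union[str, Path]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.vessel_table.to_csv(outdir / "vessel_table.csv", index=False)
    truth.imhc_points.to_csv(outdir / "imhc_points.csv", index=False)
    truth.distance_table.to_csv(outdir / "distance_table.csv", index=False)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def read_config(path: Union[str, Path]) -> dict:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return {}
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}
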