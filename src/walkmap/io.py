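"""File round-trips for movies, behavior, atlases, and components.

Movies and label volumes use NIfTI-1 (via nibabel) or multi-page TIFF
(via tifffile); behavior, regressors, and result tables use CSV with
fixed headers; specs and ground truth use JSON.  Internal array order
is (T, Z, Y, X); NIfTI files store (X, Y, Z, T) per convention.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .preprocess import FlyMeta, VolumeSeries
from .synth import BehaviorTrace, RegionAtlas
from .components import ComponentSet

BEHAVIOR_COLUMNS = ["frame", "forward_speed_mm_s", "rot_left_rad_s", "rot_right_rad_s", "label"]


def save_movie(movie: VolumeSeries, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, movie.data.astype(np.float32), photometric='minisblack')
        meta = {"frame_rate_hz": movie.frame_rate_hz, "space": movie.space,
                **dataclasses.asdict(movie.meta)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
        return
    # (T, Z, Y, X) -> (X, Y, Z, T)
    img = nib.Nifti1Image(np.transpose(movie.data, (3, 2, 1, 0)).astype(np.float32),
                          affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, 1.0 / movie.frame_rate_hz))
    img.header["descrip"] = f"space={movie.space}".encode()
    nib.save(img, path)
    meta = {"frame_rate_hz": movie.frame_rate_hz, "space": movie.space,
            **dataclasses.asdict(movie.meta)}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=1))


def _sidecar(path: Path) -> Path:
    if path.suffix in (".tif", ".tiff"):
        return path.with_suffix(path.suffix + ".json")
    return path.with_suffix("").with_suffix(".json")


def load_movie(path: str | Path) -> VolumeSeries:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    fly = FlyMeta(**{k: meta[k] for k in ("fly_id", "gal4", "gcamp", "substrate", "condition")})
    if path.suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.transpose(np.asanyarray(nib.load(path).dataobj), (3, 2, 1, 0))
    return VolumeSeries(np.asarray(data, dtype=np.float64), meta["frame_rate_hz"],
                        space=meta["space"], meta=fly)


def save_behavior(behavior: BehaviorTrace, path: str | Path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(behavior.n_frames),
        "forward_speed_mm_s": behavior.forward_speed,
        "rot_left_rad_s": behavior.rot_left,
        "rot_right_rad_s": behavior.rot_right,
        "label": behavior.label,
    })
    with open(path, "w") as fh:
        fh.write(f"# frame_rate_hz={behavior.frame_rate_hz}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def load_behavior(path: str | Path) -> BehaviorTrace:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# frame_rate_hz="):
            raise ValueError("behavior CSV missing frame_rate_hz header comment")
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"behavior CSV missing columns: {sorted(missing)}")
    return BehaviorTrace(df["forward_speed_mm_s"].to_numpy(),
                         df["rot_left_rad_s"].to_numpy(),
                         df["rot_right_rad_s"].to_numpy(),
                         df["label"].to_numpy(dtype=object), fs)


def save_atlas(atlas: RegionAtlas, volume_path: str | Path, names_path: str | Path) -> None:
    img = nib.Nifti1Image(np.transpose(atlas.labels, (2, 1, 0)).astype(np.int32),
                          affine=np.eye(4))
    nib.save(img, volume_path)
    pd.DataFrame(
        {"label": sorted(atlas.names), "name": [atlas.names[k] for k in sorted(atlas.names)]}
    ).to_csv(names_path, index=False)


def load_atlas(volume_path: str | Path, names_path: str | Path) -> RegionAtlas:
    labels = np.transpose(np.asanyarray(nib.load(volume_path).dataobj), (2, 1, 0))
    table = pd.read_csv(names_path)
    return RegionAtlas(labels.astype(np.int32),
                       dict(zip(table["label"].astype(int), table["name"])))


def save_components(cs: ComponentSet, maps_path: str | Path, tcs_path: str | Path) -> None:
    """Maps as a 4-D NIfTI stack (component on the 4th axis), time courses as CSV."""
    stack = np.transpose(cs.maps, (3, 2, 1, 0)).astype(np.float32)  # (X,Y,Z,K)
    nib.save(nib.Nifti1Image(stack, affine=np.eye(4)), maps_path)
    df = pd.DataFrame(cs.time_courses.T,
                      columns=[f"component_{k:02d}" for k in range(cs.n_components)])
    df.insert(0, "frame", np.arange(df.shape[0]))
    df.to_csv(tcs_path, index=False, float_format="%.10g")


def save_results_table(rows: list, path: str | Path) -> None:
    """RegressionResult list -> CSV, one row per (fly, unit, channel)."""
    pd.DataFrame([r.as_dict() for r in rows]).to_csv(path, index=False, float_format="%.10g")
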