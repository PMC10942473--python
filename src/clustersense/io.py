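"""Export helpers: TIFF stacks, ground-truth sidecars, tables and reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .synthetic import GroundTruth, ImageStack


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-channel stack as OME-TIFF (channels as series axis)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    acq = stack.acq
    meta = {"axes": "CZYX" if data.ndim == 4 else "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": acq.voxel_xy_nm / 1000, "PhysicalSizeXUnit": "um",
            "PhysicalSizeY": acq.voxel_xy_nm / 1000, "PhysicalSizeYUnit": "um",
            "PhysicalSizeZ": acq.voxel_z_nm / 1000, "PhysicalSizeZUnit": "um"}
    tifffile.imwrite(path, data, ome=True, metadata=meta)
    return path


def write_truth(truth: GroundTruth, outdir: str | Path, stem: str) -> list[Path]:
    """Ground-truth sidecar: JSON summary plus CSV tables where present."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    sidecar = {"seed": truth.seed,
               "extras": {k: v for k, v in truth.extras.items()
                          if np.isscalar(v)}}
    for name in ("nuclei", "clusters", "hotspots"):
        df = getattr(truth, name)
        if df is not None and len(df):
            p = outdir / f"{stem}_{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
            sidecar[name] = p.name
    if truth.points is not None:
        p = outdir / f"{stem}_points.csv"
        np.savetxt(p, truth.points, delimiter=",", header="x_um,y_um",
                   comments="")
        written.append(p)
        sidecar["points"] = p.name
    jp = outdir / f"{stem}_truth.json"
    jp.write_text(json.dumps(sidecar, indent=2, default=_coerce))
    written.append(jp)
    return written


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Write a label volume as 16-bit TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path


def dump_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_coerce))
    return path


def _coerce(o):
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"cannot serialize {type(o)!r}")
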