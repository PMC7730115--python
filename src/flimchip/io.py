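"""File formats: OME-TIFF time stacks, viability TIFFs, JSON sidecars, YAML configs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .scene import AcquisitionConfig, IRFModel, SceneGroundTruth


def write_flim_stack(path: str | Path, stack: np.ndarray, channel: str) -> None:
    """Write a (time, rows, cols) photon-count stack as OME-TIFF."""
    tifffile.imwrite(
        str(path),
        np.asarray(stack),
        ome=True,
        metadata={"axes": "TYX", "Channel": {"Name": channel}},
    )


def read_flim_stack(path: str | Path) -> np.ndarray:
    stack = tifffile.imread(str(path))
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D time stack, got shape {stack.shape}")
    return stack


def write_viability_image(path: str | Path, image: np.ndarray) -> None:
    """Write a (2, rows, cols) green/red image as a multichannel TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32),
                     metadata={"axes": "CYX"})


def read_viability_image(path: str | Path) -> np.ndarray:
    img = tifffile.imread(str(path))
    if img.ndim != 3 or img.shape[0] != 2:
        raise ValueError(f"{path}: expected a (2, rows, cols) image, got {img.shape}")
    return img


def write_sidecar(
    path: str | Path,
    scene: SceneGroundTruth,
    acq: AcquisitionConfig,
    irf: IRFModel,
    extra: dict | None = None,
) -> None:
    """Ground-truth sidecar: everything needed to score the pipeline."""
    payload = {
        "scene": scene.to_dict(),
        "acquisition": asdict(acq),
        "irf": {"fwhm_ps": irf.fwhm_ps, "t0_ps": irf.t0_ps,
                "bin_width_ps": irf.bin_width_ps},
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_sidecar(path: str | Path) -> dict:
    d = json.loads(Path(path).read_text())
    d["scene"] = SceneGroundTruth.from_dict(d["scene"])
    return d


def write_map_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(path: str | Path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
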