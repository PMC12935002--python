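"""Dataset serialization: OME-TIFF stacks, label TIFFs, truth CSV, manifest.

The manifest records the scene spec, optical model and seed, which is
sufficient to regenerate the dataset bit-identically (the generator is
deterministic given its seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ..optics import OpticalModel
from .scene import SceneResult, SceneSpec, generate_scene

MANIFEST_NAME = "manifest.json"


def write_dataset(result: SceneResult, out_dir: str | Path) -> dict[str, Path]:
    """Write stack + oracle label maps + ground truth + manifest to a
    directory; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / "stack.ome.tif",
        "cell_labels": out / "cell_labels.tif",
        "puncta_labels": out / "puncta_labels.tif",
        "truth": out / "truth.csv",
        "manifest": out / MANIFEST_NAME,
    }
    tifffile.imwrite(
        paths["stack"],
        result.stack.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TCYX",
            "Channel": {"Name": list(result.stack.channels)},
        },
    )
    tifffile.imwrite(paths["cell_labels"], np.stack(result.cell_labels).astype(np.int32), photometric="minisblack")
    tifffile.imwrite(paths["puncta_labels"], np.stack(result.puncta_labels).astype(np.int32), photometric="minisblack")
    result.truth.to_csv(paths["truth"], index=False)
    manifest = {
        "spec": json.loads(result.spec.model_dump_json()),
        "optics": json.loads(result.optics.model_dump_json()),
        "channels": list(result.stack.channels),
        "frame_interval_min": result.stack.frame_interval_min,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def read_labels(path: str | Path) -> list[np.ndarray]:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return [arr[i] for i in range(arr.shape[0])]


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def replay_manifest(manifest_path: str | Path) -> SceneResult:
    """Regenerate the exact dataset recorded in a manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    spec = SceneSpec.model_validate(manifest["spec"])
    optics = OpticalModel.model_validate(manifest["optics"])
    return generate_scene(spec, optics)
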