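"""File input/output with provenance headers.

Phantom images are written as MetaImage (.mhd/.raw) or NIfTI via SimpleITK,
meshes as ASCII PLY via trimesh, tables as CSV with ``#``-prefixed
provenance header lines (seed, config hash, stage), configs as YAML and run
manifests as JSON with SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import trimesh
import yaml


def config_hash(obj) -> str:
    """Stable short hash of a (nested) dataclass/dict configuration."""
    def norm(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: norm(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, dict):
            return {k: norm(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [norm(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o
    blob = json.dumps(norm(obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_image(image: np.ndarray, spacing: float, origin, path):
    """Write a volume as MetaImage (.mhd) or NIfTI (.nii/.nii.gz)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        np.transpose(image, (2, 1, 0))).astype(np.float32))
    img.SetSpacing((float(spacing),) * 3)
    img.SetOrigin(tuple(float(v) for v in origin))
    sitk.WriteImage(img, str(path))


def read_image(path):
    img = sitk.ReadImage(str(path))
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return arr, float(img.GetSpacing()[0]), np.array(img.GetOrigin())


def write_mesh(mesh: trimesh.Trimesh, path):
    Path(path).write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))


def write_table(df: pd.DataFrame, path, seed=None, cfg_hash=None, stage=None):
    """CSV with provenance comment header; read back with read_table."""
    with open(path, "w") as fh:
        fh.write(f"# hipfe stage={stage} seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_yaml(obj: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(entries: dict, path, seed, cfg_hash):
    manifest = {
        "seed": seed,
        "config": cfg_hash,
        "outputs": {name: {"path": str(p), "sha256": file_checksum(p)}
                    for name, p in entries.items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
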