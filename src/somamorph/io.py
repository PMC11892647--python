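"""Reading and writing of label volumes, meshes, tables, and configs.

Label volumes travel either as multi-page TIFF (pages along axis 0) with
a JSON spacing sidecar — TIFF carries no reliable 3D spacing metadata —
or as NRRD with the spacing in the header (raw encoding). Spacing is
always explicit; a volume without spacing metadata is an error, never a
silent default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from .phantom import LabelVolume

__all__ = [
    "read_label_volume",
    "write_label_volume",
    "sidecar_path",
    "write_mesh_ply",
    "save_yaml",
    "load_yaml",
]

_NRRD_TYPES = {
    "signed char": np.int8,
    "int8": np.int8,
    "uint8": np.uint8,
    "unsigned char": np.uint8,
    "short": np.int16,
    "int16": np.int16,
    "unsigned short": np.uint16,
    "uint16": np.uint16,
    "int": np.int32,
    "int32": np.int32,
    "unsigned int": np.uint32,
    "uint32": np.uint32,
    "long long": np.int64,
    "int64": np.int64,
    "uint64": np.uint64,
    "float": np.float32,
    "double": np.float64,
}


def sidecar_path(tiff_path: Path | str) -> Path:
    """Spacing sidecar filename for a TIFF label volume."""
    p = Path(tiff_path)
    return p.with_name(p.stem + ".spacing.json")


# ---------------------------------------------------------------------------
# NRRD (minimal raw-encoding subset)
# ---------------------------------------------------------------------------

def _write_nrrd(path: Path, volume: LabelVolume) -> None:
    arr = volume.labels
    dtype_name = {v: k for k, v in _NRRD_TYPES.items()}.get(arr.dtype.type, None)
    if dtype_name is None:
        dtype_name = "int32"
        arr = arr.astype(np.int32)
    sx, sy, sz = volume.spacing_um
    header = [
        "NRRD0004",
        "# somamorph label volume",
        f"type: {dtype_name}",
        "dimension: 3",
        f"sizes: {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}",
        "space dimension: 3",
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})",
        'space units: "microns" "microns" "microns"',
        "encoding: raw",
        "endian: little",
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n\n").encode())
        # NRRD stores the first listed axis fastest
        fh.write(np.ascontiguousarray(arr.T).tobytes())


def _read_nrrd(path: Path) -> LabelVolume:
    with open(path, "rb") as fh:
        raw = fh.read()
    head_end = raw.find(b"\n\n")
    if not raw.startswith(b"NRRD") or head_end < 0:
        raise ValueError(f"{path}: not a valid NRRD file")
    fields = {}
    for line in raw[:head_end].decode().splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        k, v = line.split(":", 1)
        fields[k.strip().lower()] = v.strip()
    if fields.get("encoding") != "raw":
        raise ValueError(f"{path}: only raw NRRD encoding is supported")
    dtype = _NRRD_TYPES.get(fields.get("type", ""))
    if dtype is None:
        raise ValueError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    if not np.issubdtype(dtype, np.integer):
        raise ValueError(f"{path}: label volumes must be integer-typed, got {fields['type']}")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    spacing = None
    if "space directions" in fields:
        vecs = [
            [float(x) for x in grp.strip("()").split(",")]
            for grp in fields["space directions"].split()
        ]
        spacing = tuple(float(np.linalg.norm(v)) for v in vecs)
    elif "spacings" in fields:
        spacing = tuple(float(s) for s in fields["spacings"].split())
    if spacing is None or any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: NRRD header carries no voxel spacing")
    data = np.frombuffer(raw[head_end + 2 :], dtype=dtype, count=int(np.prod(sizes)))
    arr = data.reshape(sizes[::-1]).T.copy()  # first listed axis is fastest
    return LabelVolume(labels=arr, spacing_um=spacing)


# ---------------------------------------------------------------------------
# public volume I/O
# ---------------------------------------------------------------------------

def write_label_volume(volume: LabelVolume, path: Path | str) -> Path:
    """Write a label volume as .nrrd or .tif/.tiff (+ spacing sidecar)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".nrrd":
        _write_nrrd(path, volume)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, volume.labels)
        sidecar = sidecar_path(path)
        sidecar.write_text(json.dumps({"spacing_um": list(volume.spacing_um)}))
    else:
        raise ValueError(f"unknown volume format {suffix!r} (use .nrrd, .tif or .tiff)")
    return path


def read_label_volume(path: Path | str) -> LabelVolume:
    """Read a label volume written by this package (NRRD or TIFF+sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".nrrd":
        return _read_nrrd(path)
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(
                f"{path}: label volumes must be integer-typed, got {arr.dtype}"
            )
        sidecar = sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"{path} has no spacing metadata: expected sidecar file {sidecar.name} "
                'with {"spacing_um": [sx, sy, sz]}'
            )
        meta = json.loads(sidecar.read_text())
        spacing = meta.get("spacing_um")
        if not spacing or len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"{sidecar}: invalid spacing_um {spacing!r}")
        return LabelVolume(labels=arr, spacing_um=tuple(float(s) for s in spacing))
    raise ValueError(f"unknown volume format {suffix!r} (use .nrrd, .tif or .tiff)")


# ---------------------------------------------------------------------------
# meshes and configs
# ---------------------------------------------------------------------------

def write_mesh_ply(mesh, path: Path | str, provenance: Optional[dict] = None) -> Path:
    """Binary PLY export (µm vertex units) with an optional JSON sidecar."""
    path = Path(path)
    mesh.export(path, file_type="ply")
    if provenance is not None:
        path.with_suffix(".provenance.json").write_text(json.dumps(provenance, indent=2))
    return path


def save_yaml(obj: dict, path: Path | str) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path: Path | str) -> dict:
    return yaml.safe_load(Path(path).read_text())
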