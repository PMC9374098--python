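"""Reading and writing volumes (NIfTI-1, NRRD) and JSON plan manifests.

NIfTI goes through nibabel. NRRD support is a compact reader/writer for the
subset this package emits: 3D float32, raw little-endian encoding, axis-aligned
``space directions``. Volumes are written at 32-bit float precision, which is
the package's storage precision, so round trips are lossless.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import GridSpec, ScalarVolume, VolumeKind

__all__ = ["read_volume", "write_volume", "VolumeFormatError"]


class VolumeFormatError(ValueError):
    """Malformed or unsupported volume file content."""


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    raise VolumeFormatError(f"cannot infer volume format from file name: {path}")


def read_volume(path, fmt: str | None = None, kind: VolumeKind = VolumeKind.DOSE_GY) -> ScalarVolume:
    """Read a 3D volume; grid metadata comes from the file header.

    Only axis-aligned (diagonal-affine) volumes are supported; oblique grids
    raise :class:`VolumeFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "nifti":
        return _read_nifti(path, kind)
    if fmt == "nrrd":
        return _read_nrrd(path, kind)
    raise VolumeFormatError(f"unknown format {fmt!r}")


def write_volume(volume: ScalarVolume, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "nifti":
        _write_nifti(volume, path)
    elif fmt == "nrrd":
        _write_nrrd(volume, path)
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------- NIfTI


def _write_nifti(volume: ScalarVolume, path: Path) -> None:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = volume.grid.spacing
    affine[:3, 3] = volume.grid.origin
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def _read_nifti(path: Path, kind: VolumeKind) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3D volume, got shape {data.shape}")
    affine = img.affine
    rot = affine[:3, :3]
    if np.abs(rot - np.diag(np.diag(rot))).max() > 1e-6:
        raise VolumeFormatError("oblique (non-diagonal affine) NIfTI not supported")
    spacing = tuple(float(abs(rot[i, i])) for i in range(3))
    origin = tuple(float(v) for v in affine[:3, 3])
    grid = GridSpec(data.shape, spacing, origin)
    return ScalarVolume(grid, data, kind)


# ----------------------------------------------------------------- NRRD


def _write_nrrd(volume: ScalarVolume, path: Path) -> None:
    g = volume.grid
    dirs = " ".join(
        "(%r,%r,%r)" % tuple(g.spacing[a] if i == a else 0.0 for i in range(3))
        for a in range(3)
    )
    header = (
        "NRRD0004\n"
        "type: float\n"
        "dimension: 3\n"
        "space: left-posterior-superior\n"
        f"sizes: {g.shape[0]} {g.shape[1]} {g.shape[2]}\n"
        f"space directions: {dirs}\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        "encoding: raw\n"
        f"space origin: ({g.origin[0]!r},{g.origin[1]!r},{g.origin[2]!r})\n"
        "\n"
    )
    with open(path, "wb") as f:
        f.write(header.encode("ascii"))
        # NRRD stores the first axis fastest
        f.write(volume.values.astype("<f4").tobytes(order="F"))


def _parse_vector(text: str) -> tuple[float, ...]:
    return tuple(float(t) for t in text.strip().lstrip("(").rstrip(")").split(","))


def _read_nrrd(path: Path, kind: VolumeKind) -> ScalarVolume:
    with open(path, "rb") as f:
        magic = f.readline().decode("ascii", "replace").strip()
        if not magic.startswith("NRRD"):
            raise VolumeFormatError(f"not an NRRD file: {path}")
        fields: dict[str, str] = {}
        while True:
            line = f.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").strip()
            if not text or text.startswith("#"):
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.strip()
        payload = f.read()

    if fields.get("encoding") != "raw":
        raise VolumeFormatError("only raw-encoded NRRD is supported")
    if fields.get("type") not in ("float", "float32"):
        raise VolumeFormatError("only float32 NRRD is supported")
    sizes = tuple(int(t) for t in fields["sizes"].split())
    if len(sizes) != 3:
        raise VolumeFormatError("expected a 3D NRRD")
    n_expected = int(np.prod(sizes)) * 4
    if len(payload) < n_expected:
        raise VolumeFormatError(
            f"data block too short: {len(payload)} bytes for sizes {sizes}"
        )
    data = np.frombuffer(payload[:n_expected], dtype="<f4").reshape(sizes, order="F")

    spacing = [1.0, 1.0, 1.0]
    if "space directions" in fields:
        vecs = [v for v in fields["space directions"].split(") ") if v.strip()]
        for a, v in enumerate(vecs):
            vec = _parse_vector(v)
            off_axis = [vec[i] for i in range(3) if i != a]
            if any(abs(c) > 1e-9 for c in off_axis):
                raise VolumeFormatError("oblique NRRD space directions not supported")
            spacing[a] = abs(vec[a])
    origin = (0.0, 0.0, 0.0)
    if "space origin" in fields:
        origin = _parse_vector(fields["space origin"])
    grid = GridSpec(sizes, tuple(spacing), origin)
    return ScalarVolume(grid, np.array(data), kind)


# -------------------------------------------------------------- manifests


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
        f.write("\n")


def read_manifest(path) -> dict:
    with open(path) as f:
        return json.load(f)


def ensure_dir(path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
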