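"""File formats: NIfTI images (with JSON sidecars), HDF5 sinograms, YAML specs.

2D images are stored as single-slice NIfTI volumes with the pixel spacing in
the affine; the unit tag and provenance flags go to a ``.json`` sidecar since
NIfTI has no standard slot for them.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .grids import ImageGrid
from .projection import ScannerGeometry, Sinogram
from .acquisition import Frame, FrameSet, ScanProtocol
from .phantom import PhantomSpec

__all__ = ["write_image", "read_image", "write_sinogram", "read_sinogram",
           "write_frameset", "read_frameset", "write_phantom_spec",
           "read_phantom_spec"]


def write_image(image: ImageGrid, path: str | Path) -> Path:
    path = Path(path)
    sy, sx = image.spacing_mm
    affine = np.diag([sx, sy, 1.0, 1.0])
    # store as (nx, ny, 1) so that NIfTI's (i, j, k) maps to (x, y, z)
    data = image.values.T[:, :, None].astype(np.float64)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") \
        else path.with_suffix("")
    meta = {"unit": image.unit, "spacing_mm": list(image.spacing_mm),
            **{k: v for k, v in image.meta.items()
               if isinstance(v, (str, int, float, bool))}}
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_image(path: str | Path) -> ImageGrid:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        data = data[:, :, 0]
    vals = data.T
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") \
        else path.with_suffix("")
    meta_path = Path(str(sidecar) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    zooms = img.header.get_zooms()
    spacing = tuple(meta.get("spacing_mm", (float(zooms[1]), float(zooms[0]))))
    grid = ImageGrid(vals, spacing, meta.pop("unit", "1"))
    meta.pop("spacing_mm", None)
    grid.meta.update(meta)
    return grid


def _geom_attrs(g: h5py.Group, geom: ScannerGeometry) -> None:
    g.attrs["n_angles"] = geom.n_angles
    g.attrs["n_bins"] = geom.n_bins
    g.attrs["bin_spacing_mm"] = geom.bin_spacing_mm
    g.attrs["ring_radius_mm"] = geom.ring_radius_mm


def _geom_from_attrs(g: h5py.Group) -> ScannerGeometry:
    return ScannerGeometry(int(g.attrs["n_angles"]), int(g.attrs["n_bins"]),
                           float(g.attrs["bin_spacing_mm"]),
                           float(g.attrs["ring_radius_mm"]))


def write_sinogram(sino: Sinogram, path: str | Path, name: str = "sinogram") -> Path:
    path = Path(path)
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("values", data=sino.values)
        if sino.valid is not None:
            g.create_dataset("valid", data=sino.valid)
        g.attrs["unit"] = sino.unit
        if sino.duration_s is not None:
            g.attrs["duration_s"] = sino.duration_s
        _geom_attrs(g, sino.geometry)
    return path


def read_sinogram(path: str | Path, name: str = "sinogram") -> Sinogram:
    with h5py.File(path, "r") as f:
        g = f[name]
        geom = _geom_from_attrs(g)
        valid = g["valid"][()] if "valid" in g else None
        return Sinogram(g["values"][()], str(g.attrs["unit"]), geom,
                        duration_s=float(g.attrs["duration_s"])
                        if "duration_s" in g.attrs else None,
                        valid=valid)


def write_frameset(frames: FrameSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        _geom_attrs(f, frames.geometry)
        for k, v in frames.protocol.to_dict().items():
            f.attrs[f"protocol/{k}"] = v
        f.create_dataset("duty", data=frames.duty)
        for i, fr in enumerate(frames.frames):
            g = f.create_group(f"frame_{i:03d}")
            g.attrs["kind"] = fr.kind
            g.attrs["t_start_s"] = fr.t_start_s
            g.attrs["duration_s"] = fr.sino.duration_s or 0.0
            g.create_dataset("counts", data=fr.sino.values)
            g.create_dataset("mask", data=fr.mask)
    return path


def read_frameset(path: str | Path) -> FrameSet:
    with h5py.File(path, "r") as f:
        geom = _geom_from_attrs(f)
        proto_kwargs = {k.split("/", 1)[1]: v for k, v in f.attrs.items()
                        if k.startswith("protocol/")}
        for key in ("n_tx_frames", "window_half_width", "orbit_positions", "seed"):
            if key in proto_kwargs:
                proto_kwargs[key] = int(proto_kwargs[key])
        if "model_decay" in proto_kwargs:
            proto_kwargs["model_decay"] = bool(proto_kwargs["model_decay"])
        protocol = ScanProtocol(**proto_kwargs)
        duty = f["duty"][()]
        frames = []
        for name in sorted(k for k in f if k.startswith("frame_")):
            g = f[name]
            sino = Sinogram(g["counts"][()], "counts", geom,
                            duration_s=float(g.attrs["duration_s"]))
            frames.append(Frame(str(g.attrs["kind"]), sino, g["mask"][()],
                                float(g.attrs["t_start_s"])))
        return FrameSet(frames, duty, geom, protocol)


def write_phantom_spec(spec: PhantomSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_plain(spec.to_dict()), sort_keys=False))
    return path


def read_phantom_spec(path: str | Path) -> PhantomSpec:
    return PhantomSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Recursively convert tuples/numpy scalars to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
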