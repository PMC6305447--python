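"""File formats: NIfTI volumes, b-tables, propagator containers, reports.

Tensor fields are written as 4-D NIfTI with the 6 components
``(xx, xy, xz, yy, yz, zz)`` on the last axis; the component order is
recorded in the header description and checked on read.  Concentration
series are 4-D NIfTI with snapshot times in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .fields import ScalarField, SymmetricTensorField, TENSOR_ORDER
from .phantom import AcquisitionScheme, GaussianMixturePropagatorField, TissueLabelMap

_TENSOR_DESCRIP = "cedsim tensor " + ",".join(TENSOR_ORDER)


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def _voxel_size(img: nib.Nifti1Image) -> float:
    return float(img.header.get_zooms()[0])


def save_scalar(path, f: ScalarField) -> None:
    img = nib.Nifti1Image(np.asarray(f.data, dtype=np.float64), _affine(f.voxel_size))
    img.header["descrip"] = f"cedsim scalar {f.role}".encode()[:79]
    nib.save(img, str(path))


def load_scalar(path, expected_shape=None) -> ScalarField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    _check_shape(path, data.shape, expected_shape)
    return ScalarField(data, voxel_size=_voxel_size(img))


def save_tensor(path, t: SymmetricTensorField) -> None:
    img = nib.Nifti1Image(np.asarray(t.data, dtype=np.float64), _affine(t.voxel_size))
    img.header["descrip"] = _TENSOR_DESCRIP.encode()[:79]
    nib.save(img, str(path))


def load_tensor(path, expected_shape=None) -> SymmetricTensorField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(f"{path}: expected a 6-component tensor volume, got {data.shape}")
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="replace")
    if descrip and "tensor" in descrip and ",".join(TENSOR_ORDER) not in descrip:
        raise ValueError(f"{path}: tensor component order mismatch ({descrip!r})")
    _check_shape(path, data.shape[:-1], expected_shape)
    return SymmetricTensorField(data, voxel_size=_voxel_size(img))


def save_labels(path, labels: TissueLabelMap) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.uint8), _affine(labels.voxel_size))
    img.header["descrip"] = b"cedsim labels 0=bg 1=GM 2=WM 3=CSF"
    nib.save(img, str(path))


def load_labels(path, expected_shape=None) -> TissueLabelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.uint8)
    _check_shape(path, data.shape, expected_shape)
    return TissueLabelMap(data, voxel_size=_voxel_size(img))


def _check_shape(path, shape, expected) -> None:
    if expected is not None and tuple(shape) != tuple(expected):
        raise ValueError(f"{path}: grid {tuple(shape)} does not match expected {tuple(expected)}")


def check_same_grid(**named_shapes) -> None:
    """Raise with per-file shapes if the inputs do not share one grid."""
    shapes = {k: tuple(v) for k, v in named_shapes.items()}
    if len(set(shapes.values())) > 1:
        detail = ", ".join(f"{k}={v}" for k, v in shapes.items())
        raise ValueError(f"input grids do not match: {detail}")


# ---------------------------------------------------------------------------
# Concentration series


def save_concentration_series(
    path, volumes: dict[float, np.ndarray], voxel_size: float
) -> None:
    """4-D NIfTI of snapshots (sorted by time) + JSON sidecar of times."""
    times = sorted(volumes)
    stack = np.stack([volumes[t] for t in times], axis=-1)
    img = nib.Nifti1Image(stack.astype(np.float64), _affine(voxel_size))
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii(.gz)
    Path(str(sidecar) + ".json").write_text(json.dumps({"snapshot_times_s": times}))


def load_concentration_series(path) -> tuple[dict[float, np.ndarray], float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    sidecar = Path(str(path)).with_suffix("").with_suffix("")
    times = json.loads(Path(str(sidecar) + ".json").read_text())["snapshot_times_s"]
    if len(times) != data.shape[-1]:
        raise ValueError(f"{path}: sidecar lists {len(times)} times for {data.shape[-1]} volumes")
    return {t: data[..., i] for i, t in enumerate(times)}, _voxel_size(img)


# ---------------------------------------------------------------------------
# b-table


def save_btable(path, scheme: AcquisitionScheme) -> None:
    """Plain-text b-table, one line per volume: ``b gx gy gz`` (b in s/mm^2)."""
    with open(path, "w") as fh:
        fh.write(f"# cedsim b-table; delta_diffusion_s={scheme.delta_diffusion}\n")
        for b, g in zip(scheme.b_values, scheme.directions):
            fh.write(f"{b:.6g} {g[0]:.10f} {g[1]:.10f} {g[2]:.10f}\n")


def load_btable(path) -> AcquisitionScheme:
    delta = 0.03
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "delta_diffusion_s=" in line:
                delta = float(line.split("delta_diffusion_s=")[1])
            continue
        rows.append([float(x) for x in line.split()])
    arr = np.array(rows)
    b = arr[:, 0]
    return AcquisitionScheme(b, arr[:, 1:4], n_b0=int((b == 0).sum()), delta_diffusion=delta)


# ---------------------------------------------------------------------------
# Propagator container (HDF5)


def save_propagators(path, prop: GaussianMixturePropagatorField) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["delta_s"] = prop.delta
        fh.attrs["voxel_size_mm"] = prop.voxel_size
        fh.create_dataset("weights", data=prop.weights, compression="gzip")
        fh.create_dataset("tensors", data=prop.tensors, compression="gzip")
        fh.create_dataset("n_components", data=prop.n_components)


def load_propagators(path) -> GaussianMixturePropagatorField:
    with h5py.File(path, "r") as fh:
        return GaussianMixturePropagatorField(
            weights=fh["weights"][()],
            tensors=fh["tensors"][()],
            n_components=fh["n_components"][()],
            delta=float(fh.attrs["delta_s"]),
            voxel_size=float(fh.attrs["voxel_size_mm"]),
        )


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
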