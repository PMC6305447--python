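"""Voxel field containers and symmetric-tensor linear algebra.

Symmetric 3x3 tensors are stored as 6-vectors in the fixed component order
``(xx, xy, xz, yy, yz, zz)``.  All diffusivity-like tensors carry mm^2/s;
calibrated conductivities carry mm^2 Pa^-1 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Component order of the 6-vector tensor storage.
TENSOR_ORDER = ("xx", "xy", "xz", "yy", "yz", "zz")

# (row, col) index of each of the 6 components in the 3x3 matrix.
_VOIGT_IJ = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def vec6_to_mat(v: np.ndarray) -> np.ndarray:
    """Expand ``(..., 6)`` tensor components to full ``(..., 3, 3)`` matrices."""
    v = np.asarray(v)
    m = np.empty(v.shape[:-1] + (3, 3), dtype=v.dtype)
    for k, (i, j) in enumerate(_VOIGT_IJ):
        m[..., i, j] = v[..., k]
        m[..., j, i] = v[..., k]
    return m


def mat_to_vec6(m: np.ndarray) -> np.ndarray:
    """Compress ``(..., 3, 3)`` symmetric matrices to ``(..., 6)`` components."""
    m = np.asarray(m)
    v = np.empty(m.shape[:-2] + (6,), dtype=m.dtype)
    for k, (i, j) in enumerate(_VOIGT_IJ):
        v[..., k] = 0.5 * (m[..., i, j] + m[..., j, i])
    return v


def quadratic_form(v6: np.ndarray, g: np.ndarray) -> np.ndarray:
    """g^T M g for tensors in 6-vector form; broadcasts over leading axes.

    ``v6``: (..., 6); ``g``: (..., 3) unit (or any) vectors.
    """
    gx, gy, gz = g[..., 0], g[..., 1], g[..., 2]
    return (
        v6[..., 0] * gx * gx
        + v6[..., 3] * gy * gy
        + v6[..., 5] * gz * gz
        + 2.0 * (v6[..., 1] * gx * gy + v6[..., 2] * gx * gz + v6[..., 4] * gy * gz)
    )


def design_row(g: np.ndarray) -> np.ndarray:
    """Row(s) r such that r @ v6 == g^T M g, matching TENSOR_ORDER."""
    gx, gy, gz = g[..., 0], g[..., 1], g[..., 2]
    return np.stack(
        [gx * gx, 2 * gx * gy, 2 * gx * gz, gy * gy, 2 * gy * gz, gz * gz], axis=-1
    )


def spd_sqrt(m: np.ndarray) -> np.ndarray:
    """Matrix square root of batches of symmetric PSD 3x3 matrices."""
    w, q = np.linalg.eigh(m)
    w = np.clip(w, 0.0, None)
    return np.einsum("...ik,...k,...jk->...ij", q, np.sqrt(w), q)


def repair_spd(v6: np.ndarray, floor_frac: float = 1e-12) -> np.ndarray:
    """Clamp negative eigenvalues to ``floor_frac`` times the mean eigenvalue.

    Near-zero tensors (mean eigenvalue <= 0) are returned unchanged apart from
    the clamp at zero.  Required before eigenvalue-normalised calibration and
    before handing conductivities to the flow solver.
    """
    m = vec6_to_mat(np.asarray(v6, dtype=float))
    w, q = np.linalg.eigh(m)
    mean = w.mean(axis=-1, keepdims=True)
    floor = np.where(mean > 0, floor_frac * mean, 0.0)
    w = np.maximum(w, floor)
    return mat_to_vec6(np.einsum("...ik,...k,...jk->...ij", q, w, q))


@dataclass
class SymmetricTensorField:
    """Per-voxel symmetric 3x3 tensor volume.

    Parameters
    ----------
    data:
        Array of shape ``(*vol_shape, 6)`` in :data:`TENSOR_ORDER`.
    voxel_size:
        Isotropic edge length of a voxel in mm.
    mask:
        Boolean volume; tensors outside are ignored (and zeroed on request).
    """

    data: np.ndarray
    voxel_size: float = 1.2
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[-1] != 6:
            raise ValueError("tensor field must have a trailing axis of length 6")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:-1], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:-1]:
                raise ValueError("mask shape does not match tensor volume")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    def matrices(self) -> np.ndarray:
        return vec6_to_mat(self.data)

    def trace(self) -> np.ndarray:
        return self.data[..., 0] + self.data[..., 3] + self.data[..., 5]

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues per voxel, ascending (numpy convention)."""
        return np.linalg.eigvalsh(self.matrices())

    def repaired(self, floor_frac: float = 1e-12) -> "SymmetricTensorField":
        return SymmetricTensorField(
            repair_spd(self.data, floor_frac), self.voxel_size, self.mask.copy()
        )

    @classmethod
    def from_matrices(
        cls, m: np.ndarray, voxel_size: float = 1.2, mask: np.ndarray | None = None
    ) -> "SymmetricTensorField":
        return cls(mat_to_vec6(m), voxel_size, mask)

    @classmethod
    def constant(
        cls,
        tensor: np.ndarray,
        vol_shape: tuple[int, ...],
        voxel_size: float = 1.2,
        mask: np.ndarray | None = None,
    ) -> "SymmetricTensorField":
        """Homogeneous field: the same 3x3 tensor (or 6-vector) everywhere."""
        tensor = np.asarray(tensor, dtype=float)
        v6 = mat_to_vec6(tensor) if tensor.shape == (3, 3) else tensor
        data = np.broadcast_to(v6, tuple(vol_shape) + (6,)).copy()
        return cls(data, voxel_size, mask)


@dataclass
class ScalarField:
    """Per-voxel scalar volume with a role tag (``"fa"``, ``"dc"``, ...)."""

    data: np.ndarray
    role: str = ""
    voxel_size: float = 1.2
    mask: np.ndarray | None = None
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.data)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def in_mask(self) -> np.ndarray:
        return self.data[self.mask]
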