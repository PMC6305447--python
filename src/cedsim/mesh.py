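"""Voxelized finite-volume mesh.

Mesh cells coincide with image voxels, so tissue properties transfer
voxel-by-voxel with no interpolation.  Connectivity is 6-neighbor (face)
only; tensor cross-derivative couplings enter through the flux
discretization in the solver, not the mesh graph.  Cell centers sit at
``(i + 1/2) h`` with 0-based voxel indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class VoxelMesh:
    """Regular voxel mesh restricted to a mask.

    ``cell_index`` maps voxel coordinates to a dense cell id (-1 outside);
    ``neighbors`` is ``(n_cells, 6)`` with columns ordered
    ``(-x, +x, -y, +y, -z, +z)`` and -1 where the face is a boundary face.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    mask: np.ndarray
    cell_index: np.ndarray  # (*shape,) int, -1 outside mask
    cells: np.ndarray  # (n_cells, 3) voxel coordinates
    neighbors: np.ndarray  # (n_cells, 6) cell ids or -1

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_volume(self) -> float:
        return float(self.voxel_size**3)

    @property
    def face_area(self) -> float:
        return float(self.voxel_size**2)

    @property
    def n_boundary_faces(self) -> int:
        return int(np.count_nonzero(self.neighbors < 0))

    def boundary_faces(self) -> np.ndarray:
        """(n_bfaces, 2) array of (cell id, face slot); slot k encodes axis
        k//2 and direction (-1)**(k%2==0)... slot order matches ``neighbors``."""
        cell, slot = np.nonzero(self.neighbors < 0)
        return np.stack([cell, slot], axis=1)

    def interior_faces(self) -> np.ndarray:
        """(n_faces, 3): (cell_lo, cell_hi, axis), each interior face once."""
        faces = []
        for axis in range(3):
            slot = 2 * axis + 1  # +axis neighbor
            nb = self.neighbors[:, slot]
            has = nb >= 0
            faces.append(
                np.stack([np.flatnonzero(has), nb[has], np.full(int(has.sum()), axis)], axis=1)
            )
        return np.concatenate(faces, axis=0)

    def field_at_cells(self, volume: np.ndarray) -> np.ndarray:
        """Gather a voxel volume (trailing axes preserved) at the mesh cells."""
        return volume[self.mask]

    def cells_to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-cell values back to a voxel volume."""
        out_shape = self.shape + values.shape[1:]
        out = np.full(out_shape, fill, dtype=values.dtype)
        out[self.mask] = values
        return out


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def build_mesh(mask: np.ndarray, voxel_size: float = 1.2) -> VoxelMesh:
    """Build the voxelized mesh over a mask.

    The mask must be non-empty; if it is not 6-connected the largest
    connected component is kept with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if not mask.any():
        raise ValueError("mask is empty")
    lab, n_comp = ndimage.label(mask, structure=_STRUCT6)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n_comp + 1))
        keep = 1 + int(np.argmax(sizes))
        warnings.warn(
            f"mask has {n_comp} connected components; keeping the largest "
            f"({int(sizes.max())} of {int(mask.sum())} voxels)",
            stacklevel=2,
        )
        mask = lab == keep

    cell_index = np.full(mask.shape, -1, dtype=np.int64)
    cells = np.argwhere(mask)
    cell_index[mask] = np.arange(len(cells))

    neighbors = np.full((len(cells), 6), -1, dtype=np.int64)
    for axis in range(3):
        for sign, slot in ((-1, 2 * axis), (+1, 2 * axis + 1)):
            shifted = cells[:, axis] + sign
            ok = (shifted >= 0) & (shifted < mask.shape[axis])
            coords = cells[ok].copy()
            coords[:, axis] = shifted[ok]
            nb = cell_index[tuple(coords.T)]
            col = np.full(len(cells), -1, dtype=np.int64)
            col[ok] = nb
            neighbors[:, slot] = col

    return VoxelMesh(
        shape=tuple(mask.shape),
        voxel_size=float(voxel_size),
        mask=mask,
        cell_index=cell_index,
        cells=cells,
        neighbors=neighbors,
    )


def refine_mesh(
    mesh: VoxelMesh, fields: dict[str, np.ndarray] | None = None, factor: int = 2
) -> tuple[VoxelMesh, dict[str, np.ndarray]]:
    """Split every cell into ``factor**3`` children (piecewise-constant fields).

    ``fields`` maps names to voxel volumes (scalar or with trailing axes,
    e.g. tensor 6-vectors); each child inherits its parent's value, which
    mirrors voxel-wise property assignment on the finer grid.
    """
    factor = int(factor)
    if factor < 2:
        raise ValueError("refinement factor must be an integer >= 2")

    def upsample(vol: np.ndarray) -> np.ndarray:
        out = vol
        for axis in range(3):
            out = np.repeat(out, factor, axis=axis)
        return out

    fine_mask = upsample(mesh.mask)
    fine = build_mesh(fine_mask, mesh.voxel_size / factor)
    mapped = {name: upsample(vol) for name, vol in (fields or {}).items()}
    return fine, mapped
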