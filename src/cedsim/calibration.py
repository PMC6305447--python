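"""Water-to-drug tensor calibration.

The water tensors set the *shape* (eigenvectors and eigenvalue ratios) of
the drug-transport tensors; tissue-specific scalar constants set their
magnitude.  Per voxel the eigenvalues are rescaled by their average (so
their mean is exactly 1), then

* ``D_drug = D_cal * xi_D Lambda_bar_D xi_D^T``   (drug diffusivity)
* ``K_drug = K_cal(tissue) * xi_D Lambda_bar_D xi_D^T``  (hydraulic conductivity)
* ``R_drug = D_cal * xi_R Lambda_bar_R xi_R^T``
* ``T_drug = K_cal(tissue) * xi_R Lambda_bar_R xi_R^T``  (effective permeability)

so each drug tensor shares eigenvectors with its water parent.  The
conductivity constants encode that interstitial flow in WM can be ~100x
faster than in GM; porosity is the extracellular volume fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import ScalarField, SymmetricTensorField, mat_to_vec6
from .phantom import BACKGROUND, CSF, GM, WM, TissueLabelMap


@dataclass
class CalibrationConstants:
    """Calibration scales and porosities.

    ``d_cal`` is in mm^2/s; the ``k_cal_*`` carry mm^2 Pa^-1 s^-1.  CSF
    values are not established in the source literature: the defaults treat
    CSF as free-fluid-like (conductivity equal to WM, porosity 0.9) to avoid
    artificial barriers at ventricle boundaries; both are configurable.
    """

    d_cal: float = 1e-12
    k_cal_wm: float = 1.3e-12
    k_cal_gm: float = 0.013e-12
    k_cal_csf: float = 1.3e-12
    porosity_gm: float = 0.21
    porosity_wm: float = 0.19
    porosity_csf: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "d_cal",
            "k_cal_wm",
            "k_cal_gm",
            "k_cal_csf",
            "porosity_gm",
            "porosity_wm",
            "porosity_csf",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def k_cal_map(self) -> dict[int, float]:
        return {GM: self.k_cal_gm, WM: self.k_cal_wm, CSF: self.k_cal_csf}

    def porosity_table(self) -> dict[int, float]:
        return {GM: self.porosity_gm, WM: self.porosity_wm, CSF: self.porosity_csf}


@dataclass
class DrugTensorSet:
    """Calibrated drug tensors plus porosity; D/K derive from the diffusion
    tensor, R/T from the displacement-covariance tensor."""

    D_drug: SymmetricTensorField
    K_drug: SymmetricTensorField
    R_drug: SymmetricTensorField
    T_drug: SymmetricTensorField
    porosity: ScalarField


def rescale_eigensystem(
    t: SymmetricTensorField, eps: float = 1e-20
) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose and normalise eigenvalues by their per-voxel average.

    Returns ``(eigvecs, normalized_eigvals)`` with eigenvalues sorted
    descending; the normalised eigenvalues average exactly 1 per voxel.
    Near-zero tensors (mean eigenvalue < eps) are flagged isotropic-unit:
    normalised eigenvalues (1, 1, 1).
    """
    w, q = np.linalg.eigh(t.matrices())  # ascending
    w = w[..., ::-1]
    q = q[..., ::-1]
    mean = w.mean(axis=-1, keepdims=True)
    degenerate = mean[..., 0] < eps
    safe_mean = np.where(mean < eps, 1.0, mean)
    wn = w / safe_mean
    wn[degenerate] = 1.0
    # enforce exact unit mean (guard against round-off)
    wn = wn / wn.mean(axis=-1, keepdims=True)
    return q, wn


def _scaled_reconstruction(
    t: SymmetricTensorField, scale: np.ndarray | float
) -> SymmetricTensorField:
    q, wn = rescale_eigensystem(t)
    m = np.einsum("...ik,...k,...jk->...ij", q, wn, q)
    data = mat_to_vec6(m) * np.asarray(scale)[..., None]
    data[~t.mask] = 0.0
    return SymmetricTensorField(data, t.voxel_size, t.mask)


def porosity_map(labels: TissueLabelMap, consts: CalibrationConstants) -> ScalarField:
    """Porosity phi per voxel from the tissue table; background excluded."""
    table = consts.porosity_table()
    out = np.zeros(labels.shape)
    for code, phi in table.items():
        out[labels.labels == code] = phi
    return ScalarField(
        out, role="porosity", voxel_size=labels.voxel_size, mask=labels.mask
    )


def build_drug_tensors(
    Dw: SymmetricTensorField,
    Rw: SymmetricTensorField,
    labels: TissueLabelMap,
    consts: CalibrationConstants | None = None,
) -> DrugTensorSet:
    """Full calibration chain from water tensors to drug-transport tensors."""
    consts = consts or CalibrationConstants()
    if Dw.shape != Rw.shape or Dw.shape != labels.shape:
        raise ValueError("water tensors and labels must share a grid")
    lab = labels.labels
    known = np.isin(lab, (BACKGROUND, GM, WM, CSF))
    if not known.all():
        raise ValueError("label map contains unknown tissue codes")
    mask = labels.mask & Dw.mask & Rw.mask
    unknown_in_mask = mask & (lab == BACKGROUND)
    if unknown_in_mask.any():
        raise ValueError("tensor mask extends outside the labelled tissue")

    k_cal = np.zeros(labels.shape)
    for code, k in consts.k_cal_map().items():
        k_cal[lab == code] = k

    Dm = SymmetricTensorField(Dw.data, Dw.voxel_size, mask)
    Rm = SymmetricTensorField(Rw.data, Rw.voxel_size, mask)
    return DrugTensorSet(
        D_drug=_scaled_reconstruction(Dm, consts.d_cal),
        K_drug=_scaled_reconstruction(Dm, k_cal),
        R_drug=_scaled_reconstruction(Rm, consts.d_cal),
        T_drug=_scaled_reconstruction(Rm, k_cal),
        porosity=porosity_map(labels, consts),
    )
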