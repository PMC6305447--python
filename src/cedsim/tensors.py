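"""Water-tensor estimation and scalar comparison maps.

Two microstructure summaries are estimated per voxel:

* ``D_w`` — the classical diffusion tensor, a monoexponential (Gaussian)
  fit of the log-signal over both shells;
* ``R_w`` — the displacement-covariance tensor (propagator second moment
  divided by ``2 Delta``), either read off the ground-truth mixture or
  estimated from the two-shell signals via the cumulant expansion
  ``log S = log S0 - b a_g + b^2 c_g`` (two shells + b0 determine the
  quadratic per direction exactly; the b->0 apparent diffusivity ``a_g``
  is the directional second moment / 2 Delta).

For Gaussian diffusion the two coincide; restriction and hindrance make
``R_w`` exceed the monoexponential fit, and the Difference in Covariances
(DC) map quantifies that non-Gaussianity.
"""

from __future__ import annotations

import numpy as np

from .fields import (
    ScalarField,
    SymmetricTensorField,
    design_row,
    repair_spd,
    spd_sqrt,
    vec6_to_mat,
)
from .phantom import AcquisitionScheme, GaussianMixturePropagatorField, SignalVolume
from . import phantom as _phantom


def _check_directions(scheme: AcquisitionScheme) -> None:
    g = scheme.directions[scheme.weighted]
    rows = design_row(np.unique(np.round(g, 12), axis=0))
    if np.linalg.matrix_rank(rows) < 6:
        raise ValueError("need at least 6 non-collinear weighted directions")


def fit_dt(
    signals: SignalVolume,
    scheme: AcquisitionScheme | None = None,
    weighted: bool = False,
) -> SymmetricTensorField:
    """Diffusion-tensor fit: linear least squares of log S over both shells.

    Returns the fitted tensor field; the fitted ``S0`` is attached as
    ``field.meta_s0``.  Voxels with any non-positive signal are flagged and
    excluded from the output mask.  ``weighted=True`` applies
    signal-squared WLS weights (useful with Rician noise; the noiseless
    path is plain OLS).
    """
    scheme = scheme or signals.scheme
    if scheme.n_b0 < 1:
        raise ValueError("DT fit requires at least one b0 volume")
    _check_directions(scheme)
    s = signals.signals
    valid = signals.mask & np.all(s > 0, axis=-1)

    # log S = X theta with theta = (log S0, 6 tensor components)
    rows = design_row(scheme.directions)  # (M, 6)
    X = np.concatenate([np.ones((scheme.n_volumes, 1)), -scheme.b_values[:, None] * rows], axis=1)
    y = np.empty_like(s)
    y[valid] = np.log(s[valid])
    y[~valid] = 0.0

    out = np.zeros(s.shape[:-1] + (6,))
    s0 = np.zeros(s.shape[:-1])
    yv = y[valid]
    if weighted:
        w = s[valid] ** 2
        theta = np.empty((yv.shape[0], 7))
        for i in range(yv.shape[0]):  # per-voxel WLS (weights vary by voxel)
            Xw = X * w[i][:, None]
            theta[i] = np.linalg.solve(X.T @ Xw, Xw.T @ yv[i])
    else:
        theta = yv @ np.linalg.pinv(X).T
    out[valid] = theta[:, 1:]
    s0[valid] = np.exp(theta[:, 0])
    field = SymmetricTensorField(out, signals.voxel_size, valid)
    field.meta_s0 = ScalarField(s0, role="s0", voxel_size=signals.voxel_size, mask=valid)
    return field


def _cumulant_directional(signals: SignalVolume, scheme: AcquisitionScheme):
    """Per-direction b->0 apparent diffusivity from the two-shell quadratic.

    Groups weighted volumes by gradient direction (antipodal directions are
    equivalent); each group must be sampled at two distinct b-values.
    Returns (a, dirs, valid): a is (*shape, n_dirs).
    """
    g = scheme.directions
    b = scheme.b_values
    weighted = scheme.weighted
    # canonicalise direction sign so g and -g group together
    gc = g.copy()
    flip = (gc[:, 2] < 0) | ((gc[:, 2] == 0) & (gc[:, 1] < 0)) | (
        (gc[:, 2] == 0) & (gc[:, 1] == 0) & (gc[:, 0] < 0)
    )
    gc[flip] *= -1
    key = np.round(gc, 9)
    uniq, inv = np.unique(key[weighted], axis=0, return_inverse=True)
    widx = np.flatnonzero(weighted)

    s = signals.signals
    valid = signals.mask & np.all(s > 0, axis=-1)
    logs0 = np.zeros(s.shape[:-1])
    b0_idx = np.flatnonzero(~weighted)
    logs0[valid] = np.log(s[valid][:, b0_idx].mean(axis=-1))

    a = np.zeros(s.shape[:-1] + (len(uniq),))
    for d in range(len(uniq)):
        cols = widx[inv == d]
        bs = b[cols]
        if len(np.unique(bs)) < 2:
            raise ValueError("cumulant R estimation needs two b-values per direction")
        # average duplicate shells, then solve the exact 2x2 quadratic system
        b_lo, b_hi = np.unique(bs)[:2]
        y_lo = np.zeros(s.shape[:-1])
        y_hi = np.zeros(s.shape[:-1])
        y_lo[valid] = np.log(s[valid][:, cols[bs == b_lo]].mean(axis=-1)) - logs0[valid]
        y_hi[valid] = np.log(s[valid][:, cols[bs == b_hi]].mean(axis=-1)) - logs0[valid]
        # y = -b a + b^2 c  =>  solve for a
        det = -b_lo * b_hi**2 + b_hi * b_lo**2
        a[..., d] = (b_hi**2 * y_lo - b_lo**2 * y_hi) / det
    return a, uniq, valid


def estimate_R(
    source: GaussianMixturePropagatorField | SignalVolume,
    scheme: AcquisitionScheme | None = None,
    mode: str = "auto",
) -> SymmetricTensorField:
    """Displacement-covariance tensor ``R_w`` in mm^2/s (covariance / 2 Delta).

    ``mode="ground_truth"`` (propagator input) returns ``sum w_i D_i``
    exactly.  ``mode="cumulant"`` (signal input) extracts the per-direction
    b->0 apparent diffusivity from the exact two-shell quadratic, clamps
    negative values to zero, and least-squares fits a symmetric tensor to
    the directional values.
    """
    if mode == "auto":
        mode = (
            "ground_truth"
            if isinstance(source, GaussianMixturePropagatorField)
            else "cumulant"
        )
    if mode == "ground_truth":
        if not isinstance(source, GaussianMixturePropagatorField):
            raise TypeError("ground_truth mode requires a propagator field")
        return _phantom.ground_truth_moments(source)
    if mode != "cumulant":
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(source, SignalVolume):
        raise TypeError("cumulant mode requires a signal volume")
    scheme = scheme or source.scheme
    _check_directions(scheme)
    a, dirs, valid = _cumulant_directional(source, scheme)
    n_clamped = int(np.count_nonzero(a[valid] < 0))
    a = np.clip(a, 0.0, None)
    rows = design_row(dirs)  # (n_dirs, 6)
    coeffs = np.linalg.pinv(rows)  # (6, n_dirs)
    data = a @ coeffs.T
    data[~valid] = 0.0
    field = SymmetricTensorField(data, source.voxel_size, valid)
    field.meta_clamped_directional = n_clamped
    return field


# ---------------------------------------------------------------------------
# Scalar maps


def _eigvals(t: SymmetricTensorField) -> np.ndarray:
    return np.linalg.eigvalsh(t.matrices())


def fa(t: SymmetricTensorField) -> ScalarField:
    """Fractional anisotropy from eigenvalues; FA of a zero tensor is 0."""
    lam = _eigvals(t)
    mean = lam.mean(axis=-1, keepdims=True)
    num = ((lam - mean) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    out = np.zeros(t.shape)
    nz = den > 0
    out[nz] = np.sqrt(1.5 * num[nz] / den[nz])
    out[~t.mask] = 0.0
    return ScalarField(out, role="fa", voxel_size=t.voxel_size, mask=t.mask)


def md(t: SymmetricTensorField) -> ScalarField:
    """Mean diffusivity (trace / 3), mm^2/s."""
    out = t.trace() / 3.0
    out = np.where(t.mask, out, 0.0)
    return ScalarField(out, role="md", voxel_size=t.voxel_size, mask=t.mask, units="mm^2/s")


def trace_ratio(
    R: SymmetricTensorField, D: SymmetricTensorField, eps: float = 1e-12
) -> ScalarField:
    """Per-voxel Tr(R)/Tr(D); voxels with Tr(D) < eps are masked out."""
    if R.shape != D.shape:
        raise ValueError("tensor fields must share a grid")
    trR, trD = R.trace(), D.trace()
    ok = R.mask & D.mask & (trD >= eps)
    out = np.zeros(R.shape)
    out[ok] = trR[ok] / trD[ok]
    f = ScalarField(out, role="trace_ratio", voxel_size=R.voxel_size, mask=ok)
    f.meta["n_masked_zero_trace"] = int(np.count_nonzero(R.mask & D.mask & ~ok))
    return f


def compute_dc(
    R: SymmetricTensorField,
    D: SymmetricTensorField,
    delta: float,
    repair: bool = True,
) -> ScalarField:
    """Difference in Covariances: second-order non-Gaussianity map, mm^2.

    Implemented as the squared Bures-Wasserstein distance between the
    zero-mean Gaussians with covariances ``Sigma_R = 2 delta R`` and
    ``Sigma_D = 2 delta D``::

        DC = Tr(Sigma_R) + Tr(Sigma_D)
             - 2 Tr[(Sigma_D^1/2 Sigma_R Sigma_D^1/2)^1/2]

    This is the minimum of E||r_tilde||^2 over couplings of the two
    displacement distributions: zero iff the actual second moment matches
    the Gaussian fit, growing with the covariance discrepancy.
    """
    if delta <= 0:
        raise ValueError("diffusion time must be positive")
    if R.shape != D.shape:
        raise ValueError("tensor fields must share a grid")
    rv, dv = R.data, D.data
    if repair:
        rv = repair_spd(rv)
        dv = repair_spd(dv)
    sig_r = 2.0 * delta * vec6_to_mat(rv)
    sig_d = 2.0 * delta * vec6_to_mat(dv)
    sd_half = spd_sqrt(sig_d)
    inner = spd_sqrt(sd_half @ sig_r @ sd_half)
    dc = (
        np.trace(sig_r, axis1=-2, axis2=-1)
        + np.trace(sig_d, axis1=-2, axis2=-1)
        - 2.0 * np.trace(inner, axis1=-2, axis2=-1)
    )
    dc = np.clip(dc, 0.0, None)  # round-off can leave tiny negatives
    mask = R.mask & D.mask
    dc = np.where(mask, dc, 0.0)
    return ScalarField(dc, role="dc", voxel_size=R.voxel_size, mask=mask, units="mm^2")
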