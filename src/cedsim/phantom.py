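"""Digital brain phantom: tissue labels, displacement propagators, dMRI signals.

The phantom stands in for a participant scan.  It produces

* a tissue label map (background / GM / WM / CSF) with a bent white-matter
  fiber tract and an embedded crossing region,
* a per-voxel zero-mean Gaussian-mixture displacement propagator
  ``P(r | r', Delta)`` whose mixture covariance is the ground-truth
  displacement second moment, and
* two-shell HARDI-like signals via the multi-tensor forward model
  ``S(b, g) = S0 * sum_i w_i exp(-b g^T D_i g)``.

Non-Gaussianity is concentrated in white matter: WM voxels mix an
anisotropic hindered compartment with a nearly-isotropic highly restricted
one, GM mixes two isotropic pools, CSF is a single fast Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fields import SymmetricTensorField, design_row, mat_to_vec6

# Tissue label codes.
BACKGROUND, GM, WM, CSF = 0, 1, 2, 3
LABEL_NAMES = {BACKGROUND: "background", GM: "GM", WM: "WM", CSF: "CSF"}


@dataclass
class TissueLabelMap:
    """Per-voxel tissue category plus phantom-side fiber geometry.

    ``fiber_tangent`` holds the local tract tangent (unit vector) for WM
    voxels; ``crossing`` flags WM voxels containing two fiber populations.
    """

    labels: np.ndarray  # uint8 volume of label codes
    voxel_size: float = 1.2
    fiber_tangent: np.ndarray | None = None  # (*shape, 3)
    crossing: np.ndarray | None = None  # bool volume

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == code))
            for code, name in LABEL_NAMES.items()
        }


@dataclass
class AcquisitionScheme:
    """Diffusion acquisition: b-values, gradient directions, diffusion time.

    One row per volume.  b in s/mm^2, directions unit 3-vectors (arbitrary
    for b = 0 rows), ``delta_diffusion`` is the effective diffusion time
    Delta in seconds.
    """

    b_values: np.ndarray
    directions: np.ndarray
    n_b0: int
    delta_diffusion: float = 0.03

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.b_values.ndim != 1 or self.directions.shape != (len(self.b_values), 3):
            raise ValueError("b_values must be (M,), directions (M, 3)")
        if np.any(self.b_values < 0):
            raise ValueError("b-values must be non-negative")
        if self.delta_diffusion <= 0:
            raise ValueError("diffusion time must be positive")
        weighted = self.b_values > 0
        norms = np.linalg.norm(self.directions[weighted], axis=1)
        if weighted.any() and np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("weighted gradient directions must be unit-norm")

    @property
    def n_volumes(self) -> int:
        return len(self.b_values)

    @property
    def weighted(self) -> np.ndarray:
        return self.b_values > 0

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.b_values[self.weighted])


@dataclass
class SignalVolume:
    """Per-voxel diffusion-weighted signals aligned with a scheme."""

    signals: np.ndarray  # (*vol_shape, M)
    s0: np.ndarray  # (*vol_shape,)
    scheme: AcquisitionScheme
    voxel_size: float = 1.2
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.signals.shape[:-1], dtype=bool)


@dataclass
class GaussianMixturePropagatorField:
    """Zero-mean Gaussian-mixture displacement propagator per voxel.

    Component ``i`` of a voxel is a zero-mean Gaussian with covariance
    ``2 * Delta * D_i``; ``weights`` sum to 1 over the active components
    (``n_components``).  The mixture covariance is ``2 * Delta * sum w_i D_i``.
    """

    weights: np.ndarray  # (*shape, K)
    tensors: np.ndarray  # (*shape, K, 6), mm^2/s
    n_components: np.ndarray  # (*shape,) int
    delta: float = 0.03
    voxel_size: float = 1.2

    @property
    def shape(self) -> tuple[int, ...]:
        return self.n_components.shape

    @property
    def mask(self) -> np.ndarray:
        return self.n_components > 0

    def validate(self, atol: float = 1e-12) -> None:
        wsum = self.weights.sum(axis=-1)
        bad = self.mask & (np.abs(wsum - 1.0) > atol)
        if bad.any():
            raise ValueError("mixture weights must sum to 1 in every masked voxel")
        if (self.weights < 0).any():
            raise ValueError("mixture weights must be non-negative")

    def mean_diffusivity_tensor(self) -> np.ndarray:
        """sum_i w_i D_i per voxel, (*shape, 6); covariance / (2 Delta)."""
        return np.einsum("...k,...kc->...c", self.weights, self.tensors)


# ---------------------------------------------------------------------------
# Tissue recipes


@dataclass
class PhantomTissueParams:
    """Per-tissue Gaussian-mixture recipes (diffusivities in mm^2/s).

    Defaults give mildly non-Gaussian GM (two isotropic pools), strongly
    non-Gaussian WM (anisotropic hindered pool + nearly isotropic highly
    restricted pool, aligned with the local tract tangent) and Gaussian CSF.
    """

    gm_fast: float = 1.0e-3
    gm_slow: float = 0.55e-3
    gm_fast_weight: float = 0.65
    wm_hindered_axial: float = 1.5e-3
    wm_hindered_radial: float = 0.5e-3
    wm_hindered_weight: float = 0.65
    wm_restricted: float = 0.12e-3  # near-isotropic restricted pool
    csf: float = 2.0e-3
    diffusivity_jitter: float = 0.03  # lognormal sigma, per voxel per component
    orientation_jitter: float = 0.05  # radians, per WM voxel
    delta: float = 0.03  # diffusion time, s


# ---------------------------------------------------------------------------
# Label generation

_PRESETS = ("default", "uniform_gm", "uniform_wm")


def generate_labels(
    shape: tuple[int, int, int],
    geometry_spec: str = "default",
    seed: int = 0,
    voxel_size: float = 1.2,
) -> TissueLabelMap:
    """Generate a synthetic tissue label volume.

    The ``default`` preset is an ellipsoidal brain with a CSF rim, a GM
    shell and an interior WM slab carrying a bent fiber tract plus an
    embedded crossing-fiber region.  ``uniform_gm`` / ``uniform_wm`` fill
    the whole ellipsoid with one tissue (useful for controlled solver runs).

    Deterministic for a fixed seed (the geometry itself is analytic; the
    seed only feeds downstream generators via convention).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 8:
        raise ValueError("phantom shape must be 3-D with at least 8 voxels per axis")
    if geometry_spec not in _PRESETS:
        raise ValueError(f"unknown geometry preset {geometry_spec!r}; use one of {_PRESETS}")

    idx = np.indices(shape, dtype=float)
    u = [(idx[a] - (shape[a] - 1) / 2.0) / (0.5 * shape[a]) for a in range(3)]
    rho = np.sqrt(sum((ua / 0.92) ** 2 for ua in u))  # normalised ellipsoid radius
    mask = rho < 1.0

    labels = np.zeros(shape, dtype=np.uint8)
    if geometry_spec == "uniform_gm":
        labels[mask] = GM
        return TissueLabelMap(labels, voxel_size)
    if geometry_spec == "uniform_wm":
        labels[mask] = WM
        tangent = np.zeros(shape + (3,))
        tangent[..., 0] = 1.0
        tangent[~mask] = 0.0
        return TissueLabelMap(labels, voxel_size, tangent, np.zeros(shape, dtype=bool))

    labels[mask] = GM
    labels[mask & (rho > 0.82)] = CSF
    wm = mask & (rho < 0.70) & (np.abs(u[2]) < 0.35)
    labels[wm] = WM

    # Bent fiber tract: in-plane tangent rotating smoothly with x.
    theta = (np.pi / 4.0) * u[0]
    tangent = np.zeros(shape + (3,))
    tangent[..., 0] = np.cos(theta)
    tangent[..., 1] = np.sin(theta)
    tangent[~wm] = 0.0

    crossing = wm & (np.abs(u[0]) < 0.22) & (np.abs(u[1]) < 0.22)

    lab_map = TissueLabelMap(labels, voxel_size, tangent, crossing)
    missing = [n for c, n in LABEL_NAMES.items() if c != BACKGROUND and (labels == c).sum() == 0]
    if missing:
        raise ValueError(
            f"shape {shape} too small to contain all compartments (missing {missing})"
        )
    return lab_map


# ---------------------------------------------------------------------------
# Propagator generation


def _axisymmetric_tensors(tangents: np.ndarray, axial: np.ndarray, radial: np.ndarray) -> np.ndarray:
    """Axially symmetric tensors radial*I + (axial-radial) t t^T, as 6-vectors."""
    outer = np.einsum("...i,...j->...ij", tangents, tangents)
    eye = np.eye(3)
    m = radial[..., None, None] * eye + (axial - radial)[..., None, None] * outer
    return mat_to_vec6(m)


def _jitter_orientations(t: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return t
    pert = t + sigma * rng.standard_normal(t.shape)
    return pert / np.linalg.norm(pert, axis=-1, keepdims=True)


def generate_propagators(
    labels: TissueLabelMap,
    tissue_params: PhantomTissueParams | None = None,
    seed: int = 0,
) -> GaussianMixturePropagatorField:
    """Assign a Gaussian-mixture displacement propagator to every tissue voxel.

    CSF voxels get a single isotropic Gaussian; GM voxels a two-pool
    isotropic mixture; WM voxels a hindered + restricted pair aligned with
    the local tract tangent, doubled to two crossed populations (at 90
    degrees in-plane) in the crossing region.  Per-voxel lognormal jitter of
    the component diffusivities and a small orientation jitter make distinct
    seeds produce distinct (but statistically identical) phantoms.
    """
    p = tissue_params or PhantomTissueParams()
    rng = np.random.default_rng(seed)
    shape = labels.shape
    kmax = 3  # hindered-1, hindered-2 (crossing only), restricted/second pool
    weights = np.zeros(shape + (kmax,))
    tensors = np.zeros(shape + (kmax, 6))
    ncomp = np.zeros(shape, dtype=int)

    lab = labels.labels
    eye6 = mat_to_vec6(np.eye(3))

    def scale_jitter(size):
        if p.diffusivity_jitter <= 0:
            return np.ones(size)
        return rng.lognormal(mean=0.0, sigma=p.diffusivity_jitter, size=size)

    csf = lab == CSF
    n = int(csf.sum())
    if n:
        tensors[csf, 0] = p.csf * scale_jitter((n, 1)) * eye6
        weights[csf, 0] = 1.0
        ncomp[csf] = 1

    gm = lab == GM
    n = int(gm.sum())
    if n:
        tensors[gm, 0] = p.gm_fast * scale_jitter((n, 1)) * eye6
        tensors[gm, 1] = p.gm_slow * scale_jitter((n, 1)) * eye6
        weights[gm, 0] = p.gm_fast_weight
        weights[gm, 1] = 1.0 - p.gm_fast_weight
        ncomp[gm] = 2

    wm = lab == WM
    n = int(wm.sum())
    if n:
        if labels.fiber_tangent is None:
            raise ValueError("WM voxels present but label map carries no fiber tangents")
        crossing = (
            labels.crossing if labels.crossing is not None else np.zeros(shape, dtype=bool)
        )
        single = wm & ~crossing
        cross = wm & crossing

        def hindered(tan, count):
            ax = p.wm_hindered_axial * scale_jitter(count)
            rad = p.wm_hindered_radial * scale_jitter(count)
            return _axisymmetric_tensors(tan, ax, rad)

        ns = int(single.sum())
        if ns:
            tan = _jitter_orientations(
                labels.fiber_tangent[single], p.orientation_jitter, rng
            )
            tensors[single, 0] = hindered(tan, ns)
            tensors[single, 1] = p.wm_restricted * scale_jitter((ns, 1)) * eye6
            weights[single, 0] = p.wm_hindered_weight
            weights[single, 1] = 1.0 - p.wm_hindered_weight
            ncomp[single] = 2

        nc = int(cross.sum())
        if nc:
            tan1 = _jitter_orientations(
                labels.fiber_tangent[cross], p.orientation_jitter, rng
            )
            # Second population: rotate 90 degrees about z (in-plane crossing).
            tan2 = np.stack([-tan1[:, 1], tan1[:, 0], tan1[:, 2]], axis=1)
            tan2 /= np.linalg.norm(tan2, axis=1, keepdims=True)
            tensors[cross, 0] = hindered(tan1, nc)
            tensors[cross, 1] = hindered(tan2, nc)
            tensors[cross, 2] = p.wm_restricted * scale_jitter((nc, 1)) * eye6
            w_h = p.wm_hindered_weight / 2.0
            weights[cross, 0] = w_h
            weights[cross, 1] = w_h
            weights[cross, 2] = 1.0 - p.wm_hindered_weight
            ncomp[cross] = 3

    unknown = labels.mask & (ncomp == 0)
    if unknown.any():
        raise ValueError("label map contains in-mask voxels with unknown tissue label")

    return GaussianMixturePropagatorField(
        weights, tensors, ncomp, delta=p.delta, voxel_size=labels.voxel_size
    )


# ---------------------------------------------------------------------------
# Signal synthesis and ground-truth moments


def fibonacci_directions(n: int) -> np.ndarray:
    """n approximately isotropically distributed unit vectors (Fibonacci sphere)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_default_scheme(
    n_dirs: int = 61,
    b_shells: tuple[float, ...] = (1200.0, 2400.0),
    n_b0: int = 1,
    delta: float = 0.03,
) -> AcquisitionScheme:
    """Two-shell HARDI-like scheme: b0 volumes then the same directions per shell."""
    dirs = fibonacci_directions(n_dirs)
    b = np.concatenate([[0.0] * n_b0] + [[bs] * n_dirs for bs in b_shells])
    g = np.concatenate([np.tile([[0.0, 0.0, 1.0]], (n_b0, 1))] + [dirs] * len(b_shells))
    return AcquisitionScheme(b, g, n_b0=n_b0, delta_diffusion=delta)


def synthesize_signals(
    propagators: GaussianMixturePropagatorField,
    scheme: AcquisitionScheme,
    noise_sigma: float = 0.0,
    seed: int = 0,
    s0: float = 1.0,
) -> SignalVolume:
    """Multi-tensor forward model, optionally with Rician (magnitude) noise.

    Noiseless: ``S_m = S0 sum_i w_i exp(-b_m g_m^T D_i g_m)``.  With noise,
    independent N(0, sigma*S0) perturbations on the two quadrature channels
    followed by the magnitude operation.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rows = design_row(scheme.directions)  # (M, 6)
    shape = propagators.shape
    m_tot = scheme.n_volumes
    signals = np.zeros(shape + (m_tot,))
    w = propagators.weights
    for m in range(m_tot):
        adc = propagators.tensors @ rows[m]  # (*shape, K)
        signals[..., m] = s0 * np.einsum(
            "...k,...k->...", w, np.exp(-scheme.b_values[m] * adc)
        )
    signals[~propagators.mask] = 0.0
    s0_vol = np.full(shape, float(s0))
    s0_vol[~propagators.mask] = 0.0
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.standard_normal(signals.shape) * noise_sigma * s0
        n2 = rng.standard_normal(signals.shape) * noise_sigma * s0
        signals = np.sqrt((signals + n1) ** 2 + n2**2)
        signals[~propagators.mask] = 0.0
    return SignalVolume(
        signals, s0_vol, scheme, voxel_size=propagators.voxel_size, mask=propagators.mask
    )


def ground_truth_moments(
    propagators: GaussianMixturePropagatorField,
) -> SymmetricTensorField:
    """Exact displacement second moment of the mixture, reported in mm^2/s.

    For zero-mean components the mixture covariance is ``2 Delta sum w_i D_i``;
    dividing by ``2 Delta`` gives ``sum w_i D_i``, the diffusivity-scaled
    convention used throughout.
    """
    return SymmetricTensorField(
        propagators.mean_diffusivity_tensor(),
        voxel_size=propagators.voxel_size,
        mask=propagators.mask,
    )


def sample_displacements(
    weights: np.ndarray,
    tensors6: np.ndarray,
    delta: float,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo displacement draws from a single voxel's mixture.

    Sampling oracle for the closed-form second moment: returns ``(n, 3)``
    displacements with covariance ``2 delta sum w_i D_i`` in the limit.
    """
    from .fields import vec6_to_mat

    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    out = np.empty((n, 3))
    for i in range(len(weights)):
        sel = comp == i
        if not sel.any():
            continue
        cov = 2.0 * delta * vec6_to_mat(tensors6[i])
        out[sel] = rng.multivariate_normal(np.zeros(3), cov, size=int(sel.sum()))
    return out
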