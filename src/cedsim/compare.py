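"""Concentration-comparison analytics for the two transport models.

Quantifies how accounting for diffusion non-Gaussianity changes the
predicted drug distribution: voxelwise fractional differences
``f = (C_R - C_D) / C_D``, distribution volumes (voxels reaching a
fraction of the maximum concentration), per-voxel sums of the DC
non-Gaussianity map along the Bresenham line from the infusion site,
their Pearson correlation with |f|, a paired t-test of the two
concentration fields, and the distribution-volume vs infused-volume
relationship across infusion rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fields import ScalarField


@dataclass
class ComparisonReport:
    """Collected comparison outputs for one (site, schedule) scenario."""

    f_floor: float
    fractional_difference: ScalarField | None = None
    distribution_volumes: dict = field(default_factory=dict)  # (model, t) -> mm^3
    path_dc: ScalarField | None = None
    pearson_r: float | None = None
    pearson_p: float | None = None
    t_stat: float | None = None
    t_p: float | None = None
    dv_fits: dict = field(default_factory=dict)  # rate -> fit dict

    def to_dict(self) -> dict:
        return {
            "f_floor": self.f_floor,
            "distribution_volumes_mm3": {
                f"{m}@{t}": v for (m, t), v in self.distribution_volumes.items()
            },
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "paired_t": self.t_stat,
            "paired_t_p": self.t_p,
            "dv_vs_infused": self.dv_fits,
        }


def fractional_difference(
    c_r: np.ndarray, c_d: np.ndarray, floor: float = 1e-3
) -> ScalarField:
    """f = (C_R - C_D)/C_D where C_D >= floor * max(C_D); masked elsewhere.

    The floor keeps the spreading front (where f can be large and
    meaningful) while excluding numerical zeros; changing it changes only
    the mask, never the values inside it.
    """
    c_r = np.asarray(c_r, dtype=float)
    c_d = np.asarray(c_d, dtype=float)
    if c_r.shape != c_d.shape:
        raise ValueError("concentration fields must share a grid")
    cmax = c_d.max() if c_d.size else 0.0
    mask = c_d >= floor * cmax if cmax > 0 else np.zeros(c_d.shape, dtype=bool)
    out = np.zeros(c_d.shape)
    out[mask] = (c_r[mask] - c_d[mask]) / c_d[mask]
    f = ScalarField(out, role="fractional_difference", mask=mask)
    f.meta["floor"] = floor
    return f


def distribution_volume(
    c: np.ndarray, voxel_size: float, fraction: float = 0.05
) -> float:
    """Volume (mm^3) of voxels where C >= fraction * max(C)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    c = np.asarray(c, dtype=float)
    cmax = c.max() if c.size else 0.0
    if cmax <= 0:
        return 0.0
    return float(np.count_nonzero(c >= fraction * cmax) * voxel_size**3)


def distribution_volume_mask(c: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Boolean mask of the voxels counted by :func:`distribution_volume`."""
    c = np.asarray(c, dtype=float)
    cmax = c.max() if c.size else 0.0
    if cmax <= 0:
        return np.zeros(c.shape, dtype=bool)
    return c >= fraction * cmax


def bresenham3d(a, b) -> list[tuple[int, int, int]]:
    """26-connected monotone digital line from voxel a to voxel b, inclusive.

    Classic integer error-accumulator algorithm; the driving axis is the
    largest absolute separation, ties broken with x > y > z precedence.
    The returned list has ``max |delta| + 1`` voxels.
    """
    a = tuple(int(v) for v in a)
    b = tuple(int(v) for v in b)
    d = [b[i] - a[i] for i in range(3)]
    ad = [abs(v) for v in d]
    s = [1 if v > 0 else -1 for v in d]
    drive = int(np.argmax(ad))  # argmax returns the first maximum: x > y > z
    n = ad[drive]
    pts = [a]
    if n == 0:
        return pts
    others = [i for i in range(3) if i != drive]
    err = [2 * ad[i] - n for i in others]
    cur = list(a)
    for _ in range(n):
        cur[drive] += s[drive]
        for j, i in enumerate(others):
            if err[j] > 0:
                cur[i] += s[i]
                err[j] -= 2 * n
            err[j] += 2 * ad[i]
        pts.append(tuple(cur))
    return pts


def path_dc_sum(
    dc: ScalarField | np.ndarray,
    source_voxel,
    targets: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Sum of DC over the Bresenham line from the source to each target.

    ``targets`` is (n, 3) integer voxel indices.  Voxels on a line that
    fall outside the mask contribute 0; the count of such skipped voxels is
    returned for logging.  The source must be inside the mask.
    """
    if isinstance(dc, ScalarField):
        dc_vol = dc.data
        mask = dc.mask if mask is None else mask
    else:
        dc_vol = np.asarray(dc)
        if mask is None:
            mask = np.ones(dc_vol.shape, dtype=bool)
    src = tuple(int(v) for v in source_voxel)
    if not mask[src]:
        raise ValueError(f"source voxel {src} is outside the mask")
    targets = np.asarray(targets, dtype=int)
    sums = np.zeros(len(targets))
    skipped = 0
    for i, tgt in enumerate(targets):
        total = 0.0
        for v in bresenham3d(src, tgt):
            if mask[v]:
                total += dc_vol[v]
            else:
                skipped += 1
        sums[i] = total
    return sums, skipped


def correlate_f_dc(
    f: np.ndarray, dc_sums: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of |f| against the path-DC sums (two-sided p).

    Flags degenerate inputs (fewer than 3 voxels or zero variance)."""
    f = np.asarray(f, dtype=float).ravel()
    dc_sums = np.asarray(dc_sums, dtype=float).ravel()
    if mask is not None:
        sel = np.asarray(mask, dtype=bool).ravel()
        f, dc_sums = f[sel], dc_sums[sel]
    if len(f) < 3:
        raise ValueError("correlation needs at least 3 voxels")
    if np.std(f) == 0 or np.std(dc_sums) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(np.abs(f), dc_sums)
    return float(r), float(p)


def paired_test(
    c_r: np.ndarray, c_d: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Paired t-test on voxelwise C_R - C_D over the supplied mask.

    The natural mask is the union of the two models' distribution volumes.
    """
    c_r = np.asarray(c_r, dtype=float).ravel()
    c_d = np.asarray(c_d, dtype=float).ravel()
    if mask is not None:
        sel = np.asarray(mask, dtype=bool).ravel()
        c_r, c_d = c_r[sel], c_d[sel]
    if len(c_r) < 2:
        raise ValueError("paired test needs at least 2 paired voxels")
    diff = c_r - c_d
    if np.allclose(diff, diff[0]) and np.std(diff) == 0 and diff[0] == 0:
        return 0.0, 1.0
    res = stats.ttest_rel(c_r, c_d)
    return float(res.statistic), float(res.pvalue)


def dv_vs_infused(series: dict[float, list[tuple[float, float]]]) -> dict[float, dict]:
    """Least-squares line of distribution volume against infused volume.

    ``series`` maps infusion rate -> list of (infused volume mm^3, V_d mm^3)
    points (>= 3 per rate).  Returns per-rate slope, intercept and R^2.
    """
    fits: dict[float, dict] = {}
    for rate, pts in series.items():
        if len(pts) < 3:
            raise ValueError(f"rate {rate}: need at least 3 (infused, V_d) points")
        x, y = np.array(pts, dtype=float).T
        res = stats.linregress(x, y)
        fits[rate] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
        }
    return fits
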