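"""Estimate the water diffusion tensor D_w and covariance tensor R_w.

D_w is the classical monoexponential (Gaussian) fit; R_w is the
displacement second moment / 2*Delta recovered from the exact two-shell
cumulant quadratic.  Restriction and hindrance make R_w exceed D_w, and
the Difference in Covariances (DC) maps that non-Gaussianity — it is
concentrated in white matter.
"""

import numpy as np

from cedsim import RunConfig
from cedsim.phantom import CSF, GM, WM
from cedsim.workflows import build_phantom, estimate_water_tensors

data = build_phantom(RunConfig(seed=7))
water = estimate_water_tensors(data, r_mode="cumulant")
lab = data.labels.labels

print(f"{'tissue':>6} {'FA(D)':>7} {'FA(R)':>7} {'MD(D)':>10} {'MD(R)':>10} {'Tr(R)/Tr(D)':>12} {'DC mm^2':>10}")
for name, code in (("GM", GM), ("WM", WM), ("CSF", CSF)):
    sel = lab == code
    print(
        f"{name:>6} {water.fa_d.data[sel].mean():7.3f} {water.fa_r.data[sel].mean():7.3f}"
        f" {water.md_d.data[sel].mean():10.2e} {water.md_r.data[sel].mean():10.2e}"
        f" {water.trace_ratio.data[sel].mean():12.3f} {water.dc.data[sel].mean():10.2e}"
    )

wm, gm = lab == WM, lab == GM
print("\nWhat the numbers mean:")
print(" - FA(R) > FA(D) in WM: the covariance tensor sees the anisotropy that the")
print("   Gaussian fit blurs away;", f"{(water.fa_r.data[wm] >= water.fa_d.data[wm]).mean():.0%}",
      "of WM voxels show the gain.")
print(" - Tr(R)/Tr(D) > 1: restricted pools depress the monoexponential fit.")
print(f" - DC mean in WM ({water.dc.data[wm].mean():.2e}) exceeds GM"
      f" ({water.dc.data[gm].mean():.2e}): non-Gaussianity lives in white matter.")
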