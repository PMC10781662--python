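"""Build and inspect a relevance function Φ(y).

Φ maps each target value to [0, 1] and expresses how rare-but-important
that target region is.  It is fitted by monotone piecewise cubic
Hermite interpolation (pchip) through a handful of control points; the
default recipe places relevance 0 at the sample minimum and median and
relevance 1 at the boxplot upper fence Q3 + 1.5·IQR, so the upper tail
of a right-skewed target is the "rare" region.

Run:  python examples/02_relevance_function.py
"""

import numpy as np

import pcorona as pc

rng = np.random.default_rng(0)
y = rng.lognormal(mean=0.0, sigma=1.0, size=500)

points = pc.default_control_points(y)
print("control points (y, phi, dphi):")
for p in points:
    print(f"  ({p.y:8.3f}, {p.phi:.1f}, {p.dphi})")

phi = pc.pchip_fit(points)

for q in (10, 50, 75, 90, 95, 99, 100):
    v = np.percentile(y, q)
    print(f"percentile {q:3d}: y = {v:8.3f}  ->  phi = {phi(v):.3f}")

# The interpolant is monotone and clamped to [0, 1] with constant
# extension beyond the outermost control points.
grid = np.linspace(y.min() - 1, y.max() + 1, 2001)
vals = phi(grid)
assert np.all(np.diff(vals) >= -1e-12)
assert vals.min() >= 0 and vals.max() <= 1
print("\nmonotone on a dense grid: OK")

# Custom control points work too, e.g. a relevance plateau:
custom = [pc.ControlPoint(0.0, 0.0, 0.0),
          pc.ControlPoint(2.0, 0.5, 0.0),
          pc.ControlPoint(5.0, 1.0, 0.0)]
phi2 = pc.pchip_fit(custom)
print(f"custom phi(1.0) = {phi2(1.0):.3f}, phi(3.5) = {phi2(3.5):.3f}")
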