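"""Shared independent oracles used by the test suite."""

import numpy as np


def brute_force_geometry_function(r_mm, theta_deg, L_mm, n=400_000):
    """GL by direct numerical integration of 1/d^2 over the source line,
    independent of the closed-form subtended-angle expression."""
    th = np.radians(theta_deg)
    y, z = r_mm * np.sin(th), r_mm * np.cos(th)
    t = (np.arange(n) + 0.5) / n * L_mm - L_mm / 2
    d2 = y**2 + (z - t) ** 2
    return np.sum(1.0 / d2) * (L_mm / n) / L_mm
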