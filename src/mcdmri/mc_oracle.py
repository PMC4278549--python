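"""Monte-Carlo random-walk reference for restricted diffusion.

Independent numerical oracle for the GPD series signals: spins random-walk
inside an impermeable reflecting cylinder (2-D disc cross-section) or
sphere while accumulating phase under the PGSE gradient waveform
(+G for [0, delta], off, -G for [Delta, Delta + delta]).  The attenuation
is the ensemble mean of cos(phase).

Reflection uses radial mirroring of overshooting steps, accurate for step
lengths small against the radius; accuracy is controlled by walker count
and step count.  Numba-compiled; used by the test suite and the acceptance
analysis, never by the fitting pipeline.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .protocol import GAMMA


@njit(cache=True)
def _walk_disc(
    n_walkers: int,
    n_steps: int,
    R: float,
    d: float,
    G: float,
    delta: float,
    Delta: float,
    gamma: float,
    seed: int,
) -> float:
    """Mean cos(phase) for 2-D diffusion in a reflecting disc, gradient
    along x."""
    np.random.seed(seed)
    T = Delta + delta
    dt = T / n_steps
    sig = (2.0 * d * dt) ** 0.5
    acc = 0.0
    for w in range(n_walkers):
        # uniform start in the disc
        while True:
            x = (2.0 * np.random.random() - 1.0) * R
            y = (2.0 * np.random.random() - 1.0) * R
            if x * x + y * y <= R * R:
                break
        phase = 0.0
        for k in range(n_steps):
            t = (k + 0.5) * dt
            if t < delta:
                g = G
            elif t >= Delta:
                g = -G
            else:
                g = 0.0
            x2 = x + sig * np.random.standard_normal()
            y2 = y + sig * np.random.standard_normal()
            r2 = (x2 * x2 + y2 * y2) ** 0.5
            if r2 > R:
                # mirror the overshoot across the circular boundary
                f = (2.0 * R - r2) / r2
                x2 *= f
                y2 *= f
                r2b = (x2 * x2 + y2 * y2) ** 0.5
                if r2b > R:  # pathological large step: clamp to boundary
                    x2 *= R / r2b
                    y2 *= R / r2b
            x, y = x2, y2
            phase += gamma * g * x * dt
        acc += np.cos(phase)
    return acc / n_walkers


@njit(cache=True)
def _walk_sphere(
    n_walkers: int,
    n_steps: int,
    R: float,
    d: float,
    G: float,
    delta: float,
    Delta: float,
    gamma: float,
    seed: int,
) -> float:
    """Mean cos(phase) for 3-D diffusion in a reflecting sphere, gradient
    along x."""
    np.random.seed(seed)
    T = Delta + delta
    dt = T / n_steps
    sig = (2.0 * d * dt) ** 0.5
    acc = 0.0
    for w in range(n_walkers):
        while True:
            x = (2.0 * np.random.random() - 1.0) * R
            y = (2.0 * np.random.random() - 1.0) * R
            z = (2.0 * np.random.random() - 1.0) * R
            if x * x + y * y + z * z <= R * R:
                break
        phase = 0.0
        for k in range(n_steps):
            t = (k + 0.5) * dt
            if t < delta:
                g = G
            elif t >= Delta:
                g = -G
            else:
                g = 0.0
            x2 = x + sig * np.random.standard_normal()
            y2 = y + sig * np.random.standard_normal()
            z2 = z + sig * np.random.standard_normal()
            r2 = (x2 * x2 + y2 * y2 + z2 * z2) ** 0.5
            if r2 > R:
                f = (2.0 * R - r2) / r2
                x2 *= f
                y2 *= f
                z2 *= f
                r2b = (x2 * x2 + y2 * y2 + z2 * z2) ** 0.5
                if r2b > R:
                    x2 *= R / r2b
                    y2 *= R / r2b
                    z2 *= R / r2b
            x, y, z = x2, y2, z2
            phase += gamma * g * x * dt
        acc += np.cos(phase)
    return acc / n_walkers


def mc_restricted_signal(
    geometry: str,
    R: float,
    d: float,
    G: float,
    delta: float,
    Delta: float,
    gamma: float = GAMMA,
    n_walkers: int = 100_000,
    n_steps: int = 10_000,
    seed: int = 0,
) -> float:
    """Random-walk PGSE attenuation in a reflecting cylinder or sphere.

    For the cylinder, ``G`` is the gradient component perpendicular to the
    cylinder axis (the parallel component attenuates as free diffusion and
    factorizes out).
    """
    if R <= 0 or d < 0 or G < 0 or not (0 < delta < Delta):
        raise ValueError("invalid geometry/sequence parameters")
    if geometry == "cylinder":
        return float(
            _walk_disc(n_walkers, n_steps, R, d, G, delta, Delta, gamma, seed)
        )
    if geometry == "sphere":
        return float(
            _walk_sphere(n_walkers, n_steps, R, d, G, delta, Delta, gamma, seed)
        )
    raise ValueError(f"unknown geometry {geometry!r}")
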