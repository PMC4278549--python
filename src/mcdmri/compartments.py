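"""Single-compartment PGSE signal models.

Each function returns the normalized attenuation E in (0, 1] for every row
of an acquisition scheme (E = 1 at b = 0).  The taxonomy covers:

* intracellular (anisotropic, restricted perpendicular to the fiber axis
  ``n``): Stick, Cylinder, Gamma-distributed-radius (GDR) cylinders;
* extracellular (hindered, Gaussian): Ball, Zeppelin, Tensor;
* isotropically restricted: Dot, Sphere, Astrosticks, Astrocylinders.

Restricted signals use the Gaussian-phase-distribution (GPD) series for
diffusion inside an impermeable cylinder (van Gelderen form) or sphere
(Murday-Cotts form).  Series terms involve the roots of J1'(x) = 0
(cylinder) or j1'(x) = 0 (sphere).
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from numba import njit
from scipy.optimize import brentq
from scipy.special import erf, jnp_zeros, spherical_jn

from .protocol import AcquisitionScheme

#: default number of GPD series roots
N_ROOTS = 20
#: relative truncation threshold for GPD series terms
GPD_RTOL = 1e-10


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValueError(f"{name} must be a unit 3-vector")
    return v


def orientation_vector(theta: float, phi: float) -> np.ndarray:
    """Unit vector from spherical angles (polar theta, azimuth phi)."""
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


@lru_cache(maxsize=None)
def bessel_prime_roots(geometry: str, count: int = N_ROOTS) -> np.ndarray:
    """Ascending positive roots of J1'(x)=0 (cylinder) or j1'(x)=0 (sphere)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if geometry == "cylinder":
        return jnp_zeros(1, count)
    if geometry == "sphere":
        f = lambda x: spherical_jn(1, x, derivative=True)
        roots = []
        lo = 1.0
        while len(roots) < count:
            hi = lo + 0.05
            if f(lo) * f(hi) < 0:
                roots.append(brentq(f, lo, hi, xtol=1e-12))
                lo = roots[-1] + 0.5
            else:
                lo = hi
        return np.array(roots)
    raise ValueError(f"unknown geometry {geometry!r}")


@njit(cache=True)
def _gpd_kernel(
    beta2: np.ndarray,
    s: float,
    d: float,
    R: np.ndarray,
    delta: np.ndarray,
    Delta: np.ndarray,
    rtol: float,
) -> np.ndarray:  # pragma: no cover - exercised via _gpd_sum
    out = np.empty((len(R), len(delta)))
    for i in range(len(R)):
        R2 = R[i] * R[i]
        for t in range(len(delta)):
            dl, Dl = delta[t], Delta[t]
            acc = 0.0
            for m in range(len(beta2)):
                a2 = beta2[m] / R2
                da2 = d * a2
                num = (
                    2.0 * da2 * dl
                    - 2.0
                    + 2.0 * np.exp(-da2 * dl)
                    + 2.0 * np.exp(-da2 * Dl)
                    - np.exp(-da2 * (Dl - dl))
                    - np.exp(-da2 * (Dl + dl))
                )
                den = d * d * a2**3 * (R2 * a2 - s)
                term = num / den
                acc += term
                if abs(term) < rtol * abs(acc):
                    break
            out[i, t] = acc
    return out


def _gpd_sum(
    d: float,
    R: np.ndarray | float,
    delta: np.ndarray,
    Delta: np.ndarray,
    geometry: str,
    n_roots: int = N_ROOTS,
) -> np.ndarray:
    """GPD series factor C with ln E = -2 gamma^2 G_eff^2 C.

    C = sum_m [2 d a_m^2 delta - 2 + 2 e^{-d a_m^2 delta} + 2 e^{-d a_m^2 Delta}
               - e^{-d a_m^2 (Delta-delta)} - e^{-d a_m^2 (Delta+delta)}]
        / [d^2 a_m^6 (R^2 a_m^2 - s)],

    with a_m = beta_m / R, beta_m the m-th root of J1' (cylinder, s = 1) or
    j1' (sphere, s = 2).  The series is truncated when a term's relative
    contribution drops below GPD_RTOL or at n_roots.  Returns shape (T,) for
    scalar R or (len(R), T) for a radius array, T the number of timing
    combinations; d = 0 gives C = 0 (no dephasing).
    """
    beta = bessel_prime_roots(geometry, n_roots)  # (M,)
    s = 1.0 if geometry == "cylinder" else 2.0
    R_arr = np.atleast_1d(np.asarray(R, dtype=float))
    delta = np.ascontiguousarray(delta, dtype=float)
    Delta = np.ascontiguousarray(Delta, dtype=float)
    if d == 0:
        out = np.zeros((len(R_arr), len(delta)))
    else:
        out = _gpd_kernel(beta**2, s, d, R_arr, delta, Delta, GPD_RTOL)
    return out[0] if np.ndim(R) == 0 else out


# -- hindered (Gaussian) compartments --------------------------------------------


def stick_signal(scheme: AcquisitionScheme, n: np.ndarray, d_par: float) -> np.ndarray:
    """Zero-radius cylinder: E = exp(-b d_par (g.n)^2)."""
    n = _check_unit(n, "fiber direction")
    if d_par < 0:
        raise ValueError("d_par must be >= 0")
    cos = scheme.directions @ n
    return np.exp(-scheme.b * d_par * cos**2)


def ball_signal(scheme: AcquisitionScheme, d_iso: float) -> np.ndarray:
    """Isotropic tensor: E = exp(-b d_iso)."""
    if d_iso < 0:
        raise ValueError("d_iso must be >= 0")
    return np.exp(-scheme.b * d_iso)


def zeppelin_signal(
    scheme: AcquisitionScheme, n: np.ndarray, d_par: float, d_perp: float
) -> np.ndarray:
    """Cylindrically symmetric tensor: E = exp(-b [d_perp + (d_par-d_perp)(g.n)^2])."""
    n = _check_unit(n, "fiber direction")
    if d_par < 0 or d_perp < 0:
        raise ValueError("diffusivities must be >= 0")
    cos = scheme.directions @ n
    return np.exp(-scheme.b * (d_perp + (d_par - d_perp) * cos**2))


def tensor_frame(theta: float, phi: float, alpha_rot: float) -> np.ndarray:
    """Orthonormal eigenvector frame (columns e1, e2, e3).

    e1 is the (theta, phi) axis; e2, e3 span its orthogonal plane, rotated
    about e1 by alpha_rot.
    """
    e1 = orientation_vector(theta, phi)
    # polar-frame basis vectors; rotate by alpha about e1
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    u = np.array([ct * cp, ct * sp, -st])  # d e1 / d theta
    v = np.cross(e1, u)
    ca, sa = np.cos(alpha_rot), np.sin(alpha_rot)
    e2 = ca * u + sa * v
    e3 = -sa * u + ca * v
    return np.column_stack([e1, e2, e3])


def tensor_signal(
    scheme: AcquisitionScheme,
    theta: float,
    phi: float,
    alpha_rot: float,
    d1: float,
    d2: float,
    d3: float,
) -> np.ndarray:
    """Full diffusion tensor: E = exp(-b g^T D g), eigenvalues d1 >= d2 >= d3."""
    if not (d1 >= d2 >= d3 >= 0):
        raise ValueError("tensor eigenvalues must satisfy d1 >= d2 >= d3 >= 0")
    E = tensor_frame(theta, phi, alpha_rot)
    D = E @ np.diag([d1, d2, d3]) @ E.T
    quad = np.einsum("ij,jk,ik->i", scheme.directions, D, scheme.directions)
    return np.exp(-scheme.b * quad)


# -- restricted compartments ------------------------------------------------------


def cylinder_signal(
    scheme: AcquisitionScheme,
    n: np.ndarray,
    d_par: float,
    d_intra: float,
    R: float,
    n_roots: int = N_ROOTS,
) -> np.ndarray:
    """Impermeable cylinder of radius R along n (GPD perpendicular term).

    Free diffusion d_par along the axis; restricted diffusion with
    intrinsic diffusivity d_intra across it.  E = exp(-b (g.n)^2 d_par)
    * exp(-2 gamma^2 G_perp^2 C(d_intra, R)).
    """
    n = _check_unit(n, "fiber direction")
    if R <= 0:
        raise ValueError("R must be > 0 (use stick_signal for R = 0)")
    if d_par < 0 or d_intra < 0:
        raise ValueError("diffusivities must be >= 0")
    cos = scheme.directions @ n
    par = np.exp(-scheme.b * d_par * cos**2)
    Gu, du, Du, inv = scheme.unique_timings()
    C = _gpd_sum(d_intra, R, du, Du, "cylinder", n_roots)  # per unique timing
    Gperp2 = scheme.G**2 * (1.0 - cos**2)
    ln_perp = -2.0 * scheme.gamma**2 * Gperp2 * C[inv]
    return par * np.exp(ln_perp)


@lru_cache(maxsize=None)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def _gamma_volume_quadrature(
    kappa: float, theta_scale: float, n_nodes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes over the central Gamma(kappa, theta) mass with
    volume (R^2) weighting, normalized to sum to 1."""
    from scipy.special import gammaincinv, gammaln

    # quantile range [1e-5, 1 - 1e-5] of the Gamma distribution
    lo = float(gammaincinv(kappa, 1e-5)) * theta_scale
    hi = float(gammaincinv(kappa, 1.0 - 1e-5)) * theta_scale
    lo = max(lo, 1e-12)  # avoid log(0) for tiny shape parameters
    x, w = _leggauss(n_nodes)
    with np.errstate(over="ignore", under="ignore", invalid="ignore", divide="ignore"):
        Ri = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        log_pdf = (
            (kappa - 1.0) * np.log(Ri)
            - Ri / theta_scale
            - gammaln(kappa)
            - kappa * np.log(theta_scale)
        )
        wi = w * np.exp(log_pdf) * Ri**2
        total = wi.sum()
    if not np.isfinite(total) or total <= 0 or not np.all(np.isfinite(Ri)):
        # degenerate shape: collapse onto the distribution mean
        return np.array([kappa * theta_scale]), np.array([1.0])
    return Ri, wi / total


def gdr_cylinders_signal(
    scheme: AcquisitionScheme,
    n: np.ndarray,
    d_par: float,
    d_intra: float,
    kappa: float,
    theta_scale: float,
    n_nodes: int = 16,
    n_roots: int = N_ROOTS,
) -> np.ndarray:
    """Cylinders with Gamma(kappa, theta_scale)-distributed radii.

    Volume-weighted mixture over quadrature nodes R_i: weights proportional
    to p(R_i) R_i^2 (signal fraction scales with cross-sectional area),
    normalized to sum to 1.  Gauss-Legendre nodes over the central Gamma
    mass.
    """
    if not (0 < kappa <= 10):
        raise ValueError("kappa must be in (0, 10]")
    if theta_scale <= 0:
        raise ValueError("theta_scale must be > 0")
    Ri, wi = _gamma_volume_quadrature(kappa, theta_scale, n_nodes)

    n = _check_unit(n, "fiber direction")
    cos = scheme.directions @ n
    par = np.exp(-scheme.b * d_par * cos**2)
    Gu, du, Du, inv = scheme.unique_timings()
    C = _gpd_sum(d_intra, Ri, du, Du, "cylinder", n_roots)  # (n_nodes, T)
    Gperp2 = scheme.G**2 * (1.0 - cos**2)
    ln_perp = -2.0 * scheme.gamma**2 * Gperp2[None, :] * C[:, inv]  # (n_nodes, N)
    return par * (wi @ np.exp(ln_perp))


def sphere_signal(
    scheme: AcquisitionScheme, d_intra: float, R: float, n_roots: int = N_ROOTS
) -> np.ndarray:
    """Impermeable sphere of radius R (Murday-Cotts GPD series)."""
    if R <= 0:
        raise ValueError("R must be > 0 (use dot_signal for R = 0)")
    if d_intra < 0:
        raise ValueError("d_intra must be >= 0")
    Gu, du, Du, inv = scheme.unique_timings()
    C = _gpd_sum(d_intra, R, du, Du, "sphere", n_roots)
    ln_e = -2.0 * scheme.gamma**2 * scheme.G**2 * C[inv]
    return np.exp(ln_e)


def dot_signal(scheme: AcquisitionScheme) -> np.ndarray:
    """Fully restricted, non-attenuating pool: E = 1 for every row."""
    return np.ones(len(scheme))


def astrosticks_signal(scheme: AcquisitionScheme, d_par: float) -> np.ndarray:
    """Sticks isotropically distributed in 3D.

    Closed form E = sqrt(pi) erf(sqrt(b d)) / (2 sqrt(b d)); 1 at b = 0.
    """
    if d_par < 0:
        raise ValueError("d_par must be >= 0")
    bd = scheme.b * d_par
    out = np.ones(len(scheme))
    nz = bd > 0
    out[nz] = np.sqrt(np.pi) * erf(np.sqrt(bd[nz])) / (2.0 * np.sqrt(bd[nz]))
    return out


def astrocylinders_signal(
    scheme: AcquisitionScheme,
    d_intra: float,
    R: float,
    n_nodes: int = 32,
    n_roots: int = N_ROOTS,
) -> np.ndarray:
    """Cylinders isotropically distributed in 3D.

    Orientation average over the polar angle between gradient and cylinder
    axis; with u = cos(angle) the average is a uniform integral over
    u in [0, 1], evaluated by Gauss-Legendre quadrature.  Independent of
    gradient direction.
    """
    if R <= 0:
        raise ValueError("R must be > 0 (use astrosticks_signal for R = 0)")
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (x + 1.0)  # nodes in (0, 1)
    w = 0.5 * w
    Gu, du, Du, inv = scheme.unique_timings()
    C = _gpd_sum(d_intra, R, du, Du, "cylinder", n_roots)  # (T,)
    b = scheme.b
    par = np.exp(-b[None, :] * d_intra * u[:, None] ** 2)  # (n_nodes, N)
    Gperp2 = scheme.G[None, :] ** 2 * (1.0 - u[:, None] ** 2)
    perp = np.exp(-2.0 * scheme.gamma**2 * Gperp2 * C[inv][None, :])
    return w @ (par * perp)
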