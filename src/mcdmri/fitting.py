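"""Offset-Gaussian model fitting with multi-restart Levenberg-Marquardt.

The objective is the offset-Gaussian least-squares error

    LSE = sum_i (S_hat_i - sqrt(S_i^2 + sigma^2))^2,

where S_hat_i is the measured (b=0-normalized) signal, S_i the model
prediction and sigma the noise SD estimated a priori from the b=0 signals
(0.05 by default).  The sqrt(S^2 + sigma^2) offset approximates the mean of
a Rician with underlying signal S, and is simpler and more stable than a
full Rician likelihood.

Minimization runs in the unconstrained reparametrized space
(:mod:`mcdmri.model_space`), from a default or warm start plus perturbed
restarts; the reported fit is the restart with the minimum LSE.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model_space import (
    CompositeModel,
    parent_model,
    transform_params,
    untransform_params,
    warm_start_order,
)
from .protocol import AcquisitionScheme

SIGMA_DEFAULT = 0.05
#: SD of restart perturbations in transformed space
PERTURB_SD = 0.3


class FitFailure(RuntimeError):
    """All restarts of a fit failed; carries per-restart diagnostics."""

    def __init__(self, message: str, diagnostics: list[str]):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class FitResult:
    """Best fit of one model to one signal vector."""

    model_name: str
    params: dict[str, float]
    lse: float
    K: int
    N: int
    n_restarts_used: int
    converged_fraction: float
    seed: int
    bound_hits: dict[str, str] = field(default_factory=dict)


def offset_gaussian_lse(
    predicted: np.ndarray, measured: np.ndarray, sigma: float
) -> float:
    """Offset-Gaussian least-squares error between prediction and data."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValueError("predicted and measured signals must have equal length")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return float(np.sum((measured - np.sqrt(predicted**2 + sigma**2)) ** 2))


def _dt_orientation(measured: np.ndarray, scheme: AcquisitionScheme) -> tuple[float, float]:
    """Quick log-linear DT fit to seed the starting fiber orientation."""
    s = np.clip(np.asarray(measured, dtype=float), 1e-6, None)
    g = scheme.directions
    b = scheme.b
    X = np.column_stack(
        [
            np.ones(len(b)),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    w = s**2
    coef, *_ = np.linalg.lstsq(X * w[:, None], np.log(s) * w, rcond=None)
    D = np.array(
        [
            [coef[1], coef[4], coef[5]],
            [coef[4], coef[2], coef[6]],
            [coef[5], coef[6], coef[3]],
        ]
    )
    vals, vecs = np.linalg.eigh(D)
    e1 = vecs[:, np.argmax(vals)]
    theta = float(np.arccos(np.clip(e1[2], -1, 1)))
    phi = float(np.arctan2(e1[1], e1[0]))
    return theta, phi


def fit_model(
    model: CompositeModel,
    measured: np.ndarray,
    scheme: AcquisitionScheme,
    sigma: float = SIGMA_DEFAULT,
    n_restarts: int = 50,
    seed: int = 0,
    x0: dict[str, float] | None = None,
    max_nfev: int | None = None,
    ftol: float = 1e-10,
) -> FitResult:
    """Fit one model by multi-restart damped least squares.

    Restart 1 starts from ``x0`` (a warm start inherited from a simpler
    model, typically) or from physiological defaults with a DT-seeded
    orientation; restarts 2..n perturb that start by Normal(0, 0.3) in the
    transformed space.  Same seed and data give a bit-identical result.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    measured = np.asarray(measured, dtype=float)
    if len(measured) != len(scheme):
        raise ValueError("measured signal length must match the scheme")
    rng = np.random.default_rng(seed)

    provided = set(x0) if x0 is not None else set()
    start = dict(x0) if x0 is not None else {}
    defaults = model.default_params()
    for s in model.symbols:
        start.setdefault(s, defaults[s])
    if model.oriented and "theta" not in provided:
        start["theta"], start["phi"] = _dt_orientation(measured, scheme)
    u0 = transform_params(model, start)

    def residuals(u: np.ndarray) -> np.ndarray:
        p = untransform_params(model, u)
        pred = model.predict(p, scheme)
        r = measured - np.sqrt(pred**2 + sigma**2)
        # keep the optimizer alive if a wild step produces non-finite signals
        if not np.all(np.isfinite(r)):
            r = np.where(np.isfinite(r), r, 1e3)
        return r

    best_u, best_lse = None, np.inf
    n_ok = 0
    diagnostics: list[str] = []
    # convergence: relative objective decrease < ftol or 500 iterations
    nfev_cap = max_nfev if max_nfev is not None else 500
    for r in range(n_restarts):
        u_start = u0 if r == 0 else u0 + rng.normal(0.0, PERTURB_SD, size=model.K)
        try:
            sol = least_squares(
                residuals,
                u_start,
                method="lm",
                ftol=ftol,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=nfev_cap,
            )
        except Exception as exc:  # singular jacobians on degenerate starts
            diagnostics.append(f"restart {r}: {exc}")
            continue
        n_ok += 1
        lse = float(2 * sol.cost)
        if lse < best_lse:
            best_lse, best_u = lse, sol.x
    if best_u is None:
        raise FitFailure(
            f"all {n_restarts} restarts failed for {model.name}", diagnostics
        )
    from .model_space import bound_flags

    params = untransform_params(model, best_u)
    return FitResult(
        model_name=model.name,
        params=params,
        lse=best_lse,
        K=model.K,
        N=len(measured),
        n_restarts_used=n_restarts,
        converged_fraction=n_ok / n_restarts,
        seed=seed,
        bound_hits=bound_flags(model, params),
    )


def warm_start_params(
    model: CompositeModel, parent_fit: FitResult | None
) -> dict[str, float] | None:
    """Child start from a parent's best fit: shared symbols copied; symbols
    the parent lacks are left unset (defaults / DT-seeded orientation)."""
    if parent_fit is None:
        return None
    return {s: parent_fit.params[s] for s in model.symbols if s in parent_fit.params}


def warm_start_chain(
    models: list[CompositeModel],
    measured: np.ndarray,
    scheme: AcquisitionScheme,
    sigma: float = SIGMA_DEFAULT,
    n_restarts: int = 50,
    seed: int = 0,
) -> list[FitResult]:
    """Fit a family of models, seeding each from its simpler parent.

    Models are processed in complexity order (so parents come first) but
    results are returned in the input order.  A model whose parent is not
    in the list (or failed) falls back to the default start.
    """
    order = warm_start_order(models)
    done: dict[str, FitResult] = {}
    for m in order:
        p = parent_model(m)
        parent_fit = done.get(p.name) if p is not None else None
        x0 = warm_start_params(m, parent_fit)
        done[m.name] = fit_model(
            m, measured, scheme, sigma=sigma, n_restarts=n_restarts,
            seed=seed, x0=x0,
        )
    return [done[m.name] for m in models]
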