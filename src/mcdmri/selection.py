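"""Model selection: BIC ranking, bootstrap positional variance,
shell-partitioned four-fold cross-validation.

With a fixed, known noise SD sigma the offset-Gaussian -2 log-likelihood is
LSE / sigma^2 up to model-independent constants, so the implemented BIC is

    BIC = LSE / sigma^2 + K ln N,

which preserves all pairwise BIC differences and hence the ranking.  The
likelihood convention is pluggable via the ``neg2_loglik`` argument.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fitting import (
    FitResult,
    fit_model,
    offset_gaussian_lse,
    warm_start_chain,
    warm_start_params,
)
from .model_space import CompositeModel, taxonomy_group
from .protocol import AcquisitionScheme


def bic(
    lse: float,
    sigma: float,
    K: int,
    N: int,
    neg2_loglik: Callable[[float, float], float] | None = None,
) -> float:
    """Bayesian Information Criterion -2 ln L + K ln N (constants dropped)."""
    if not N > K >= 1:
        raise ValueError(f"require N > K >= 1, got N={N}, K={K}")
    if neg2_loglik is None:
        neg2 = lse / sigma**2
    else:
        neg2 = neg2_loglik(lse, sigma)
    return float(neg2 + K * np.log(N))


@dataclass
class Ranking:
    """Models sorted ascending by BIC; ties broken by smaller K, then name."""

    table: pd.DataFrame  # columns: model, BIC, LSE, K
    N: int

    @property
    def order(self) -> list[str]:
        return list(self.table["model"])

    def position(self, name: str) -> int:
        return self.order.index(name)


def rank_models(fits: Sequence[FitResult], sigma: float) -> Ranking:
    """Rank fitted models from lowest BIC (best) to highest (worst)."""
    if not fits:
        raise ValueError("no fits to rank")
    Ns = {f.N for f in fits}
    if len(Ns) != 1:
        raise ValueError(f"fits disagree on N: {sorted(Ns)}")
    N = Ns.pop()
    rows = [
        {"model": f.model_name, "BIC": bic(f.lse, sigma, f.K, N), "LSE": f.lse, "K": f.K}
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values(
        ["BIC", "K", "model"], kind="mergesort", ignore_index=True
    )
    return Ranking(table=df, N=N)


@dataclass
class PositionalVariance:
    """models x rank-position count matrix over bootstrap replicates."""

    counts: pd.DataFrame  # index: model names, columns: positions 1..M
    B: int  # effective number of replicates counted

    def top_k_mass(self, models: Sequence[str], k: int) -> float:
        """Fraction of the first k positions' mass held by the given models."""
        top = self.counts.iloc[:, :k]
        return float(top.loc[top.index.intersection(models)].to_numpy().sum()) / (
            self.B * k
        )


def resample_within_shells(
    scheme: AcquisitionScheme, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap row indices: weighted rows resampled with replacement
    within each shell (same count), b=0 rows kept intact, scheme order."""
    idx = np.arange(len(scheme))
    out = idx.copy()
    for s in np.unique(scheme.shell_id):
        rows = np.flatnonzero((scheme.shell_id == s) & scheme.weighted)
        out[rows] = rng.choice(rows, size=len(rows), replace=True)
    return out


def bootstrap_rankings(
    measured: np.ndarray,
    scheme: AcquisitionScheme,
    models: Sequence[CompositeModel],
    B: int = 100,
    n_restarts: int = 50,
    seed: int = 0,
    sigma: float = 0.05,
    full_fits: Sequence[FitResult] | None = None,
) -> PositionalVariance:
    """Positional-variance diagram over B within-shell bootstrap replicates.

    Each replicate resamples the weighted rows per shell with replacement,
    refits every model (optionally warm-started from full-data fits) and
    ranks by BIC; counts[m, p] is how often model m lands at position p.
    Replicates whose fits all fail are dropped and the effective B recorded.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    names = [m.name for m in models]
    counts = pd.DataFrame(0, index=names, columns=range(1, len(models) + 1))
    warm = {f.model_name: f for f in full_fits} if full_fits else {}
    b_eff = 0
    for rep in range(B):
        idx = resample_within_shells(scheme, rng)
        sub = scheme.take(idx)
        y = measured[idx]
        rep_seed = int(rng.integers(0, 2**31 - 1))
        fits = []
        try:
            for m in models:
                x0 = warm_start_params(m, warm.get(m.name))
                fits.append(
                    fit_model(m, y, sub, sigma=sigma, n_restarts=n_restarts,
                              seed=rep_seed, x0=x0)
                )
        except Exception:
            continue
        r = rank_models(fits, sigma)
        for pos, name in enumerate(r.order, start=1):
            counts.loc[name, pos] += 1
        b_eff += 1
    return PositionalVariance(counts=counts, B=b_eff)


@dataclass(frozen=True)
class CVFold:
    """One quarter of the protocol: a set of shell ids."""

    quarter: str  # Q1..Q4
    shells: tuple[int, ...]


def make_cv_folds(
    scheme: AcquisitionScheme, seed: int = 0
) -> list[CVFold]:
    """Partition the 32 shells into four quarters.

    For each pulse width delta, the shells split into a low-Delta group
    (30, 50 ms) and a high-Delta group (70, 90 ms), four shells each; one
    shell from each group goes to each quarter (the assignment policy is
    :func:`_assign_shells_to_quarters`).  Every quarter then holds, for
    every delta, one low-Delta and one high-Delta shell: 8 shells total.
    """
    table = scheme.shell_table()
    deltas = sorted({v[1] for v in table.values()})
    Deltas = sorted({v[2] for v in table.values()})
    if len(Deltas) != 4:
        raise ValueError("scheme must have four Delta values for quartering")
    low = set(Deltas[:2])
    rng = np.random.default_rng(seed)
    quarters: dict[int, list[int]] = {q: [] for q in range(4)}
    for d in deltas:
        low_shells = sorted(s for s, v in table.items() if v[1] == d and v[2] in low)
        high_shells = sorted(s for s, v in table.items() if v[1] == d and v[2] not in low)
        if len(low_shells) != 4 or len(high_shells) != 4:
            raise ValueError(
                f"delta={d}: need 4 low-Delta and 4 high-Delta shells, got "
                f"{len(low_shells)}/{len(high_shells)}"
            )
        for q, s in _assign_shells_to_quarters(low_shells, high_shells, rng):
            quarters[q].append(s)
    return [
        CVFold(quarter=f"Q{q + 1}", shells=tuple(sorted(quarters[q]))) for q in range(4)
    ]


def _assign_shells_to_quarters(
    low_shells: list[int], high_shells: list[int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Fold-assignment policy: random bijections low->quarters and
    high->quarters.

    Isolated here so the grouping rule for the two gradient strengths of a
    matched (delta, Delta) pair can be swapped; the default honors the
    constraint that each quarter receives exactly one low-Delta and one
    high-Delta shell per delta, which forces the two G shells of a pair
    into different quarters.
    """
    out = []
    for shells in (low_shells, high_shells):
        order = rng.permutation(4)
        out.extend((int(order[i]), s) for i, s in enumerate(shells))
    return out


def cross_validate(
    models: Sequence[CompositeModel],
    measured: np.ndarray,
    scheme: AcquisitionScheme,
    folds: Sequence[CVFold],
    n_restarts: int = 50,
    seed: int = 0,
    sigma: float = 0.05,
) -> pd.DataFrame:
    """Held-out offset-Gaussian LSE per model and fold.

    For each fold, models are fitted (warm-start chain) on the complement
    shells and scored on the held-out rows; no row used in a fit is ever
    scored.  Returns a tidy frame with columns model, fold, lse.
    """
    all_shells = set(np.unique(scheme.shell_id))
    covered = [s for f in folds for s in f.shells]
    if sorted(covered) != sorted(all_shells):
        raise ValueError("folds must partition the scheme's shells")
    rows = []
    for fold in folds:
        held = np.isin(scheme.shell_id, fold.shells)
        train_idx = np.flatnonzero(~held)
        test_idx = np.flatnonzero(held)
        train_scheme = scheme.take(train_idx)
        test_scheme = scheme.take(test_idx)
        fits = warm_start_chain(
            list(models), measured[train_idx], train_scheme,
            sigma=sigma, n_restarts=n_restarts, seed=seed,
        )
        for m, f in zip(models, fits):
            pred = m.predict(f.params, test_scheme)
            rows.append(
                {
                    "model": m.name,
                    "fold": fold.quarter,
                    "lse": offset_gaussian_lse(pred, measured[test_idx], sigma),
                    "group": taxonomy_group(m),
                }
            )
    return pd.DataFrame(rows)


def group_recovery_fraction(
    rankings: Sequence[Ranking], generator_model: str
) -> float:
    """Fraction of rankings whose BIC-top model shares the generator's
    taxonomy group."""
    g = taxonomy_group(generator_model)
    hits = sum(1 for r in rankings if taxonomy_group(r.order[0]) == g)
    return hits / len(rankings)
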