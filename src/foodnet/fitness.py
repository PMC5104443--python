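"""Coupled non-linear fixed-point ranking of countries and products.

Each iteration updates a country score as the specialization-weighted
sum of its per-capita production row, and a product score as the
reciprocal of the inverse-score-weighted sum of its producer column:

    F~_c = sum_p W_cp Q_p          Q~_p = 1 / sum_c W_cp (1 / F_c)

followed by division of each vector by its arithmetic mean, so both
stay mean-one. Iterating from the all-ones state converges to a fixed
point that is independent of the initial condition; the converged F
ranks countries and Q ranks products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from foodnet.panel import BipartitePanel

RECIPROCAL_FLOOR = 1e-15  # guards 1/F once low scores decay toward zero


@dataclass
class FitnessState:
    F: np.ndarray  # normalized country scores, mean 1
    Q: np.ndarray  # normalized product scores, mean 1
    iteration: int
    F_raw: np.ndarray | None = None  # pre-normalization intermediates
    Q_raw: np.ndarray | None = None

    @classmethod
    def ones(cls, n_countries: int, n_products: int) -> "FitnessState":
        return cls(F=np.ones(n_countries), Q=np.ones(n_products), iteration=0)


@dataclass
class FitnessResult:
    state: FitnessState
    converged: bool
    n_iterations: int
    delta_final: float
    countries: list[str]
    products: list[str]
    dropped_countries: list[str] = field(default_factory=list)
    dropped_products: list[str] = field(default_factory=list)
    history: list[tuple[int, float]] = field(default_factory=list)  # (iteration, delta)

    @property
    def F(self) -> pd.Series:
        return pd.Series(self.state.F, index=self.countries, name="F")

    @property
    def Q(self) -> pd.Series:
        return pd.Series(self.state.Q, index=self.products, name="Q")


def fitness_step(W: np.ndarray, state: FitnessState, floor: float = RECIPROCAL_FLOOR) -> FitnessState:
    """One update of the coupled map followed by mean-one normalization.

    Raw scores are kept in the returned state; the reciprocal in the
    product update floors the previous country scores at ``floor``
    (pass ``floor=0`` to forbid this, in which case an exact zero raises).
    """
    W = np.asarray(W, dtype=float)
    if floor > 0:
        F_safe = np.maximum(state.F, floor)
    else:
        if (state.F == 0).any():
            raise ValueError("zero country score: reciprocal update undefined")
        F_safe = state.F
    F_raw = W @ state.Q
    Q_raw = 1.0 / (W.T @ (1.0 / F_safe))
    return FitnessState(
        F=F_raw / F_raw.mean(),
        Q=Q_raw / Q_raw.mean(),
        iteration=state.iteration + 1,
        F_raw=F_raw,
        Q_raw=Q_raw,
    )


def fitness_fixed_point(
    W: np.ndarray,
    countries: list[str] | None = None,
    products: list[str] | None = None,
    tolerance: float = 1e-10,
    max_iter: int = 10_000,
    init: str = "ones",
    seed: int | None = None,
) -> FitnessResult:
    """Iterate the map to its fixed point.

    All-zero rows and columns are removed first (a product nobody makes
    has an undefined score) and reported in the dropped lists.
    Convergence is the infinity norm of successive normalized changes
    dropping below ``tolerance``; hitting ``max_iter`` flags the result
    as non-converged instead of raising.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("W must be non-negative")
    n_c, n_p = W.shape
    countries = list(countries) if countries is not None else [f"C{i:03d}" for i in range(n_c)]
    products = list(products) if products is not None else [f"P{j:03d}" for j in range(n_p)]

    row_keep = W.sum(axis=1) > 0
    col_keep = W.sum(axis=0) > 0
    dropped_c = [c for c, k in zip(countries, row_keep) if not k]
    dropped_p = [p for p, k in zip(products, col_keep) if not k]
    W = W[np.ix_(row_keep, col_keep)]
    kept_c = [c for c, k in zip(countries, row_keep) if k]
    kept_p = [p for p, k in zip(products, col_keep) if k]
    if W.size == 0:
        raise ValueError("empty matrix after removing all-zero rows/columns")

    if init == "ones":
        state = FitnessState.ones(len(kept_c), len(kept_p))
    elif init == "random":
        rng = np.random.default_rng(seed)
        state = FitnessState(
            F=_mean_one(rng.lognormal(0.0, 1.0, len(kept_c))),
            Q=_mean_one(rng.lognormal(0.0, 1.0, len(kept_p))),
            iteration=0,
        )
    else:
        raise ValueError(f"init must be 'ones' or 'random', got {init!r}")

    # raw-array loop: identical arithmetic to fitness_step, without the
    # per-iteration state objects (the map can need 1e5+ iterations on
    # degenerate matrices whose low scores decay algebraically)
    F, Q = state.F, state.Q
    Wt = W.T.copy()
    history: list[tuple[int, float]] = []
    delta = np.inf
    iteration = state.iteration
    F_raw, Q_raw = F, Q
    for _ in range(max_iter):
        F_raw = W @ Q
        Q_raw = 1.0 / (Wt @ (1.0 / np.maximum(F, RECIPROCAL_FLOOR)))
        F_new = F_raw / F_raw.mean()
        Q_new = Q_raw / Q_raw.mean()
        delta = max(
            float(np.abs(F_new - F).max()),
            float(np.abs(Q_new - Q).max()),
        )
        F, Q = F_new, Q_new
        iteration += 1
        history.append((iteration, delta))
        if delta < tolerance:
            break
    state = FitnessState(F=F, Q=Q, iteration=iteration, F_raw=F_raw, Q_raw=Q_raw)
    return FitnessResult(
        state=state,
        converged=delta < tolerance,
        n_iterations=state.iteration,
        delta_final=delta,
        countries=kept_c,
        products=kept_p,
        dropped_countries=dropped_c,
        dropped_products=dropped_p,
        history=history,
    )


def _mean_one(x: np.ndarray) -> np.ndarray:
    return x / x.mean()


def panel_fitness(panel: BipartitePanel, **kwargs) -> FitnessResult:
    """Fixed point of a panel's weighted matrix with its labels attached."""
    return fitness_fixed_point(panel.W, panel.countries, panel.products, **kwargs)


def rank(values: pd.Series, descending: bool = True) -> list[tuple[str, int]]:
    """Competition ranks (rank 1 = best) with ties sharing the minimum rank.

    Output rows are ordered by rank then lexicographically by label, so
    tied entries appear in a deterministic display order. Ranks are
    invariant under any positive rescaling of the values.
    """
    if len(values) == 0:
        raise ValueError("cannot rank an empty vector")
    values = pd.Series(values, dtype=float)
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("values must be finite")
    ranks = values.rank(method="min", ascending=not descending).astype(int)
    order = sorted(values.index, key=lambda lab: (ranks[lab], str(lab)))
    return [(str(lab), int(ranks[lab])) for lab in order]


def fitness_trajectory(
    panels: dict[int, BipartitePanel],
    tolerance: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[int, FitnessResult]]:
    """Independent fixed-point runs for a panel per year.

    Returns aligned (country x year) and (product x year) score tables
    (NaN where a label was absent or dropped that year) plus the per-year
    results with their convergence diagnostics.
    """
    if not panels:
        raise ValueError("need at least one panel")
    results = {
        year: panel_fitness(panel, tolerance=tolerance, max_iter=max_iter)
        for year, panel in sorted(panels.items())
    }
    F_table = pd.DataFrame({year: res.F for year, res in results.items()})
    Q_table = pd.DataFrame({year: res.Q for year, res in results.items()})
    return F_table, Q_table, results


def percent_change(before: float, after: float) -> float:
    """Relative change in percent, e.g. 2.0 -> 1.5 gives -25.0."""
    if before == 0:
        raise ValueError("undefined percent change from zero")
    return 100.0 * (after - before) / before
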