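"""Synthetic response landscapes and closed-loop evaluation harness.

Wet-lab campaigns cannot back a test suite, so these landscapes emulate the
structural features of media-optimisation responses: smooth nonlinear
continuous trends, category-dependent optima (each co-feed type has its own
best continuous location, with one globally best category), and a
simplex-constrained blend response whose interior optimum strictly beats
every pure-component vertex.  Optima are certified by dense-grid search at
construction, so closed-loop efficiency claims can be checked against known
ground truth.  A run-count calculator for classical DoE schemes (OFAT,
factorials, CCD, BBD, full screens) quantifies the budget a static design
would have needed on the same space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .acquisition import AcquisitionConfig
from .campaign import CampaignState
from .design_space import DesignFactor, DesignPoint, DesignSpace, LinearEqualityConstraint

__all__ = [
    "SyntheticLandscape",
    "make_mixed_landscape",
    "make_continuous_landscape",
    "make_simplex_landscape",
    "run_closed_loop",
    "compare_strategies",
    "doe_size",
]


@dataclass
class SyntheticLandscape:
    """Ground-truth mixed-variable response with a certified optimum."""

    space: DesignSpace
    true_response: Callable[[DesignPoint], float]
    noise_sd: float
    optimum_point: DesignPoint
    optimum_value: float
    seed: int
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        self._rng = np.random.default_rng(self.seed)

    def evaluate(self, point: DesignPoint, rng: np.random.Generator | None = None) -> float:
        """Noisy observation of the true response."""
        r = rng if rng is not None else self._rng
        return float(self.true_response(point) + r.normal(0.0, self.noise_sd)) \
            if self.noise_sd > 0 else float(self.true_response(point))

    def reset_noise(self) -> None:
        self._rng = np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# mixed landscape

def make_mixed_landscape(
    n_cont: int, n_categories: int, noise_sd: float, seed: int, grid_per_axis: int = 50
) -> SyntheticLandscape:
    """Continuous factors on [0,1] plus one categorical factor.

    The response is a shared smooth trend plus a per-category radial bump
    with its own centre, width, height and offset; one category's bump is
    boosted so the global optimum lives in a unique category.  The optimum
    is the argmax over a ``grid_per_axis``-per-axis grid within every
    category (resolution-limited certification).
    """
    if n_cont < 1 or n_categories < 2:
        raise ValueError("need n_cont >= 1 and n_categories >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    labels = tuple(f"C{j:02d}" for j in range(n_categories))
    factors = [
        DesignFactor(name=f"x{i+1}", kind="continuous", lower=0.0, upper=1.0)
        for i in range(n_cont)
    ] + [DesignFactor(name="category", kind="categorical", categories=labels)]
    space = DesignSpace(factors)

    base = rng.uniform(0.0, 0.3, size=n_categories)
    amp = rng.uniform(0.5, 1.0, size=n_categories)
    centers = rng.uniform(0.1, 0.9, size=(n_categories, n_cont))
    widths = rng.uniform(0.15, 0.3, size=n_categories)
    best_cat = int(rng.integers(n_categories))
    amp[best_cat] = 1.3
    trend_center = rng.uniform(0.2, 0.8, size=n_cont)

    def response_xj(x: np.ndarray, j: int) -> np.ndarray:
        x = np.atleast_2d(x)
        trend = 0.4 * np.exp(-np.sum((x - trend_center) ** 2, axis=1) / (2 * 0.35**2))
        d2 = np.sum((x - centers[j]) ** 2, axis=1)
        return base[j] + amp[j] * np.exp(-d2 / (2 * widths[j] ** 2)) + trend

    def true_response(point: DesignPoint) -> float:
        x = np.array([float(point[f"x{i+1}"]) for i in range(n_cont)])
        j = labels.index(point["category"])
        return float(response_xj(x, j)[0])

    axes = [np.linspace(0.0, 1.0, grid_per_axis)] * n_cont
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, n_cont)
    best_val, best_x, best_j = -np.inf, None, 0
    for j in range(n_categories):
        vals = response_xj(grid, j)
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val, best_x, best_j = float(vals[i]), grid[i], j
    opt_values: dict[str, float | str] = {f"x{i+1}": float(best_x[i]) for i in range(n_cont)}
    opt_values["category"] = labels[best_j]
    return SyntheticLandscape(
        space, true_response, noise_sd, DesignPoint(opt_values), best_val, seed
    )


def make_continuous_landscape(n_cont: int, noise_sd: float, seed: int) -> SyntheticLandscape:
    """Unconstrained continuous response (a cytokine-cocktail stand-in).

    A single radial bump of unit height: the optimum is its centre, known
    in closed form, so no grid certification is needed and the factory
    scales to many factors (eight cytokines and chemokines in the
    motivating campaign).
    """
    if n_cont < 1:
        raise ValueError("need n_cont >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    names = tuple(f"x{i+1}" for i in range(n_cont))
    factors = [DesignFactor(name=n, kind="continuous", lower=0.0, upper=1.0) for n in names]
    space = DesignSpace(factors)
    center = rng.uniform(0.2, 0.8, size=n_cont)
    width = 0.35

    def true_response(point: DesignPoint) -> float:
        x = np.array([float(point[n]) for n in names])
        return float(np.exp(-np.sum((x - center) ** 2) / (2 * width**2)))

    opt = DesignPoint({n: float(center[j]) for j, n in enumerate(names)})
    return SyntheticLandscape(space, true_response, noise_sd, opt, 1.0, seed)


# ---------------------------------------------------------------------------
# simplex landscape

def _simplex_grid(k: int, resolution: int) -> np.ndarray:
    """All compositions of ``resolution`` into k parts, as fractions."""
    combos = itertools.combinations(range(resolution + k - 1), k - 1)
    pts = []
    for c in combos:
        bars = (-1,) + c + (resolution + k - 1,)
        pts.append([bars[i + 1] - bars[i] - 1 for i in range(k)])
    return np.asarray(pts, dtype=float) / resolution


def make_simplex_landscape(
    k_components: int, noise_sd: float, seed: int, grid_resolution: int = 50
) -> SyntheticLandscape:
    """Blend response over k nonnegative ratios summing to one.

    A linear blending term (each pure component has its own moderate value)
    plus an interior radial bump make the optimum an interior blend that
    strictly exceeds every vertex — the single-medium cultures underperform
    the optimised mixture.
    """
    if k_components < 2:
        raise ValueError("need k >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    names = tuple(f"ratio_{i+1}" for i in range(k_components))
    factors = [
        DesignFactor(name=n, kind="continuous", lower=0.0, upper=1.0) for n in names
    ]
    constraint = LinearEqualityConstraint({n: 1.0 for n in names}, rhs=1.0)
    space = DesignSpace(factors, [constraint])

    v = rng.uniform(0.3, 0.6, size=k_components)
    w_star = rng.dirichlet(np.full(k_components, 4.0))
    amp, width = 0.5, 0.25

    def response_w(w: np.ndarray) -> np.ndarray:
        w = np.atleast_2d(w)
        return w @ v + amp * np.exp(-np.sum((w - w_star) ** 2, axis=1) / (2 * width**2))

    def true_response(point: DesignPoint) -> float:
        w = np.array([float(point[n]) for n in names])
        return float(response_w(w)[0])

    grid = _simplex_grid(k_components, grid_resolution)
    vals = response_w(grid)
    i = int(np.argmax(vals))
    vertex_best = float(np.max(response_w(np.eye(k_components))))
    if vals[i] <= vertex_best:  # bump too weak for this draw; re-centre it
        w_star = np.full(k_components, 1.0 / k_components)
        vals = response_w(grid)
        i = int(np.argmax(vals))
    opt = DesignPoint({n: float(grid[i, j]) for j, n in enumerate(names)})
    return SyntheticLandscape(space, true_response, noise_sd, opt, float(vals[i]), seed)


# ---------------------------------------------------------------------------
# closed loop

def run_closed_loop(
    landscape: SyntheticLandscape,
    n_init: int,
    batch_size: int,
    n_batches: int,
    seed: int,
    config: AcquisitionConfig | None = None,
    n_restarts: int = 3,
    stop_on_convergence: bool = False,
) -> dict:
    """Initial design -> fit -> suggest -> simulated observe, repeated.

    Returns a trace with the campaign state, the per-experiment observed
    targets, the monotone best-so-far sequence and per-iteration batch
    dispersion (mean pairwise distance of the encoded batch points).
    """
    if n_init < 1 or batch_size < 1 or n_batches < 0:
        raise ValueError("budget must cover the initial design")
    config = config or AcquisitionConfig(batch_size=batch_size)
    eval_rng = np.random.default_rng(seed + 7)
    state = CampaignState(
        space=landscape.space, config=config, seed=seed, n_restarts=n_restarts,
        initial_noise_variance=landscape.noise_sd**2,
    )

    def run_batch(points: Sequence[DesignPoint]) -> None:
        df = state.ledger.rows(role="planned")
        ids = df["experiment_id"].tolist()[-len(points):]
        results = [(i, [landscape.evaluate(p, eval_rng)]) for i, p in zip(ids, points)]
        state.ingest(results)

    dispersion = []
    points = state.suggest_initial(n_init)
    run_batch(points)
    for b in range(n_batches):
        batch = state.suggest(seed=seed + 101 * (b + 1))
        x, h = state.space.encode_many(batch)
        z = np.hstack([x, h.astype(float)])
        if len(batch) > 1:
            diffs = z[:, None, :] - z[None, :, :]
            dd = np.sqrt(np.sum(diffs**2, axis=-1))
            dispersion.append(float(np.sum(dd) / (len(batch) * (len(batch) - 1))))
        run_batch(batch)
        if stop_on_convergence and state.convergence_history and state.convergence_history[-1]:
            break

    df = state.ledger.rows(role="executed")
    targets = df["target"].to_numpy(dtype=float)
    signed = state.sign * targets
    best = state.sign * np.maximum.accumulate(signed)
    return {
        "state": state,
        "targets": targets,
        "best_so_far": best,
        "batch_dispersion": dispersion,
        "ledger_rows": len(state.ledger),
    }


def compare_strategies(
    landscape: SyntheticLandscape,
    budget: int,
    seeds: Sequence[int],
    n_init: int | None = None,
    batch_size: int = 6,
    config: AcquisitionConfig | None = None,
    n_restarts: int = 2,
) -> dict[str, np.ndarray]:
    """Best-found true response per strategy at equal budget, across seeds.

    Strategies: BO closed loop, uniform random search, and a static grid
    (largest full grid fitting inside the budget; it evaluates exactly its
    grid size).
    """
    if len(seeds) < 5:
        raise ValueError("need at least 5 seeds for a meaningful comparison")
    space = landscape.space
    n_init = n_init or max(batch_size, budget // 4)
    n_batches = (budget - n_init) // batch_size
    out: dict[str, list[float]] = {"bo": [], "random": [], "grid": []}
    for seed in seeds:
        trace = run_closed_loop(
            landscape, n_init, batch_size, n_batches, int(seed), config, n_restarts
        )
        df = trace["state"].ledger.rows(role="executed")
        pts = [trace["state"].ledger.point_for(r) for _, r in df.iterrows()]
        out["bo"].append(max(landscape.true_response(p) for p in pts))

        rand_pts = _random_strategy(space, budget, int(seed) + 5000)
        out["random"].append(max(landscape.true_response(p) for p in rand_pts))

        grid_pts = _grid_strategy(space, budget)
        out["grid"].append(max(landscape.true_response(p) for p in grid_pts))
    return {k: np.asarray(v) for k, v in out.items()}


def _random_strategy(space: DesignSpace, budget: int, seed: int) -> list[DesignPoint]:
    return space.sample_uniform_feasible(budget, seed)


def _grid_strategy(space: DesignSpace, budget: int) -> list[DesignPoint]:
    """Largest L-per-axis full grid (times all category combinations) whose
    size fits the budget; constrained spaces grid the simplex instead."""
    n_cat_combos = int(np.prod([len(f.categories) for f in space.categorical_factors])) or 1
    d = space.n_numeric
    if space.constraints:
        from math import comb

        res = 1
        while comb(res + d, d - 1) * n_cat_combos <= budget:
            res += 1
        pts = _simplex_grid(d, res)  # size comb(res+d-1, d-1), largest within budget
        names = [f.name for f in space.numeric_factors]
        return [DesignPoint({n: float(w[j]) for j, n in enumerate(names)}) for w in pts]
    L = max(int(np.floor((budget / n_cat_combos) ** (1.0 / d))), 1)
    axes = [np.linspace(0.0, 1.0, L)] * d
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d) if L > 1 else \
        np.full((1, d), 0.5)
    cat_levels = [range(len(f.categories)) for f in space.categorical_factors]
    points = []
    for row in grid:
        for combo in itertools.product(*cat_levels) if cat_levels else [()]:
            points.append(space.decode_point(row, np.asarray(combo, dtype=int)))
    return points


# ---------------------------------------------------------------------------
# DoE budget calculator

def doe_size(
    method: str,
    k_continuous: int,
    levels: int = 3,
    category_counts: Sequence[int] = (),
    center_points: int = 1,
    fraction: int = 0,
    grid_levels: int = 10,
) -> int:
    """Experiment count of a classical DoE scheme on the given space.

    Standard textbook counts; any categorical factors multiply the
    continuous design size by the product of their category counts.  The
    full screen assumes ``grid_levels`` levels per continuous axis.
    """
    if k_continuous < 1:
        raise ValueError("need k_continuous >= 1")
    k, L = k_continuous, levels
    cat_mult = int(np.prod([int(c) for c in category_counts])) if category_counts else 1
    if method == "ofat":
        n = k * (L - 1) + 1
    elif method == "full_factorial":
        n = L**k
    elif method == "fractional_factorial":
        if not 0 < fraction < k:
            raise ValueError("fractional designs need 0 < fraction < k")
        n = L ** (k - fraction)
    elif method == "ccd":
        n = 2**k + 2 * k + center_points
    elif method == "fractional_ccd":
        if not 0 < fraction < k:
            raise ValueError("fractional designs need 0 < fraction < k")
        n = 2 ** (k - fraction) + 2 * k + center_points
    elif method == "bbd":
        if k < 3:
            raise ValueError("Box-Behnken designs are undefined for k < 3")
        n = 2 * k * (k - 1) + center_points
    elif method == "full_screen":
        n = grid_levels**k
    else:
        raise ValueError(f"unknown DoE method {method!r}")
    return int(n) * cat_mult
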