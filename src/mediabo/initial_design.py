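"""Iteration-0 designs: Latin hypercube over continuous factors, uniform
random over categorical factors, feasible random sampling under constraints.

Each numeric axis is split into n equal-width bins and every bin receives
exactly one point (placed uniformly at random within its bin), giving a
space-filling first iteration that maximises the input variability seen by
the initial surrogate.  Constrained spaces (media blends on a simplex) fall
back to uniform feasible sampling because the axis-stratification property
cannot coexist with an equality constraint.
"""

from __future__ import annotations

import numpy as np

from .design_space import DesignPoint, DesignSpace

__all__ = ["lhs", "lhs_unit", "mixed_initial_design"]


def lhs_unit(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """n×d Latin hypercube on the unit cube, one point per axis bin."""
    u = rng.uniform(size=(n, d))
    out = np.empty((n, d))
    for j in range(d):
        perm = rng.permutation(n)
        out[:, j] = (perm + u[:, j]) / n
    return out


def lhs(space: DesignSpace, n: int, seed: int) -> list[DesignPoint]:
    """Latin hypercube design over the numeric factors of an unconstrained
    space; discrete factors are sampled on their continuous span and snapped
    to the nearest declared level."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if space.constraints:
        raise ValueError(
            "LHS assumes an unconstrained cuboid; use sample_uniform_feasible for constrained spaces"
        )
    if space.n_categorical:
        raise ValueError("lhs covers numeric factors only; use mixed_initial_design")
    rng = np.random.default_rng(seed)
    unit = lhs_unit(n, space.n_numeric, rng)
    return [space.decode_point(row, np.zeros(0, dtype=int)) for row in unit]


def mixed_initial_design(space: DesignSpace, n: int, seed: int) -> list[DesignPoint]:
    """LHS over numeric factors x independent uniform categorical draws.

    Separate child generators drive the numeric and categorical streams so
    that adding or removing categories does not perturb the continuous
    coordinates for a given seed.  Constrained spaces delegate the numeric
    part to uniform feasible sampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng_cont, rng_cat = np.random.default_rng(seed).spawn(2)
    if space.constraints:
        base = space.sample_uniform_feasible(n, seed)
        points = []
        for p in base:
            values = dict(p.values)
            for f in space.categorical_factors:
                values[f.name] = str(rng_cat.choice(f.categories))
            points.append(DesignPoint(values))
        return points
    unit = lhs_unit(n, space.n_numeric, rng_cont)
    points = []
    for row in unit:
        h = np.array(
            [rng_cat.integers(len(f.categories)) for f in space.categorical_factors], dtype=int
        )
        points.append(space.decode_point(row, h))
    return points
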