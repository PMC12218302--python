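"""Mixed continuous/discrete/categorical design spaces for media campaigns.

A design space declares the factors a campaign may vary — e.g. glycerol
percentage during outgrowth, methanol percentage during production, the type
of carbon co-feed (categorical) and its concentration — together with any
linear equality constraints such as blend ratios of basal media summing to
one.  Continuous and discrete factors are min–max scaled to [0, 1] internally
so that length scales are comparable across factors whose raw ranges differ
by orders of magnitude (0–10 % vs 0–50 g/L); categorical factors are encoded
as indices in their declared order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DesignFactor",
    "LinearEqualityConstraint",
    "DesignSpace",
    "DesignPoint",
    "ValidationResult",
    "load_space",
    "save_space",
]

_KINDS = ("continuous", "discrete", "categorical")


@dataclass(frozen=True)
class DesignFactor:
    """One design factor: a continuous range, a discrete level set, or a
    categorical label set.

    ``linked_to`` is metadata naming a categorical factor this continuous
    factor is coupled with (a co-feed concentration linked to the co-feed
    type); it does not change modelling, only reporting.
    """

    name: str
    kind: str
    lower: float | None = None
    upper: float | None = None
    levels: tuple[float, ...] = ()
    categories: tuple[str, ...] = ()
    units: str = ""
    phase: str = ""
    linked_to: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"factor {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "continuous":
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ValueError(f"factor {self.name!r}: need lower < upper")
            if self.levels or self.categories:
                raise ValueError(f"factor {self.name!r}: continuous factors take no levels/categories")
        elif self.kind == "discrete":
            lv = tuple(float(v) for v in self.levels)
            if len(lv) < 2 or any(b <= a for a, b in zip(lv, lv[1:])):
                raise ValueError(f"factor {self.name!r}: need >=2 strictly increasing levels")
            object.__setattr__(self, "levels", lv)
            object.__setattr__(self, "lower", lv[0])
            object.__setattr__(self, "upper", lv[-1])
        else:
            cats = tuple(str(c) for c in self.categories)
            if len(cats) < 2 or len(set(cats)) != len(cats):
                raise ValueError(f"factor {self.name!r}: need >=2 distinct categories")
            object.__setattr__(self, "categories", cats)

    @property
    def is_numeric(self) -> bool:
        return self.kind in ("continuous", "discrete")


@dataclass(frozen=True)
class LinearEqualityConstraint:
    """sum_i coefficients[name_i] * x_i == rhs, within tolerance."""

    coefficients: Mapping[str, float]
    rhs: float
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if not any(c != 0 for c in self.coefficients.values()):
            raise ValueError("constraint needs at least one nonzero coefficient")

    def residual(self, values: Mapping[str, float]) -> float:
        return sum(c * float(values[n]) for n, c in self.coefficients.items()) - self.rhs


@dataclass(frozen=True)
class DesignPoint:
    """A fully specified experimental condition: factor name -> value."""

    values: Mapping[str, float | str]

    def __getitem__(self, name: str) -> float | str:
        return self.values[name]


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    violations: tuple[str, ...] = ()


class DesignSpace:
    """Ordered collection of factors plus linear equality constraints."""

    def __init__(
        self,
        factors: Sequence[DesignFactor],
        constraints: Sequence[LinearEqualityConstraint] = (),
    ) -> None:
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        for f in factors:
            if f.linked_to is not None:
                target = next((g for g in factors if g.name == f.linked_to), None)
                if target is None or target.kind != "categorical":
                    raise ValueError(f"factor {f.name!r}: linked_to must name a categorical factor")
        for con in constraints:
            for n in con.coefficients:
                g = next((g for g in factors if g.name == n), None)
                if g is None:
                    raise ValueError(f"constraint names unknown factor {n!r}")
                if g.kind != "continuous":
                    raise ValueError(f"constraint names non-continuous factor {n!r}")
        self.factors: tuple[DesignFactor, ...] = tuple(factors)
        self.constraints: tuple[LinearEqualityConstraint, ...] = tuple(constraints)
        self._by_name = {f.name: f for f in self.factors}

    # -- structure ---------------------------------------------------------
    @property
    def numeric_factors(self) -> tuple[DesignFactor, ...]:
        return tuple(f for f in self.factors if f.is_numeric)

    @property
    def categorical_factors(self) -> tuple[DesignFactor, ...]:
        return tuple(f for f in self.factors if f.kind == "categorical")

    @property
    def n_numeric(self) -> int:
        return len(self.numeric_factors)

    @property
    def n_categorical(self) -> int:
        """c, the number of categorical variables entering the overlap kernel."""
        return len(self.categorical_factors)

    def factor(self, name: str) -> DesignFactor:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown factor {name!r}") from None

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DesignSpace)
            and self.factors == other.factors
            and self.constraints == other.constraints
        )

    def __repr__(self) -> str:
        return f"DesignSpace({[f.name for f in self.factors]}, constraints={len(self.constraints)})"

    # -- validation --------------------------------------------------------
    def validate_point(self, point: DesignPoint) -> ValidationResult:
        """Check completeness, bounds/levels/categories and constraints."""
        for name in point.values:
            if name not in self._by_name:
                raise KeyError(f"unknown factor {name!r}")
        violations: list[str] = []
        for f in self.factors:
            if f.name not in point.values:
                violations.append(f"{f.name}: missing value")
                continue
            v = point.values[f.name]
            if f.kind == "continuous":
                if not (isinstance(v, (int, float)) and np.isfinite(v)):
                    violations.append(f"{f.name}: non-numeric value {v!r}")
                elif not (f.lower - 1e-12 <= float(v) <= f.upper + 1e-12):
                    violations.append(f"{f.name}: {v} outside [{f.lower}, {f.upper}]")
            elif f.kind == "discrete":
                if not isinstance(v, (int, float)) or not any(
                    abs(float(v) - lv) <= 1e-9 for lv in f.levels
                ):
                    violations.append(f"{f.name}: {v} is not a declared level")
            else:
                if v not in f.categories:
                    violations.append(f"{f.name}: {v!r} is not a declared category")
        if not violations:
            for con in self.constraints:
                r = con.residual({n: point.values[n] for n in con.coefficients})
                if abs(r) > con.tolerance:
                    names = "+".join(con.coefficients)
                    violations.append(f"constraint[{names}]: residual {r:.3g} exceeds {con.tolerance}")
        return ValidationResult(not violations, tuple(violations))

    # -- encoding ----------------------------------------------------------
    def encode_point(self, point: DesignPoint) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, h): numeric values scaled to [0,1], category indices."""
        res = self.validate_point(point)
        if not res.valid:
            raise ValueError("invalid point: " + "; ".join(res.violations))
        x = np.array(
            [(float(point[f.name]) - f.lower) / (f.upper - f.lower) for f in self.numeric_factors],
            dtype=float,
        )
        h = np.array(
            [f.categories.index(point[f.name]) for f in self.categorical_factors], dtype=int
        )
        return x, h

    def decode_point(self, x: np.ndarray, h: np.ndarray) -> DesignPoint:
        """Inverse of :meth:`encode_point`; discrete values snap to the
        nearest declared level."""
        values: dict[str, float | str] = {}
        for f, xi in zip(self.numeric_factors, np.asarray(x, dtype=float)):
            raw = f.lower + float(xi) * (f.upper - f.lower)
            if f.kind == "discrete":
                raw = min(f.levels, key=lambda lv: abs(lv - raw))
            values[f.name] = raw
        for f, hi in zip(self.categorical_factors, np.asarray(h, dtype=int)):
            values[f.name] = f.categories[int(hi)]
        return DesignPoint(values)

    def encode_many(self, points: Iterable[DesignPoint]) -> tuple[np.ndarray, np.ndarray]:
        pts = list(points)
        if not pts:
            return np.zeros((0, self.n_numeric)), np.zeros((0, self.n_categorical), dtype=int)
        xs, hs = zip(*(self.encode_point(p) for p in pts))
        return np.vstack(xs), np.vstack(hs)

    # -- sampling ----------------------------------------------------------
    def sample_uniform_feasible(self, n: int, seed: int) -> list[DesignPoint]:
        """Draw n valid points uniformly over the feasible region.

        A single sum-to-one style constraint over nonnegative ratios is
        sampled exactly via a symmetric Dirichlet; anything else falls back
        to rejection sampling against the constraint tolerance.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        points: list[DesignPoint] = []
        simplex = self._single_simplex_constraint()
        for _ in range(n):
            values: dict[str, float | str] = {}
            if simplex is not None:
                con, scale = simplex
                w = rng.dirichlet(np.ones(len(con.coefficients))) * scale
                for name, wi in zip(con.coefficients, w):
                    values[name] = float(wi)
            for f in self.factors:
                if f.name in values:
                    continue
                if f.kind == "continuous":
                    values[f.name] = float(rng.uniform(f.lower, f.upper))
                elif f.kind == "discrete":
                    values[f.name] = float(rng.choice(f.levels))
                else:
                    values[f.name] = str(rng.choice(f.categories))
            p = DesignPoint(values)
            if simplex is None and self.constraints:
                p = self._sample_affine_slice(p, rng)
            points.append(p)
        return points

    def _single_simplex_constraint(self) -> tuple[LinearEqualityConstraint, float] | None:
        """Detect one constraint of the form sum(c*x_i) = rhs with equal
        positive coefficients and lower bounds 0 — the media-blend case."""
        if len(self.constraints) != 1:
            return None
        con = self.constraints[0]
        coefs = list(con.coefficients.values())
        if not all(c == coefs[0] and c > 0 for c in coefs):
            return None
        scale = con.rhs / coefs[0]
        if scale <= 0:
            return None
        for name in con.coefficients:
            f = self.factor(name)
            if f.lower != 0 or f.upper < scale:
                return None
        return con, scale

    def _sample_affine_slice(self, start: DesignPoint, rng: np.random.Generator) -> DesignPoint:
        """General linear-equality fallback: find a feasible point of the
        affine slice by linear programming, then take random bounded steps
        in the constraint null space (approximately uniform)."""
        from scipy.linalg import null_space
        from scipy.optimize import linprog

        cons_names = sorted({n for con in self.constraints for n in con.coefficients})
        A = np.array([[con.coefficients.get(n, 0.0) for n in cons_names] for con in self.constraints])
        b = np.array([con.rhs for con in self.constraints])
        bounds = [(self.factor(n).lower, self.factor(n).upper) for n in cons_names]
        res = linprog(rng.uniform(-1, 1, size=len(cons_names)), A_eq=A, b_eq=b, bounds=bounds,
                      method="highs")
        if not res.success:
            raise RuntimeError("constraint system is infeasible within the factor bounds")
        x = res.x
        N = null_space(A)
        lo = np.array([bd[0] for bd in bounds])
        hi = np.array([bd[1] for bd in bounds])
        for _ in range(50):  # random-walk mixing over the feasible polytope
            direction = N @ rng.standard_normal(N.shape[1]) if N.size else np.zeros_like(x)
            nrm = np.linalg.norm(direction)
            if nrm < 1e-12:
                break
            direction /= nrm
            with np.errstate(divide="ignore", invalid="ignore"):
                steps_hi = np.where(direction > 1e-12, (hi - x) / direction, np.inf)
                steps_lo = np.where(direction < -1e-12, (lo - x) / direction, np.inf)
            t_max = float(min(np.min(steps_hi), np.min(steps_lo)))
            with np.errstate(divide="ignore", invalid="ignore"):
                steps_hi = np.where(direction < -1e-12, (hi - x) / direction, -np.inf)
                steps_lo = np.where(direction > 1e-12, (lo - x) / direction, -np.inf)
            t_min = float(max(np.max(steps_hi), np.max(steps_lo)))
            x = np.clip(x + rng.uniform(t_min, t_max) * direction, lo, hi)
        values = dict(start.values)
        for n, xi in zip(cons_names, x):
            values[n] = float(xi)
        return DesignPoint(values)


# ---------------------------------------------------------------------------
# config round trip

def _factor_to_dict(f: DesignFactor) -> dict:
    d: dict = {"name": f.name, "kind": f.kind}
    if f.kind == "continuous":
        d["lower"], d["upper"] = f.lower, f.upper
    elif f.kind == "discrete":
        d["levels"] = list(f.levels)
    else:
        d["categories"] = list(f.categories)
    if f.units:
        d["units"] = f.units
    if f.phase:
        d["phase"] = f.phase
    if f.linked_to:
        d["linked_to"] = f.linked_to
    return d


def space_to_dict(space: DesignSpace) -> dict:
    return {
        "factors": [_factor_to_dict(f) for f in space.factors],
        "constraints": [
            {"coefficients": dict(c.coefficients), "rhs": c.rhs, "tolerance": c.tolerance}
            for c in space.constraints
        ],
    }


def space_from_dict(d: Mapping) -> DesignSpace:
    factors = [DesignFactor(**fd) for fd in d["factors"]]
    constraints = [LinearEqualityConstraint(**cd) for cd in d.get("constraints", [])]
    return DesignSpace(factors, constraints)


def save_space(space: DesignSpace, path: str | Path) -> None:
    path = Path(path)
    d = space_to_dict(space)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_space(path: str | Path) -> DesignSpace:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return space_from_dict(d)
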