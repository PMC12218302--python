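"""Acquisition functions and batch suggestion strategies.

Suggestion of the next experimental batch is a maximisation of an
acquisition score over the design space (minimisation targets are negated
upstream, at the objective boundary):

* upper confidence bound (UCB), posterior mean + κ·sd, maximised by
  multistart L-BFGS-B on unconstrained continuous spaces and by a
  trust-region method restricted to the feasible affine slice when linear
  equality constraints are present;
* a brute-force screen that scores a large Latin-hypercube/uniform candidate
  set (default 10 000 points) and takes the argmax — the workhorse for mixed
  categorical-continuous spaces;
* Thompson sampling, the argmax of one joint posterior sample path per batch
  slot, paired with an EXP3 multi-armed bandit over the categories of the
  dominant categorical factor during early, exploration-heavy iterations;
* constant-liar batching: after each suggestion the model is temporarily
  augmented with a "lie" (the mean of the observed targets) at that point,
  which collapses the local uncertainty and pushes later batch members to
  new regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .design_space import DesignPoint, DesignSpace
from .gp_model import GPModel
from .initial_design import lhs_unit

__all__ = [
    "AcquisitionConfig",
    "BanditState",
    "ucb",
    "maximize_acquisition",
    "bandit_select_category",
    "thompson_batch",
    "constant_liar_batch",
    "suggest_batch",
]

ACQUISITION_KINDS = ("ucb", "thompson", "bandit_thompson", "brute_force_screen")


@dataclass
class AcquisitionConfig:
    """Acquisition settings for a campaign.

    ``screen_size`` is the brute-force candidate count; Thompson sampling
    uses the smaller ``thompson_screen_size`` because drawing a joint
    posterior sample is cubic in the number of candidates.
    ``phase_schedule`` maps iteration index -> acquisition kind, overriding
    the default dispatch.
    """

    kind: str = "ucb"
    kappa: float = 2.0
    screen_size: int = 10_000
    batch_size: int = 6
    lie: str = "mean"
    phase_schedule: dict[int, str] | None = None
    thompson_screen_size: int = 512
    n_restarts: int = 5
    bandit_switch_iteration: int = 4  # mixed spaces: bandit+Thompson before, brute force after

    def __post_init__(self) -> None:
        if self.kind not in ACQUISITION_KINDS:
            raise ValueError(f"unknown acquisition kind {self.kind!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.screen_size < self.batch_size:
            raise ValueError("screen_size must be >= batch_size")
        if self.lie != "mean":
            raise ValueError("only the 'mean' constant-liar strategy is supported")

    def kind_for_iteration(self, iteration: int, space: DesignSpace) -> str:
        if self.phase_schedule and iteration in self.phase_schedule:
            return self.phase_schedule[iteration]
        if space.n_categorical > 0:
            return "bandit_thompson" if iteration < self.bandit_switch_iteration else "brute_force_screen"
        return self.kind


# ---------------------------------------------------------------------------
# UCB

def ucb(model: GPModel, x: np.ndarray, h: np.ndarray | None, kappa: float) -> np.ndarray:
    """mean + kappa * sd (maximisation convention)."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    mean, sd = model.predict(np.atleast_2d(x), h)
    return mean + kappa * sd


# ---------------------------------------------------------------------------
# candidate screens

def _screen(space: DesignSpace, m: int, rng: np.random.Generator,
            fixed_h: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """m encoded candidates: LHS over numeric axes (uniform feasible when
    constrained), uniform categories unless ``fixed_h`` pins them."""
    if space.constraints:
        pts = space.sample_uniform_feasible(m, int(rng.integers(2**31)))
        x, h = space.encode_many(pts)
    else:
        x = lhs_unit(m, space.n_numeric, rng)
        c = space.n_categorical
        h = np.column_stack(
            [rng.integers(len(f.categories), size=m) for f in space.categorical_factors]
        ) if c else np.zeros((m, 0), dtype=int)
    if fixed_h is not None:
        h = np.broadcast_to(np.asarray(fixed_h, dtype=int), h.shape).copy()
    return x, h


def _decode_snapped(space: DesignSpace, x: np.ndarray, h: np.ndarray) -> DesignPoint:
    return space.decode_point(np.clip(x, 0.0, 1.0), h)


# ---------------------------------------------------------------------------
# acquisition maximisation

def _scaled_constraints(space: DesignSpace) -> list[optimize.LinearConstraint]:
    """Linear equality constraints re-expressed on the [0,1]-scaled axes."""
    cons = []
    numeric = space.numeric_factors
    for con in space.constraints:
        a = np.zeros(len(numeric))
        shift = 0.0
        for i, f in enumerate(numeric):
            c = con.coefficients.get(f.name, 0.0)
            a[i] = c * (f.upper - f.lower)
            shift += c * f.lower
        cons.append(optimize.LinearConstraint(a, con.rhs - shift, con.rhs - shift))
    return cons


def maximize_acquisition(
    model: GPModel, config: AcquisitionConfig, space: DesignSpace, seed: int
) -> DesignPoint:
    """Return the point maximising the acquisition for the given strategy.

    Mixed spaces and the explicit brute-force kind use a screen-and-argmax;
    unconstrained continuous spaces use multistart L-BFGS-B; constrained
    spaces use a trust-region method on the feasible affine slice.  Ties in
    the screen resolve to the lowest candidate index.
    """
    rng = np.random.default_rng(seed)
    if space.n_categorical > 0 or config.kind == "brute_force_screen":
        x, h = _screen(space, config.screen_size, rng)
        scores = ucb(model, x, h, config.kappa)
        i = int(np.argmax(scores))  # np.argmax takes the first maximum
        return _decode_snapped(space, x[i], h[i])

    d = space.n_numeric
    neg = lambda v: -float(ucb(model, v[None, :], None, config.kappa)[0])
    starts = [rng.uniform(size=d) for _ in range(config.n_restarts)]
    best_x, best_val = None, np.inf
    if space.constraints:
        cons = _scaled_constraints(space)
        feas = space.sample_uniform_feasible(config.n_restarts, int(rng.integers(2**31)))
        starts = [space.encode_point(p)[0] for p in feas]
        import warnings

        for s in starts:
            with warnings.catch_warnings():
                # quasi-Newton Hessian updates on near-linear slices are benign
                warnings.filterwarnings("ignore", message="delta_grad == 0.0")
                res = optimize.minimize(
                    neg, s, method="trust-constr", bounds=[(0.0, 1.0)] * d,
                    constraints=cons, options={"maxiter": 200, "gtol": 1e-8},
                )
            if res.fun < best_val:
                best_x, best_val = res.x, res.fun
        # project exactly onto the affine slice to absorb solver slack
        point = _decode_snapped(space, best_x, np.zeros(0, dtype=int))
        return _project_onto_constraints(space, point)
    for s in starts:
        res = optimize.minimize(neg, s, method="L-BFGS-B", bounds=[(0.0, 1.0)] * d)
        if res.fun < best_val:
            best_x, best_val = res.x, res.fun
    if best_x is None:
        raise RuntimeError("acquisition maximisation failed")
    return _decode_snapped(space, best_x, np.zeros(0, dtype=int))


def _project_onto_constraints(space: DesignSpace, point: DesignPoint) -> DesignPoint:
    """Rescale constrained coordinate blocks so equality residuals vanish."""
    values = dict(point.values)
    for con in space.constraints:
        current = sum(con.coefficients[n] * float(values[n]) for n in con.coefficients)
        if current != 0 and abs(current - con.rhs) > 0:
            scale = con.rhs / current
            for n in con.coefficients:
                values[n] = float(values[n]) * scale
    return DesignPoint(values)


# ---------------------------------------------------------------------------
# EXP3 bandit over categories

@dataclass
class BanditState:
    """EXP3 weights over the arms of one categorical factor.

    Probability matching with a γ-uniform mixture guarantees every arm keeps
    nonzero selection probability; rewards are importance-weighted into the
    chosen arm's log-weight.
    """

    n_arms: int
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    t: int = 0

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise ValueError("need at least one arm")
        if self.weights is None:
            self.weights = np.ones(self.n_arms)
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def gamma(self) -> float:
        horizon = max(self.t, 1)
        return float(min(1.0, np.sqrt(self.n_arms * np.log(max(self.n_arms, 2)) / ((np.e - 1) * horizon))))

    def probabilities(self) -> np.ndarray:
        g = self.gamma
        w = self.weights / self.weights.sum()
        return (1.0 - g) * w + g / self.n_arms

    def select(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.n_arms, p=self.probabilities()))

    def update(self, arm: int, reward: float) -> None:
        """Importance-weighted EXP3 update; reward should be in [0, 1]."""
        p = self.probabilities()[arm]
        g = self.gamma
        self.t += 1
        self.weights[arm] *= np.exp(g * reward / (p * self.n_arms))
        self.weights /= self.weights.max()  # keep weights bounded

    def to_dict(self) -> dict:
        return {"n_arms": self.n_arms, "weights": self.weights.tolist(), "t": self.t}

    @classmethod
    def from_dict(cls, d: dict) -> "BanditState":
        return cls(n_arms=d["n_arms"], weights=np.asarray(d["weights"]), t=d["t"])


def bandit_select_category(state: BanditState, rng: np.random.Generator) -> int:
    """Draw one arm by probability matching from the EXP3 state."""
    return state.select(rng)


# ---------------------------------------------------------------------------
# Thompson sampling

def thompson_batch(
    model: GPModel,
    space: DesignSpace,
    batch_size: int,
    screen_size: int,
    seed: int,
    fixed_h_per_slot: list[np.ndarray] | None = None,
) -> list[DesignPoint]:
    """One posterior sample path per batch slot; each slot returns the
    argmax of its own path over a fresh candidate screen.

    ``fixed_h_per_slot`` pins the categorical coordinates of each slot (the
    bandit-chosen co-feed type); continuous coordinates are still screened.
    """
    rng = np.random.default_rng(seed)
    batch = []
    for slot in range(batch_size):
        fixed = None if fixed_h_per_slot is None else fixed_h_per_slot[slot]
        x, h = _screen(space, screen_size, rng, fixed_h=fixed)
        draw = model.sample_posterior(x, h, 1, rng)[0]
        i = int(np.argmax(draw))
        batch.append(_decode_snapped(space, x[i], h[i]))
    return batch


# ---------------------------------------------------------------------------
# constant liar

def constant_liar_batch(
    model: GPModel, config: AcquisitionConfig, space: DesignSpace, seed: int
) -> list[DesignPoint]:
    """Sequentially maximise the acquisition, lying the mean target value at
    each suggestion before picking the next; the original model is untouched
    and hyperparameters are not re-optimised inside the loop."""
    rng = np.random.default_rng(seed)
    scratch = model
    batch: list[DesignPoint] = []
    for _ in range(config.batch_size):
        point = maximize_acquisition(scratch, config, space, int(rng.integers(2**31)))
        batch.append(point)
        lie = float(np.mean(scratch.training.y))
        x, h = space.encode_point(point)
        scratch = scratch.with_observation(x, h, lie, noise=0.0)
    return batch


# ---------------------------------------------------------------------------
# dispatch

def suggest_batch(
    model: GPModel,
    space: DesignSpace,
    config: AcquisitionConfig,
    iteration: int,
    seed: int,
    bandit_state: BanditState | None = None,
) -> list[DesignPoint]:
    """Plan the next batch for iteration ``iteration`` (>= 1).

    Mixed spaces default to bandit-selected categories + Thompson sampling
    in early iterations and a brute-force screen with constant-liar batching
    later; continuous spaces use UCB with quasi-Newton (unconstrained) or
    trust-region (constrained) maximisation under the constant liar.
    """
    kind = config.kind_for_iteration(iteration, space)
    rng = np.random.default_rng(seed)
    if kind == "bandit_thompson":
        if space.n_categorical == 0:
            raise ValueError("bandit_thompson requires a categorical factor")
        lead = space.categorical_factors[0]
        if bandit_state is None:
            bandit_state = BanditState(len(lead.categories))
        slots = []
        for _ in range(config.batch_size):
            arm = bandit_select_category(bandit_state, rng)
            h = np.array([arm] + [
                int(rng.integers(len(f.categories))) for f in space.categorical_factors[1:]
            ])
            slots.append(h)
        batch = thompson_batch(
            model, space, config.batch_size, config.thompson_screen_size,
            int(rng.integers(2**31)), fixed_h_per_slot=slots,
        )
    elif kind == "thompson":
        batch = thompson_batch(
            model, space, config.batch_size, config.thompson_screen_size, int(rng.integers(2**31))
        )
    else:  # ucb / brute_force_screen under the constant liar
        sub = AcquisitionConfig(
            kind=kind, kappa=config.kappa, screen_size=config.screen_size,
            batch_size=config.batch_size, thompson_screen_size=config.thompson_screen_size,
            n_restarts=config.n_restarts,
        )
        batch = constant_liar_batch(model, sub, space, int(rng.integers(2**31)))
    bad = [p for p in batch if not space.validate_point(p).valid]
    if bad:
        raise RuntimeError(f"suggested infeasible points: {bad}")
    return batch
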