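"""Warm-starting a campaign on an extended design space.

When new media supplements (factors) are added after a campaign, the fitted
GP already encodes what was learned about the original factors.  Instead of
re-running a space-filling design over the enlarged space, the historical
experiments are embedded into it — new factors pinned at the benchmark
conditions under which the history was generated — and the embedded model's
acquisition plans the first batch directly.  At the embedding fill values
the new dimensions contribute zero distance, so the embedded model's
predictions at historical points coincide with the original model's before
any re-optimisation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .acquisition import AcquisitionConfig
from .campaign import CampaignLedger, CampaignState
from .design_space import DesignFactor, DesignPoint, DesignSpace
from .gp_model import TrainingSet

__all__ = ["extend_space", "embed_history", "warm_start_campaign", "percent_reduction"]


def extend_space(old: DesignSpace, new_factors: Sequence[DesignFactor]) -> DesignSpace:
    """Union space: old factors in order, then the new ones; constraints
    carry over unchanged."""
    old_names = {f.name for f in old.factors}
    for f in new_factors:
        if f.name in old_names:
            raise ValueError(f"factor name collision: {f.name!r}")
    return DesignSpace(tuple(old.factors) + tuple(new_factors), old.constraints)


def embed_history(
    ledger: CampaignLedger,
    old_space: DesignSpace,
    new_space: DesignSpace,
    fill_values: Mapping[str, float | str],
    sign: float = 1.0,
    noise_variance: float = 0.0,
) -> TrainingSet:
    """Map every executed historical experiment into the new space.

    New factors take ``fill_values`` (the benchmark conditions the history
    was actually run under); targets and noise carry over unchanged.
    """
    new_names = [f.name for f in new_space.factors if f.name not in {g.name for g in old_space.factors}]
    missing = [n for n in new_names if n not in fill_values]
    if missing:
        raise ValueError(f"missing fill values for new factors: {missing}")
    df = ledger.rows()
    df = df[df["role"].isin(["executed", "control"]) & df["target"].notna()]
    points = []
    for _, row in df.iterrows():
        values = dict(ledger.point_for(row).values)
        for n in new_names:
            values[n] = fill_values[n]
        points.append(DesignPoint(values))
    x, h = new_space.encode_many(points)
    y = sign * df["target"].to_numpy(dtype=float)
    return TrainingSet(x, h, y, np.full(len(df), noise_variance))


def warm_start_campaign(
    old_state: CampaignState,
    new_space: DesignSpace,
    fill_values: Mapping[str, float | str],
    acquisition_config: AcquisitionConfig | None = None,
    seed: int | None = None,
) -> CampaignState:
    """New campaign whose prior is the old GP, not a space-filling design.

    The embedded history is refit on the new space (new continuous
    dimensions start at length scale 1.0 on the scaled axis: maximally
    uncertain but smooth), the bandit state carries over for shared
    categorical arms, and iteration 0 of the new campaign is planned by the
    acquisition rather than by LHS.
    """
    if old_state.model is None:
        raise RuntimeError("old campaign has no fitted model")
    config = acquisition_config or old_state.config
    seed = old_state.seed if seed is None else seed
    state = CampaignState(
        space=new_space, config=config, direction=old_state.direction, seed=seed,
        nu=old_state.nu, n_restarts=old_state.n_restarts,
        initial_noise_variance=old_state.noise_variance(),
        control_pool=list(old_state.control_pool),
    )
    train = embed_history(
        old_state.ledger, old_state.space, new_space, fill_values,
        sign=old_state.sign, noise_variance=old_state.noise_variance(),
    )
    # copy history into the new ledger so accounting stays end-to-end
    df = old_state.ledger.rows()
    df = df[df["role"].isin(["executed", "control"]) & df["target"].notna()]
    hist_points = []
    new_names = [f.name for f in new_space.factors
                 if f.name not in {g.name for g in old_state.space.factors}]
    for _, row in df.iterrows():
        values = dict(old_state.ledger.point_for(row).values)
        for n in new_names:
            values[n] = fill_values[n]
        hist_points.append(DesignPoint(values))
    state.ledger.append_planned(hist_points, 0)
    for exp_id, (_, row) in zip(state.ledger.frame["experiment_id"], df.iterrows()):
        state.ledger.mark_executed(int(exp_id), [float(row["target"])], role=str(row["role"]))
    state.iteration = 0

    from .gp_model import fit_gp

    state.model = fit_gp(
        train, nu=state.nu,
        n_categories=tuple(len(f.categories) for f in new_space.categorical_factors),
        n_restarts=state.n_restarts, seed=seed,
    )
    if old_state.bandit is not None and new_space.n_categorical:
        shared = min(old_state.bandit.n_arms, len(new_space.categorical_factors[0].categories))
        from .acquisition import BanditState

        weights = np.ones(len(new_space.categorical_factors[0].categories))
        weights[:shared] = old_state.bandit.weights[:shared]
        state.bandit = BanditState(len(weights), weights=weights, t=old_state.bandit.t)
    return state


def percent_reduction(baseline_experiments: int, warm_start_experiments: int) -> float:
    """Percent fewer experiments than the cold-start baseline campaign."""
    if baseline_experiments <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (baseline_experiments - warm_start_experiments) / baseline_experiments
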