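"""Campaign state, the experiment ledger, and the ingest/refit cycle.

A campaign is an append-only ledger of experiments (planned, executed,
control, validation) plus the current surrogate model and bandit state.  The
loop is: plan an initial space-filling design, execute and ingest the
measurements, refit the GP with the pooled control-derived noise, suggest
the next batch, repeat until the model's predictions agree with the
observations or the budget is spent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig, BanditState, suggest_batch
from .design_space import DesignPoint, DesignSpace, load_space, space_from_dict, space_to_dict
from .gp_model import GPModel, TrainingSet, check_convergence, estimate_noise_variance, fit_gp
from .initial_design import mixed_initial_design
from .objectives import replicate_target

logger = logging.getLogger(__name__)

__all__ = ["CampaignLedger", "CampaignState", "read_ledger", "write_ledger"]

ROLES = ("planned", "executed", "control", "validation")
META_COLUMNS = ("experiment_id", "iteration", "role")


class CampaignLedger:
    """Append-only record of planned and executed experiments.

    Stored as a CSV with one row per experiment: metadata columns, one
    column per design factor, replicate columns ``rep_1..rep_n`` and a
    ``target`` column (filled from the replicate mean when empty).
    """

    def __init__(self, space: DesignSpace, frame: pd.DataFrame | None = None) -> None:
        self.space = space
        cols = list(META_COLUMNS) + [f.name for f in space.factors] + ["target"]
        self.frame = frame if frame is not None else pd.DataFrame(columns=cols)
        if frame is not None:
            self._validate()

    def _validate(self) -> None:
        df = self.frame
        ids = df["experiment_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate experiment_id {dup!r}")
        for _, row in df.iterrows():
            if row["role"] not in ROLES:
                raise ValueError(f"row {row['experiment_id']}: unknown role {row['role']!r}")
            point = self.point_for(row)
            res = self.space.validate_point(point)
            if not res.valid:
                raise ValueError(
                    f"row {row['experiment_id']}: " + "; ".join(res.violations)
                )

    @property
    def rep_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("rep_")]

    def point_for(self, row: Mapping) -> DesignPoint:
        values: dict[str, float | str] = {}
        for f in self.space.factors:
            v = row[f.name]
            values[f.name] = str(v) if f.kind == "categorical" else float(v)
        return DesignPoint(values)

    def next_id(self) -> int:
        return len(self.frame) + 1

    def append_planned(self, points: Sequence[DesignPoint], iteration: int) -> None:
        rows = []
        for p in points:
            row = {"experiment_id": self.next_id() + len(rows), "iteration": iteration,
                   "role": "planned", "target": np.nan}
            row.update(p.values)
            rows.append(row)
        new = pd.DataFrame(rows)
        if self.frame.empty:
            new = new.reindex(columns=list(self.frame.columns) + [c for c in new.columns if c not in self.frame.columns])
            self.frame = new
        else:
            self.frame = pd.concat([self.frame, new], ignore_index=True)

    def mark_executed(self, experiment_id: int, replicates: Sequence[float],
                      role: str = "executed") -> float:
        idx = self.frame.index[self.frame["experiment_id"] == experiment_id]
        if len(idx) == 0:
            raise KeyError(f"unknown experiment_id {experiment_id}")
        i = idx[0]
        for j, r in enumerate(replicates, start=1):
            col = f"rep_{j}"
            if col not in self.frame.columns:
                self.frame[col] = np.nan
            self.frame.loc[i, col] = r
        target = replicate_target(replicates)
        self.frame.loc[i, "target"] = target
        self.frame.loc[i, "role"] = role
        return target

    def rows(self, role: str | None = None, iteration: int | None = None) -> pd.DataFrame:
        df = self.frame
        if role is not None:
            df = df[df["role"] == role]
        if iteration is not None:
            df = df[df["iteration"] == iteration]
        return df

    def __len__(self) -> int:
        return len(self.frame)


def write_ledger(ledger: CampaignLedger, path: str | Path) -> None:
    ledger.frame.to_csv(path, index=False)


def read_ledger(path: str | Path, space: DesignSpace) -> CampaignLedger:
    """Load a ledger CSV; empty targets are filled from replicate means."""
    df = pd.read_csv(path)
    ledger = CampaignLedger(space, df)
    rep_cols = ledger.rep_columns
    for i, row in df.iterrows():
        if pd.isna(row.get("target", np.nan)) and rep_cols:
            reps = [row[c] for c in rep_cols if pd.notna(row[c])]
            if reps:
                df.loc[i, "target"] = replicate_target(reps)
    return ledger


@dataclass
class CampaignState:
    """Everything needed to continue a campaign: space, ledger, model,
    bandit and noise bookkeeping, plus the acquisition configuration."""

    space: DesignSpace
    config: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    direction: str = "maximize"
    seed: int = 0
    nu: float | None = None
    n_restarts: int = 10
    initial_noise_variance: float = 0.0
    ledger: CampaignLedger = None  # type: ignore[assignment]
    model: GPModel | None = None
    bandit: BanditState | None = None
    control_pool: list[float] = field(default_factory=list)
    convergence_history: list[bool] = field(default_factory=list)
    iteration: int = -1  # last planned iteration

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise ValueError("direction must be 'maximize' or 'minimize'")
        if self.ledger is None:
            self.ledger = CampaignLedger(self.space)

    # -- direction handling ------------------------------------------------
    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "maximize" else -1.0

    # -- noise -------------------------------------------------------------
    def noise_variance(self) -> float:
        """Pooled control variance across all iterations, falling back to
        the initial estimate while fewer than two controls exist."""
        if len(self.control_pool) >= 2:
            return estimate_noise_variance(np.asarray(self.control_pool))
        return self.initial_noise_variance

    # -- planning ----------------------------------------------------------
    def suggest_initial(self, n: int) -> list[DesignPoint]:
        """Iteration-0 space-filling design, appended as planned rows."""
        if self.iteration >= 0:
            raise RuntimeError("initial design already planned")
        points = mixed_initial_design(self.space, n, self.seed)
        self.iteration = 0
        self.ledger.append_planned(points, 0)
        return points

    def suggest(self, seed: int | None = None) -> list[DesignPoint]:
        """Plan the next batch from the fitted model."""
        if self.model is None:
            raise RuntimeError("no fitted model; ingest executed experiments first")
        seed = self.seed + 1000 * (self.iteration + 1) if seed is None else seed
        if self.space.n_categorical and self.bandit is None:
            self.bandit = BanditState(len(self.space.categorical_factors[0].categories))
        points = suggest_batch(
            self.model, self.space, self.config, self.iteration + 1, seed, self.bandit
        )
        self.iteration += 1
        self.ledger.append_planned(points, self.iteration)
        return points

    # -- ingestion ---------------------------------------------------------
    def ingest(self, results: Sequence[tuple[int, Sequence[float]]],
               roles: Mapping[int, str] | None = None) -> None:
        """Record replicate measurements for planned experiments, update
        the pooled noise, refit the model and run the convergence check.

        ``results`` is a list of (experiment_id, replicates); ``roles`` may
        re-tag ids as 'control' or 'validation'.  Control replicates join the
        pooled noise estimate; validation rows never enter the training set.
        """
        roles = roles or {}
        ingested: list[int] = []
        for exp_id, reps in results:
            role = roles.get(exp_id, "executed")
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}")
            self.ledger.mark_executed(exp_id, reps, role=role)
            if role == "control":
                self.control_pool.extend(float(r) for r in reps)
            ingested.append(exp_id)
        self.refit()
        self._record_convergence(ingested)
        df = self.ledger.frame
        executed = df[df["experiment_id"].isin(ingested) & (df["role"] == "executed")]
        if not executed.empty:
            self.update_bandit(int(executed["iteration"].max()))

    def training_set(self) -> TrainingSet:
        df = self.ledger.rows()
        df = df[df["role"].isin(["executed", "control"]) & df["target"].notna()]
        points = [self.ledger.point_for(row) for _, row in df.iterrows()]
        x, h = self.space.encode_many(points)
        y = self.sign * df["target"].to_numpy(dtype=float)
        noise = np.full(len(df), self.noise_variance())
        return TrainingSet(x, h, y, noise)

    def refit(self) -> None:
        train = self.training_set()
        if train.n < 2:
            return
        self.model = fit_gp(
            train,
            nu=self.nu,
            n_categories=tuple(len(f.categories) for f in self.space.categorical_factors),
            n_restarts=self.n_restarts,
            seed=self.seed,
        )

    def _record_convergence(self, ingested: Sequence[int]) -> None:
        if self.model is None:
            return
        df = self.ledger.frame
        batch = []
        for exp_id in ingested:
            row = df[df["experiment_id"] == exp_id].iloc[0]
            if row["role"] == "validation":
                continue
            x, h = self.space.encode_point(self.ledger.point_for(row))
            batch.append((x, h, self.sign * float(row["target"])))
        if batch:
            converged, _ = check_convergence(self.model, batch)
            self.convergence_history.append(converged)

    def update_bandit(self, iteration: int) -> None:
        """EXP3 reward update from the latest executed batch: per category,
        the best (direction-adjusted) target, min-max scaled over history."""
        if self.bandit is None or self.space.n_categorical == 0:
            return
        lead = self.space.categorical_factors[0]
        df = self.ledger.rows(role="executed")
        df = df[df["target"].notna()]
        if df.empty:
            return
        y = self.sign * df["target"].to_numpy(dtype=float)
        lo, hi = float(np.min(y)), float(np.max(y))
        span = hi - lo if hi > lo else 1.0
        latest = df[df["iteration"] == iteration]
        for cat, grp in latest.groupby(lead.name):
            arm = lead.categories.index(str(cat))
            best = float(np.max(self.sign * grp["target"].to_numpy(dtype=float)))
            self.bandit.update(arm, (best - lo) / span)

    # -- summaries ---------------------------------------------------------
    def best_so_far(self) -> tuple[DesignPoint | None, float | None]:
        df = self.ledger.rows(role="executed")
        df = df[df["target"].notna()]
        if df.empty:
            return None, None
        vals = self.sign * df["target"].to_numpy(dtype=float)
        i = int(np.argmax(vals))
        row = df.iloc[i]
        return self.ledger.point_for(row), float(row["target"])

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "space": space_to_dict(self.space),
            "direction": self.direction,
            "seed": self.seed,
            "nu": self.nu,
            "n_restarts": self.n_restarts,
            "initial_noise_variance": self.initial_noise_variance,
            "iteration": self.iteration,
            "control_pool": list(self.control_pool),
            "convergence_history": list(self.convergence_history),
            "config": {
                "kind": self.config.kind, "kappa": self.config.kappa,
                "screen_size": self.config.screen_size, "batch_size": self.config.batch_size,
                "lie": self.config.lie, "phase_schedule": self.config.phase_schedule,
                "thompson_screen_size": self.config.thompson_screen_size,
                "n_restarts": self.config.n_restarts,
                "bandit_switch_iteration": self.config.bandit_switch_iteration,
            },
            "bandit": self.bandit.to_dict() if self.bandit else None,
        }
        if self.model is not None:
            p = self.model.params
            d["model"] = {
                "theta": p.theta.tolist(), "nu": p.nu, "sigma_cat": p.sigma_cat,
                "alpha": p.alpha, "noise_variance": p.noise_variance,
                "signal_variance": p.signal_variance,
                "kernel": self.model.kernel, "n_categories": list(self.model.n_categories),
                "y_mean": self.model.y_mean, "y_std": self.model.y_std,
            }
        return d

    def save(self, state_path: str | Path, ledger_path: str | Path) -> None:
        Path(state_path).write_text(json.dumps(self.to_dict(), indent=2))
        write_ledger(self.ledger, ledger_path)

    @classmethod
    def load(cls, state_path: str | Path, ledger_path: str | Path) -> "CampaignState":
        d = json.loads(Path(state_path).read_text())
        space = space_from_dict(d["space"])
        cfg = d["config"]
        if cfg.get("phase_schedule"):
            cfg["phase_schedule"] = {int(k): v for k, v in cfg["phase_schedule"].items()}
        config = AcquisitionConfig(**cfg)
        ledger = read_ledger(ledger_path, space)
        state = cls(
            space=space, config=config, direction=d["direction"], seed=d["seed"],
            nu=d["nu"], n_restarts=d["n_restarts"],
            initial_noise_variance=d["initial_noise_variance"], ledger=ledger,
            control_pool=list(d["control_pool"]),
            convergence_history=list(d["convergence_history"]),
            iteration=d["iteration"],
        )
        if d.get("bandit"):
            state.bandit = BanditState.from_dict(d["bandit"])
        if "model" in d:
            from .kernels import KernelParams

            m = d["model"]
            params = KernelParams(
                theta=np.asarray(m["theta"]), nu=m["nu"], sigma_cat=m["sigma_cat"],
                alpha=m["alpha"], noise_variance=m["noise_variance"],
                signal_variance=m.get("signal_variance", 1.0),
            )
            state.model = GPModel(
                state.training_set(), params, kernel=m["kernel"],
                n_categories=tuple(m["n_categories"]),
                y_mean=m["y_mean"], y_std=m["y_std"],
            )
        return state
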