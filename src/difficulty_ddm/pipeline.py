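"""End-to-end orchestration: behavior summaries, model comparison,
model/parameter recovery, and optimal-policy-vs-fitted-models analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import design_exp1_difficulty, generate_dataset
from .fitting import (
    ComparisonResult,
    exceedance_probabilities,
    fit_difficulty_model,
)
from .models import MODEL_NAMES
from .optimal import simulate_optimal

__all__ = [
    "BehaviorSummary",
    "summarize_behavior",
    "rt_variance_explained",
    "run_model_comparison",
    "run_model_recovery",
    "run_optimal_fit_comparison",
]


@dataclass
class BehaviorSummary:
    """Aggregated difficulty behavior.

    ``by_strength``: per (S1 strength, S2 strength) cell — P(choose S1),
    mean RT, SEM, n.  ``by_delta``: the same collapsed over the unique
    strength differences |C1| - |C2|.  ``by_duration``: per-duration
    accuracy (controlled-duration tables only, equal-strength excluded).
    """

    by_strength: pd.DataFrame
    by_delta: pd.DataFrame
    by_duration: pd.DataFrame | None = None


def summarize_behavior(table: pd.DataFrame) -> BehaviorSummary:
    """Cell means of choices and RTs over the strength design."""
    df = table.copy()
    if "included" in df.columns:
        df = df[df["included"]]
    df = df[df["task"] == "difficulty"]
    df["s1"] = df["c1_signed"].abs().round(6)
    df["s2"] = df["c2_signed"].abs().round(6)
    df["chose_s1"] = (df["choice"] == 1).astype(float)
    df["delta"] = (df["s1"] - df["s2"]).round(6)

    def agg(g):
        out = g.agg(
            p_s1=("chose_s1", "mean"),
            mean_rt=("rt", "mean"),
            sem_rt=("rt", "sem"),
            n=("chose_s1", "size"),
        )
        return out.reset_index()

    by_strength = agg(df.groupby(["s1", "s2"]))
    by_delta = agg(df.groupby("delta"))
    by_duration = None
    if len(df) and df["paradigm"].iloc[0] == "controlled_duration":
        acc = df[df["s1"] != df["s2"]].groupby("duration").agg(
            accuracy=("correct", "mean"), n=("correct", "size")
        )
        by_duration = acc.reset_index()
    return BehaviorSummary(by_strength, by_delta, by_duration)


def rt_variance_explained(table: pd.DataFrame) -> dict:
    """Cell-means variance decomposition of RT.

    R^2 of the model predicting each trial's RT by its |C1|-|C2| cell mean,
    and the increment from predicting by the full (delta, S2-strength)
    cell means.  For a process whose RT depends only on the strength
    difference (the known-color reduction), the increment is ~0.
    """
    df = table.copy()
    if "included" in df.columns:
        df = df[df["included"]]
    df = df[(df["task"] == "difficulty") & df["rt"].notna()]
    s1 = df["c1_signed"].abs().round(6)
    s2 = df["c2_signed"].abs().round(6)
    delta = (s1 - s2).round(6)
    rt = df["rt"].to_numpy()
    if delta.nunique() < 2:
        return {"r2_delta": np.nan, "r2_full": np.nan, "increment": np.nan}
    sst = float(((rt - rt.mean()) ** 2).sum())
    pred_d = df.groupby(delta)["rt"].transform("mean").to_numpy()
    pred_f = df.groupby([delta, s2])["rt"].transform("mean").to_numpy()
    r2_d = 1.0 - float(((rt - pred_d) ** 2).sum()) / sst
    r2_f = 1.0 - float(((rt - pred_f) ** 2).sum()) / sst
    return {"r2_delta": r2_d, "r2_full": r2_f, "increment": r2_f - r2_d}


def run_model_comparison(
    datasets: dict,
    models=MODEL_NAMES,
    rng=None,
    **fit_kwargs,
) -> ComparisonResult:
    """Fit each model to each participant's data and compare.

    ``datasets`` maps participant id -> trial table.  Returns per-cell
    fits, the BIC matrix, per-participant deltas versus the best model,
    group BIC and exceedance probabilities (evidence = -BIC/2).
    """
    if rng is None:
        rng = np.random.default_rng()
    fits = {}
    rows = {}
    for pid, data in datasets.items():
        for m in models:
            fits[(pid, m)] = fit_difficulty_model(m, data, rng=rng, **fit_kwargs)
        rows[pid] = {m: fits[(pid, m)].bic for m in models}
    bic = pd.DataFrame(rows).T[list(models)]
    delta = bic.sub(bic.min(axis=1), axis=0)
    xp, _, freq = exceedance_probabilities(-bic.to_numpy() / 2.0, rng=rng)
    return ComparisonResult(
        models=tuple(models),
        participants=tuple(datasets),
        bic=bic,
        delta_bic=delta,
        group_bic=bic.sum(axis=0),
        frequencies=pd.Series(freq, index=list(models)),
        exceedance=pd.Series(xp, index=list(models)),
        fits=fits,
    )


def run_model_recovery(
    generating_models,
    params,
    n_datasets: int = 5,
    design: pd.DataFrame | None = None,
    fit_models=None,
    seed: int = 0,
    dt: float = 0.005,
    delta_bic_threshold: float = 0.0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Generate datasets from each model and classify them by lowest BIC.

    Returns the confusion matrix (rows: generating model, columns: fitted
    model, entries: classification counts).  ``delta_bic_threshold > 0``
    additionally requires the winner to lead by that margin, leaving
    unclassified datasets in an ``ambiguous`` column.
    """
    if design is None:
        design = design_exp1_difficulty(seed=seed)
    if fit_models is None:
        fit_models = tuple(generating_models)
    rng = np.random.default_rng(seed)
    cols = list(fit_models) + (["ambiguous"] if delta_bic_threshold > 0 else [])
    confusion = pd.DataFrame(
        0, index=list(generating_models), columns=cols, dtype=int
    )
    for gen in generating_models:
        for rep in range(n_datasets):
            data = generate_dataset(
                gen, params, design, seed=int(rng.integers(2**31 - 1)), dt=dt
            )
            bics = {
                m: fit_difficulty_model(m, data, dt=dt, rng=rng, **fit_kwargs).bic
                for m in fit_models
            }
            ranked = sorted(bics, key=bics.get)
            if (
                delta_bic_threshold > 0
                and bics[ranked[1]] - bics[ranked[0]] < delta_bic_threshold
            ):
                confusion.loc[gen, "ambiguous"] += 1
            else:
                confusion.loc[gen, ranked[0]] += 1
    return confusion


def run_optimal_fit_comparison(
    solution,
    n_sim_trials: int = 20_000,
    models=MODEL_NAMES,
    seed: int = 0,
    dt: float = 0.005,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit the difficulty models to optimal-policy simulations.

    Returns a table ranked by BIC (best first) with each model's log
    likelihood and BIC; reproduces the structural question of which
    bounded-accumulation heuristic best mimics the reward-rate-optimal
    agent.
    """
    rng = np.random.default_rng(seed)
    sim = simulate_optimal(solution, n_sim_trials, rng)
    data = pd.DataFrame(
        {
            "c1_signed": sim["c1"],
            "c2_signed": sim["c2"],
            "choice": sim["choice"],
            "rt": sim["rt"],
        }
    )
    rows = []
    for m in models:
        fr = fit_difficulty_model(m, data, dt=dt, rng=rng, **fit_kwargs)
        rows.append({"model": m, "log_lik": fr.log_lik, "bic": fr.bic})
    out = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    out["delta_bic"] = out["bic"] - out["bic"].iloc[0]
    return out
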