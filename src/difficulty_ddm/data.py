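"""Experimental designs, model-generated datasets, and trial-table I/O.

The tidy trial table is the interchange format for every stage: one row
per trial with the design columns (signed coherences, paradigm, color
knowledge, duration) and, once simulated or observed, the behavior columns
(choice, rt, decision_time, terminated_by, correct, feedback).

Designs emulate two experiments: a reaction-time difficulty task over all
12 x 12 signed-coherence pairings (1152 trials: each pair 8 times), and a
second experiment crossing paradigm (reaction time vs controlled duration)
with color knowledge (unknown: 12 x 12; known: same-sign 6 x 6 blocks),
where equal-strength pairs appear at one third the frequency of other
cells and controlled-duration trials draw from six durations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import COHERENCE_STRENGTHS, CollapsingBound, ColorDDMParams
from .models import (
    CONTROLLED_DURATIONS,
    DifficultyParams,
    T_BUFFER,
    controlled_duration_batch,
    simulate_difficulty_batch,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "design_exp1_difficulty",
    "design_exp1_color",
    "design_exp2",
    "generate_dataset",
    "read_trials",
    "write_trials",
    "exp2_analysis_filter",
]

#: Columns every trial table must carry (behavior columns are optional
#: until a dataset is generated).
REQUIRED_COLUMNS = (
    "participant",
    "session",
    "block",
    "task",
    "paradigm",
    "color_knowledge",
    "c1_signed",
)

_BEHAVIOR_COLUMNS = ("choice", "rt", "decision_time", "terminated_by", "correct", "feedback")


def _signed_levels():
    out = []
    for s in COHERENCE_STRENGTHS:
        if s == 0.0:
            out.extend([(0.0, 1), (0.0, -1)])
        else:
            out.extend([(s, 1), (-s, -1)])
    return out  # 12 (value, tag) pairs


def _base_frame(n, participant, task, paradigm, color_knowledge):
    return pd.DataFrame(
        {
            "participant": participant,
            "session": np.ones(n, dtype=int),
            "block": np.zeros(n, dtype=int),
            "task": task,
            "paradigm": paradigm,
            "color_knowledge": color_knowledge,
        }
    )


def design_grid(
    strengths=COHERENCE_STRENGTHS,
    trials_per_pair: int = 8,
    seed: int = 0,
    participant: str = "sim01",
) -> pd.DataFrame:
    """Balanced RT difficulty design over an arbitrary strength set.

    Like the full first-experiment design but over a caller-chosen set of
    strengths (each contributing +/- signed levels); used for scaled-down
    recovery studies.
    """
    levels = []
    for s in strengths:
        if s == 0.0:
            levels.extend([(0.0, 1), (0.0, -1)])
        else:
            levels.extend([(s, 1), (-s, -1)])
    rng = np.random.default_rng(seed)
    rows = [
        (v1, t1, v2, t2) for v1, t1 in levels for v2, t2 in levels
    ] * trials_per_pair
    arr = np.array(rows)[rng.permutation(len(rows))]
    df = _base_frame(len(arr), participant, "difficulty", "rt", "unknown")
    df["c1_signed"] = arr[:, 0]
    df["c1_tag"] = arr[:, 1].astype(int)
    df["c2_signed"] = arr[:, 2]
    df["c2_tag"] = arr[:, 3].astype(int)
    df["block"] = 1
    df["duration"] = np.nan
    return df


def design_exp1_difficulty(
    n_blocks: int = 12,
    trials_per_block: int = 96,
    seed: int = 0,
    participant: str = "sim01",
) -> pd.DataFrame:
    """Reaction-time difficulty design: all 144 signed pairs, balanced.

    The default 12 blocks x 96 trials give each of the 12 x 12 signed
    pairs exactly 8 presentations.  The +/- tag of zero coherence is part
    of the pair (it decides the rewarded response on ties).  Order is
    shuffled per block by ``seed``.
    """
    n_total = n_blocks * trials_per_block
    levels = _signed_levels()
    n_pairs = len(levels) ** 2
    if n_total % n_pairs:
        raise ValueError(
            f"{n_total} trials cannot balance {n_pairs} signed pairs exactly"
        )
    reps = n_total // n_pairs
    rng = np.random.default_rng(seed)
    rows = [(v1, t1, v2, t2) for v1, t1 in levels for v2, t2 in levels] * reps
    arr = np.array(rows)
    order = rng.permutation(n_total)
    arr = arr[order]
    df = _base_frame(n_total, participant, "difficulty", "rt", "unknown")
    df["c1_signed"] = arr[:, 0]
    df["c1_tag"] = arr[:, 1].astype(int)
    df["c2_signed"] = arr[:, 2]
    df["c2_tag"] = arr[:, 3].astype(int)
    df["block"] = np.repeat(np.arange(1, n_blocks + 1), trials_per_block)
    df["session"] = np.where(df["block"] <= 3, 1, 2)
    df["duration"] = np.nan
    return df


def design_exp1_color(
    n_blocks: int = 6, trials_per_block: int = 72, seed: int = 0, participant: str = "sim01"
) -> pd.DataFrame:
    """Single-stimulus color-judgment design: 12 signed levels balanced."""
    n_total = n_blocks * trials_per_block
    levels = _signed_levels()
    if n_total % len(levels):
        raise ValueError("trial count must balance the 12 signed levels")
    rng = np.random.default_rng(seed)
    arr = np.array(levels * (n_total // len(levels)))
    arr = arr[rng.permutation(n_total)]
    df = _base_frame(n_total, participant, "color", "rt", "unknown")
    df["c1_signed"] = arr[:, 0]
    df["c1_tag"] = arr[:, 1].astype(int)
    df["c2_signed"] = np.nan
    df["c2_tag"] = 0
    df["block"] = np.repeat(np.arange(1, n_blocks + 1), trials_per_block)
    df["duration"] = np.nan
    return df


def design_exp2(
    condition: str = "rt",
    color: str = "unknown",
    n_units: int = 1,
    seed: int = 0,
    participant: str = "sim01",
) -> pd.DataFrame:
    """Second-experiment designs with equal-strength down-weighting.

    Unequal-strength cells appear 3 times per unit and equal-strength
    cells once (one-third frequency, exact by construction).  ``unknown``
    uses the full 12 x 12 signed grid (384 trials/unit); ``known``
    restricts to same-sign 6 x 6 pairings (96 trials/unit), split between
    blue- and yellow-dominant blocks.  Controlled-duration designs attach
    the six durations with an exactly uniform marginal.
    """
    if condition not in ("rt", "controlled"):
        raise ValueError("condition must be 'rt' or 'controlled'")
    if color not in ("unknown", "known"):
        raise ValueError("color must be 'unknown' or 'known'")
    rng = np.random.default_rng(seed)
    levels = _signed_levels()

    def unit_pairs(level_subset):
        rows = []
        for v1, t1 in level_subset:
            for v2, t2 in level_subset:
                reps = 1 if abs(v1) == abs(v2) else 3
                rows.extend([(v1, t1, v2, t2)] * reps)
        return rows

    if color == "unknown":
        chunks = [(unit_pairs(levels) * n_units, "unknown")]
    else:
        blue = [(v, t) for v, t in levels if t > 0]
        yellow = [(v, t) for v, t in levels if t < 0]
        chunks = [
            (unit_pairs(blue) * n_units, "known_blue"),
            (unit_pairs(yellow) * n_units, "known_yellow"),
        ]

    frames = []
    for rows, knowledge in chunks:
        arr = np.array(rows)
        n = len(arr)
        if condition == "controlled":
            if n % len(CONTROLLED_DURATIONS):
                raise ValueError("unit size must balance the 6 durations")
            dur = np.tile(CONTROLLED_DURATIONS, n // len(CONTROLLED_DURATIONS))
        else:
            dur = np.full(n, np.nan)
        order = rng.permutation(n)
        df = _base_frame(n, participant, "difficulty", condition, knowledge)
        df["c1_signed"] = arr[order, 0]
        df["c1_tag"] = arr[order, 1].astype(int)
        df["c2_signed"] = arr[order, 2]
        df["c2_tag"] = arr[order, 3].astype(int)
        df["duration"] = dur[rng.permutation(n)] if condition == "controlled" else dur
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    block_size = 96
    out["block"] = np.arange(len(out)) // block_size + 1
    if condition == "controlled":
        out["paradigm"] = "controlled_duration"
    return out


def _designated_correct(choice, c1, c2, rng):
    """Correct = chose the strictly easier stimulus; ties randomly designated."""
    s1 = np.abs(c1)
    s2 = np.abs(c2)
    easier = np.where(s1 > s2, 1, 2)
    tie = s1 == s2
    easier = np.where(tie, rng.integers(1, 3, size=len(c1)), easier)
    return choice == easier


def generate_dataset(
    model: str,
    params,
    design: pd.DataFrame,
    seed: int = 0,
    dt: float = 0.005,
    horizon: float = 5.0,
    t_buf: float = T_BUFFER,
    conf_map=None,
) -> pd.DataFrame:
    """Fill a design with model-generated behavior.

    Dispatches on the design's task/paradigm/color_knowledge: color-task
    rows use the 1D color DDM (``params`` must then be ColorDDMParams;
    choice 1 = blue, 2 = yellow), difficulty rows use the named 2D model
    with the known-color decision rule in known blocks, and
    controlled-duration rows produce choices only.  ``correct`` applies
    the feedback rule: the strictly stronger stimulus is correct, with
    random designation on equal-strength trials.
    """
    rng = np.random.default_rng(seed)
    df = design.copy()
    task = df["task"].iloc[0] if len(df) else "difficulty"
    if task == "color":
        if not isinstance(params, ColorDDMParams):
            raise ValueError("color task requires ColorDDMParams")
        return _generate_color(params, df, rng, dt, horizon)
    if not isinstance(params, DifficultyParams):
        raise ValueError("difficulty task requires DifficultyParams")

    paradigm = df["paradigm"].iloc[0]
    known = df["color_knowledge"].iloc[0] != "unknown"
    c1 = df["c1_signed"].to_numpy(dtype=float)
    c2 = df["c2_signed"].to_numpy(dtype=float)
    tags = (df["c1_tag"].to_numpy(dtype=np.int8), df["c2_tag"].to_numpy(dtype=np.int8))

    if paradigm in ("controlled", "controlled_duration"):
        res = controlled_duration_batch(
            "known_color" if known else "difference",
            params,
            c1,
            c2,
            df["duration"].to_numpy(dtype=float),
            t_buf=t_buf,
            dt=dt,
            rng=rng,
            known_signs=tags if known else None,
        )
        df["choice"] = res["choice"]
        df["decision_time"] = res["decision_time"]
        df["rt"] = np.nan
        df["terminated_by"] = np.where(
            res["terminated_by"] == 0, "bound", "stimulus_offset"
        )
    else:
        model_name = model
        kw = {}
        if known:
            if model == "difference":
                model_name = "known_color"
            elif model == "confidence":
                model_name = "confidence_known"
            else:
                raise ValueError(f"no known-color variant for model {model!r}")
            kw["known_signs"] = tags
        if model_name.startswith("confidence"):
            kw["conf_map"] = conf_map
        res = simulate_difficulty_batch(
            model_name, params, c1, c2, dt=dt, horizon=horizon, rng=rng, **kw
        )
        df["choice"] = res["choice"]
        df["decision_time"] = res["decision_time"]
        df["rt"] = res["rt"]
        df["terminated_by"] = np.where(res["terminated_by"] == 0, "bound", "horizon")
        if "t_mini" in res:
            df["t_mini"] = res["t_mini"]
    df["correct"] = _designated_correct(df["choice"].to_numpy(), c1, c2, rng)
    df["feedback"] = df["correct"]
    return df


def _generate_color(params, df, rng, dt, horizon):
    from .core import simulate_first_passage_batch

    c = df["c1_signed"].to_numpy(dtype=float)
    choice = np.zeros(len(df), dtype=np.int8)
    dtime = np.zeros(len(df))
    term = np.zeros(len(df), dtype=object)
    for value in np.unique(c):
        idx = np.flatnonzero(c == value)
        ch, tt = simulate_first_passage_batch(
            params, value, dt, horizon, rng, idx.size
        )
        # horizon-censored color trials: choice by DV sign unavailable from
        # the batch kernel; resolve randomly (rare for sensible parameters)
        ch = np.where(ch == 0, rng.choice([1, -1], size=idx.size), ch)
        choice[idx] = np.where(ch == 1, 1, 2)
        dtime[idx] = tt
        term[idx] = np.where(tt < horizon, "bound", "horizon")
    tnd = np.maximum(rng.normal(params.tnd_mean, params.tnd_sd, len(df)), 0.0)
    df["choice"] = choice
    df["decision_time"] = dtime
    df["rt"] = dtime + tnd
    df["terminated_by"] = term
    # correct = chose the tagged dominant color (ties broken by the tag)
    dominant = np.where(df["c1_tag"].to_numpy() > 0, 1, 2)
    df["correct"] = df["choice"].to_numpy() == dominant
    df["feedback"] = df["correct"]
    return df


# ---------------------------------------------------------------------------
# I/O and analysis filters
# ---------------------------------------------------------------------------


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as canonical CSV (comma, '.' decimal, header)."""
    table.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Unknown columns are preserved; missing required columns or coherences
    outside [-1, 1] raise a ValueError.  A header-only file is a valid
    empty table.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    for col in ("c1_signed", "c2_signed"):
        if col in df.columns and len(df):
            vals = df[col].to_numpy(dtype=float)
            bad = np.abs(vals[~np.isnan(vals)]) > 1.0
            if bad.any():
                raise ValueError(f"{col} contains coherences outside [-1, 1]")
    return df


def exp2_analysis_filter(table: pd.DataFrame, context: str) -> pd.DataFrame:
    """Flag rows excluded by the second experiment's analysis rules.

    Contexts: ``rt_unknown`` excludes opposite-dominance pairs (so the
    unknown condition is comparable to known-color blocks);
    ``controlled_accuracy`` excludes equal-strength pairs (no objectively
    correct answer).  Rows are flagged via an ``included`` column, never
    deleted; color-task rows are always included.
    """
    if context not in ("rt_unknown", "controlled_accuracy"):
        raise ValueError(f"unknown analysis context {context!r}")
    df = table.copy()
    included = np.ones(len(df), dtype=bool)
    is_difficulty = (df["task"] == "difficulty").to_numpy()
    c1 = df["c1_signed"].to_numpy(dtype=float)
    c2 = df["c2_signed"].to_numpy(dtype=float)
    if context == "rt_unknown":
        t1 = df["c1_tag"].to_numpy() if "c1_tag" in df else np.sign(c1)
        t2 = df["c2_tag"].to_numpy() if "c2_tag" in df else np.sign(c2)
        included &= ~is_difficulty | (t1 == t2)
    else:
        included &= ~is_difficulty | (np.abs(c1) != np.abs(c2))
    df["included"] = included
    return df
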