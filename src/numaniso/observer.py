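"""Synthetic observers: session designs and trial-level response simulation.

The simulator is the analysis model run forward, not a perceptual theory:
responses are the true numerosity plus contrast-coded fixed effects,
participant-level random intercepts and arrangement slopes, an optional
pull toward the block mean, and Gaussian trial noise, rounded half-up and
floored at 1.  Control trials in the subitizing range are answered
correctly with a configurable error rate, and a configurable fraction of
responses is replaced by an invalid (NaN) marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ObserverParams",
    "SessionPlan",
    "EXPERIMENT_TAGS",
    "NUMEROSITY_SETS",
    "reference_numerosities",
    "design_session",
    "simulate_trials",
]

EXPERIMENT_TAGS = ("1a", "1b", "2", "3a", "3b", "4")

#: Main-trial numerosity sets per experiment and range.
NUMEROSITY_SETS: dict[str, dict[str, list[int]]] = {
    "1a": {"small": list(range(34, 45, 2))},
    "1b": {"large": list(range(54, 65, 2))},
    "3a": {"small": list(range(34, 45, 2))},
    "3b": {"large": list(range(54, 65, 2))},
    "2": {
        "small": [51, 54, 57, 60, 63, 69, 72],
        "large": [78, 81, 84, 87, 90, 93, 96, 99],
    },
    "4": {"small": list(range(34, 45, 2)), "large": list(range(54, 65, 2))},
}

N_CONTROL_TRIALS = 30
SUBITIZING_RANGE = (2, 3, 4)

CONTRAST_CODES = {
    "arrangement": {"radial": -0.5, "tangential": 0.5},
    "polarity": {"mixed": -0.5, "uniform": 0.5},
    "numerosity_range": {"small": -0.5, "large": 0.5},
}


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the synthetic observer (units: items)."""

    beta0: float = -2.0
    beta_arr: float = 0.89
    beta_pol: float = 0.0
    beta_num: float = 0.0
    sd_intercept: float = 2.0
    sd_arr_slope: float = 1.0
    resid_sd: float = 4.0
    regression_weight: float = 0.0
    subitizing_error_rate: float = 0.0
    invalid_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sd_intercept", "sd_arr_slope", "resid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("regression_weight", "subitizing_error_rate", "invalid_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SessionPlan:
    """Per-participant trial template plus the reference displays."""

    experiment_tag: str
    trials: pd.DataFrame  # block, arrangement, polarity_scheme, range, true_n, is_control, block_mean
    references: dict[int, list[int]]

    @property
    def n_main(self) -> int:
        return int((~self.trials["is_control"]).sum())

    @property
    def n_control(self) -> int:
        return int(self.trials["is_control"].sum())


def _round_half_up(x: np.ndarray | float) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def reference_numerosities(block_mean: float) -> list[int]:
    """The five reference numerosities for a block: mean and mean * (1 +/- 0.125, 0.25)."""
    factors = (0.75, 0.875, 1.0, 1.125, 1.25)
    return [int(_round_half_up(block_mean * f)) for f in factors]


def _block_rows(
    block: int,
    numerosities: list[int],
    n_trials: int,
    polarity_schemes: list[str],
    num_range: str,
) -> list[dict]:
    """Spread ``n_trials`` over numerosity x arrangement x polarity cells."""
    rows: list[dict] = []
    base, rem = divmod(n_trials, len(numerosities))
    block_mean = float(np.mean(numerosities))
    for i, n in enumerate(numerosities):
        count = base + (1 if i < rem else 0)
        for j in range(count):
            rows.append(
                {
                    "block": block,
                    # alternate arrangement fastest so it crosses the scheme cycle
                    "arrangement": "radial" if j % 2 == 0 else "tangential",
                    "polarity_scheme": polarity_schemes[(j // 2) % len(polarity_schemes)],
                    "numerosity_range": num_range,
                    "true_n": n,
                    "is_control": False,
                    "block_mean": block_mean,
                }
            )
    return rows


def _control_rows(n_control: int) -> list[dict]:
    rows = []
    for i in range(n_control):
        n = SUBITIZING_RANGE[i % len(SUBITIZING_RANGE)]
        rows.append(
            {
                "block": -1,
                "arrangement": "radial" if i % 2 == 0 else "tangential",
                "polarity_scheme": "uniform_dark",
                "numerosity_range": "small",
                "true_n": n,
                "is_control": True,
                "block_mean": float(n),
            }
        )
    return rows


def design_session(experiment_tag: str) -> SessionPlan:
    """Build the per-participant trial plan for one experiment.

    Tags 1a/1b/3a/3b: 300 main trials (6 numerosities x 50) plus 30
    interspersed subitizing control trials.  Tag 2: six 80-trial blocks
    (three per numerosity range).  Tag 4: eight 144-trial blocks (four per
    range) crossing arrangement and polarity within participants.  The
    actual presentation order is randomized per participant at simulation
    time; the plan fixes the trial composition.
    """
    tag = str(experiment_tag)
    if tag not in EXPERIMENT_TAGS:
        raise ValueError(f"unknown experiment tag {tag!r}")
    rows: list[dict] = []
    if tag in ("1a", "1b", "3a", "3b"):
        polarity = ["mixed"] if tag.startswith("3") else ["uniform_dark"]
        (num_range, numerosities), = NUMEROSITY_SETS[tag].items()
        rows += _block_rows(0, numerosities, 50 * len(numerosities), polarity, num_range)
    elif tag == "2":
        block = 0
        for num_range in ("small", "large"):
            for _ in range(3):
                rows += _block_rows(
                    block, NUMEROSITY_SETS["2"][num_range], 80,
                    ["uniform_dark"], num_range,
                )
                block += 1
    else:  # tag == "4"
        schemes = ["mixed", "uniform_dark", "mixed", "uniform_light"]
        block = 0
        for num_range in ("small", "large"):
            for _ in range(4):
                rows += _block_rows(
                    block, NUMEROSITY_SETS["4"][num_range], 144, schemes, num_range
                )
                block += 1
    rows += _control_rows(N_CONTROL_TRIALS)
    trials = pd.DataFrame(rows)
    references = {
        int(b): reference_numerosities(g["block_mean"].iloc[0])
        for b, g in trials[~trials["is_control"]].groupby("block")
    }
    return SessionPlan(tag, trials, references)


def _polarity_code(scheme: pd.Series) -> np.ndarray:
    return np.where(scheme.str.startswith("uniform"), 0.5, -0.5)


def simulate_trials(
    plan: SessionPlan,
    params: ObserverParams,
    n_participants: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate a full dataset of trial records.

    Response model (main trials)::

        response = round(true_n + beta0 + beta_arr * Xarr + beta_pol * Xpol
                         + beta_num * Xnum + u0_j + u1_j * Xarr
                         + w * (block_mean - true_n) + eps)

    with the X's the +/-0.5 contrast codes, participant effects
    u0 ~ N(0, sd_intercept^2), u1 ~ N(0, sd_arr_slope^2), trial noise
    eps ~ N(0, resid_sd^2), and responses floored at 1.  Control trials are
    answered correctly except with probability ``subitizing_error_rate``;
    any response may be replaced by NaN (invalid) with probability
    ``invalid_rate``.  Fully reproducible from ``seed``.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    frames = []
    for j in range(n_participants):
        u0 = rng.normal(0.0, params.sd_intercept) if params.sd_intercept else 0.0
        u1 = rng.normal(0.0, params.sd_arr_slope) if params.sd_arr_slope else 0.0
        t = plan.trials.sample(frac=1.0, random_state=rng).reset_index(drop=True)
        x_arr = t["arrangement"].map(CONTRAST_CODES["arrangement"]).to_numpy()
        x_pol = _polarity_code(t["polarity_scheme"])
        x_num = t["numerosity_range"].map(CONTRAST_CODES["numerosity_range"]).to_numpy()
        true_n = t["true_n"].to_numpy(dtype=float)
        eps = (
            rng.normal(0.0, params.resid_sd, len(t))
            if params.resid_sd
            else np.zeros(len(t))
        )
        main = (
            true_n
            + params.beta0
            + params.beta_arr * x_arr
            + params.beta_pol * x_pol
            + params.beta_num * x_num
            + u0
            + u1 * x_arr
            + params.regression_weight * (t["block_mean"].to_numpy() - true_n)
            + eps
        )
        response = np.maximum(_round_half_up(main), 1.0)

        is_control = t["is_control"].to_numpy()
        if is_control.any():
            n_ctl = int(is_control.sum())
            wrong = rng.uniform(size=n_ctl) < params.subitizing_error_rate
            offset = rng.choice([-1.0, 1.0], size=n_ctl)
            ctl_resp = true_n[is_control] + np.where(wrong, offset, 0.0)
            response[is_control] = np.maximum(ctl_resp, 1.0)

        invalid = rng.uniform(size=len(t)) < params.invalid_rate
        response = np.where(invalid, np.nan, response)

        frame = t.copy()
        frame.insert(0, "participant", j)
        frame.insert(1, "experiment", plan.experiment_tag)
        frame["trial"] = np.arange(len(t))
        frame["response"] = response
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    cols = [
        "participant", "experiment", "block", "trial", "arrangement",
        "polarity_scheme", "numerosity_range", "true_n", "response",
        "is_control", "block_mean",
    ]
    return out[cols]
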