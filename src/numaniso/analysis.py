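"""Inference chain: screening, deviation scores, contrast-coded mixed
models, likelihood-ratio tests, cross-experiment comparisons and
simulation-based power.

The mixed-model solver is statsmodels' MixedLM; this module contributes
the design matrices, contrast coding, screening rules and orchestration.
REML is used for reported estimates, ML whenever two models are compared
by likelihood ratio.  Denominator degrees of freedom are reported as
(number of participants - 1); the df method is recorded on every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .observer import CONTRAST_CODES, ObserverParams, SessionPlan, simulate_trials

__all__ = [
    "FitResult",
    "LRTResult",
    "ScreeningReport",
    "PowerResult",
    "screen_participants",
    "compute_dv",
    "code_contrasts",
    "prepare_trials",
    "fit_lmm",
    "lrt_interaction",
    "compare_experiments",
    "power_simulation",
]

INVALID_THRESHOLD = 0.05  # "more than 5%" is exclusion, exactly 5% is kept
CONTROL_ERROR_THRESHOLD = 0.10  # "10% or more incorrect" is exclusion


@dataclass(frozen=True)
class FitResult:
    """Fixed-effect estimates of one linear mixed model."""

    terms: tuple[str, ...]
    estimates: tuple[float, ...]
    se: tuple[float, ...]
    t: tuple[float, ...]
    df: float
    p: tuple[float, ...]
    log_likelihood: float
    converged: bool
    estimation: str  # "ml" or "reml"
    df_method: str = "participants-1"
    n_groups: int = 0

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.terms.index(term)
        return {
            "estimate": self.estimates[i],
            "se": self.se[i],
            "t": self.t[i],
            "df": self.df,
            "p": self.p[i],
        }


@dataclass(frozen=True)
class LRTResult:
    chi_square: float
    df: int
    p: float


@dataclass(frozen=True)
class ScreeningReport:
    kept: tuple[object, ...]
    excluded: dict[object, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_significant: int
    n_reps: int
    alpha: float


def compute_dv(response: float, true_n: float) -> float:
    """Deviation score: response minus true numerosity (negative =
    underestimation)."""
    if response is None or (isinstance(response, float) and np.isnan(response)):
        raise ValueError("invalid responses must be excluded before computing DV")
    return float(response) - float(true_n)


def code_contrasts(level: str, factor: str) -> float:
    """Simple contrast code of a two-level factor (+/-0.5).

    radial, mixed and small map to -0.5; tangential, uniform and large to
    +0.5.  Uniform polarity schemes of either color count as ``uniform``.
    """
    if factor not in CONTRAST_CODES:
        raise ValueError(f"unknown factor {factor!r}")
    key = "uniform" if factor == "polarity" and str(level).startswith("uniform") else level
    try:
        return CONTRAST_CODES[factor][key]
    except KeyError:
        raise ValueError(f"unknown level {level!r} for factor {factor!r}") from None


def _is_invalid(response: pd.Series) -> pd.Series:
    return pd.to_numeric(response, errors="coerce").isna()


def screen_participants(trials: pd.DataFrame) -> ScreeningReport:
    """Apply the participant-exclusion rules.

    A participant is dropped when the session is incomplete (fewer trials
    than the maximum observed), when strictly more than 5% of responses
    are invalid, or when control-trial accuracy is below 90% correct
    (i.e. 10% or more incorrect).  Screening an already screened table is
    a no-op.
    """
    if trials.empty:
        raise ValueError("empty trial table")
    kept: list = []
    excluded: dict = {}
    expected = trials.groupby("participant").size().max()
    for pid, g in trials.groupby("participant"):
        if len(g) < expected:
            excluded[pid] = "incomplete"
            continue
        n_invalid = int(_is_invalid(g["response"]).sum())
        if n_invalid > INVALID_THRESHOLD * len(g):
            excluded[pid] = "invalid_responses"
            continue
        ctl = g[g["is_control"]]
        if len(ctl):
            valid = pd.to_numeric(ctl["response"], errors="coerce")
            n_wrong = int((valid != ctl["true_n"]).sum())  # NaN counts as wrong
            if n_wrong >= CONTROL_ERROR_THRESHOLD * len(ctl):
                excluded[pid] = "subitizing_fail"
                continue
        kept.append(pid)
    return ScreeningReport(kept=tuple(kept), excluded=excluded)


def prepare_trials(trials: pd.DataFrame, screen: bool = True) -> pd.DataFrame:
    """Screen, drop control/invalid trials, and add dv and contrast codes."""
    t = trials
    if screen:
        report = screen_participants(t)
        t = t[t["participant"].isin(report.kept)]
    t = t[~t["is_control"]]
    t = t[~_is_invalid(t["response"])].copy()
    t["response"] = pd.to_numeric(t["response"])
    t["dv"] = t["response"] - t["true_n"]
    t["x_arr"] = t["arrangement"].map(CONTRAST_CODES["arrangement"])
    t["x_pol"] = [
        code_contrasts(s, "polarity") for s in t["polarity_scheme"]
    ]
    t["x_num"] = t["numerosity_range"].map(CONTRAST_CODES["numerosity_range"])
    return t.reset_index(drop=True)


def fit_lmm(
    data: pd.DataFrame,
    fixed_terms: tuple[str, ...] = ("x_arr",),
    random_spec: str = "intercept+slope",
    outcome: str = "dv",
    estimation: str = "reml",
) -> FitResult:
    """Fit a contrast-coded linear mixed model.

    ``fixed_terms`` name columns of ``data`` (``a:b`` denotes a product
    term); an intercept is always included.  ``random_spec`` is one of
    ``intercept``, ``intercept+slope`` (participant intercept plus
    arrangement slope) or ``intercept+slope+numerosity`` (additionally a
    variance component over tested numerosities).  ``outcome`` is ``dv``
    or ``abs_dv``.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    if data["participant"].nunique() < 2:
        raise ValueError("mixed model needs at least two participants")
    if estimation not in ("ml", "reml"):
        raise ValueError("estimation must be 'ml' or 'reml'")
    if outcome == "abs_dv":
        data = data.assign(abs_dv=data["dv"].abs())
    elif outcome != "dv":
        raise ValueError(f"unknown outcome {outcome!r}")

    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    formula = f"{outcome} ~ {rhs}"
    if random_spec == "intercept":
        re_formula = "~1"
        vc_formula = None
    elif random_spec == "intercept+slope":
        re_formula = "~x_arr"
        vc_formula = None
    elif random_spec == "intercept+slope+numerosity":
        re_formula = "~x_arr"
        vc_formula = {"numerosity": "0 + C(true_n)"}
    else:
        raise ValueError(f"unknown random_spec {random_spec!r}")

    model = MixedLM.from_formula(
        formula,
        data=data,
        groups=data["participant"],
        re_formula=re_formula,
        vc_formula=vc_formula,
    )
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=(estimation == "reml"), method="lbfgs")
        except Exception:
            result = model.fit(reml=(estimation == "reml"))
        # llf and bse are lazy; evaluate inside the suppression context
        llf = float(result.llf)
        k = len(fixed_terms) + 1
        estimates = np.asarray(result.fe_params)[:k]
        se = np.asarray(result.bse_fe)[:k]
    converged = bool(getattr(result, "converged", True))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = estimates / se
    n_groups = int(data["participant"].nunique())
    df = float(n_groups - 1)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    terms = ("intercept",) + tuple(fixed_terms)
    return FitResult(
        terms=terms,
        estimates=tuple(float(x) for x in estimates),
        se=tuple(float(x) for x in se),
        t=tuple(float(x) for x in tvals),
        df=df,
        p=tuple(float(x) for x in pvals),
        log_likelihood=llf,
        converged=converged,
        estimation=estimation,
        n_groups=n_groups,
    )


def lrt_interaction(full: FitResult, reduced: FitResult) -> LRTResult:
    """Likelihood-ratio test between nested ML fits."""
    if full.estimation != "ml" or reduced.estimation != "ml":
        raise ValueError("likelihood-ratio tests require ML fits")
    if not set(reduced.terms) < set(full.terms):
        raise ValueError("reduced model terms must nest within the full model")
    df = len(full.terms) - len(reduced.terms)
    if df < 1:
        raise ValueError("models differ by no fixed-effect terms")
    chi_square = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = float(stats.chi2.sf(chi_square, df))
    return LRTResult(chi_square=chi_square, df=df, p=p)


def _sum_code_experiments(
    data: pd.DataFrame, levels: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    # deviation coding: k-1 columns, last level coded -1 everywhere
    cols = []
    for lev in levels[:-1]:
        col = f"x_exp_{lev}"
        data[col] = np.where(
            data["experiment"] == lev, 1.0,
            np.where(data["experiment"] == levels[-1], -1.0, 0.0),
        )
        cols.append(col)
    return data, cols


def compare_experiments(
    tables: list[pd.DataFrame],
    coding: str = "simple",
    random_spec: str = "intercept+slope",
) -> dict[str, FitResult]:
    """Stack experiments and fit signed-DV and accuracy (|DV|) models.

    ``simple`` coding (two experiments) codes them -0.5/+0.5; ``sum``
    coding compares each experiment against the grand mean.  Participant
    ids must be disjoint across tables.
    """
    if len(tables) < 2:
        raise ValueError("need at least two experiment tables")
    seen: set = set()
    for t in tables:
        pids = set(t["participant"].unique())
        if seen & pids:
            raise ValueError(f"overlapping participant ids: {sorted(seen & pids)}")
        seen |= pids
    data = pd.concat(tables, ignore_index=True)
    levels = list(dict.fromkeys(data["experiment"]))
    if coding == "simple":
        if len(levels) != 2:
            raise ValueError("simple coding requires exactly two experiments")
        data["x_exp"] = np.where(data["experiment"] == levels[0], -0.5, 0.5)
        exp_terms = ["x_exp"]
    elif coding == "sum":
        data, exp_terms = _sum_code_experiments(data, levels)
    else:
        raise ValueError(f"unknown coding {coding!r}")
    fixed = ("x_arr", *exp_terms)
    return {
        outcome: fit_lmm(
            data, fixed_terms=fixed, random_spec=random_spec, outcome=outcome
        )
        for outcome in ("dv", "abs_dv")
    }


def power_simulation(
    params: ObserverParams,
    n_participants: int,
    plan: SessionPlan,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
    random_spec: str = "intercept+slope",
) -> PowerResult:
    """Estimate power of the arrangement test by repeated simulation.

    Each repetition simulates a dataset, fits the experiment's model and
    records whether the arrangement term reaches ``p < alpha``.  Returns
    the significant fraction with an exact (Clopper-Pearson) binomial
    confidence interval.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    n_sig = 0
    for child in children:
        rep_seed = int(child.generate_state(1)[0])
        trials = simulate_trials(plan, params, n_participants, rep_seed)
        data = prepare_trials(trials)
        fit = fit_lmm(data, fixed_terms=("x_arr",), random_spec=random_spec)
        if fit["x_arr"]["p"] < alpha:
            n_sig += 1
    ci = stats.binomtest(n_sig, n_reps).proportion_ci(0.95, method="exact")
    return PowerResult(
        power=n_sig / n_reps,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_significant=n_sig,
        n_reps=n_reps,
        alpha=alpha,
    )
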