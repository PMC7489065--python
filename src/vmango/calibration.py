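"""GLM-based parameterization from simulated (or observed) event tables.

The probability tables driving the automata are estimated process by
process: each stochastic decision taken during development contributes one
row (the four structural/temporal factor levels plus the response) to that
process's event table.  Binomial responses are fitted with logistic GLMs,
counts with (zero-truncated) Poisson regressions, and ordered categorical
responses (burst months, bloom weeks) with cumulative-logit
proportional-odds models.  Explanatory factors are selected by backward
stepwise minimization of the AIC, with ties broken toward the smaller
model, and significant first-order interactions of the selected factors
are added afterwards when they lower the AIC.  Predicted probabilities for
every combination of the selected factors' levels are then tabulated into
:class:`~vmango.parameters.ProbabilityTable` rows ready to drive new
simulations — enabling closed-loop validation: simulate with known tables,
refit, and compare.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.truncated_model import TruncatedLFPoisson
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .architecture import TreeArchitecture
from .parameters import (
    DistributionSpec,
    ProbabilityTable,
    truncated_poisson_rate_for_mean,
)

__all__ = [
    "FACTOR_COLUMNS",
    "FitError",
    "FittedProcess",
    "build_event_table",
    "fit_process",
    "predict_table",
    "fit_all",
]

FACTOR_COLUMNS = (
    "mother_burst_date",
    "mother_position",
    "ancestor_position",
    "ancestor_fate",
)

#: response family of each fittable process
PROCESS_FAMILIES = {
    "vegetative_burst_within": "binomial",
    "vegetative_burst_between": "binomial",
    "has_apical_daughter": "binomial",
    "has_apical_daughter_between": "binomial",
    "has_lateral_daughters": "binomial",
    "has_lateral_daughters_between": "binomial",
    "n_lateral_daughters": "poisson-truncated",
    "n_lateral_daughters_between": "poisson-truncated",
    "burst_month": "ordinal",
    "burst_month_between": "ordinal",
    "is_mixed_inflorescence": "binomial",
    "flowering": "binomial",
    "n_inflorescences": "poisson-truncated",
    "bloom_week": "ordinal",
    "fruiting": "binomial",
    "n_fruits": "poisson-truncated",
}


class FitError(Exception):
    """GLM fitting failed (separation, singularity or non-convergence)."""


def build_event_table(archs: Sequence[TreeArchitecture], process_id: str) -> pd.DataFrame:
    """One row per stochastic decision of ``process_id`` across the trees.

    Eligibility is inherited from the automata: e.g. lateral-count rows
    exist only where the lateral test was positive, so the zero-truncated
    convention holds by construction.
    """
    if process_id not in PROCESS_FAMILIES:
        raise FitError(f"unknown process {process_id!r}")
    rows = []
    for tree_idx, arch in enumerate(archs):
        for d in arch.decisions:
            if d["process"] != process_id:
                continue
            rows.append(
                {
                    "tree": tree_idx,
                    "gu_id": d["gu_id"],
                    "cycle": d["cycle"],
                    "mother_burst_date": d["mother_burst_date"],
                    "mother_position": d["mother_position"],
                    "ancestor_position": d["ancestor_position"],
                    "ancestor_fate": d["ancestor_fate"],
                    "response": d["response"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["tree", "gu_id", "cycle", *FACTOR_COLUMNS, "response"],
    )


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _usable_factors(df: pd.DataFrame, candidates: Sequence[str]) -> list[str]:
    return [f for f in candidates if f in df.columns and df[f].nunique() > 1]


def _levels(df: pd.DataFrame, factors: Sequence[str]) -> dict[str, list]:
    return {f: sorted(df[f].unique(), key=str) for f in factors}


def _design(
    df: pd.DataFrame,
    factors: Sequence[str],
    levels: dict[str, list],
    interactions: Sequence[tuple[str, str]] = (),
    constant: bool = True,
) -> pd.DataFrame:
    cols = {}
    if constant:
        cols["const"] = np.ones(len(df))
    for f in factors:
        for lev in levels[f][1:]:  # reference level dropped
            cols[f"{f}[{lev}]"] = (df[f] == lev).astype(float).to_numpy()
    for fa, fb in interactions:
        for la in levels[fa][1:]:
            for lb in levels[fb][1:]:
                cols[f"{fa}[{la}]:{fb}[{lb}]"] = (
                    ((df[fa] == la) & (df[fb] == lb)).astype(float).to_numpy()
                )
    return pd.DataFrame(cols, index=df.index)


def _fit_one(family: str, y, X: pd.DataFrame):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if family == "binomial":
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            elif family == "poisson":
                res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            elif family == "poisson-truncated":
                res = TruncatedLFPoisson(np.asarray(y), X.to_numpy(), truncation=0).fit(
                    disp=0, maxiter=200
                )
            elif family == "ordinal":
                # OrderedModel wants no explicit constant (absorbed in cuts)
                exog = X.drop(columns=["const"], errors="ignore")
                endog = pd.Categorical(y, ordered=True)
                res = OrderedModel(endog, exog if exog.shape[1] else None, distr="logit").fit(
                    method="bfgs", disp=0, maxiter=300
                )
            else:
                raise FitError(f"unknown family {family!r}")
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise FitError(f"{family} fit failed: {exc}") from exc
    if not np.all(np.isfinite(np.asarray(res.params, dtype=float))):
        raise FitError(f"{family} fit diverged (non-finite coefficients)")
    return res


@dataclass
class FittedProcess:
    process_id: str
    family: str
    selected_factors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]
    levels: dict[str, list]
    result: object
    aic: float
    categories: Optional[list] = None  # ordinal response levels, in order


def fit_process(
    table: pd.DataFrame,
    family: str,
    process_id: str = "",
    factors: Optional[Sequence[str]] = None,
    stepwise: bool = True,
    interactions: bool = True,
) -> FittedProcess:
    """Fit one developmental process and select its factors by AIC.

    Backward stepwise selection starts from the main-effects model with all
    candidate factors; at each step the factor whose removal gives the
    lowest AIC is dropped if that AIC does not exceed the current one (ties
    go to the smaller model).  First-order interactions between the
    surviving factors are then added pair by pair when they strictly lower
    the AIC.  ``stepwise=False`` keeps the supplied factors as is.
    """
    if len(table) == 0:
        raise FitError(f"empty event table for {process_id or family}")
    y = table["response"]
    if family in ("binomial", "ordinal") and y.nunique() < 2:
        raise FitError(f"{process_id or family}: degenerate response ({y.nunique()} level)")
    candidates = list(factors) if factors is not None else list(FACTOR_COLUMNS)
    candidates = _usable_factors(table, candidates)
    levels = _levels(table, candidates)

    endog = y
    if family == "poisson-truncated":
        endog = y.astype(int)

    def fit(fs: Sequence[str], inters: Sequence[tuple[str, str]] = ()):
        X = _design(table, fs, levels, inters)
        res = _fit_one(family, endog, X)
        return res, float(res.aic)

    current = list(candidates)
    res, aic = fit(current)
    if stepwise:
        improved = True
        while improved and current:
            improved = False
            trials = []
            for f in current:
                reduced = [g for g in current if g != f]
                try:
                    r, a = fit(reduced)
                except FitError:
                    continue
                trials.append((a, f, r))
            if trials:
                trials.sort(key=lambda t: (t[0], t[1]))
                best_aic, best_f, best_res = trials[0]
                if best_aic <= aic:  # ties favour the smaller model
                    current = [g for g in current if g != best_f]
                    res, aic = best_res, best_aic
                    improved = True

    chosen_inters: list[tuple[str, str]] = []
    if interactions and len(current) >= 2:
        for fa, fb in itertools.combinations(current, 2):
            try:
                r, a = fit(current, chosen_inters + [(fa, fb)])
            except FitError:
                continue
            if a < aic:
                chosen_inters.append((fa, fb))
                res, aic = r, a

    categories = None
    if family == "ordinal":
        categories = sorted(y.unique())
    return FittedProcess(
        process_id=process_id,
        family=family,
        selected_factors=tuple(current),
        interactions=tuple(chosen_inters),
        levels={f: levels[f] for f in current},
        result=res,
        aic=aic,
        categories=categories,
    )


# ---------------------------------------------------------------------------
# Prediction back into probability tables
# ---------------------------------------------------------------------------

def predict_table(fit: FittedProcess) -> ProbabilityTable:
    """Predicted probabilities for every combination of the selected
    factors' levels, tabulated as a probability table."""
    factors = fit.selected_factors
    combos = list(itertools.product(*(fit.levels[f] for f in factors))) or [()]
    rows = {}
    for combo in combos:
        point = pd.DataFrame({f: [v] for f, v in zip(factors, combo)}, index=[0])
        X = _design(point, factors, fit.levels, fit.interactions)
        if fit.family == "binomial":
            p = float(fit.result.predict(X)[0])
            spec = DistributionSpec("bernoulli", {"p": min(max(p, 0.0), 1.0)})
        elif fit.family == "poisson-truncated":
            mean = float(
                np.atleast_1d(fit.result.predict(X.to_numpy(), which="mean"))[0]
            )
            spec = DistributionSpec(
                "poisson-truncated", {"rate": truncated_poisson_rate_for_mean(max(mean, 1.0))}
            )
        elif fit.family == "poisson":
            mean = float(fit.result.predict(X)[0])
            spec = DistributionSpec(
                "poisson-truncated", {"rate": truncated_poisson_rate_for_mean(max(mean, 1.0))}
            )
        elif fit.family == "ordinal":
            exog = X.drop(columns=["const"], errors="ignore")
            probs = np.asarray(
                fit.result.model.predict(fit.result.params,
                                         exog=exog.to_numpy() if exog.shape[1] else None)
            ).ravel()
            probs = probs / probs.sum()
            spec = DistributionSpec(
                "ordinal-multinomial",
                {"categories": list(fit.categories), "probs": probs.tolist()},
            )
        else:
            raise FitError(f"unknown family {fit.family!r}")
        rows[tuple(combo)] = spec
    return ProbabilityTable(fit.process_id, factors, rows)


def fit_all(
    archs: Sequence[TreeArchitecture],
    processes: Optional[Sequence[str]] = None,
    stepwise: bool = True,
) -> dict[str, ProbabilityTable]:
    """Fit every (requested) process observed in the trees' decision logs
    and return the recovered probability tables."""
    out = {}
    for pid in processes or PROCESS_FAMILIES:
        df = build_event_table(archs, pid)
        if df.empty:
            continue
        try:
            fitted = fit_process(df, PROCESS_FAMILIES[pid], process_id=pid, stepwise=stepwise)
        except FitError:
            continue
        out[pid] = predict_table(fitted)
    return out
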