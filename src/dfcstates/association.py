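"""Mixed-effects brain-behavior association with FDR control.

For every (state, score) pair the fractional rate is modeled as

    occ_state ~ score + age + gender + race + height + weight
                + (1 | site) + (1 | family-within-site)

fit by REML.  The score coefficient's t-statistic is converted to an
effect-size correlation r = t / sqrt(t^2 + df) and Cohen's d = 2t / sqrt(df)
with df = n - (number of fixed effects).  p-values from a screen over
all (state, score) cells are corrected by Benjamini-Hochberg FDR in one
global family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io import BehaviorTable
from .states import OccupancyTable

DEFAULT_COVARIATES = ("age", "gender", "race", "height", "weight")


@dataclass
class AssocResult:
    state: int
    score: str
    beta: float
    t: float
    df: float
    p: float
    r: float
    cohens_d: float
    n: int
    q: float = np.nan
    singular_fallback: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("state", "score", "beta", "t", "df", "p", "r",
                 "cohens_d", "q", "n", "singular_fallback")}


def effect_sizes(t: float, df: float) -> Tuple[float, float]:
    """Correlation and Cohen's d implied by a t-statistic at df."""
    r = t / np.sqrt(t * t + df)
    d = 2.0 * t / np.sqrt(df)
    return float(r), float(d)


def _merged_frame(occ: OccupancyTable, behavior: BehaviorTable, state: int,
                  score: str, covariates: Sequence[str]) -> pd.DataFrame:
    col = f"state_{state}"
    if col not in occ.per_subject.columns:
        raise ValueError(f"no occupancy column {col}")
    df = behavior.table.merge(
        occ.per_subject[[col]].rename(columns={col: "occ"}),
        left_on="subject_id", right_index=True, how="inner")
    needed = ["occ", score, "site_id", "family_id", *covariates]
    return df.dropna(subset=[c for c in needed if c in df.columns])


def _formula(score: str, covariates: Sequence[str]) -> Tuple[str, int]:
    terms, n_fixed = [], 2   # intercept + score
    for c in covariates:
        if c in ("gender", "race"):
            terms.append(f"C({c})")
        else:
            terms.append(c)
    return "occ ~ " + " + ".join([score] + terms), n_fixed


def fit_state_score_lmm(occ: OccupancyTable, behavior: BehaviorTable,
                        state: int, score: str,
                        covariates: Sequence[str] = DEFAULT_COVARIATES,
                        reml: bool = True) -> AssocResult:
    """Mixed model for one (state, score) cell.

    Random intercepts for site and for family nested within site; if the
    nested fit is singular or fails to converge, falls back to a
    site-only random intercept and flags the result.
    """
    data = _merged_frame(occ, behavior, state, score, covariates)
    n = len(data)
    if n < 30:
        raise ValueError(f"only {n} complete cases for state {state}/{score}")
    data = data.copy()
    for c in ("site_id", "family_id"):
        data[c] = data[c].astype(str)
    formula, _ = _formula(score, covariates)

    def _fit(vc: Optional[dict]):
        model = smf.mixedlm(formula, data=data, groups=data["site_id"],
                            re_formula="1", vc_formula=vc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            return model.fit(reml=reml, method="lbfgs", maxiter=200)

    fallback = False
    try:
        fit = _fit({"family": "0 + C(family_id)"})
        if not np.isfinite(fit.tvalues.get(score, np.nan)):
            raise ValueError("non-finite score t-value")
    except Exception:
        fallback = True
        fit = _fit(None)

    beta = float(fit.params[score])
    t = float(fit.tvalues[score])
    n_fixed = len(fit.fe_params)
    dof = float(n - n_fixed)
    p = 2.0 * _sf_t(abs(t), dof)
    r, d = effect_sizes(t, dof)
    return AssocResult(state=state, score=score, beta=beta, t=t, df=dof,
                       p=p, r=r, cohens_d=d, n=n,
                       singular_fallback=fallback)


def _sf_t(x: float, df: float) -> float:
    from scipy.stats import t as t_dist
    return float(t_dist.sf(x, df))


def fdr_bh(p_values: Sequence[float], q: float = 0.05
           ) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, q_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, q_adj


def association_screen(occ: OccupancyTable, behavior: BehaviorTable,
                       score_set: Optional[Sequence[str]] = None,
                       states: Optional[Sequence[int]] = None,
                       covariates: Sequence[str] = DEFAULT_COVARIATES,
                       fdr_q: float = 0.05, fdr_scope: str = "global",
                       reml: bool = True) -> pd.DataFrame:
    """Run the mixed model for every (state, score) cell and FDR-correct.

    ``fdr_scope`` is "global" (one family over all cells, default) or
    "per_state".  Failed cells are kept with NaN statistics so a screen
    never silently drops a comparison.
    """
    if score_set is None:
        score_set = behavior.score_columns
    if states is None:
        states = range(occ.K)
    results: List[AssocResult] = []
    for state in states:
        for score in score_set:
            try:
                results.append(fit_state_score_lmm(
                    occ, behavior, state, score, covariates, reml=reml))
            except Exception:
                results.append(AssocResult(state=state, score=score,
                                           beta=np.nan, t=np.nan, df=np.nan,
                                           p=np.nan, r=np.nan,
                                           cohens_d=np.nan, n=0))
    table = pd.DataFrame([res.as_dict() for res in results])
    ok = table["p"].notna()
    table["q"] = np.nan
    if fdr_scope == "global":
        if ok.any():
            _, q_adj = fdr_bh(table.loc[ok, "p"], fdr_q)
            table.loc[ok, "q"] = q_adj
    elif fdr_scope == "per_state":
        for state, grp in table[ok].groupby("state"):
            _, q_adj = fdr_bh(grp["p"], fdr_q)
            table.loc[grp.index, "q"] = q_adj
    else:
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    return table.sort_values(["q", "p"]).reset_index(drop=True)
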