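"""Normal linear mixed models over network measures, with AICc selection.

The modelling stage compares individual network measures across deprivation
classes while controlling for sex and age class and absorbing between-group
differences in a random intercept.  The full fixed structure is

    measure ~ age_class + sex + deprivation_class + sex:deprivation_class
              + (1 | group)

fitted as a normal linear mixed model (identity link) by maximum likelihood,
so that fixed structures can be compared by the small-sample corrected AIC

    AICc = -2 logLik + 2k + 2k(k+1) / (n - k - 1),

with k counting the fixed-effect columns plus the two variance parameters.
Backward selection repeatedly removes the single term whose removal lowers
the AICc most, never removing a main effect while its interaction remains
(marginality), and stops when no removal lowers the AICc.

Per-term tests are marginal (type-III-style) Wald F tests on a sum-to-zero
coded design; the denominator df is the residual df, n - rank(X).  Aliased
columns (empty cells) are dropped, which reduces the affected term's
numerator df accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "DEFAULT_TERMS",
    "aicc",
    "check_marginality",
    "NetworkMeasureLMM",
    "NetworkMeasureLMMResults",
    "SelectionStep",
    "backward_select",
]

DEFAULT_TERMS = ("age_class", "sex", "deprivation_class", "sex:deprivation_class")

_TERM_FORMULA = {
    "age_class": "C(age_class, Sum)",
    "sex": "C(sex, Sum)",
    "deprivation_class": "C(deprivation_class, Sum)",
    "sex:deprivation_class": "C(sex, Sum):C(deprivation_class, Sum)",
}

_PERFECT_FIT_RTOL = 1e-12


def term_order(term: str) -> int:
    return term.count(":")


def check_marginality(terms: Sequence[str]) -> None:
    """Every interaction must be accompanied by both of its main effects."""
    present = set(terms)
    for t in terms:
        if ":" not in t:
            continue
        for component in t.split(":"):
            if component not in present:
                raise ValueError(
                    f"term {t!r} requires its main effect {component!r} (marginality)"
                )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n = {n} <= k + 1 = {k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _independent_columns(x: np.ndarray) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns."""
    keep: list[int] = []
    for j in range(x.shape[1]):
        trial = x[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return keep


class NetworkMeasureLMM:
    """Linear mixed model for one network measure.

    Parameters
    ----------
    data : DataFrame with the response, the fixed-term covariates and the
        grouping column; rows with a missing response are dropped.
    response : name of the measure column (e.g. ``strength_centrality``).
    fixed_terms : ordered fixed terms drawn from ``DEFAULT_TERMS``.
    groups : column defining the random-intercept grouping (``group_id`` by
        default; pass a group-size column to group by size instead).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        fixed_terms: Sequence[str] = DEFAULT_TERMS,
        groups: str = "group_id",
    ) -> None:
        for t in fixed_terms:
            if t not in _TERM_FORMULA:
                raise ValueError(f"unknown fixed term {t!r}")
        check_marginality(fixed_terms)
        df = data.dropna(subset=[response]).reset_index(drop=True)
        if df[groups].nunique() < 2:
            raise ValueError("random intercept needs >= 2 groups")
        self.data = df
        self.response = response
        self.fixed_terms = tuple(fixed_terms)
        self.groups = groups

        rhs = " + ".join(["1"] + [_TERM_FORMULA[t] for t in fixed_terms])
        design = patsy.dmatrix(rhs, df, return_type="dataframe")
        x = design.to_numpy()
        keep = _independent_columns(x)
        self.exog = x[:, keep]
        self.exog_names = [design.columns[j] for j in keep]
        self.endog = df[response].to_numpy(dtype=float)
        self.group_labels = df[groups].to_numpy()

        info = design.design_info
        self._term_columns: dict[str, list[int]] = {}
        rev = {v: k for k, v in _TERM_FORMULA.items()}
        for term_name, sl in info.term_name_slices.items():
            canonical = rev.get(term_name, "Intercept" if term_name == "Intercept" else term_name)
            cols = [keep.index(j) for j in range(*sl.indices(x.shape[1])) if j in keep]
            self._term_columns[canonical] = cols

    @property
    def nobs(self) -> int:
        return len(self.endog)

    @property
    def k_fe(self) -> int:
        return self.exog.shape[1]

    @property
    def k(self) -> int:
        """AICc parameter count: fixed effects + group variance + residual variance."""
        return self.k_fe + 2

    def fit(self, reml: bool = False) -> "NetworkMeasureLMMResults":
        """Fit by ML (default) or REML; never raises on a singular fit."""
        n, k = self.nobs, self.k
        if n <= k + 1:
            raise ValueError(f"n = {n} too small for k = {k} parameters (AICc undefined)")

        beta, res, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
        fitted = self.exog @ beta
        ssr = float(np.sum((self.endog - fitted) ** 2))
        scale0 = max(float(np.var(self.endog)), 1.0)
        if ssr <= _PERFECT_FIT_RTOL * scale0 * n:
            # response is an exact linear function of the design (or constant)
            return NetworkMeasureLMMResults(
                model=self,
                params=pd.Series(beta, index=self.exog_names),
                cov_fe=np.zeros((self.k_fe, self.k_fe)),
                scale=ssr / n,
                group_var=0.0,
                llf=np.inf,
                method="REML" if reml else "ML",
                converged=True,
                singular=True,
                perfect_fit=True,
            )

        singular = False
        converged = True
        fit = None
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for method in (None, "powell", "nm"):
                try:
                    model = sm.MixedLM(self.endog, self.exog, groups=self.group_labels)
                    trial = model.fit(reml=reml, method=method)
                except np.linalg.LinAlgError:
                    continue
                if np.isfinite(trial.llf):
                    fit = trial
                    break
            if fit is not None:
                params = pd.Series(fit.fe_params, index=self.exog_names)
                cov_fe = np.asarray(fit.cov_params())[: self.k_fe, : self.k_fe]
                scale = float(fit.scale)
                group_var = float(np.asarray(fit.cov_re).ravel()[0])
                llf = float(fit.llf)
                converged = bool(fit.converged)
            else:
                # group variance on the zero boundary: fall back to the
                # boundary solution, which is the ordinary ML linear fit
                ols = sm.OLS(self.endog, self.exog).fit()
                params = pd.Series(ols.params, index=self.exog_names)
                cov_fe = np.asarray(ols.cov_params())
                scale = ssr / (n - self.k_fe)
                group_var = 0.0
                llf = float(ols.llf)
                singular = True
            messages = " | ".join(str(w.message) for w in caught)
        if "singular" in messages.lower() or "boundary" in messages.lower():
            singular = True
        if "failed to converge" in messages.lower():
            converged = False

        return NetworkMeasureLMMResults(
            model=self,
            params=params,
            cov_fe=cov_fe,
            scale=scale,
            group_var=group_var,
            llf=llf,
            method="REML" if reml else "ML",
            converged=converged,
            singular=singular,
        )


@dataclass
class NetworkMeasureLMMResults:
    """Estimates, uncertainty, per-term F tests and AICc for one fit."""

    model: NetworkMeasureLMM
    params: pd.Series
    cov_fe: np.ndarray = field(repr=False)
    scale: float  # residual variance
    group_var: float  # random-intercept variance
    llf: float
    method: str
    converged: bool
    singular: bool
    perfect_fit: bool = False

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def aicc(self) -> float:
        if not np.isfinite(self.llf):
            return -np.inf  # a perfect fit dominates every candidate
        return aicc(self.llf, self.model.k, self.nobs)

    @property
    def resid_df(self) -> int:
        return self.nobs - self.model.k_fe

    def f_test_terms(self, include_intercept: bool = True) -> pd.DataFrame:
        """Marginal Wald F test per fixed term (type-III-style)."""
        rows = []
        terms = (["Intercept"] if include_intercept else []) + list(self.model.fixed_terms)
        for term in terms:
            cols = self.model._term_columns.get(term, [])
            if not cols:
                continue
            b = self.params.iloc[cols].to_numpy()
            if self.perfect_fit:
                degenerate_zero = bool(np.all(np.abs(b) < 1e-10))
                f_val = 0.0 if degenerate_zero else np.inf
                p = 1.0 if degenerate_zero else 0.0
            else:
                v = self.cov_fe[np.ix_(cols, cols)]
                try:
                    f_val = float(b @ np.linalg.solve(v, b)) / len(cols)
                except np.linalg.LinAlgError:
                    f_val = np.nan
                p = float(stats.f.sf(f_val, len(cols), self.resid_df))
            rows.append(
                {"term": term, "F": f_val, "df1": len(cols),
                 "df2": self.resid_df, "p": p}
            )
        return pd.DataFrame(rows, columns=["term", "F", "df1", "df2", "p"])

    def summary(self) -> str:
        """Human-readable report: fit info, per-term F table, coefficients."""
        lines = [
            "Linear mixed model for network measure"
            f" ({self.model.response}, {self.method})",
            "=" * 66,
            f"n = {self.nobs}   groups = {pd.unique(self.model.group_labels).size}"
            f"   k = {self.model.k}",
            f"logLik = {self.llf:.3f}   AICc = {self.aicc:.3f}"
            if np.isfinite(self.llf)
            else "logLik = inf (perfect fit)",
            f"residual var = {self.scale:.5g}   group var = {self.group_var:.5g}",
            f"converged = {self.converged}   singular = {self.singular}",
            "-" * 66,
            "Fixed-effect tests (marginal F):",
            self.f_test_terms().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "-" * 66,
            "Coefficients (sum-to-zero coding):",
            self.params.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class SelectionStep:
    """One step of the backward search: candidate AICc's and the decision."""

    step: int
    terms: tuple[str, ...]
    aicc: float
    candidates: Mapping[str, float]
    dropped: str | None


def _droppable(terms: Sequence[str]) -> list[str]:
    """Terms not protected by a retained higher-order interaction."""
    protected: set[str] = set()
    for t in terms:
        if ":" in t:
            protected.update(t.split(":"))
    return [t for t in terms if t not in protected or ":" in t]


def backward_select(
    data: pd.DataFrame,
    response: str,
    full_terms: Sequence[str] = DEFAULT_TERMS,
    groups: str = "group_id",
) -> tuple[NetworkMeasureLMMResults, list[SelectionStep]]:
    """Backward stepwise reduction of the fixed structure by AICc.

    At each step every droppable term (interactions before the main effects
    they protect) is removed in turn; the removal that lowers the AICc most
    is applied.  Ties break toward the higher-order term, then
    alphabetically.  The ledger records every candidate AICc at every step.
    """
    current = tuple(full_terms)
    best = NetworkMeasureLMM(data, response, current, groups).fit(reml=False)
    ledger: list[SelectionStep] = []
    step = 0
    while True:
        candidates: dict[str, float] = {}
        fits: dict[str, NetworkMeasureLMMResults] = {}
        for t in _droppable(current):
            reduced = tuple(x for x in current if x != t)
            fits[t] = NetworkMeasureLMM(data, response, reduced, groups).fit(reml=False)
            candidates[t] = fits[t].aicc
        choice = None
        if candidates:
            choice = min(
                candidates, key=lambda t: (candidates[t], -term_order(t), t)
            )
            if candidates[choice] >= best.aicc:
                choice = None
        ledger.append(
            SelectionStep(
                step=step,
                terms=current,
                aicc=best.aicc,
                candidates=dict(candidates),
                dropped=choice,
            )
        )
        if choice is None:
            return best, ledger
        current = tuple(x for x in current if x != choice)
        best = fits[choice]
        step += 1
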