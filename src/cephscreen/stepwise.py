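"""Stepwise multiple linear regression with probability-of-F entry/removal.

``StepwiseOLS`` follows the classic bidirectional selection used by legacy
statistics packages: at each step the candidate with the smallest
probability-of-F-to-enter is added if that probability is below ``p_enter``
(default 0.05); any included term whose probability-of-F-to-remove rises
above ``p_remove`` (default 0.10) is then dropped. For a single term the
partial F equals the squared t statistic of its coefficient, so the
probabilities are computed from coefficient t-tests in the augmented model.
Entry ties break toward the larger partial F, then lexicographically, making
the procedure fully deterministic.

The inner least-squares solver is ordinary least squares with an intercept
(statsmodels). Rows with a missing value in the response or any candidate
are dropped up front (complete-case analysis on the candidate union).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import CollinearityError, CycleError, SchemaError


def fit_ols(X: pd.DataFrame, y) -> sm.regression.linear_model.RegressionResultsWrapper:
    """OLS with intercept; raises :class:`CollinearityError` naming the first
    column that is exactly collinear with the preceding ones (tolerance 1e-8
    on the scaled design)."""
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise SchemaError(f"need n > p + 1 observations, got n={X.shape[0]}, p={X.shape[1]}")
    design = sm.add_constant(X.astype(float), has_constant="add")
    arr = design.to_numpy()
    scale = np.linalg.norm(arr, axis=0)
    scale[scale == 0] = 1.0
    r = np.linalg.qr(arr / scale, mode="r")
    small = np.abs(np.diag(r)) < 1e-8
    if small.any():
        raise CollinearityError(str(design.columns[int(np.argmax(small))]))
    return sm.OLS(y, design).fit()


@dataclass
class StepEvent:
    """One entry or removal in the selection log."""

    action: str       # "enter" or "remove"
    term: str
    p_value: float
    partial_f: float


@dataclass
class StepwiseResults:
    """Fitted stepwise model: selected terms, coefficients and diagnostics."""

    response: str
    selected: list[str]
    params: pd.Series            # raw coefficients B, incl. "const"
    bse: pd.Series               # standard errors
    tvalues: pd.Series
    pvalues: pd.Series
    beta: pd.Series              # standardized coefficients (no intercept)
    rsquared: float
    rsquared_adj: float
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    nobs: int
    log: list[StepEvent] = field(default_factory=list)

    def predict(self, row) -> float | np.ndarray:
        """Evaluate intercept + sum(B_j * x_j) on a mapping or DataFrame."""
        if isinstance(row, pd.DataFrame):
            missing = [t for t in self.selected if t not in row.columns]
            if missing:
                raise SchemaError(f"missing predictors: {missing}")
            out = np.full(len(row), self.params["const"], dtype=float)
            for t in self.selected:
                out += self.params[t] * row[t].to_numpy(dtype=float)
            return out
        missing = [t for t in self.selected if t not in row]
        if missing:
            raise SchemaError(f"missing predictors: {missing}")
        return float(self.params["const"]
                     + sum(self.params[t] * float(row[t]) for t in self.selected))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": "const", "B": self.params["const"],
                 "SE": self.bse["const"], "beta": np.nan,
                 "t": self.tvalues["const"], "p": self.pvalues["const"]}]
        for t in self.selected:
            rows.append({"term": t, "B": self.params[t], "SE": self.bse[t],
                         "beta": self.beta[t], "t": self.tvalues[t],
                         "p": self.pvalues[t]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Stepwise OLS: {self.response} ~ {' + '.join(self.selected) or '1'}",
            f"n = {self.nobs}, R^2 = {self.rsquared:.3f}, "
            f"R^2_adj = {self.rsquared_adj:.3f}, "
            f"F({self.df_model}, {self.df_resid}) = {self.fvalue:.3f} "
            f"(p = {self.f_pvalue:.3g})",
            self.to_frame().to_string(index=False, float_format="%.4f"),
            "selection log: " + "; ".join(
                f"{e.action} {e.term} (p={e.p_value:.3g})" for e in self.log),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "selected": list(self.selected),
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "beta": {k: float(v) for k, v in self.beta.items()},
            "rsquared": self.rsquared,
            "rsquared_adj": self.rsquared_adj,
            "fvalue": self.fvalue,
            "f_pvalue": self.f_pvalue,
            "nobs": self.nobs,
            "log": [[e.action, e.term, e.p_value] for e in self.log],
        }


class StepwiseOLS:
    """Model object for stepwise selection over a candidate pool.

    Parameters
    ----------
    endog
        Response vector.
    exog_candidates
        DataFrame of candidate predictors (no intercept column).
    p_enter, p_remove
        Probability-of-F thresholds; ``p_enter`` must be < ``p_remove``.
    """

    def __init__(self, endog, exog_candidates: pd.DataFrame,
                 p_enter: float = 0.05, p_remove: float = 0.10,
                 response_name: str = "y"):
        if not p_enter < p_remove:
            raise ValueError(f"p_enter ({p_enter}) must be < p_remove ({p_remove})")
        if exog_candidates.shape[1] == 0:
            raise ValueError("candidate set is empty")
        y = pd.Series(np.asarray(endog, dtype=float))
        X = exog_candidates.reset_index(drop=True).astype(float)
        keep = y.notna() & X.notna().all(axis=1)
        self.endog = y[keep].to_numpy()
        self.exog = X[keep].reset_index(drop=True)
        self.p_enter = float(p_enter)
        self.p_remove = float(p_remove)
        self.response_name = response_name

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str,
                       candidates: list[str], **kwargs) -> "StepwiseOLS":
        missing = [c for c in [response, *candidates] if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        return cls(df[response], df[list(candidates)],
                   response_name=response, **kwargs)

    # -- selection machinery -------------------------------------------------

    def _entry_scan(self, selected: list[str]) -> list[tuple[float, float, str]]:
        """(p, -partial_F, name) for every addable candidate.

        All candidates are residualised against [1, X_selected] in one QR
        pass; the partial-correlation t statistic equals the coefficient
        t-test of the candidate in the augmented model, so the p-values are
        exactly the probability-of-F-to-enter.
        """
        n = self.endog.size
        base = np.column_stack(
            [np.ones(n)] + [self.exog[t].to_numpy() for t in selected])
        q, _ = np.linalg.qr(base)
        ry = self.endog - q @ (q.T @ self.endog)
        df = n - len(selected) - 2
        if df < 1 or float(ry @ ry) <= 0:
            return []
        scored = []
        remaining = [t for t in self.exog.columns if t not in selected]
        if not remaining:
            return []
        xc = self.exog[remaining].to_numpy()
        ex = xc - q @ (q.T @ xc)
        norms = np.linalg.norm(ex, axis=0)
        scale = np.linalg.norm(xc, axis=0)
        scale[scale == 0] = 1.0
        ry_norm = float(np.sqrt(ry @ ry))
        for j, term in enumerate(remaining):
            if norms[j] <= 1e-8 * scale[j]:
                continue  # collinear with the current model
            r_part = float(ex[:, j] @ ry) / (norms[j] * ry_norm)
            r_part = float(np.clip(r_part, -1.0, 1.0))
            if abs(r_part) >= 1.0:
                scored.append((0.0, -np.inf, term))
                continue
            t = r_part * np.sqrt(df / (1.0 - r_part**2))
            p = float(2 * sps.t.sf(abs(t), df))
            scored.append((p, -t * t, term))
        return scored

    def fit(self) -> StepwiseResults:
        selected: list[str] = []
        log: list[StepEvent] = []
        max_steps = 2 * self.exog.shape[1]
        for _ in range(max_steps):
            # entry: smallest p-of-F-to-enter below the threshold
            scored = self._entry_scan(selected)
            acted = False
            if scored:
                p, neg_f, term = min(scored)
                if p < self.p_enter:
                    selected.append(term)
                    log.append(StepEvent("enter", term, p, -neg_f))
                    acted = True
            # removal: any included term with p-of-F-to-remove above threshold
            while selected:
                res = fit_ols(self.exog[selected], self.endog)
                pvals = res.pvalues[selected]
                worst = pvals.idxmax()
                if float(pvals[worst]) > self.p_remove:
                    selected.remove(worst)
                    t = float(res.tvalues[worst])
                    log.append(StepEvent("remove", worst, float(pvals[worst]), t * t))
                    acted = True
                else:
                    break
            if not acted:
                break
        else:
            raise CycleError(
                f"stepwise selection did not settle within {max_steps} steps")
        return self._results(selected, log)

    def _results(self, selected: list[str], log: list[StepEvent]) -> StepwiseResults:
        y = self.endog
        if selected:
            res = fit_ols(self.exog[selected], y)
            params = res.params
            bse, tv, pv = res.bse, res.tvalues, res.pvalues
            sd_y = float(np.std(y, ddof=1))
            beta = pd.Series({t: float(params[t])
                              * float(np.std(self.exog[t], ddof=1)) / sd_y
                              for t in selected})
            return StepwiseResults(
                response=self.response_name, selected=list(selected),
                params=params, bse=bse, tvalues=tv, pvalues=pv, beta=beta,
                rsquared=float(res.rsquared),
                rsquared_adj=float(res.rsquared_adj),
                fvalue=float(res.fvalue), f_pvalue=float(res.f_pvalue),
                df_model=int(res.df_model), df_resid=int(res.df_resid),
                nobs=int(res.nobs), log=log,
            )
        # intercept-only model
        n = y.size
        mean = float(np.mean(y))
        se = float(np.std(y, ddof=1) / np.sqrt(n))
        t = mean / se if se > 0 else np.inf
        p = 2 * sps.t.sf(abs(t), n - 1) if np.isfinite(t) else 0.0
        zero = pd.Series(dtype=float)
        return StepwiseResults(
            response=self.response_name, selected=[],
            params=pd.Series({"const": mean}),
            bse=pd.Series({"const": se}),
            tvalues=pd.Series({"const": t}),
            pvalues=pd.Series({"const": p}),
            beta=zero, rsquared=0.0, rsquared_adj=0.0,
            fvalue=np.nan, f_pvalue=np.nan,
            df_model=0, df_resid=n - 1, nobs=n, log=log,
        )


def stepwise_fit(candidates: pd.DataFrame, y, p_enter: float = 0.05,
                 p_remove: float = 0.10, response_name: str = "y") -> StepwiseResults:
    """Functional wrapper around :class:`StepwiseOLS`."""
    return StepwiseOLS(y, candidates, p_enter=p_enter, p_remove=p_remove,
                       response_name=response_name).fit()


def predict(model: StepwiseResults, row) -> float | np.ndarray:
    """Evaluate a fitted (or published) stepwise model on one case."""
    return model.predict(row)


def results_from_coefficients(response: str, coefficients: dict[str, float]) -> StepwiseResults:
    """Wrap published coefficients (incl. ``"const"``) as a StepwiseResults
    usable with :func:`predict`; uncertainty fields are NaN."""
    selected = [k for k in coefficients if k != "const"]
    params = pd.Series(coefficients, dtype=float)
    nan = pd.Series({k: np.nan for k in coefficients})
    return StepwiseResults(
        response=response, selected=selected, params=params, bse=nan,
        tvalues=nan, pvalues=nan,
        beta=pd.Series({k: np.nan for k in selected}),
        rsquared=np.nan, rsquared_adj=np.nan, fvalue=np.nan, f_pvalue=np.nan,
        df_model=len(selected), df_resid=0, nobs=0, log=[],
    )
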