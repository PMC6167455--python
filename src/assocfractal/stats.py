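"""Inferential layer: inverted-U regression, correlations, rater agreement.

The central hypothesis test is a quadratic multiple regression of a
divergent-thinking score on the two temporal-structure estimates and
their squares,

    score ~ 1 + PSD + PSD² + DFA + DFA²,

where an inverted-U relation (peak performance at flexible-stable
structure) maps to negative, significant quadratic coefficients.  The
model is exposed statsmodels-style: :class:`InvertedUModel` is built
from arrays or a study table and ``fit()`` returns a
:class:`RegressionResult` with coefficients, standard errors, t/p values,
the overall F on (4, n−5) degrees of freedom, R² and a ``summary()``.

Also here: Pearson correlation tests, the simple regression of mean SmD
on mean response time (the serial-order-effect check), and ICC(2,k)
inter-rater agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import CollinearityError, InvalidInputError

__all__ = [
    "RegressionResult",
    "InvertedUModel",
    "quadratic_model_test",
    "pearson_test",
    "rt_smd_regression",
    "icc2k",
    "correlation_table",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS results: per-term estimates and the overall test.

    ``params``/``bse``/``tvalues``/``pvalues`` are indexed by term name;
    ``fvalue``/``f_pvalue`` are the overall F test on (df_model,
    df_resid); both plain and adjusted R² are carried because reported
    R² values in the literature are often ambiguous between the two.
    """

    model: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    rsquared: float
    rsquared_adj: float
    nobs: int
    conf_int: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"Model: {self.model}",
            f"n = {self.nobs}, F({self.df_model}, {self.df_resid}) = "
            f"{self.fvalue:.3f}, p = {self.f_pvalue:.4f}"
            if np.isfinite(self.fvalue)
            else f"n = {self.nobs} (overall F undefined)",
            f"R^2 = {self.rsquared:.4f} (adj. {self.rsquared_adj:.4f})",
            "",
            f"{'term':<12} {'coef':>12} {'se':>12} {'t':>9} {'p':>9}",
        ]
        for term in self.params.index:
            lines.append(
                f"{term:<12} {self.params[term]:>12.5f} {self.bse[term]:>12.5f} "
                f"{self.tvalues[term]:>9.3f} {self.pvalues[term]:>9.4f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable report of the fit."""

        def _clean(v):
            return None if not np.isfinite(v) else float(v)

        return {
            "model": self.model,
            "n": int(self.nobs),
            "coefficients": {
                t: {
                    "estimate": _clean(self.params[t]),
                    "se": _clean(self.bse[t]),
                    "t": _clean(self.tvalues[t]),
                    "p": _clean(self.pvalues[t]),
                }
                for t in self.params.index
            },
            "F": _clean(self.fvalue),
            "df": [int(self.df_model), int(self.df_resid)],
            "R2": _clean(self.rsquared),
            "R2_adj": _clean(self.rsquared_adj),
            "p": _clean(self.f_pvalue),
        }


def _check_design(X: np.ndarray, names: list[str]) -> None:
    """Raise CollinearityError naming the first term that adds no rank."""
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            raise CollinearityError(names[j])
        rank = new_rank


def _ols(y: np.ndarray, X: np.ndarray, names: list[str], label: str) -> RegressionResult:
    res = sm.OLS(y, X).fit()
    idx = pd.Index(names)
    with np.errstate(invalid="ignore"):
        ci = res.conf_int()
    return RegressionResult(
        model=label,
        params=pd.Series(res.params, index=idx),
        bse=pd.Series(res.bse, index=idx),
        tvalues=pd.Series(res.tvalues, index=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        fvalue=float(res.fvalue) if res.df_resid > 0 else np.nan,
        f_pvalue=float(res.f_pvalue) if res.df_resid > 0 else np.nan,
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        nobs=int(res.nobs),
        conf_int=pd.DataFrame(ci, index=idx, columns=["lower", "upper"]),
    )


class InvertedUModel:
    """Quadratic regression of a score on PSD and DFA estimates.

    Parameters
    ----------
    outcome, psd, dfa
        Equal-length vectors; rows with any missing value are dropped
        (complete-case analysis).  At least 10 complete cases required.
    center
        If True, predictors are mean-centred before squaring.  The
        default (False) enters them raw; centring is offered because raw
        squares are strongly collinear with their linear terms.
    """

    terms = ("const", "psd", "psd^2", "dfa", "dfa^2")

    def __init__(self, outcome, psd, dfa, center: bool = False, label: str = "outcome"):
        outcome = np.asarray(outcome, dtype=float)
        psd = np.asarray(psd, dtype=float)
        dfa = np.asarray(dfa, dtype=float)
        if not (len(outcome) == len(psd) == len(dfa)):
            raise InvalidInputError("outcome, psd and dfa must have equal length")
        keep = np.isfinite(outcome) & np.isfinite(psd) & np.isfinite(dfa)
        outcome, psd, dfa = outcome[keep], psd[keep], dfa[keep]
        if len(outcome) < 10:
            raise InvalidInputError(
                f"need at least 10 complete cases, got {len(outcome)}"
            )
        if center:
            psd = psd - psd.mean()
            dfa = dfa - dfa.mean()
        self.endog = outcome
        self.exog = np.column_stack(
            [np.ones_like(psd), psd, psd**2, dfa, dfa**2]
        )
        self.label = label
        _check_design(self.exog, list(self.terms))

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        outcome: str = "aut_creativity",
        psd: str = "psd_slope",
        dfa: str = "dfa_alpha",
        center: bool = False,
    ) -> "InvertedUModel":
        """Build the model from a per-participant study table."""
        return cls(
            table[outcome].to_numpy(),
            table[psd].to_numpy(),
            table[dfa].to_numpy(),
            center=center,
            label=outcome,
        )

    def fit(self) -> RegressionResult:
        return _ols(self.endog, self.exog, list(self.terms), f"{self.label} ~ psd + psd^2 + dfa + dfa^2")


def quadratic_model_test(outcome, psd, dfa, center: bool = False) -> RegressionResult:
    """Convenience wrapper: fit the inverted-U model in one call."""
    return InvertedUModel(outcome, psd, dfa, center=center).fit()


def pearson_test(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided p from the t transform on n−2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InvalidInputError(f"need at least 3 paired observations, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidInputError("zero variance input to correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


def correlation_table(
    table: pd.DataFrame, columns: list[str], holm: bool = False
) -> pd.DataFrame:
    """Pairwise Pearson correlations with p-values, long format.

    With ``holm=True`` the p-values additionally carry a Holm step-down
    adjustment in ``p_holm`` (exploratory tables only; the confirmatory
    model is never adjusted).
    """
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1 :]:
            try:
                r, p, n = pearson_test(table[a], table[b])
            except InvalidInputError:
                r, p, n = np.nan, np.nan, 0
            rows.append({"var_a": a, "var_b": b, "r": r, "p": p, "n": n})
    out = pd.DataFrame(rows)
    if holm and len(out):
        from statsmodels.stats.multitest import multipletests

        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                out.loc[mask, "p"], method="holm"
            )[1]
        out["p_holm"] = adj
    return out


def rt_smd_regression(mean_rt, mean_smd) -> RegressionResult:
    """Simple OLS of mean semantic distance on mean response time.

    A positive significant slope is the serial-order effect: longer
    thinking time goes with semantically more distant responses.  A
    two-point input fits perfectly (R² = 1) with undefined p values.
    """
    rt = np.asarray(mean_rt, dtype=float)
    smd = np.asarray(mean_smd, dtype=float)
    if len(rt) != len(smd):
        raise InvalidInputError("mean_rt and mean_smd must have equal length")
    keep = np.isfinite(rt) & np.isfinite(smd)
    rt, smd = rt[keep], smd[keep]
    if len(rt) < 2:
        raise InvalidInputError(f"need at least 2 complete cases, got {len(rt)}")
    names = ["const", "mean_rt"]
    X = np.column_stack([np.ones_like(rt), rt])
    _check_design(X, names)
    return _ols(smd, X, names, "mean_smd ~ mean_rt")


def icc2k(ratings) -> float:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    ``ratings`` is an items × raters matrix with no missing cells.  From
    the two-way ANOVA mean squares (rows = items, columns = raters):

        ICC(2,k) = (MS_rows − MS_error) / (MS_rows + (MS_cols − MS_error) / n_items)
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2:
        raise InvalidInputError("ratings must be a 2-d items x raters matrix")
    n, k = R.shape
    if n < 2 or k < 2:
        raise InvalidInputError(f"need >= 2 items and >= 2 raters, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise InvalidInputError("ratings matrix has missing cells")
    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((R - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float((ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n))
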