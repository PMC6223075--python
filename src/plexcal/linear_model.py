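"""Gene-wise multifactorial linear models with empirical-Bayes moderation.

Fits, per feature, an ordinary least-squares model of the log2
calibrator ratio on the clinical covariates (Class fast/slow, Age, Stage
early/late, Group ALS/control; treatment coding), then shrinks the
residual variances toward a common prior by empirical Bayes: the prior
degrees of freedom d0 and prior variance s0^2 are estimated by the method
of moments on log s^2 under a scaled-F sampling model, the posterior
variance is (d0*s0^2 + d*s^2)/(d0 + d), and the moderated t-statistic
logFC / posterior SE is referred to a t distribution on d0 + d degrees of
freedom. Benjamini-Hochberg correction controls the false discovery rate
and features are called regulated when |logFC| >= log2(1.3) and the
selection p-value is below 0.05.

Usage::

    model = DifferentialExpressionModel.from_design(matrix, design,
                                                    covariates=["Class", "Age"])
    res = model.fit(coef="Class[fast]")
    print(res.summary())
    hits = res.regulated()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Default regulated-feature thresholds: fold change 1.3, p < 0.05.
DEFAULT_FC_THRESHOLD = 1.3
DEFAULT_P_THRESHOLD = 0.05

_COVARIATE_COLUMNS = {
    "Class": "class_label",
    "Stage": "stage_label",
    "Age": "age_years",
    "Group": "group",
    "Batch": "batch",
}

#: Reference levels so coefficients read as fast-vs-slow, late-vs-early,
#: ALS-vs-control.
_DEFAULT_REFERENCES = {"Class": "slow", "Stage": "early", "Group": "control"}


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float | np.ndarray) -> tuple[float, float]:
    """Estimate the variance-prior hyperparameters (d0, s0^2).

    Method of moments on z = log s^2 assuming s^2 | sigma^2 is sigma^2 *
    chi^2_d / d and sigma^2 is an inverse-chi^2 scale mixture with d0
    degrees of freedom: E[z] and Var[z] have closed forms in di/trigamma
    functions, inverted numerically. A degenerate (under-dispersed) sample
    of variances yields d0 = inf, i.e. complete shrinkage to s0^2.
    """
    s2 = np.asarray(s2, float)
    if s2.size < 10:
        raise ValueError("need >= 10 features to estimate the variance prior")
    if (s2 <= 0).any():
        raise ValueError("residual variances must be positive")
    df = np.broadcast_to(np.asarray(df, float), s2.shape)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return float(d0), s02


def posterior_variances(
    s2: np.ndarray, df: float | np.ndarray, d0: float, s02: float
) -> np.ndarray:
    """Shrink residual variances toward the prior:
    (d0*s0^2 + d*s^2) / (d0 + d); with d0 = inf every posterior variance
    equals s0^2, with d0 = 0 the raw variances are returned."""
    s2 = np.asarray(s2, float)
    if np.isinf(d0):
        return np.full_like(s2, s02)
    df = np.broadcast_to(np.asarray(df, float), s2.shape)
    return (d0 * s02 + df * s2) / (d0 + df)


def moderate_variances(
    s2: np.ndarray, df: float | np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes variance moderation: estimate the prior and return
    (posterior variances, prior df d0, prior variance s0^2)."""
    d0, s02 = estimate_variance_prior(s2, df)
    return posterior_variances(s2, df, d0, s02), d0, s02


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_regulated(
    table: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Regulated features: |logFC| >= log2(fc_threshold) and selection p <
    p_threshold, with an up/down ``direction`` column by sign of logFC."""
    pcol = "adj_pvalue" if use_adjusted else "pvalue"
    lfc_gate = np.abs(table["logFC"]) >= np.log2(fc_threshold)
    out = table[lfc_gate & (table[pcol] < p_threshold)].copy()
    out["direction"] = np.where(out["logFC"] > 0, "up", "down")
    return out


def _build_design_matrix(
    covariate_values: pd.DataFrame,
    covariates: list[str],
    references: dict[str, str],
) -> tuple[np.ndarray, list[str], list[str]]:
    n = covariate_values.shape[0]
    cols = [np.ones(n)]
    names = ["Intercept"]
    dropped: list[str] = []
    kept = np.ones((n, 1))
    rank = 1
    for cov in covariates:
        series = covariate_values[cov]
        if pd.api.types.is_numeric_dtype(series):
            col = series.to_numpy(float)
            cand = np.column_stack([kept, col])
            if np.linalg.matrix_rank(cand) > rank:
                kept, rank = cand, rank + 1
                cols.append(col)
                names.append(cov)
            else:
                dropped.append(cov)
            continue
        levels = sorted(series.astype(str).unique())
        ref = references.get(cov)
        if ref in levels:
            levels = [ref] + [l for l in levels if l != ref]
        for lev in levels[1:]:
            col = (series.astype(str) == lev).to_numpy(float)
            cand = np.column_stack([kept, col])
            if np.linalg.matrix_rank(cand) > rank:
                kept, rank = cand, rank + 1
                cols.append(col)
                names.append(f"{cov}[{lev}]")
            else:
                dropped.append(f"{cov}[{lev}]")
        if len(levels) == 1:
            dropped.append(f"{cov}[{levels[0]}]")
    if dropped:
        logger.warning("dropped aliased/constant design columns: %s", dropped)
    return np.column_stack(cols), names, dropped


class DifferentialExpressionModel:
    """Gene-wise linear model of log2 ratios on clinical covariates.

    Parameters
    ----------
    matrix
        Complete feature x sample DataFrame of log2 ratios.
    covariate_values
        Sample x covariate DataFrame aligned to the matrix columns;
        categorical covariates are treatment-coded with the reference
        levels of ``references`` (Class: slow, Stage: early, Group:
        control by default).
    covariates
        Covariate names, in design order.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        covariate_values: pd.DataFrame,
        covariates: list[str] | None = None,
        references: dict[str, str] | None = None,
    ) -> None:
        if matrix.isna().any().any():
            raise ValueError("model matrix must be complete (impute first)")
        covariates = list(covariates or covariate_values.columns)
        refs = dict(_DEFAULT_REFERENCES)
        refs.update(references or {})
        self.matrix = matrix
        self.covariate_values = covariate_values.loc[matrix.columns, covariates]
        self.covariates = covariates
        X, names, dropped = _build_design_matrix(self.covariate_values, covariates, refs)
        self.exog = X
        self.exog_names = names
        self.dropped_columns = dropped
        self.df_residual = matrix.shape[1] - X.shape[1]
        if self.df_residual < 1:
            raise ValueError(
                "zero residual degrees of freedom; reduce the model "
                f"(n={matrix.shape[1]} samples, {X.shape[1]} design columns)"
            )

    @classmethod
    def from_design(
        cls,
        matrix: pd.DataFrame,
        design: pd.DataFrame,
        covariates: list[str] = ("Class", "Age", "Stage", "Group"),
        references: dict[str, str] | None = None,
    ) -> "DifferentialExpressionModel":
        """Build from a pipeline design table (columns ``sample_id``,
        ``class_label``, ``stage_label``, ``age_years``, ``group``),
        selecting the standard covariates Class + Age + Stage + Group."""
        d = design.set_index("sample_id")
        vals = pd.DataFrame(
            {c: d[_COVARIATE_COLUMNS[c]] for c in covariates}, index=d.index
        )
        return cls(matrix, vals.loc[matrix.columns], list(covariates), references)

    def fit(
        self,
        coef: str | None = None,
        moderate: bool = True,
    ) -> "DEResults":
        """Fit every feature by OLS and moderate the variances.

        Parameters
        ----------
        coef
            Name of the design column reported as the contrast (e.g.
            ``"Class[fast]"``). Defaults to the first non-intercept column.
        moderate
            Apply empirical-Bayes variance shrinkage (ordinary t-tests
            when False).
        """
        X = self.exog
        Y = self.matrix.to_numpy(float)  # features x samples
        n, p = X.shape
        beta, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
        resid = Y.T - X @ beta
        d = n - p
        s2 = (resid**2).sum(axis=0) / d
        if coef is None:
            coef = self.exog_names[1] if len(self.exog_names) > 1 else self.exog_names[0]
        if coef not in self.exog_names:
            raise ValueError(f"unknown coefficient {coef!r}; have {self.exog_names}")
        ci = self.exog_names.index(coef)
        xtx_inv = np.linalg.inv(X.T @ X)
        v_c = xtx_inv[ci, ci]
        logfc = beta[ci]
        if moderate:
            s2 = np.maximum(s2, 1e-300)
            post_var, d0, s02 = moderate_variances(s2, d)
            df_total = d0 + d if np.isfinite(d0) else np.inf
        else:
            post_var, d0, s02 = s2, 0.0, float(np.median(s2))
            df_total = d
        se = np.sqrt(post_var * v_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = logfc / se
        if np.isinf(df_total):
            from scipy.stats import norm

            pvals = 2 * norm.sf(np.abs(tstat))
        else:
            pvals = 2 * t_dist.sf(np.abs(tstat), df_total)
        table = pd.DataFrame(
            {
                "logFC": logfc,
                "t": tstat,
                "pvalue": pvals,
                "adj_pvalue": adjust_bh(pvals),
                "residual_var": s2,
                "posterior_var": post_var,
            },
            index=self.matrix.index,
        )
        table["regulated"] = (
            (np.abs(table["logFC"]) >= np.log2(DEFAULT_FC_THRESHOLD))
            & (table["pvalue"] < DEFAULT_P_THRESHOLD)
        )
        return DEResults(
            table=table,
            coef=coef,
            df_residual=d,
            df_total=float(df_total),
            prior_df=float(d0),
            prior_var=float(s02),
            moderated=moderate,
            exog_names=list(self.exog_names),
            params=pd.DataFrame(beta.T, index=self.matrix.index, columns=self.exog_names),
        )


@dataclass
class DEResults:
    """Differential-expression results for one contrast.

    ``table`` has one row per feature: logFC (log2 fold change for the
    contrast), moderated t, raw and BH-adjusted p-values, residual and
    posterior variances and the regulated flag.
    """

    table: pd.DataFrame
    coef: str
    df_residual: float
    df_total: float
    prior_df: float
    prior_var: float
    moderated: bool
    exog_names: list[str]
    params: pd.DataFrame

    def regulated(
        self,
        fc_threshold: float = DEFAULT_FC_THRESHOLD,
        p_threshold: float = DEFAULT_P_THRESHOLD,
        use_adjusted: bool = False,
    ) -> pd.DataFrame:
        """Regulated features at the given thresholds, with direction."""
        return select_regulated(self.table, fc_threshold, p_threshold, use_adjusted)

    def to_report(self, annotations: pd.DataFrame | None = None) -> pd.DataFrame:
        """Report-style table: id, logFC, raw p, adjusted p, direction,
        sorted by decreasing logFC; optional annotation columns (e.g.
        peptide counts) are joined in."""
        rep = self.table[["logFC", "pvalue", "adj_pvalue", "regulated"]].copy()
        rep["direction"] = np.where(rep["logFC"] > 0, "up", "down")
        if annotations is not None:
            rep = rep.join(annotations, how="left")
        return rep.sort_values("logFC", ascending=False)

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary."""
        n_reg = int(self.table["regulated"].sum())
        lines = [
            "Differential expression results",
            "===============================",
            f"contrast:          {self.coef}",
            f"features:          {self.table.shape[0]}",
            f"design columns:    {', '.join(self.exog_names)}",
            f"residual df:       {self.df_residual:g}",
            f"moderation:        {'empirical Bayes' if self.moderated else 'off (OLS t)'}",
            f"prior df (d0):     {self.prior_df:g}",
            f"prior var (s0^2):  {self.prior_var:.6g}",
            f"total df:          {self.df_total:g}",
            f"regulated (|FC|>=1.3, p<0.05): {n_reg}",
            "",
            f"top {top} features by p-value:",
            self.table.sort_values("pvalue")
            .head(top)[["logFC", "t", "pvalue", "adj_pvalue"]]
            .to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def run_comparisons(
    matrix: pd.DataFrame, design: pd.DataFrame, moderate: bool = True
) -> dict[str, DEResults]:
    """The four study comparisons on their estimable sample subsets.

    Cross-sectional: fast vs slow within each stage, model value ~ Class +
    Age + Batch — class is crossed with plex within a stage, so the plex
    term belongs in the inference model (fitting it here, rather than
    testing on pre-corrected data, keeps the residual degrees of freedom
    honest). Longitudinal: late vs early within each class, model value ~
    Stage + Age with no batch term: plexes are nested in stage, so a batch
    term is confounded with the contrast; leaving it out keeps the
    between-plex variation in the residual, where it widens (never
    narrows) the error estimate. The Group term is omitted on these
    all-case subsets, where it is constant.

    For this reason the matrix supplied here should be the uncorrected
    (imputed) one; the batch-corrected matrix is for visualisation (PCA,
    heat maps), not inference.
    """
    d = design.set_index("sample_id").loc[matrix.columns]
    out: dict[str, DEResults] = {}
    for stage in ("early", "late"):
        cols = d.index[d["stage_label"] == stage]
        m = DifferentialExpressionModel.from_design(
            matrix[cols], design, covariates=["Class", "Age", "Batch"]
        )
        out[f"fast_vs_slow_{stage}"] = m.fit(coef="Class[fast]", moderate=moderate)
    for cls in ("fast", "slow"):
        cols = d.index[d["class_label"] == cls]
        m = DifferentialExpressionModel.from_design(
            matrix[cols], design, covariates=["Stage", "Age"]
        )
        out[f"late_vs_early_{cls}"] = m.fit(coef="Stage[late]", moderate=moderate)
    return out
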