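"""Pre-processing and feature selection for calibrator-referenced matrices.

Operates on peptide (or protein) x sample DataFrames of log2 ratios with
NaN marking missing values. Stages, in pipeline order: per-group
missingness filtering, within-group k-nearest-neighbour imputation,
linear-model batch/channel correction protecting the experimental groups,
trimmed-mean rollup of unique non-phosphorylated peptides to gene-level
values, per-sample QC metrics with a 3-SD outlier rule, and PCA of the
variance structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

logger = logging.getLogger(__name__)


def groups_from_design(design: pd.DataFrame) -> pd.DataFrame:
    """Build the sample -> (group, batch, channel) assignment from a design
    table. The experimental group is the Class x Stage combination
    (Fast-Early, Fast-Late, Slow-Early, Slow-Late)."""
    out = pd.DataFrame(
        {
            "group": design["class_label"].str.capitalize()
            + "-"
            + design["stage_label"].str.capitalize(),
            "batch": design["batch"] if "batch" in design else design["plex_id"],
            "channel": design["channel"],
        }
    )
    out.index = pd.Index(design["sample_id"], name="sample_id")
    return out


def _check_groups(matrix: pd.DataFrame, groups: pd.DataFrame) -> pd.Series:
    missing = [s for s in matrix.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples without a group assignment: {missing}")
    g = groups.loc[matrix.columns, "group"]
    if (g.value_counts() == 0).any():
        raise ValueError("empty experimental group")
    return g


def filter_missingness(
    matrix: pd.DataFrame, groups: pd.DataFrame, threshold: float = 0.35
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove features with too many missing values in any experimental group.

    A feature is removed iff in at least one group the missing fraction
    strictly exceeds ``threshold`` (default 0.35, i.e. "more than ~35%").
    Returns the filtered matrix and a removal log naming, per removed
    feature, the first offending group and its missing fraction.
    """
    g = _check_groups(matrix, groups)
    remove = pd.Series(False, index=matrix.index)
    log_rows = []
    for group_name, cols in matrix.columns.groupby(g).items():
        block = matrix[list(cols)]
        frac = block.isna().sum(axis=1) / block.shape[1]
        offending = frac > threshold
        for feat in matrix.index[offending & ~remove]:
            log_rows.append(
                {
                    "feature": feat,
                    "offending_group": group_name,
                    "missing_fraction": float(frac.loc[feat]),
                }
            )
        remove |= offending
    removal_log = pd.DataFrame(log_rows, columns=["feature", "offending_group", "missing_fraction"])
    kept = matrix.loc[~remove]
    logger.info(
        "missingness filter: %d of %d features removed (> %.0f%% missing in a group)",
        int(remove.sum()), matrix.shape[0], 100 * threshold,
    )
    return kept, removal_log


def impute_knn(matrix: pd.DataFrame, groups: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Impute missing cells by k-nearest-neighbour features within each
    experimental group.

    For a missing cell (feature f, sample s): restrict to the columns of
    s's group; candidate neighbours are other features observed at s with
    at least one column observed in common with f; distance is the
    Euclidean distance over the shared observed columns normalised by the
    number of shared columns; the cell is imputed as the mean of the k
    nearest neighbours' values at s, ties broken by feature order. With no
    eligible neighbour the feature's within-group observed mean is used
    (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    g = _check_groups(matrix, groups)
    out = matrix.copy()
    n_fallback = 0
    for group_name, cols in matrix.columns.groupby(g).items():
        cols = list(cols)
        block = matrix[cols].to_numpy(float)
        obs = ~np.isnan(block)
        miss_feats = np.flatnonzero(~obs.all(axis=1))
        for fi in miss_feats:
            for sj in np.flatnonzero(~obs[fi]):
                cand = np.flatnonzero(obs[:, sj])
                cand = cand[cand != fi]
                shared = obs[cand] & obs[fi]
                n_shared = shared.sum(axis=1)
                ok = n_shared > 0
                cand, shared, n_shared = cand[ok], shared[ok], n_shared[ok]
                if cand.size == 0:
                    row = block[fi, obs[fi]]
                    if row.size == 0:
                        raise ValueError(
                            f"feature {matrix.index[fi]!r} has no observed value in "
                            f"group {group_name!r}; filter before imputing"
                        )
                    out.iloc[fi, out.columns.get_indexer(cols)[sj]] = row.mean()
                    n_fallback += 1
                    continue
                diff = np.where(shared, block[cand] - block[fi], 0.0)
                dist = np.sqrt((diff**2).sum(axis=1) / n_shared)
                order = np.lexsort((cand, dist))  # stable: distance, then feature order
                chosen = cand[order[:k]]
                out.iloc[fi, out.columns.get_indexer(cols)[sj]] = block[chosen, sj].mean()
    if n_fallback:
        logger.warning(
            "kNN imputation: %d cells imputed by within-group feature mean "
            "(no eligible neighbour)", n_fallback,
        )
    return out


def _design_matrix(
    factors: dict[str, pd.Series],
) -> tuple[np.ndarray, list[str], list[str]]:
    """Treatment-coded design matrix with intercept; drops aliased columns.

    Columns are added in the order given; a column is dropped (and
    reported) if it is constant or linearly dependent on the columns
    already kept.
    """
    n = len(next(iter(factors.values())))
    cols = [np.ones(n)]
    names = ["Intercept"]
    dropped: list[str] = []
    kept = np.ones((n, 1))
    rank = 1
    for fname, series in factors.items():
        levels = sorted(pd.unique(series.astype(str)))
        for lev in levels[1:]:
            col = (series.astype(str) == lev).to_numpy(float)
            cand = np.column_stack([kept, col])
            r = np.linalg.matrix_rank(cand)
            if r > rank:
                kept, rank = cand, r
                cols.append(col)
                names.append(f"{fname}[{lev}]")
            else:
                dropped.append(f"{fname}[{lev}]")
        if len(levels) == 1:
            dropped.append(f"{fname}[{levels[0]}]")
    if dropped:
        logger.warning("design matrix: dropped aliased/constant columns %s", dropped)
    return np.column_stack(cols), names, dropped


def correct_batch(matrix: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Remove batch (plex) and channel effects while protecting group effects.

    Per feature, fits value ~ group + batch + channel by least squares
    (treatment coding, first level as reference) and subtracts the fitted
    batch and channel contributions, leaving group effects and residuals
    in place — the removeBatchEffect semantics. Collinear batch/channel
    columns are dropped with a warning.

    When batches nest within groups (e.g. whole plexes assigned to one
    disease stage), part of the batch fit lives in the group space and is
    unidentifiable from a genuine group effect; subtracting it would be an
    arbitrary reference-level choice. Only the group-centred component of
    the nuisance fit (up to one overall constant) is therefore removed,
    which protects group contrasts exactly on balanced and nested designs
    alike.
    """
    if matrix.isna().any().any():
        raise ValueError("batch correction requires a complete (imputed) matrix")
    meta = groups.loc[matrix.columns]
    X, names, _dropped = _design_matrix(
        {
            "group": meta["group"],
            "batch": meta["batch"],
            "channel": meta["channel"],
        }
    )
    nuisance = [i for i, nm in enumerate(names) if nm.startswith(("batch[", "channel["))]
    if not nuisance:
        logger.info("batch correction: no estimable batch/channel term; matrix unchanged")
        return matrix.copy()
    Y = matrix.to_numpy(float)  # features x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # columns x features
    fitted_nuisance = X[:, nuisance] @ beta[nuisance]  # samples x features
    # group-centre the nuisance fit: its group-wise means stay in the data
    # (minus their overall mean, so a fully-crossed design is unchanged)
    group_codes = meta["group"].to_numpy()
    group_means = np.zeros_like(fitted_nuisance)
    for gname in np.unique(group_codes):
        sel = group_codes == gname
        group_means[sel] = fitted_nuisance[sel].mean(axis=0)
    subtract = fitted_nuisance - group_means + group_means.mean(axis=0)
    out = pd.DataFrame(Y - subtract.T, index=matrix.index, columns=matrix.columns)
    logger.info(
        "batch correction: removed %d nuisance columns (%s)",
        len(nuisance), [names[i] for i in nuisance],
    )
    return out


def rollup_peptide_to_protein(
    matrix: pd.DataFrame, annotations: pd.DataFrame, trim: float = 0.2
) -> pd.DataFrame:
    """Trimmed-mean rollup of eligible peptides to gene-level expression.

    Eligible peptides are non-phosphorylated and match a single gene.
    Per gene and sample, the trimmed mean removes floor(trim * n) values
    from each tail of the sorted observed values (plain mean when that is
    zero). Genes with no eligible peptide are omitted.
    """
    if not 0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    anno = annotations.loc[matrix.index]
    eligible = (~anno["is_phospho"].astype(bool)) & anno["is_unique_gene_match"].astype(bool)
    sub = matrix.loc[eligible]
    genes = anno.loc[eligible, "gene"]

    def _tmean(col: np.ndarray) -> float:
        v = col[~np.isnan(col)]
        if v.size == 0:
            return np.nan
        return float(trim_mean(v, trim))

    rows = {}
    for gene, idx in sub.index.groupby(genes).items():
        block = sub.loc[list(idx)].to_numpy(float)
        rows[gene] = [_tmean(block[:, j]) for j in range(block.shape[1])]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(matrix.columns))
    out.index.name = "gene"
    out = out.sort_index()
    logger.info(
        "protein rollup: %d peptides (%d eligible) -> %d genes",
        matrix.shape[0], int(eligible.sum()), out.shape[0],
    )
    return out


@dataclass
class QcReport:
    """Per-sample QC metrics and 3-SD outlier flags."""

    table: pd.DataFrame

    @property
    def outliers(self) -> list[str]:
        flagged = self.table["median_outlier"] | self.table["iqr_outlier"]
        return list(self.table.index[flagged])


def qc_metrics(matrix: pd.DataFrame) -> QcReport:
    """Per-sample median (central tendency) and IQR (scale; linear-
    interpolation quartiles), each flagged when more than three standard
    deviations from its across-sample mean. With fewer than three samples
    the metrics are reported without flags."""
    med = matrix.median(axis=0, skipna=True)
    q75 = matrix.quantile(0.75, axis=0, interpolation="linear")
    q25 = matrix.quantile(0.25, axis=0, interpolation="linear")
    iqr = q75 - q25
    table = pd.DataFrame({"median": med, "iqr": iqr})
    if matrix.shape[1] < 3:
        logger.warning("QC: fewer than 3 samples; outlier flags not computed")
        table["median_outlier"] = False
        table["iqr_outlier"] = False
        return QcReport(table)
    for metric in ("median", "iqr"):
        v = table[metric]
        sd = v.std(ddof=1)
        table[f"{metric}_outlier"] = (
            (v - v.mean()).abs() > 3 * sd if sd > 0 else False
        )
    return QcReport(table)


@dataclass
class PcaResult:
    """PCA of a complete feature x sample matrix.

    ``scores``: samples x components; ``loadings``: features x
    components; ``variance_explained``: fraction of total variance per
    component, non-increasing and summing to 1.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray


def pca(matrix: pd.DataFrame) -> PcaResult:
    """Feature-centred SVD principal component analysis.

    Each feature is centred across samples; components are ordered by
    decreasing variance; each component's sign is fixed so its largest-
    magnitude loading is positive.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    if matrix.isna().any().any():
        raise ValueError("PCA requires a complete matrix")
    X = matrix.to_numpy(float).T  # samples x features
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size and s[0] > 0 else s > 0
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    for i in range(len(s)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(U * s, index=matrix.columns, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=matrix.index, columns=comp),
        variance_explained=frac,
    )
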