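"""Calibrator-referenced quantification of TMT 10-plex reporter-ion data.

Converts raw PSM (peptide-spectrum match) reporter intensities into log2
peptide/calibrator ratios. Four of the ten TMT channels carry a pooled
tissue lysate loaded as a dilution series (the calibrator); the remaining
six carry individual plasma samples. Within each MS run the calibrant
channels are median-scaled onto a common level, a per-PSM reference
intensity (the mid-point of the calibrant distribution) is computed, and
every sample channel is expressed as a log2 ratio against that reference.
PSM-level ratios are then rolled up to peptide level by the median.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: TMT 10-plex reporter channel labels, in mass order.
CHANNELS: tuple[str, ...] = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131",
)

#: Channels carrying individual plasma samples (six per plex).
SAMPLE_CHANNELS: tuple[str, ...] = CHANNELS[:6]

#: Channels carrying the tissue-calibrator dilution series.
CALIBRANT_CHANNELS: tuple[str, ...] = ("129C", "130N", "130C", "131")

#: Intensity column names used in PSM tables.
INTENSITY_COLUMNS: tuple[str, ...] = tuple(f"intensity_{c}" for c in CHANNELS)
SAMPLE_INTENSITY_COLUMNS: tuple[str, ...] = tuple(
    f"intensity_{c}" for c in SAMPLE_CHANNELS
)
CALIBRANT_INTENSITY_COLUMNS: tuple[str, ...] = tuple(
    f"intensity_{c}" for c in CALIBRANT_CHANNELS
)


@dataclass(frozen=True)
class ImpurityMatrix:
    """Reporter isotope-impurity matrix.

    ``values[i, j]`` is the fraction of channel ``j``'s true signal that is
    detected in channel ``i``, so observed = values @ true. The identity
    matrix (no cross-talk) is the valid default. Columns must sum to at
    most 1 and be diagonally dominant.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (10, 10):
            raise ValueError(f"impurity matrix must be 10x10, got {v.shape}")
        if (v < 0).any():
            raise ValueError("impurity matrix entries must be non-negative")
        colsums = v.sum(axis=0)
        if (colsums > 1 + 1e-9).any():
            raise ValueError("impurity matrix columns must sum to <= 1")
        diag = np.diag(v)
        offmax = np.where(np.eye(10, dtype=bool), -np.inf, v).max(axis=0)
        if not (diag > offmax).all():
            raise ValueError("impurity matrix must be diagonally dominant")
        object.__setattr__(self, "values", v)

    @classmethod
    def identity(cls) -> "ImpurityMatrix":
        return cls(np.eye(10))

    @classmethod
    def from_spill(cls, spill: float) -> "ImpurityMatrix":
        """Symmetric nearest-neighbour cross-talk model.

        A fraction ``spill`` of each channel's signal leaks into each of
        the (at most two) adjacent channels; the diagonal keeps the rest,
        so columns sum to 1 exactly.
        """
        if not 0 <= spill < 0.5:
            raise ValueError("spill must lie in [0, 0.5)")
        m = np.zeros((10, 10))
        for j in range(10):
            neighbours = [i for i in (j - 1, j + 1) if 0 <= i < 10]
            for i in neighbours:
                m[i, j] = spill
            m[j, j] = 1.0 - spill * len(neighbours)
        return cls(m)

    @classmethod
    def from_csv(cls, path) -> "ImpurityMatrix":
        """Read a labelled 10x10 impurity CSV (header row and index column
        of channel labels, in CHANNELS order)."""
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        try:
            df = df.loc[list(CHANNELS), list(CHANNELS)]
        except KeyError as exc:
            raise ValueError(f"impurity CSV must be labelled by channels {CHANNELS}") from exc
        return cls(df.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=CHANNELS, columns=CHANNELS).to_csv(path)

    def apply(self, true_intensities: np.ndarray) -> np.ndarray:
        """Forward model: mix true channel signals by the cross-talk matrix."""
        x = np.asarray(true_intensities, dtype=float)
        return x @ self.values.T

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.values, np.eye(10))


def correct_impurities(
    raw: np.ndarray, impurity: ImpurityMatrix
) -> tuple[np.ndarray, int]:
    """Remove reporter-channel cross-talk by solving ``M x = raw`` row-wise.

    Parameters
    ----------
    raw
        Array of shape (n, 10) of non-negative intensities; NaN marks a
        missing channel.
    impurity
        The cross-talk matrix ``M``.

    Returns
    -------
    corrected, n_skipped
        Corrected intensities (negative solutions clamped to NaN, since a
        negative abundance is physically impossible and log2 is undefined
        at 0) and the number of rows passed through uncorrected because
        at least one channel was missing.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[1] != 10:
        raise ValueError("expected 10 intensity columns")
    if impurity.is_identity:
        return raw.copy(), 0
    if abs(np.linalg.det(impurity.values)) < 1e-12:
        raise ValueError("impurity matrix is singular; cannot correct")
    out = raw.copy()
    complete = ~np.isnan(raw).any(axis=1)
    n_skipped = int((~complete).sum())
    if n_skipped:
        logger.warning(
            "impurity correction skipped for %d PSM rows with missing channels",
            n_skipped,
        )
    if complete.any():
        solved = np.linalg.solve(impurity.values, raw[complete].T).T
        solved[solved < 0] = np.nan
        out[complete] = solved
    return out, n_skipped


def median_scale_calibrants(
    psms: pd.DataFrame, run_col: str = "plex_id"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-scale the four calibrant channels within each MS run.

    Each calibrant channel is multiplied by a scalar chosen so that the
    post-scaling median of that channel (over the run's PSMs) equals the
    grand median of the four pre-scaling channel medians. Sample channels
    are untouched; any common target cancels in the downstream ratios.

    Returns the scaled table and a table of scale factors (run x channel).

    Raises
    ------
    ValueError
        If a calibrant channel has no observed value in some run.
    """
    if run_col not in psms.columns:
        raise ValueError(f"PSM table lacks run column {run_col!r}")
    scaled = psms.copy()
    rows = []
    for run, idx in psms.groupby(run_col, sort=False).groups.items():
        block = psms.loc[idx, list(CALIBRANT_INTENSITY_COLUMNS)].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            medians = np.nanmedian(block, axis=0)
        if np.isnan(medians).any():
            missing = [
                CALIBRANT_CHANNELS[i] for i in np.flatnonzero(np.isnan(medians))
            ]
            raise ValueError(
                f"run {run!r}: calibrant channel(s) {missing} entirely missing; "
                "run rejected"
            )
        target = float(np.median(medians))
        factors = target / medians
        scaled.loc[idx, list(CALIBRANT_INTENSITY_COLUMNS)] = block * factors
        rows.append({run_col: run, **dict(zip(CALIBRANT_CHANNELS, factors))})
    return scaled, pd.DataFrame(rows)


def compute_reference(calibrant_intensities: np.ndarray) -> np.ndarray:
    """Per-PSM reference intensity: median of the observed scaled calibrant
    intensities (the mid-point of the calibrant distribution).

    Rows with fewer than two observed calibrant values are unquantifiable
    and yield NaN.
    """
    x = np.atleast_2d(np.asarray(calibrant_intensities, dtype=float))
    n_obs = (~np.isnan(x)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref = np.nanmedian(x, axis=1)
    ref[n_obs < 2] = np.nan
    if (ref[~np.isnan(ref)] <= 0).any():
        raise ValueError("non-positive reference intensity")
    return ref


def psm_log_ratios(
    sample_intensities: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """log2(sample intensity / per-PSM reference).

    Non-positive intensities are treated as missing (logged); missing
    intensities and missing references propagate as NaN.
    """
    x = np.atleast_2d(np.asarray(sample_intensities, dtype=float)).copy()
    ref = np.asarray(reference, dtype=float).reshape(-1, 1)
    nonpos = np.sum(x <= 0)
    if nonpos:
        logger.warning("%d non-positive sample intensities treated as missing", nonpos)
        x[x <= 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2(x / ref)


def rollup_psm_to_peptide(ratio_records: pd.DataFrame) -> pd.DataFrame:
    """Median-aggregate PSM-level log2 ratios to peptide level.

    ``ratio_records`` has one row per PSM: a ``peptide_sequence`` key plus
    one ratio column per sample id. The peptide x sample cell is the median
    of observed PSM ratios and is missing only when all contributing PSMs
    are missing. Modified forms (e.g. phospho) must be encoded in the
    sequence key to remain distinct.
    """
    if "peptide_sequence" not in ratio_records.columns:
        raise ValueError("ratio records need a 'peptide_sequence' column")
    grouped = ratio_records.groupby("peptide_sequence", sort=True).median()
    grouped.index.name = "peptide_sequence"
    return grouped


def quantify_plexes(
    psm_tables: dict[str, pd.DataFrame],
    design: pd.DataFrame,
    impurity: ImpurityMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full quantification stage over a set of plex PSM tables.

    Per plex: impurity-correct, median-scale calibrants, compute the
    per-PSM calibrant reference, form log2 sample/reference ratios, then
    roll PSMs up to a peptide x sample matrix across all plexes.

    Parameters
    ----------
    psm_tables
        Mapping plex id -> PSM table with the documented CSV schema.
    design
        Sample design table with columns ``sample_id``, ``plex_id``,
        ``channel`` (plus covariates, unused here).
    impurity
        Optional cross-talk matrix; identity (no correction) by default.

    Returns
    -------
    matrix, annotations
        ``matrix``: peptide x sample DataFrame of log2 ratios (NaN =
        missing). ``annotations``: peptide-level table with ``gene``,
        ``is_phospho`` and ``is_unique_gene_match``.
    """
    impurity = impurity or ImpurityMatrix.identity()
    frames = []
    anno_frames = []
    for plex_id, table in psm_tables.items():
        table = table.copy()
        raw = table[list(INTENSITY_COLUMNS)].to_numpy(float)
        corrected, _ = correct_impurities(raw, impurity)
        table[list(INTENSITY_COLUMNS)] = corrected
        scaled, _ = median_scale_calibrants(table, run_col="plex_id")
        ref = compute_reference(
            scaled[list(CALIBRANT_INTENSITY_COLUMNS)].to_numpy(float)
        )
        n_unq = int(np.isnan(ref).sum())
        if n_unq:
            logger.warning(
                "plex %s: %d PSMs unquantifiable (<2 observed calibrant values)",
                plex_id, n_unq,
            )
        ratios = psm_log_ratios(
            scaled[list(SAMPLE_INTENSITY_COLUMNS)].to_numpy(float), ref
        )
        sub = design[design["plex_id"].astype(str) == str(plex_id)]
        channel_to_sample = dict(zip(sub["channel"], sub["sample_id"]))
        cols = []
        for ch in SAMPLE_CHANNELS:
            if ch not in channel_to_sample:
                raise ValueError(
                    f"design lacks a sample for plex {plex_id} channel {ch}"
                )
            cols.append(channel_to_sample[ch])
        rec = pd.DataFrame(ratios, columns=cols)
        rec.insert(0, "peptide_sequence", table["peptide_sequence"].to_numpy())
        frames.append(rec)
        anno_frames.append(
            table[["peptide_sequence", "gene", "is_phospho", "is_unique_gene_match"]]
        )
    if not frames:
        raise ValueError("no PSM tables supplied")
    per_plex = [rollup_psm_to_peptide(f) for f in frames]
    matrix = pd.concat(per_plex, axis=1)
    annotations = (
        pd.concat(anno_frames)
        .drop_duplicates(subset="peptide_sequence")
        .set_index("peptide_sequence")
        .loc[matrix.index]
    )
    logger.info(
        "quantified %d peptides across %d samples", matrix.shape[0], matrix.shape[1]
    )
    return matrix, annotations
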