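"""Synthetic TMT 10-plex experiments with known ground truth.

Emulates the tissue-enhanced plasma study design: four 10-plexes, each with
six plasma channels (three fast- and three slow-progressing subjects) and
four calibrant channels carrying a pooled PBMC lysate loaded at 1/21, 4/21,
6/21 and 10/21 of total protein. Two plexes hold early-stage samples, two
hold late-stage samples. Injected signals — class and stage fold changes on
chosen genes, an age trend, per-plex batch offsets, reporter cross-talk and
intensity-dependent missingness — are all recorded in a ground-truth ledger
so downstream stages can be tested for parameter recovery.

Also houses the clinical stratification utilities: the progression rate to
last visit, PRL = (48 - ALSFRS-R at last visit) / months from onset, with
fast progression defined by PRL > 0.7 and slow by PRL < 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .quantify import (
    CHANNELS,
    SAMPLE_CHANNELS,
    CALIBRANT_CHANNELS,
    INTENSITY_COLUMNS,
    ImpurityMatrix,
)

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: PRL cut-offs for progression classes.
PRL_FAST_THRESHOLD = 0.7
PRL_SLOW_THRESHOLD = 0.5


def compute_prl(alsfrs_r_last: float, months: float) -> float:
    """Progression rate to last visit: (48 - ALSFRS-R) / months from onset.

    ALSFRS-R is the revised ALS functional rating scale (0-48, lower =
    more impaired); ``months`` is the disease duration from symptom onset
    to the last visit.
    """
    if not 0 <= alsfrs_r_last <= 48:
        raise ValueError(f"ALSFRS-R score must lie in [0, 48], got {alsfrs_r_last}")
    if months <= 0:
        raise ValueError(f"months from onset must be positive, got {months}")
    return (48.0 - alsfrs_r_last) / months


def stratify_progression(prl: float) -> str:
    """Classify a PRL value: > 0.7 -> 'fast', < 0.5 -> 'slow', else
    'intermediate'. Intermediate values are legal inputs even though the
    study design enrols only fast and slow progressors; rejecting them
    silently would hide data errors."""
    if prl < 0:
        raise ValueError(f"PRL must be non-negative, got {prl}")
    if prl > PRL_FAST_THRESHOLD:
        return "fast"
    if prl < PRL_SLOW_THRESHOLD:
        return "slow"
    return "intermediate"


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's clinical stratification inputs.

    Stage labels follow the ALSFRS-R convention: early disease means a
    score above 40, late disease below 35.
    """

    alsfrs_r_last: float
    months_onset_to_last_visit: float
    class_label: str
    stage_label: str
    age_years: float

    def __post_init__(self) -> None:
        if not 0 <= self.alsfrs_r_last <= 48:
            raise ValueError("ALSFRS-R out of [0, 48]")
        if self.months_onset_to_last_visit <= 0:
            raise ValueError("months must be positive")
        if self.class_label not in ("fast", "slow", "intermediate"):
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.stage_label not in ("early", "late"):
            raise ValueError(f"unknown stage label {self.stage_label!r}")
        if self.stage_label == "early" and not self.alsfrs_r_last > 40:
            raise ValueError("early stage requires ALSFRS-R > 40")
        if self.stage_label == "late" and not self.alsfrs_r_last < 35:
            raise ValueError("late stage requires ALSFRS-R < 35")
        if self.age_years <= 0:
            raise ValueError("age must be positive")

    @property
    def prl(self) -> float:
        return compute_prl(self.alsfrs_r_last, self.months_onset_to_last_visit)


def draw_subject(rng: np.random.Generator, class_label: str, stage_label: str) -> SubjectRecord:
    """Draw a clinically consistent subject for a given class and stage.

    The ALSFRS-R score respects the stage definition, and months from onset
    is back-solved so the PRL lands in the class's range.
    """
    if stage_label == "early":
        score = float(rng.uniform(41, 46))
    else:
        score = float(rng.uniform(24, 34))
    if class_label == "fast":
        prl = float(rng.uniform(0.8, 1.9))
    elif class_label == "slow":
        prl = float(rng.uniform(0.1, 0.45))
    else:
        prl = float(rng.uniform(0.5, 0.7))
    months = (48.0 - score) / prl
    age = float(np.clip(rng.normal(60.0, 8.0), 30.0, 85.0))
    return SubjectRecord(score, months, class_label, stage_label, age)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic tissue-calibrator experiment.

    Defaults encode the study conditions: 4 plexes of 6 plasma + 4
    calibrant channels, calibrant loadings 1/21..10/21, class effect 1.5
    log2 units on 10% of genes, stage effect 1.0 log2 on a disjoint 10%,
    PSM noise 0.5 log2 units, modest per-plex batch offsets, 2% MCAR and
    left-censored MNAR missingness.
    """

    n_proteins: int = 400
    peptides_per_protein: tuple[int, int] = (2, 6)
    psms_per_peptide: tuple[int, int] = (1, 3)
    n_plexes: int = 4
    sample_channels_per_plex: int = 6
    calibrant_fractions: tuple[float, float, float, float] = (1 / 21, 4 / 21, 6 / 21, 10 / 21)
    sample_loading_fraction: float | None = None  # default: median calibrant fraction
    class_effect_log2: float = 1.5
    stage_effect_log2: float = 1.0
    age_effect_per_year_log2: float = 0.0
    frac_regulated: float = 0.1
    noise_sd_log2: float = 0.5
    batch_offsets_log2: tuple[float, ...] | None = None  # default: +/-0.2-0.25, centred within stage
    mcar_rate: float = 0.02
    mnar_intensity_threshold: float = 2.0**14
    mnar_rate: float = 0.5
    impurity_spill: float = 0.0
    phospho_fraction: float = 0.05
    shared_peptide_fraction: float = 0.05
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    ionisation_sd_log2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")
        if self.n_plexes < 1:
            raise ValueError("need at least one plex")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("peptides_per_protein must be a valid range >= 1")
        lo, hi = self.psms_per_peptide
        if not (1 <= lo <= hi):
            raise ValueError("psms_per_peptide must be a valid range >= 1")
        fr = np.asarray(self.calibrant_fractions, float)
        if len(fr) != 4 or (fr <= 0).any() or not (np.diff(fr) > 0).all():
            raise ValueError("calibrant fractions must be 4 strictly positive, strictly increasing values")
        if fr.sum() > 1 + 1e-12:
            raise ValueError("calibrant fractions must sum to <= 1")
        for name in ("frac_regulated", "mcar_rate", "mnar_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if not 0 <= self.impurity_spill < 0.5:
            raise ValueError("impurity_spill must lie in [0, 0.5)")
        if not 0 <= self.phospho_fraction <= 1:
            raise ValueError("phospho_fraction must lie in [0, 1]")
        if not 0 <= self.shared_peptide_fraction <= 1:
            raise ValueError("shared_peptide_fraction must lie in [0, 1]")
        if self.sample_channels_per_plex < 2 or self.sample_channels_per_plex > 6:
            raise ValueError("sample_channels_per_plex must lie in [2, 6]")
        if self.batch_offsets_log2 is not None and len(self.batch_offsets_log2) != self.n_plexes:
            raise ValueError("batch_offsets_log2 needs one value per plex")
        if self.frac_regulated > 0:
            for name in ("class_effect_log2", "stage_effect_log2"):
                if 0 < abs(getattr(self, name)) < np.log2(1.3):
                    raise ValueError(
                        f"{name} below the log2(1.3) regulation floor; regulated genes "
                        "must carry |log2 FC| >= log2(1.3)"
                    )

    @property
    def resolved_batch_offsets(self) -> np.ndarray:
        if self.batch_offsets_log2 is not None:
            return np.asarray(self.batch_offsets_log2, float)
        # default offsets are centred within each disease stage: with plexes
        # nested in stage, a between-stage mean offset is confounded with the
        # stage effect and no correction could identify it
        base = np.array([0.2, -0.2, -0.25, 0.25])
        reps = int(np.ceil(self.n_plexes / 4))
        return np.tile(base, reps)[: self.n_plexes]

    @property
    def resolved_sample_loading(self) -> float:
        if self.sample_loading_fraction is not None:
            return float(self.sample_loading_fraction)
        return float(np.median(self.calibrant_fractions))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("peptides_per_protein", "psms_per_peptide", "calibrant_fractions",
                  "batch_offsets_log2"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Ledger of every injected effect, for parameter-recovery testing.

    ``genes``: per-gene true log2 fold changes (fast vs slow; late vs
    early) and regulation flags. ``peptides``: per-peptide gene mapping,
    phospho and gene-uniqueness flags. ``batch_offsets``: per-plex log2
    offsets applied to the plasma channels. ``reference_loading``: the
    calibrant-pool fraction the per-PSM reference corresponds to, so the
    designed null log2 ratio is log2(sample loading / reference loading).
    """

    genes: pd.DataFrame
    peptides: pd.DataFrame
    batch_offsets: pd.DataFrame
    sample_loading: float
    reference_loading: float
    age_effect_per_year_log2: float
    age_center_years: float

    def expected_peptide_ratios(self, design: pd.DataFrame) -> pd.DataFrame:
        """Designed (noise-free) log2 ratio for every peptide x sample."""
        pep = self.peptides
        gene_fc = self.genes.set_index("gene")
        class_fc = gene_fc.loc[pep["gene"], "class_lfc"].to_numpy()
        stage_fc = gene_fc.loc[pep["gene"], "stage_lfc"].to_numpy()
        base = np.log2(self.sample_loading / self.reference_loading)
        offsets = self.batch_offsets.set_index("plex_id")["offset_log2"]
        cols = {}
        for _, s in design.iterrows():
            val = (
                base
                + class_fc * (s["class_label"] == "fast")
                + stage_fc * (s["stage_label"] == "late")
                + self.age_effect_per_year_log2 * (s["age_years"] - self.age_center_years)
                + offsets.loc[s["plex_id"]]
            )
            cols[s["sample_id"]] = val
        return pd.DataFrame(cols, index=pep["peptide_sequence"]).rename_axis(
            "peptide_sequence"
        )


@dataclass
class SimulatedExperiment:
    """One generated experiment: PSM tables per plex, the design table and
    the ground-truth ledger."""

    psm_tables: dict[str, pd.DataFrame]
    design: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir) -> list[Path]:
        """Write plex CSVs, design, truth tables and the config YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for plex_id, table in self.psm_tables.items():
            p = outdir / f"psm_{plex_id}.csv"
            table.to_csv(p, index=False)
            written.append(p)
        p = outdir / "design.csv"
        self.design.to_csv(p, index=False)
        written.append(p)
        for name, df in (
            ("truth_genes", self.truth.genes),
            ("truth_peptides", self.truth.peptides),
            ("truth_batch_offsets", self.truth.batch_offsets),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        p = outdir / "config.yaml"
        self.config.to_yaml(p)
        written.append(p)
        return written


def _random_peptides(rng: np.random.Generator, n: int) -> list[str]:
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(8, 15))
        s = "".join(rng.choice(_AMINO_ACIDS, size=length))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


def generate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate PSM tables, a design table and the ground truth.

    Intensity model per PSM row and channel, on the log2 scale:
    protein baseline + peptide ionisation efficiency + log2(channel
    loading) + (plasma channels only) injected covariate effects and the
    plex batch offset + Gaussian noise; then reporter cross-talk mixing
    and missingness thinning. Identical config (including seed) gives
    bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    genes = [f"GENE{i:04d}" for i in range(cfg.n_proteins)]
    n_reg = int(round(cfg.frac_regulated * cfg.n_proteins))
    if 2 * n_reg > cfg.n_proteins:
        raise ValueError("frac_regulated too large for disjoint class/stage sets")
    perm = rng.permutation(cfg.n_proteins)
    class_idx, stage_idx = perm[:n_reg], perm[n_reg : 2 * n_reg]
    class_lfc = np.zeros(cfg.n_proteins)
    stage_lfc = np.zeros(cfg.n_proteins)
    class_lfc[class_idx] = rng.choice([-1.0, 1.0], n_reg) * cfg.class_effect_log2
    stage_lfc[stage_idx] = rng.choice([-1.0, 1.0], n_reg) * cfg.stage_effect_log2
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_proteins)

    pep_counts = rng.integers(
        cfg.peptides_per_protein[0], cfg.peptides_per_protein[1] + 1, cfg.n_proteins
    )
    n_peptides = int(pep_counts.sum())
    sequences = _random_peptides(rng, n_peptides)
    pep_gene_idx = np.repeat(np.arange(cfg.n_proteins), pep_counts)
    is_phospho = rng.random(n_peptides) < cfg.phospho_fraction
    is_unique = rng.random(n_peptides) >= cfg.shared_peptide_fraction
    ionisation = rng.normal(0.0, cfg.ionisation_sd_log2, n_peptides)

    gene_truth = pd.DataFrame(
        {
            "gene": genes,
            "baseline_log2": baseline,
            "class_lfc": class_lfc,
            "stage_lfc": stage_lfc,
            "regulated_class": class_lfc != 0,
            "regulated_stage": stage_lfc != 0,
        }
    )
    pep_truth = pd.DataFrame(
        {
            "peptide_sequence": sequences,
            "gene": [genes[i] for i in pep_gene_idx],
            "is_phospho": is_phospho,
            "is_unique_gene_match": is_unique,
            "ionisation_log2": ionisation,
        }
    )

    offsets = cfg.resolved_batch_offsets
    n_fast = cfg.sample_channels_per_plex // 2
    age_center = 60.0
    impurity = (
        ImpurityMatrix.from_spill(cfg.impurity_spill)
        if cfg.impurity_spill > 0
        else ImpurityMatrix.identity()
    )
    f_load = cfg.resolved_sample_loading
    calib = np.asarray(cfg.calibrant_fractions, float)

    design_rows = []
    psm_tables: dict[str, pd.DataFrame] = {}
    for p in range(cfg.n_plexes):
        plex_id = f"plex{p + 1}"
        stage = "early" if p < cfg.n_plexes / 2 else "late"
        classes = ["fast"] * n_fast + ["slow"] * (cfg.sample_channels_per_plex - n_fast)
        # random channel assignment avoids systematic channel/class confounding
        channels = list(rng.permutation(SAMPLE_CHANNELS[: cfg.sample_channels_per_plex]))
        sample_effects = []
        for k, (cls, ch) in enumerate(zip(classes, channels)):
            subj = draw_subject(rng, cls, stage)
            sid = f"{plex_id}_{ch}"
            design_rows.append(
                {
                    "sample_id": sid,
                    "plex_id": plex_id,
                    "channel": ch,
                    "class_label": cls,
                    "stage_label": stage,
                    "age_years": round(subj.age_years, 1),
                    "group": "ALS",
                    "batch": plex_id,
                    "alsfrs_r_last": round(subj.alsfrs_r_last, 1),
                    "months_onset_to_last_visit": round(subj.months_onset_to_last_visit, 1),
                    "prl": round(subj.prl, 3),
                }
            )
            sample_effects.append(
                (
                    ch,
                    (cls == "fast"),
                    (stage == "late"),
                    cfg.age_effect_per_year_log2 * (round(subj.age_years, 1) - age_center),
                )
            )

        n_psm = rng.integers(cfg.psms_per_peptide[0], cfg.psms_per_peptide[1] + 1, n_peptides)
        total = int(n_psm.sum())
        row_pep = np.repeat(np.arange(n_peptides), n_psm)
        row_gene = pep_gene_idx[row_pep]
        base_log2 = baseline[row_gene] + ionisation[row_pep]

        log2_int = np.empty((total, 10))
        channel_pos = {ch: i for i, ch in enumerate(CHANNELS)}
        for ch, is_fast, is_late, age_term in sample_effects:
            eff = (
                class_lfc[row_gene] * is_fast
                + stage_lfc[row_gene] * is_late
                + age_term
                + offsets[p]
            )
            log2_int[:, channel_pos[ch]] = base_log2 + np.log2(f_load) + eff
        # unused sample channels (if fewer than six) carry the null loading
        used = {ch for ch, *_ in sample_effects}
        for ch in SAMPLE_CHANNELS:
            if ch not in used:
                log2_int[:, channel_pos[ch]] = base_log2 + np.log2(f_load)
        for ch, frac in zip(CALIBRANT_CHANNELS, calib):
            log2_int[:, channel_pos[ch]] = base_log2 + np.log2(frac)
        if cfg.noise_sd_log2 > 0:
            log2_int += rng.normal(0.0, cfg.noise_sd_log2, log2_int.shape)

        intensities = 2.0**log2_int
        if not impurity.is_identity:
            intensities = impurity.apply(intensities)
        mask = rng.random(intensities.shape) < cfg.mcar_rate
        if cfg.mnar_rate > 0:
            low = intensities < cfg.mnar_intensity_threshold
            mask |= low & (rng.random(intensities.shape) < cfg.mnar_rate)
        intensities[mask] = np.nan

        table = pd.DataFrame(
            {
                "plex_id": plex_id,
                "psm_id": [f"{plex_id}_psm{j:06d}" for j in range(total)],
                "peptide_sequence": [sequences[i] for i in row_pep],
                "is_phospho": is_phospho[row_pep],
                "gene": [genes[i] for i in row_gene],
                "is_unique_gene_match": is_unique[row_pep],
            }
        )
        for i, col in enumerate(INTENSITY_COLUMNS):
            table[col] = intensities[:, i]
        psm_tables[plex_id] = table

    design = pd.DataFrame(design_rows)
    truth = GroundTruth(
        genes=gene_truth,
        peptides=pep_truth,
        batch_offsets=pd.DataFrame(
            {"plex_id": [f"plex{p + 1}" for p in range(cfg.n_plexes)], "offset_log2": offsets}
        ),
        sample_loading=f_load,
        reference_loading=float(np.median(calib)),
        age_effect_per_year_log2=cfg.age_effect_per_year_log2,
        age_center_years=age_center,
    )
    return SimulatedExperiment(psm_tables, design, truth, cfg)
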