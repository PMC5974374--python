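"""Synthetic PDX-like cohort generator with full ground truth.

Emulates the statistical structure the downstream pipeline assumes: a
cohort of patients hybridised in technical duplicate, two latent subgroups
("E2F-high" / "E2F-low") distinguished by a block of up- and down-regulated
marker transcripts, subgroup-dependent exponential survival with
independent censoring, and per-sample dose-response curves whose IC50s are
subgroup-dependent only for an E2F-inhibitor-like compound.

Expression is simulated per gene as Gaussian on the log2 scale (baseline
mean per gene, plus the configured log2 effect on markers in the relevant
subgroup, plus per-patient biological noise and per-replicate technical
noise) and exported on the linear scale (2^x), giving RMA-like strictly
positive intensities.

The default configuration mirrors a 55-patient cohort with 12 high-group
patients, 35 up- and 111 down-regulated transcripts among 1000 genes, a
1.5 log2 marker effect, and group median overall survival of 9.5 vs 16.8
months.  The first 11 up- and 13 down-markers carry the bundled 24-gene
signature's gene names, so the shipped signature applies to simulated
cohorts out of the box.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .doseresponse import dose_response_model
from .exceptions import ConfigError
from .io import ExpressionMatrix, GeneSet
from .signature import LABEL_HIGH, LABEL_LOW, bundled_signature

__all__ = [
    "DrugParams",
    "SimConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "write_cohort",
]

#: 8 half-log dose steps, 0.1 .. ~316 µM
DEFAULT_DOSES_UM = tuple(float(10.0 ** e) for e in np.arange(-1.0, 3.0, 0.5))


@dataclass(frozen=True)
class DrugParams:
    """Per-drug IC50 distribution and assay design.

    ``mean_log10_ic50`` maps subgroup label → mean log10 IC50 (µM); equal
    values make the drug subgroup-independent (a cytotoxic), unequal values
    an E2F-inhibitor-like compound.
    """

    mean_log10_ic50: dict
    sd_log10: float = 0.1
    hill: float = 1.0
    doses_um: tuple = DEFAULT_DOSES_UM
    viability_noise_sd: float = 5.0  # % points


def _default_drugs() -> dict:
    cyto = {LABEL_HIGH: 1.0, LABEL_LOW: 1.0}  # 10 µM both groups
    return {
        "gemcitabine": DrugParams(mean_log10_ic50=dict(cyto)),
        "oxaliplatin": DrugParams(mean_log10_ic50=dict(cyto)),
        # e2f inhibitor: ~19.4 µM (high) vs ~44.1 µM (low)
        "e2f_inhibitor": DrugParams(
            mean_log10_ic50={LABEL_HIGH: float(np.log10(19.4)), LABEL_LOW: float(np.log10(44.1))}
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator configuration (defaults = the emulated study design)."""

    n_patients: int = 55
    frac_high: float = 12 / 55
    n_genes: int = 1000
    n_up_markers: int = 35
    n_down_markers: int = 111
    effect_log2: float = 1.5
    noise_sd: float = 0.4
    duplicate_sd: float = 0.15
    os_median_high: float = 9.5
    os_median_low: float = 16.8
    rfs_median_high: float = 6.0
    rfs_median_low: float = 10.6
    censor_rate: float = 0.2
    ic50_params: dict = field(default_factory=_default_drugs)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_genes, self.n_up_markers, self.n_down_markers) < 1:
            raise ConfigError("all counts must be ≥ 1")
        if not 0 < self.frac_high < 1:
            raise ConfigError("frac_high must lie in (0,1)")
        if self.effect_log2 < 0:
            raise ConfigError("effect_log2 must be ≥ 0")
        if min(self.os_median_high, self.os_median_low,
               self.rfs_median_high, self.rfs_median_low) <= 0:
            raise ConfigError("survival medians must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must lie in [0,1)")
        if self.noise_sd < 0 or self.duplicate_sd < 0:
            raise ConfigError("noise SDs must be ≥ 0")
        if self.n_up_markers + self.n_down_markers > self.n_genes:
            raise ConfigError("markers cannot outnumber genes")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Latent labels behind a simulated cohort."""

    sample_labels: pd.Series  # sample → E2F-high / E2F-low
    gene_roles: pd.Series  # gene → up / down / null
    true_log10_ic50: pd.DataFrame  # sample x drug

    def __post_init__(self) -> None:
        if self.sample_labels.index.has_duplicates or self.gene_roles.index.has_duplicates:
            raise ConfigError("ground truth labels must be unique per sample/gene")


@dataclass
class SimulatedCohort:
    """Bundle of everything one simulation run produces."""

    config: SimConfig
    expression: ExpressionMatrix  # linear scale, duplicate columns <sid>_rep1/2
    pairing: dict  # replicate column → sample
    samples: pd.DataFrame  # annotations incl. survival + truth_label
    truth: GroundTruth
    responses: pd.DataFrame  # sample_id, drug, dose_uM, viability_pct, replicate
    gene_set: GeneSet  # the simulated E2F-target set (all up markers)


def _marker_names(n: int, base_names: tuple, prefix: str) -> list[str]:
    names = list(base_names[:n])
    names += [f"{prefix}{i:04d}" for i in range(len(names) + 1, n + 1)]
    return names


def _exponential_with_censoring(
    rng: np.random.Generator, n: int, median: float, censor_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Event times ~ Exp(ln2/median); independent exponential censoring whose
    rate is set so the expected censored fraction equals censor_rate."""
    lam = np.log(2.0) / median
    t_event = rng.exponential(1.0 / lam, size=n)
    if censor_rate == 0:
        return t_event, np.ones(n, dtype=int)
    mu = lam * censor_rate / (1.0 - censor_rate)
    t_cens = rng.exponential(1.0 / mu, size=n)
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return observed, event


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Generate a fully labeled synthetic cohort (byte-identical per seed)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    n_high = max(1, int(round(cfg.n_patients * cfg.frac_high)))
    n_high = min(n_high, cfg.n_patients - 1)
    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_patients)]
    labels = np.array([LABEL_HIGH] * n_high + [LABEL_LOW] * (cfg.n_patients - n_high))
    rng.shuffle(labels)
    sample_labels = pd.Series(labels, index=sample_ids, name="truth_label")

    sig = bundled_signature()
    up_names = _marker_names(cfg.n_up_markers, sig.up_genes, "UPMK")
    down_names = _marker_names(cfg.n_down_markers, sig.down_genes, "DNMK")
    n_null = cfg.n_genes - cfg.n_up_markers - cfg.n_down_markers
    null_names = [f"G{i:05d}" for i in range(1, n_null + 1)]
    gene_ids = up_names + down_names + null_names
    roles = pd.Series(
        ["up"] * len(up_names) + ["down"] * len(down_names) + ["null"] * len(null_names),
        index=gene_ids,
        name="role",
    )

    baseline = rng.normal(8.0, 1.5, size=cfg.n_genes)
    high = (sample_labels == LABEL_HIGH).to_numpy()
    shift = np.zeros((cfg.n_genes, cfg.n_patients))
    shift[: cfg.n_up_markers, high] = cfg.effect_log2
    shift[cfg.n_up_markers: cfg.n_up_markers + cfg.n_down_markers, ~high] = cfg.effect_log2
    log2_true = baseline[:, None] + shift + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_patients)
    )

    rep_cols: list[str] = []
    rep_vals = np.empty((cfg.n_genes, 2 * cfg.n_patients))
    pairing: dict = {}
    for j, sid in enumerate(sample_ids):
        for r in (1, 2):
            col = f"{sid}_rep{r}"
            rep_cols.append(col)
            pairing[col] = sid
            rep_vals[:, 2 * j + (r - 1)] = log2_true[:, j] + rng.normal(
                0.0, cfg.duplicate_sd, size=cfg.n_genes
            )
    expression = ExpressionMatrix(
        pd.DataFrame(np.exp2(rep_vals), index=gene_ids, columns=rep_cols), scale="linear"
    )

    # survival (per-subgroup exponential; censoring independent of event time)
    os_t = np.empty(cfg.n_patients)
    os_e = np.empty(cfg.n_patients, dtype=int)
    rfs_t = np.empty(cfg.n_patients)
    rfs_e = np.empty(cfg.n_patients, dtype=int)
    for is_high, os_med, rfs_med in (
        (True, cfg.os_median_high, cfg.rfs_median_high),
        (False, cfg.os_median_low, cfg.rfs_median_low),
    ):
        mask = high if is_high else ~high
        k = int(mask.sum())
        os_t[mask], os_e[mask] = _exponential_with_censoring(rng, k, os_med, cfg.censor_rate)
        rfs_t[mask], rfs_e[mask] = _exponential_with_censoring(rng, k, rfs_med, cfg.censor_rate)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "os_months": np.round(os_t, 3),
            "os_event": os_e,
            "rfs_months": np.round(rfs_t, 3),
            "rfs_event": rfs_e,
            "truth_label": labels,
        }
    )

    # chemograms
    resp_rows = []
    true_ic50 = pd.DataFrame(index=sample_ids, columns=list(cfg.ic50_params), dtype=float)
    for drug, dp in cfg.ic50_params.items():
        for sid in sample_ids:
            grp = sample_labels[sid]
            li = rng.normal(dp.mean_log10_ic50[grp], dp.sd_log10)
            true_ic50.loc[sid, drug] = li
            doses = np.asarray(dp.doses_um, dtype=float)
            clean = dose_response_model(doses, li, dp.hill)
            noisy = clean + rng.normal(0.0, dp.viability_noise_sd, size=doses.size)
            for d, v in zip(doses, noisy):
                resp_rows.append((sid, drug, float(d), float(v), 1))
    responses = pd.DataFrame(
        resp_rows, columns=["sample_id", "drug", "dose_uM", "viability_pct", "replicate"]
    )

    gene_set = GeneSet(
        name="SIM_E2F_TARGETS",
        description="simulated E2F-target transcripts (all up-regulated markers)",
        members=list(up_names),
    )
    return SimulatedCohort(
        config=cfg,
        expression=expression,
        pairing=pairing,
        samples=samples,
        truth=GroundTruth(
            sample_labels=sample_labels, gene_roles=roles, true_log10_ic50=true_ic50
        ),
        responses=responses,
        gene_set=gene_set,
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write a simulated cohort to ``outdir`` as plain text files.

    Produces ``expression.tsv`` (with duplicate columns), ``samples.tsv``,
    ``responses.tsv`` and ``e2f_targets.gmt``; returns the path map.
    """
    from pathlib import Path

    from .io import write_gmt, write_matrix, write_samples

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "responses": outdir / "responses.tsv",
        "gene_set": outdir / "e2f_targets.gmt",
    }
    write_matrix(cohort.expression, paths["expression"])
    write_samples(cohort.samples, paths["samples"])
    cohort.responses.to_csv(paths["responses"], sep="\t", index=False, float_format="%.6g")
    write_gmt([cohort.gene_set], paths["gene_set"])
    return paths
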