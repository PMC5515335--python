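"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a trial-style breast-cancer cohort profiled on a
custom probe-count panel: four intrinsic subtypes drawn from log-normal
centroids with within-subtype noise, housekeeping probes with
subtype-independent means, Poisson negative-control background, per-sample
scaling (input-amount variation), an optional degraded fraction that fails
QC, IHC receptor labels generated by a confusion process around the true
subtype, subtype-dependent PIK3CA mutation prevalence, six TNBC
sub-populations aligned to subtype gene sets, immune-high/low strata, planted
copy-number amplifications read out through a simulated qPCR Ct matrix, and
exponential (or Weibull) disease-free survival with planted hazard ratios
and independent censoring.

A single global seed drives a hierarchy of per-stage random streams
(``numpy.random.SeedSequence``), so identical configs give byte-identical
cohorts and each stage can be re-drawn independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cna import CtTable
from .pam50 import INTRINSIC_SUBTYPES, CentroidSet
from .qcnorm import (
    PROBE_ENDOGENOUS,
    PROBE_HOUSEKEEPING,
    PROBE_NEGATIVE,
    CountMatrix,
)
from .tnbc import TNBC_SUBTYPES, GeneSetCollection

# Observed cohort composition: 327/124/69/296 luminal A / luminal B /
# HER2-enriched / basal-like of 816 confidently classified tumors.
DEFAULT_SUBTYPE_PROPORTIONS = {
    "LumA": 327 / 816,
    "LumB": 124 / 816,
    "Her2E": 69 / 816,
    "Basal": 296 / 816,
}

# PIK3CA hotspot-mutation prevalence by intrinsic subtype.
DEFAULT_PIK3CA_PREVALENCE = {
    "LumA": 0.46,
    "LumB": 0.26,
    "Her2E": 0.35,
    "Basal": 0.03,
}

# Planted prognostic contrasts (hazard ratios as reported for the cohort).
DEFAULT_HAZARD_RATIOS = {
    "lumb_vs_luma": 2.07,
    "pik3ca_mutant_hrpos": 0.66,
    "immune_high_tnbc": 0.59,
}

# P(IHC group | true subtype): luminal tumors are overwhelmingly HR+,
# basal-like tumors overwhelmingly triple-negative, HER2-enriched mixed.
DEFAULT_IHC_CONFUSION = {
    "LumA": {"HRpos": 0.924, "HER2pos": 0.046, "TNBC": 0.03},
    "LumB": {"HRpos": 0.924, "HER2pos": 0.046, "TNBC": 0.03},
    "Her2E": {"HRpos": 0.30, "HER2pos": 0.594, "TNBC": 0.106},
    "Basal": {"HRpos": 0.082, "HER2pos": 0.05, "TNBC": 0.868},
}

IHC_GROUPS = ("HRpos", "HER2pos", "TNBC")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the study conditions.

    Units: expression quantities are log2 counts; hazards are events per
    year; times are years.
    """

    n_samples: int = 600
    n_genes: int = 800
    n_housekeeping: int = 10
    n_negative_controls: int = 8
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPORTIONS)
    )
    centroid_separation: float = 2.0
    noise_sd: float = 1.0
    scale_sd: float = 0.5  # per-sample log2 scale factor (input amount)
    housekeeping_noise_sd: float = 0.2
    negative_control_mean: float = 10.0  # Poisson background
    degraded_fraction: float = 0.0
    pik3ca_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PIK3CA_PREVALENCE)
    )
    ihc_confusion: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_IHC_CONFUSION.items()}
    )
    immune_high_fraction: float = 0.5
    immune_shift: float = 2.0  # log2 up-shift of the immune panel in immune-high
    tnbc_separation: float = 2.0  # log2 up-shift of a TNBC sub-population's gene set
    hazard_ratios: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_RATIOS)
    )
    gene_hazard_ratios: dict[str, float] = field(default_factory=dict)  # per SD
    censoring_rate: float = 0.2
    baseline_hazard: float = 0.04
    follow_up_years: float = 10.0
    event_time_law: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.0
    n_cna_genes: int = 35
    n_assays_per_gene: int = 3
    cna_amplification_rate: float = 0.03  # per (sample, gene)
    cna_amplified_copies: float = 6.0
    ct_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0 or self.n_housekeeping <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_negative_controls < 2:
            raise ValueError("need at least 2 negative-control probes")
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype proportions sum to {total}, not 1")
        for name, p in {
            **self.pik3ca_prevalence,
            "immune_high_fraction": self.immune_high_fraction,
            "censoring_rate": self.censoring_rate,
            "degraded_fraction": self.degraded_fraction,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"fraction {name!r}={p} outside [0, 1]")
        for name, hr in {**self.hazard_ratios, **self.gene_hazard_ratios}.items():
            if hr <= 0:
                raise ValueError(f"hazard ratio {name!r}={hr} must be positive")
        if self.centroid_separation < 0:
            raise ValueError("centroid separation must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.event_time_law not in ("exponential", "weibull"):
            raise ValueError("event_time_law must be exponential or weibull")


@dataclass
class GenePanel:
    """Partition of the endogenous genes into functional blocks."""

    classifier: list[str]
    immune: list[str]
    tnbc_blocks: dict[str, list[str]]
    background: list[str]

    @property
    def all_genes(self) -> list[str]:
        out = list(self.classifier) + list(self.immune)
        for block in self.tnbc_blocks.values():
            out.extend(block)
        out.extend(self.background)
        return out

    @property
    def tnbc_signature(self) -> list[str]:
        return [g for block in self.tnbc_blocks.values() for g in block]


@dataclass
class SyntheticCohort:
    """Everything one run of the generator produced, ground truth included."""

    counts: CountMatrix
    annotation: pd.DataFrame
    truth: pd.DataFrame
    centroids: CentroidSet
    panel: GenePanel
    genesets: GeneSetCollection
    copy_number: pd.DataFrame
    ct: CtTable
    log2_true: pd.DataFrame  # biological log2 signal before scaling/rounding
    config: SimulationConfig

    def __post_init__(self) -> None:
        samples = self.counts.counts.index
        if not self.truth.index.equals(samples) or self.truth.index.has_duplicates:
            raise ValueError("truth must cover every sample exactly once")


def build_gene_panel(config: SimulationConfig) -> GenePanel:
    """Carve the endogenous genes into classifier / immune / TNBC / background.

    Default sizes follow the panel design: 50 subtype-classifier genes, 88
    immune genes, 6 x 25 TNBC-subtype genes; smaller panels shrink the later
    blocks first.
    """
    n = config.n_genes
    n_classifier = min(50, n)
    n_immune = min(88, n - n_classifier)
    n_tnbc = min(150, n - n_classifier - n_immune)
    per_block = n_tnbc // len(TNBC_SUBTYPES)
    classifier = [f"PAM_{i + 1:03d}" for i in range(n_classifier)]
    immune = [f"IMM_{i + 1:03d}" for i in range(n_immune)]
    blocks = {
        s: [f"TNBC_{s}_{i + 1:02d}" for i in range(per_block)] for s in TNBC_SUBTYPES
    } if per_block > 0 else {}
    used = n_classifier + n_immune + per_block * len(blocks)
    background = [f"GENE_{i + 1:04d}" for i in range(n - used)]
    return GenePanel(
        classifier=classifier, immune=immune, tnbc_blocks=blocks, background=background
    )


def build_centroids(
    panel: GenePanel, config: SimulationConfig, rng: np.random.Generator
) -> CentroidSet:
    """Subtype centroids over the classifier genes.

    Every gene gets a base log2 level ~ Uniform(5, 10); classifier genes are
    split round-robin into one block per subtype and shifted up by
    ``centroid_separation`` log2 units in that subtype's centroid.
    """
    subtypes = list(INTRINSIC_SUBTYPES)
    base = rng.uniform(5.0, 10.0, size=len(panel.classifier))
    C = pd.DataFrame(
        np.tile(base[:, None], (1, len(subtypes))),
        index=panel.classifier,
        columns=subtypes,
    )
    for i, gene in enumerate(panel.classifier):
        C.loc[gene, subtypes[i % len(subtypes)]] += config.centroid_separation
    return CentroidSet(centroids=C)


def _choice(rng, options, p, size):
    return rng.choice(np.asarray(options, dtype=object), size=size, p=p)


def simulate_expression(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (expression, annotation, truth, CNA).

    See the module docstring for the generative model.  The survival columns
    of the annotation are drawn by :func:`simulate_survival` from the planted
    group structure.
    """
    ss = np.random.SeedSequence(config.seed)
    (
        _ss_unused,
        ss_labels,
        ss_expr,
        ss_annot,
        ss_surv,
        ss_cna,
        ss_degrade,
    ) = ss.spawn(7)
    # Panel properties (per-gene baselines, centroid shifts, housekeeping
    # means) are biology shared across cohorts, not cohort noise: they come
    # from a fixed stream so independently seeded cohorts are comparable,
    # the way two cohorts profiled on the same assay panel would be.
    rng_centroid = np.random.default_rng(np.random.SeedSequence(181059))
    rng_labels = np.random.default_rng(ss_labels)
    rng_expr = np.random.default_rng(ss_expr)
    rng_annot = np.random.default_rng(ss_annot)
    rng_degrade = np.random.default_rng(ss_degrade)

    panel = build_gene_panel(config)
    centroids = build_centroids(panel, config, rng_centroid)
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    genes = panel.all_genes

    # --- true labels -----------------------------------------------------
    subtype_names = list(config.subtype_proportions)
    props = np.array([config.subtype_proportions[s] for s in subtype_names])
    subtype = _choice(rng_labels, subtype_names, props / props.sum(), config.n_samples)
    immune_high = rng_labels.random(config.n_samples) < config.immune_high_fraction
    tnbc_sub = np.array([None] * config.n_samples, dtype=object)
    basal_mask = subtype == "Basal"
    if panel.tnbc_blocks:
        tnbc_sub[basal_mask] = _choice(
            rng_labels,
            list(panel.tnbc_blocks),
            np.full(len(panel.tnbc_blocks), 1.0 / len(panel.tnbc_blocks)),
            int(basal_mask.sum()),
        )
    degraded = rng_degrade.random(config.n_samples) < config.degraded_fraction

    # --- biological log2 signal -----------------------------------------
    base_rest = rng_centroid.uniform(5.0, 10.0, size=len(genes) - len(panel.classifier))
    base = pd.Series(
        np.concatenate(
            [centroids.centroids.iloc[:, 0].to_numpy() * 0.0, base_rest]
        ),
        index=genes,
    )
    mean = np.tile(base.to_numpy()[None, :], (config.n_samples, 1))
    gene_pos = {g: j for j, g in enumerate(genes)}
    cls_cols = [gene_pos[g] for g in panel.classifier]
    for i, s in enumerate(subtype):
        mean[i, cls_cols] = centroids.centroids[s].to_numpy()
        if immune_high[i] and panel.immune:
            for g in panel.immune:
                mean[i, gene_pos[g]] += config.immune_shift
        if tnbc_sub[i] is not None:
            for g in panel.tnbc_blocks[tnbc_sub[i]]:
                mean[i, gene_pos[g]] += config.tnbc_separation
    log2_true = pd.DataFrame(
        mean + rng_expr.normal(0.0, config.noise_sd, size=mean.shape),
        index=samples,
        columns=genes,
    )

    # --- counts ----------------------------------------------------------
    scale = rng_expr.normal(0.0, config.scale_sd, size=config.n_samples)
    endo_counts = np.round(np.power(2.0, log2_true.to_numpy() + scale[:, None]))
    hk_names = [f"HK_{i + 1:02d}" for i in range(config.n_housekeeping)]
    hk_base = rng_centroid.uniform(9.0, 12.0, size=config.n_housekeeping)
    hk_log2 = (
        hk_base[None, :]
        + scale[:, None]
        + rng_expr.normal(0.0, config.housekeeping_noise_sd, size=(config.n_samples, config.n_housekeeping))
    )
    hk_counts = np.round(np.power(2.0, hk_log2))
    neg_names = [f"NEG_{i + 1:02d}" for i in range(config.n_negative_controls)]
    neg_counts = rng_expr.poisson(
        config.negative_control_mean, size=(config.n_samples, config.n_negative_controls)
    ).astype(float)

    # Degradation collapses signal toward the control background.
    if degraded.any():
        shrink = rng_degrade.uniform(0.005, 0.05, size=int(degraded.sum()))
        lam = (
            config.negative_control_mean
            + endo_counts[degraded] * shrink[:, None]
        )
        endo_counts[degraded] = rng_degrade.poisson(lam)
        hk_lam = config.negative_control_mean + hk_counts[degraded] * shrink[:, None]
        hk_counts[degraded] = rng_degrade.poisson(hk_lam)

    counts = pd.DataFrame(
        np.hstack([endo_counts, hk_counts, neg_counts]).astype(int),
        index=samples,
        columns=genes + hk_names + neg_names,
    )
    probe_class = pd.Series(
        [PROBE_ENDOGENOUS] * len(genes)
        + [PROBE_HOUSEKEEPING] * len(hk_names)
        + [PROBE_NEGATIVE] * len(neg_names),
        index=genes + hk_names + neg_names,
    )
    count_matrix = CountMatrix(counts=counts, probe_class=probe_class)

    # --- annotation ------------------------------------------------------
    annotation = pd.DataFrame(index=pd.Index(samples, name="sample"))
    ihc = np.empty(config.n_samples, dtype=object)
    for i, s in enumerate(subtype):
        conf = config.ihc_confusion[s]
        groups = list(conf)
        ihc[i] = _choice(rng_annot, groups, np.array([conf[g] for g in groups]), 1)[0]
    er = np.where(ihc == "HRpos", "pos", "neg").astype(object)
    pr = np.where(
        (ihc == "HRpos") & (rng_annot.random(config.n_samples) < 0.7), "pos", "neg"
    ).astype(object)
    her2 = np.where(ihc == "HER2pos", "pos", "neg").astype(object)
    # half of HER2+ tumors are also ER+
    er[(ihc == "HER2pos") & (rng_annot.random(config.n_samples) < 0.5)] = "pos"
    annotation["er"], annotation["pr"], annotation["her2"] = er, pr, her2
    annotation["ihc_group"] = np.where(
        (er == "pos") | (pr == "pos"),
        np.where(her2 == "pos", "HRpos_HER2pos", "HRpos"),
        np.where(her2 == "pos", "HER2pos", "TNBC"),
    )
    mut_p = np.array([config.pik3ca_prevalence[s] for s in subtype])
    annotation["pik3ca"] = np.where(
        rng_annot.random(config.n_samples) < mut_p, "mut", "wt"
    )
    annotation["arm"] = _choice(
        rng_annot, ["control", "experimental"], np.array([0.5, 0.5]), config.n_samples
    )

    truth = pd.DataFrame(
        {
            "subtype": subtype,
            "tnbc_subtype": tnbc_sub,
            "immune_stratum": np.where(immune_high, "immune-high", "immune-low"),
            "degraded": degraded,
        },
        index=pd.Index(samples, name="sample"),
    )

    # --- survival --------------------------------------------------------
    hrpos = annotation["ihc_group"].str.startswith("HRpos").to_numpy()
    tnbc_ihc = (annotation["ihc_group"] == "TNBC").to_numpy()
    indicators = pd.DataFrame(index=annotation.index)
    for name in config.hazard_ratios:
        indicators[name] = _contrast_indicator(
            name, subtype, annotation, immune_high, hrpos, tnbc_ihc
        )
    gene_z = None
    if config.gene_hazard_ratios:
        cols = list(config.gene_hazard_ratios)
        z = log2_true[cols]
        gene_z = (z - z.mean()) / z.std(ddof=1)
    surv_cols = simulate_survival(
        indicators, config, seed_sequence=ss_surv, gene_z=gene_z
    )
    annotation = annotation.join(surv_cols)

    # --- copy number + Ct ------------------------------------------------
    rng_cna = np.random.default_rng(ss_cna)
    cna_genes = [f"CNA_{i + 1:02d}" for i in range(config.n_cna_genes)]
    copy_number = pd.DataFrame(2.0, index=annotation.index, columns=cna_genes)
    amp = rng_cna.random(copy_number.shape) < config.cna_amplification_rate
    copy_number = copy_number.mask(
        pd.DataFrame(amp, index=copy_number.index, columns=copy_number.columns),
        config.cna_amplified_copies,
    )
    ct = simulate_ct_matrix(
        copy_number,
        n_assays=config.n_assays_per_gene,
        noise_sd=config.ct_noise_sd,
        rng=rng_cna,
    )

    genesets = GeneSetCollection(
        sets={s: list(block) for s, block in panel.tnbc_blocks.items()}
    ) if panel.tnbc_blocks else GeneSetCollection(sets={"ALL": genes[:1]})

    return SyntheticCohort(
        counts=count_matrix,
        annotation=annotation,
        truth=truth,
        centroids=centroids,
        panel=panel,
        genesets=genesets,
        copy_number=copy_number,
        ct=ct,
        log2_true=log2_true,
        config=config,
    )


simulate_cohort = simulate_expression  # descriptive alias


def _contrast_indicator(name, subtype, annotation, immune_high, hrpos, tnbc_ihc):
    """Resolve a planted-contrast name to its per-sample indicator."""
    if name == "lumb_vs_luma":
        return (subtype == "LumB").astype(float)
    if name == "pik3ca_mutant":
        return (annotation["pik3ca"] == "mut").to_numpy(dtype=float)
    if name == "pik3ca_mutant_hrpos":
        return ((annotation["pik3ca"] == "mut").to_numpy() & hrpos).astype(float)
    if name == "immune_high":
        return immune_high.astype(float)
    if name == "immune_high_tnbc":
        return (immune_high & tnbc_ihc).astype(float)
    if name == "experimental_arm":
        return (annotation["arm"] == "experimental").to_numpy(dtype=float)
    raise KeyError(
        f"unknown planted contrast {name!r}; known: lumb_vs_luma, pik3ca_mutant, "
        "pik3ca_mutant_hrpos, immune_high, immune_high_tnbc, experimental_arm"
    )


def simulate_survival(
    indicators: pd.DataFrame,
    config: SimulationConfig,
    seed_sequence: np.random.SeedSequence | None = None,
    gene_z: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw DFS times from proportional hazards over the planted groups.

    Each sample's hazard is ``baseline_hazard`` times the product of the
    planted hazard ratios for the groups it belongs to (columns of
    ``indicators``, 0/1) and, optionally, per-gene ratios raised to the
    sample's standardized expression.  Event times are exponential by
    default or Weibull (proportional-hazards parameterization) when
    configured; censoring is an independent exponential clocked to hit the
    configured censoring fraction, truncated at the follow-up horizon.
    """
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(config.seed).spawn(5)[4]
    rng = np.random.default_rng(seed_sequence)
    n = len(indicators)
    log_hr = np.zeros(n)
    for name in indicators.columns:
        if name not in config.hazard_ratios:
            raise KeyError(f"no planted hazard ratio for contrast {name!r}")
        log_hr += np.log(config.hazard_ratios[name]) * indicators[name].to_numpy(
            dtype=float
        )
    if gene_z is not None:
        for gene in gene_z.columns:
            log_hr += np.log(config.gene_hazard_ratios[gene]) * gene_z[
                gene
            ].to_numpy(dtype=float)
    hazard = config.baseline_hazard * np.exp(log_hr)

    unit_exp = rng.exponential(1.0, size=n)
    if config.event_time_law == "weibull":
        event_time = np.power(unit_exp, 1.0 / config.weibull_shape) / np.power(
            hazard, 1.0 / config.weibull_shape
        )
    else:
        event_time = unit_exp / hazard

    if config.censoring_rate >= 1.0:
        censor_time = np.zeros(n)
    elif config.censoring_rate <= 0.0:
        censor_time = np.full(n, np.inf)
    else:
        c_rate = config.baseline_hazard * config.censoring_rate / (
            1.0 - config.censoring_rate
        )
        censor_time = rng.exponential(1.0 / c_rate, size=n)
    censor_time = np.minimum(censor_time, config.follow_up_years)

    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {"dfs_years": time, "dfs_event": event}, index=indicators.index
    )


def simulate_ct_matrix(
    copy_numbers: pd.DataFrame,
    n_assays: int = 3,
    noise_sd: float = 0.2,
    assay_offset_loc: float = 25.0,
    assay_offset_sd: float = 2.0,
    sample_offset_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CtTable:
    """qPCR Ct readout of a true copy-number profile.

    ``Ct(sample, assay) = assay_offset + sample_offset - log2(copy_number)
    + noise``: amplified genes show up as *lower* Ct.  Each gene gets
    ``n_assays`` independent assays (the panel design runs three per gene).
    """
    if n_assays < 1:
        raise ValueError("need at least one assay per gene")
    cn = copy_numbers.to_numpy(dtype=float)
    if (cn <= 0).any():
        raise ValueError("copy numbers must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    genes = list(copy_numbers.columns)
    assay_ids, assay_gene = [], []
    for g in genes:
        for a in range(n_assays):
            assay_ids.append(f"{g}_a{a + 1}")
            assay_gene.append(g)
    assay_offsets = rng.normal(assay_offset_loc, assay_offset_sd, size=len(assay_ids))
    sample_offsets = rng.normal(0.0, sample_offset_sd, size=cn.shape[0])
    log2cn = np.log2(cn)
    ct = np.empty((cn.shape[0], len(assay_ids)))
    for j, g in enumerate(assay_gene):
        gi = genes.index(g)
        ct[:, j] = (
            assay_offsets[j]
            + sample_offsets
            - log2cn[:, gi]
            + rng.normal(0.0, noise_sd, size=cn.shape[0])
        )
    return CtTable(
        ct=pd.DataFrame(ct, index=copy_numbers.index, columns=assay_ids),
        assay_map=pd.Series(assay_gene, index=assay_ids),
    )


def simulate_recurrence_cohort(
    n_samples: int = 400,
    n_genes: int = 800,
    n_prognostic: int = 35,
    log2_shift: float = 1.0,
    early_fraction: float = 0.125,
    noise_sd: float = 1.0,
    horizon: float = 5.0,
    follow_up_years: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Expression + survival cohort with genes tied to 5-year recurrence.

    A fraction ``early_fraction`` of patients recurs within the horizon (the
    observed proportion in the HR+ subgroup was 49/391); the first
    ``n_prognostic`` genes are expressed ``log2_shift`` units *higher* in
    long-term event-free patients (protective orientation).  Returns
    ``(expr, survival_table, prognostic_genes)``.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE_{i + 1:04d}" for i in range(n_genes)]
    prognostic = genes[:n_prognostic]
    samples = [f"V{i + 1:04d}" for i in range(n_samples)]
    early = rng.random(n_samples) < early_fraction
    if early.all() or not early.any():
        raise ValueError("degenerate early/late split; adjust early_fraction or n")
    base = rng.uniform(5.0, 10.0, size=n_genes)
    mean = np.tile(base[None, :], (n_samples, 1))
    mean[~early, :n_prognostic] += log2_shift
    expr = pd.DataFrame(
        mean + rng.normal(0.0, noise_sd, size=mean.shape), index=samples, columns=genes
    )
    time = np.where(
        early,
        rng.uniform(0.2, horizon, size=n_samples),
        rng.uniform(horizon + 0.01, follow_up_years, size=n_samples),
    )
    surv_table = pd.DataFrame(
        {"dfs_years": time, "dfs_event": early.astype(int)},
        index=pd.Index(samples, name="sample"),
    )
    return expr, surv_table, prognostic
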