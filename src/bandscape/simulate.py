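"""Synthetic cohort generator.

Emits cohorts carrying the statistical structure every downstream stage
assumes, so the whole pipeline is testable offline:

* segmental copy-number profiles over a toy genome, with optional
  within-band breakpoints (mixed gene values inside one band, the situation
  an "ambiguous" band call flags),
* mutation features planted at a chosen odds ratio against the anchor-band
  loss event,
* dosage-coupled expression (cis effect per CN step) plus trans effects in
  anchor-loss samples,
* bulk mixtures generated exactly as ``P = SM . beta + eps`` with
  Dirichlet-distributed fractions and Gaussian noise,
* drug log10 IC50 shifted by planted feature effects,
* exponential (proportional-hazards) survival with independent censoring.

Determinism: one global seed is expanded into per-stage child seeds via
``numpy.random.SeedSequence.spawn`` with a fixed stage order, so identical
seeds give bit-identical outputs and changing one stage's parameters never
perturbs another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import (
    CohortBundle,
    CohortTable,
    DrugResponseTable,
    ExpressionMatrix,
    FeatureMatrix,
    GeneCNMatrix,
    GenomeAnnotation,
    MutationTable,
    SignatureMatrix,
)
from .errors import ConfigError

CN_STATES = np.array([-2, -1, 0, 1, 2])

# fixed stage order for child-seed derivation; never reorder
_STAGES = (
    "subtypes",
    "cn",
    "mutations",
    "expression",
    "mixtures",
    "drugs",
    "survival",
)

# rough PAM50 composition of an unselected breast-tumor cohort
_PAM50_LEVELS = ("LumA", "LumB", "Her2", "Basal", "Normal")
_PAM50_PROBS = (0.45, 0.20, 0.10, 0.18, 0.07)


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Expand one global seed into independent per-stage generators."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PlantedAssociation:
    """A binary feature planted at a given odds ratio against the anchor."""

    feature_id: str
    kind: str  # mutation | band_loss | band_gain
    odds_ratio: float
    prevalence: float

    def __post_init__(self) -> None:
        if self.kind not in ("mutation", "band_loss", "band_gain"):
            raise ConfigError(f"unknown planted-feature kind {self.kind!r}")
        if self.odds_ratio <= 0:
            raise ConfigError("odds_ratio must be > 0")
        if not 0 <= self.prevalence < 1:
            raise ConfigError("prevalence must be in [0, 1)")


@dataclass(frozen=True)
class GenomeConfig:
    n_chroms: int = 4
    bands_per_chrom: int = 10
    genes_per_band: int = 4

    def __post_init__(self) -> None:
        if self.genes_per_band < 1:
            raise ConfigError("genes_per_band must be >= 1")
        if self.n_chroms < 1 or self.bands_per_chrom < 1:
            raise ConfigError("genome must have >= 1 chromosome and band")


@dataclass(frozen=True)
class SegmentConfig:
    """First-order Markov segment process over bands."""

    mean_segment_length: float = 4.0  # bands
    state_probs: tuple[float, ...] = (0.01, 0.22, 0.60, 0.15, 0.02)  # P(-2..+2)
    breakpoint_rate: float = 0.02  # per band per sample

    def __post_init__(self) -> None:
        if self.mean_segment_length < 1:
            raise ConfigError("mean_segment_length must be >= 1 band")
        p = np.asarray(self.state_probs, dtype=float)
        if len(p) != 5 or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ConfigError("state_probs must be 5 non-negative values summing to 1")
        if not 0 <= self.breakpoint_rate <= 1:
            raise ConfigError("breakpoint_rate must be in [0, 1]")


@dataclass(frozen=True)
class ExpressionConfig:
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    cis_effect: float = 0.5  # expression units per CN step
    n_trans_genes: int = 10
    trans_effect: float = 1.0  # shift in anchor-loss samples, in noise sds
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ConfigError("standard deviations must be non-negative")


@dataclass(frozen=True)
class MixtureConfig:
    n_cell_types: int = 5
    n_genes: int = 200
    dirichlet_concentration: float = 1.0
    noise_sd: float = 0.05  # eps in P = SM . beta + eps
    n_signature_matrices: int = 10
    sm_noise_sd: float = 0.1  # perturbation of the ensemble SMs
    # default: a modest macrophage-like increase in anchor-loss samples
    shift_cell_type: int | None = 0  # index of type shifted in loss samples
    shift_amount: float = 0.08

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.sm_noise_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        if self.n_cell_types < 2:
            raise ConfigError("need >= 2 cell types")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be > 0")


@dataclass(frozen=True)
class DrugConfig:
    n_cell_lines: int = 50
    n_drugs: int = 300
    screens: tuple[str, ...] = ("S1", "S2")
    n_features: int = 20
    feature_prevalence: float = 0.5
    # (feature_id, drug, screen_id, effect on log10 IC50); negative = sensitivity.
    # Default: the anchor loss sensitises to a few drugs, one of them
    # replicated across both screens (the BCL2-inhibitor pattern).
    planted_effects: tuple[tuple[str, str, str, float], ...] = (
        ("ANCHOR_LOSS", "D001", "S1", -1.5),
        ("ANCHOR_LOSS", "D001", "S2", -1.5),
        ("ANCHOR_LOSS", "D002", "S1", -1.2),
        ("ANCHOR_LOSS", "D003", "S2", -1.0),
    )
    residual_sd: float = 0.5
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0 or self.baseline_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        if not 0 < self.feature_prevalence < 1:
            raise ConfigError("feature_prevalence must be in (0, 1)")


@dataclass(frozen=True)
class SurvivalConfig:
    baseline_hazard: float = 0.015  # events per month
    hazard_ratio: float = 2.0  # anchor-loss vs neutral
    censoring_rate: float = 0.008  # independent exponential censoring

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.censoring_rate < 0:
            raise ConfigError("hazard rates must be positive")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_samples: int = 500
    anchor_band: str | None = None  # default: middle band of the toy genome
    anchor_loss_prevalence: float = 0.44
    # per-subtype loss prevalence; the defaults average to ~0.44 under the
    # default PAM50 mix, with the loss enriched outside luminal A tumors
    subtype_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "LumA": 0.35,
            "LumB": 0.55,
            "Her2": 0.55,
            "Basal": 0.55,
            "Normal": 0.30,
        }
    )
    pathogenic_carrier_fraction: float = 0.008
    background_mutation_genes: int = 20
    background_mutation_prevalence: float = 0.05
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    segments: SegmentConfig = field(default_factory=SegmentConfig)
    # default planted associations mirror the consistent cohort findings:
    # a strongly co-occurring mutation and two mutually exclusive ones
    planted: tuple[PlantedAssociation, ...] = (
        PlantedAssociation("TP53", "mutation", 3.0, 0.35),
        PlantedAssociation("PIK3CA", "mutation", 0.35, 0.35),
        PlantedAssociation("MAP3K1", "mutation", 0.35, 0.08),
    )
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    mixtures: MixtureConfig = field(default_factory=MixtureConfig)
    drugs: DrugConfig = field(default_factory=DrugConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.anchor_loss_prevalence < 1:
            raise ConfigError("anchor_loss_prevalence must be in [0, 1)")
        for v in self.subtype_prevalence.values():
            if not 0 <= v < 1:
                raise ConfigError("subtype prevalence values must be in [0, 1)")
        if not 0 <= self.pathogenic_carrier_fraction < 1:
            raise ConfigError("pathogenic_carrier_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Oracle values for parameter-recovery tests."""

    band_status: pd.DataFrame | None = None  # bands x samples, integer CN state
    anchor_status: pd.Series | None = None  # per-sample 0/1 (1 = loss)
    feature_log_odds: dict[str, float] = field(default_factory=dict)
    beta: pd.DataFrame | None = None  # cell types x samples
    drug_effects: tuple[tuple[str, str, str, float], ...] = ()
    hazard_ratio: float | None = None


# ---------------------------------------------------------------------------
# genome + copy number


def make_annotation(genome: GenomeConfig) -> GenomeAnnotation:
    """Build a toy genome.

    Chromosomes ``chr1..chrN``; the first half of each chromosome's bands
    are the p arm, the rest the q arm.  Genes are 10 kb, evenly spaced, and
    lie strictly inside their band.
    """
    band_bp = 1_000_000
    gene_bp = 10_000
    bands = []
    genes = []
    for c in range(1, genome.n_chroms + 1):
        chrom = f"chr{c}"
        n_p = genome.bands_per_chrom // 2
        for b in range(genome.bands_per_chrom):
            arm = "p" if b < n_p else "q"
            k = (n_p - b) if b < n_p else (b - n_p + 1)
            start = b * band_bp
            name = f"{c}{arm}{k}"
            bands.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + band_bp,
                    "band_name": name,
                    "stain": "gneg",
                }
            )
            for g in range(genome.genes_per_band):
                gs = start + 50_000 + g * (band_bp - 100_000) // max(genome.genes_per_band, 1)
                genes.append(
                    {
                        "gene_id": f"G_{name}_{g + 1}",
                        "chrom": chrom,
                        "start": gs,
                        "end": gs + gene_bp,
                    }
                )
    return GenomeAnnotation(genes=pd.DataFrame(genes), bands=pd.DataFrame(bands))


def default_anchor_band(annotation: GenomeAnnotation) -> str:
    names = annotation.band_names
    return names[len(names) // 2]


def _solve_conditional_rates(prevalence: float, odds_ratio: float, p_anchor: float) -> tuple[float, float]:
    """Rates P(feature | anchor=1), P(feature | anchor=0) matching a target
    marginal prevalence and odds ratio.  Monotone in the baseline odds, so a
    bracketed root always exists for prevalence in (0, 1)."""
    if not 0 < p_anchor < 1:
        raise ConfigError(
            "anchor must have both classes to plant an association "
            f"(anchor prevalence {p_anchor:g}); feasible prevalence range is (0, 1)"
        )

    def marginal(log_o0: float) -> float:
        o0 = np.exp(log_o0)
        p0 = o0 / (1 + o0)
        o1 = odds_ratio * o0
        p1 = o1 / (1 + o1)
        return p_anchor * p1 + (1 - p_anchor) * p0 - prevalence

    log_o0 = brentq(marginal, -50, 50, xtol=1e-13)
    o0 = np.exp(log_o0)
    p0 = o0 / (1 + o0)
    o1 = odds_ratio * o0
    return o1 / (1 + o1), p0


def simulate_cn_profiles(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    anchor_prev: np.ndarray | float | None = None,
) -> tuple[GeneCNMatrix, GenomeAnnotation, GroundTruth]:
    """Segmental CN profiles over the toy genome.

    Per sample a first-order Markov chain over bands emits one state per
    band (persistence 1 - 1/mean_segment_length); every gene in the band
    takes that state.  The anchor band is overridden by an independent
    Bernoulli loss draw at the configured prevalence, and planted band_loss
    / band_gain features override their own band conditionally on the
    anchor.  Finally, with probability ``breakpoint_rate`` a band acquires
    a state switch at a uniform random within-band gene index, producing
    mixed values (an intra-band breakpoint).
    """
    annotation = make_annotation(cfg.genome)
    anchor = cfg.anchor_band or default_anchor_band(annotation)
    band_names = annotation.band_names
    if anchor not in band_names:
        raise ConfigError(f"anchor band {anchor!r} not in genome")
    n = cfg.n_samples
    g = cfg.genome.genes_per_band
    n_bands = len(band_names)
    if anchor_prev is None:
        anchor_prev = cfg.anchor_loss_prevalence
    prev = np.broadcast_to(np.asarray(anchor_prev, dtype=float), (n,)).copy()

    p_stay = 1.0 - 1.0 / cfg.segments.mean_segment_length
    probs = np.asarray(cfg.segments.state_probs)

    # Markov chain over bands, vectorized across samples
    states = np.empty((n_bands, n), dtype=int)
    chrom_of_band = dict(
        zip(annotation.bands["band_name"], annotation.bands["chrom"])
    )
    prev_chrom = None
    draw_state = lambda size: rng.choice(CN_STATES, size=size, p=probs)  # noqa: E731
    for b, name in enumerate(band_names):
        chrom = chrom_of_band[name]
        if chrom != prev_chrom:
            states[b] = draw_state(n)  # chain restarts at each chromosome
        else:
            stay = rng.random(n) < p_stay
            fresh = draw_state(n)
            states[b] = np.where(stay, states[b - 1], fresh)
        prev_chrom = chrom

    # anchor override: Bernoulli loss at the configured prevalence
    a_idx = band_names.index(anchor)
    anchor_loss = (rng.random(n) < prev).astype(int)
    states[a_idx] = np.where(anchor_loss == 1, -1, 0)

    truth = GroundTruth(anchor_status=pd.Series(anchor_loss, index=_sample_ids(n)))

    # planted CNA features override their band conditionally on the anchor
    pa = float(anchor_loss.mean())
    for feat in cfg.planted:
        if feat.kind == "mutation":
            continue
        if feat.feature_id not in band_names:
            raise ConfigError(f"planted CNA feature {feat.feature_id!r} is not a band")
        if feat.prevalence == 0:
            present = np.zeros(n, dtype=bool)
            truth.feature_log_odds[feat.feature_id] = np.log2(feat.odds_ratio)
        else:
            p1, p0 = _solve_conditional_rates(feat.prevalence, feat.odds_ratio, pa)
            u = rng.random(n)
            present = np.where(anchor_loss == 1, u < p1, u < p0)
            truth.feature_log_odds[feat.feature_id] = np.log2(feat.odds_ratio)
        value = -1 if feat.kind == "band_loss" else 1
        states[band_names.index(feat.feature_id)] = np.where(present, value, 0)

    truth.band_status = pd.DataFrame(
        states.copy(), index=pd.Index(band_names, name="band"), columns=_sample_ids(n)
    )

    # expand band states to genes, then insert within-band breakpoints
    values = np.repeat(states, g, axis=0).astype(float)  # genes x samples (band order)
    if cfg.segments.breakpoint_rate > 0 and g >= 2:
        brk = rng.random((n_bands, n)) < cfg.segments.breakpoint_rate
        for b in range(n_bands):
            hit = np.nonzero(brk[b])[0]
            if hit.size == 0:
                continue
            splits = rng.integers(1, g, size=hit.size)
            cur = states[b, hit]
            # switch to a uniformly drawn different state
            offs = rng.integers(1, 5, size=hit.size)
            new = CN_STATES[(np.searchsorted(CN_STATES, cur) + offs) % 5]
            for s, split, v in zip(hit, splits, new):
                values[b * g + split : (b + 1) * g, s] = v

    gene_order = [
        f"G_{name}_{k + 1}" for name in band_names for k in range(g)
    ]
    cn = GeneCNMatrix(
        pd.DataFrame(values, index=pd.Index(gene_order, name="gene_id"), columns=_sample_ids(n))
    )
    return cn, annotation, truth


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# mutations


def simulate_mutations(
    cfg: SimulationConfig,
    anchor_status: pd.Series,
    rng: np.random.Generator,
    annotation: GenomeAnnotation | None = None,
    truth: GroundTruth | None = None,
) -> MutationTable:
    """Mutation table with planted anchor associations.

    Each planted mutation feature is drawn from the 2x2 distribution implied
    by its (marginal prevalence, odds ratio vs anchor); non-planted
    background genes are independent of the anchor.  A configurable
    fraction of samples carries a pathogenic mutation in the first
    anchor-band gene (the RB1-like exclusion target).
    """
    samples = list(anchor_status.index)
    a = anchor_status.to_numpy()
    n = len(samples)
    pa = float(a.mean())
    records: list[dict] = []

    for feat in cfg.planted:
        if feat.kind != "mutation":
            continue
        if feat.prevalence == 0:
            if truth is not None:
                truth.feature_log_odds[feat.feature_id] = np.log2(feat.odds_ratio)
            continue
        p1, p0 = _solve_conditional_rates(feat.prevalence, feat.odds_ratio, pa)
        u = rng.random(n)
        present = np.where(a == 1, u < p1, u < p0)
        if truth is not None:
            truth.feature_log_odds[feat.feature_id] = np.log2(feat.odds_ratio)
        for s in np.nonzero(present)[0]:
            records.append(
                {
                    "sample_id": samples[s],
                    "gene_id": feat.feature_id,
                    "mutation_class": "missense",
                    "pathogenic": False,
                }
            )

    for b in range(cfg.background_mutation_genes):
        gene = f"BG{b + 1:03d}"
        present = rng.random(n) < cfg.background_mutation_prevalence
        for s in np.nonzero(present)[0]:
            records.append(
                {
                    "sample_id": samples[s],
                    "gene_id": gene,
                    "mutation_class": "missense",
                    "pathogenic": False,
                }
            )

    if cfg.pathogenic_carrier_fraction > 0 and annotation is not None:
        anchor = cfg.anchor_band or default_anchor_band(annotation)
        tsg = f"G_{anchor}_1"
        carriers = rng.random(n) < cfg.pathogenic_carrier_fraction
        for s in np.nonzero(carriers)[0]:
            records.append(
                {
                    "sample_id": samples[s],
                    "gene_id": tsg,
                    "mutation_class": "nonsense",
                    "pathogenic": True,
                }
            )

    df = pd.DataFrame(
        records, columns=["sample_id", "gene_id", "mutation_class", "pathogenic"]
    )
    return MutationTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    cfg: SimulationConfig,
    cn: GeneCNMatrix,
    anchor_status: pd.Series,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Dosage-coupled expression: baseline + cis_effect x CN + trans + noise.

    Trans genes (``TRANS_###``) shift by ``trans_effect x noise_sd`` in
    anchor-loss samples and have no CN coupling.
    """
    e = cfg.expression
    vals = cn.values.to_numpy(dtype=float)
    vals = np.nan_to_num(vals, nan=0.0)
    n_genes, n = vals.shape
    baseline = rng.normal(e.baseline_mean, e.baseline_sd, size=n_genes)
    expr = baseline[:, None] + e.cis_effect * vals
    expr = expr + rng.normal(0.0, e.noise_sd, size=expr.shape)
    index = list(cn.values.index)
    if e.n_trans_genes > 0:
        a = anchor_status.reindex(cn.values.columns).to_numpy()
        tb = rng.normal(e.baseline_mean, e.baseline_sd, size=e.n_trans_genes)
        trans = (
            tb[:, None]
            + e.trans_effect * e.noise_sd * a[None, :]
            + rng.normal(0.0, e.noise_sd, size=(e.n_trans_genes, n))
        )
        expr = np.vstack([expr, trans])
        index = index + [f"TRANS_{k + 1:03d}" for k in range(e.n_trans_genes)]
    df = pd.DataFrame(expr, index=pd.Index(index, name="gene_id"), columns=cn.values.columns)
    return ExpressionMatrix(df, scale_tag="raw")


# ---------------------------------------------------------------------------
# bulk mixtures


def simulate_bulk_mixtures(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    anchor_status: pd.Series | None = None,
) -> tuple[list[SignatureMatrix], ExpressionMatrix, GroundTruth]:
    """Bulk mixtures generated exactly as ``P = SM . beta + eps``.

    ``beta`` is drawn per sample from a symmetric Dirichlet; ``eps`` is iid
    Gaussian with sd ``noise_sd``.  The returned signature-matrix list holds
    ``n_signature_matrices`` noisy observations of the generating matrix
    (sd ``sm_noise_sd``), emulating an ensemble of independently derived
    references; the generating matrix itself is the first entry when
    ``sm_noise_sd == 0``.  An optional cell-type shift is added to beta in
    anchor-loss samples before renormalisation.
    """
    m = cfg.mixtures
    if anchor_status is not None:
        samples = list(anchor_status.index)
    else:
        samples = _sample_ids(cfg.n_samples)
    n = len(samples)
    types = [f"CT{k + 1}" for k in range(m.n_cell_types)]
    genes = [f"MG{i + 1:04d}" for i in range(m.n_genes)]

    sm_true = rng.gamma(shape=2.0, scale=1.0, size=(m.n_genes, m.n_cell_types))
    beta = rng.dirichlet([m.dirichlet_concentration] * m.n_cell_types, size=n).T

    if m.shift_cell_type is not None and anchor_status is not None and m.shift_amount != 0:
        a = anchor_status.reindex(samples).to_numpy()
        beta[m.shift_cell_type, :] += m.shift_amount * a
        beta = np.clip(beta, 0.0, None)
        beta = beta / beta.sum(axis=0, keepdims=True)

    p = sm_true @ beta + rng.normal(0.0, m.noise_sd, size=(m.n_genes, n))

    sms = []
    for _ in range(m.n_signature_matrices):
        if m.sm_noise_sd == 0:
            obs = sm_true.copy()
        else:
            obs = np.clip(sm_true + rng.normal(0.0, m.sm_noise_sd, sm_true.shape), 1e-9, None)
        sms.append(
            SignatureMatrix(pd.DataFrame(obs, index=pd.Index(genes, name="gene_id"), columns=types))
        )

    truth = GroundTruth(
        beta=pd.DataFrame(beta, index=pd.Index(types, name="cell_type"), columns=samples)
    )
    bulk = ExpressionMatrix(
        pd.DataFrame(p, index=pd.Index(genes, name="gene_id"), columns=samples), scale_tag="raw"
    )
    return sms, bulk, truth


# ---------------------------------------------------------------------------
# drug response


def simulate_drug_response(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    anchor_feature: str = "ANCHOR_LOSS",
) -> tuple[DrugResponseTable, FeatureMatrix, GroundTruth]:
    """Drug log10 IC50 = per-drug baseline + planted feature effects + noise.

    The feature matrix holds ``n_features`` binary genomic features at the
    configured prevalence; the first column is the anchor-loss indicator.
    Planted effects reference (feature, drug, screen) triples; a negative
    effect means lower IC50 in feature-positive lines, i.e. sensitivity.
    """
    d = cfg.drugs
    lines = [f"CL{i + 1:03d}" for i in range(d.n_cell_lines)]
    feats = [anchor_feature] + [f"F{k + 1:03d}" for k in range(d.n_features - 1)]
    fm = (rng.random((d.n_cell_lines, d.n_features)) < d.feature_prevalence).astype(int)
    fmat = FeatureMatrix(pd.DataFrame(fm, index=pd.Index(lines, name="cell_line"), columns=feats))

    drugs = [f"D{j + 1:03d}" for j in range(d.n_drugs)]
    effects: dict[tuple[str, str], dict[str, float]] = {}
    for feat, drug, screen, eff in d.planted_effects:
        if feat not in feats or drug not in drugs or screen not in d.screens:
            raise ConfigError(f"planted effect references unknown entity: {(feat, drug, screen)}")
        effects.setdefault((drug, screen), {})[feat] = eff

    records = []
    for screen in d.screens:
        baselines = rng.normal(0.0, d.baseline_sd, size=d.n_drugs)
        for j, drug in enumerate(drugs):
            shift = np.zeros(d.n_cell_lines)
            for feat, eff in effects.get((drug, screen), {}).items():
                shift += eff * fmat.values[feat].to_numpy()
            y = baselines[j] + shift + rng.normal(0.0, d.residual_sd, size=d.n_cell_lines)
            for i, line in enumerate(lines):
                records.append(
                    {"cell_line": line, "drug": drug, "screen_id": screen, "log10_ic50": y[i]}
                )
    table = DrugResponseTable(pd.DataFrame(records))
    truth = GroundTruth(drug_effects=tuple(d.planted_effects))
    return table, fmat, truth


# ---------------------------------------------------------------------------
# survival + clinical


def simulate_survival(
    cfg: SimulationConfig,
    anchor_status: pd.Series,
    rng: np.random.Generator,
    subtypes: pd.DataFrame | None = None,
) -> CohortTable:
    """Exponential survival with a proportional anchor-loss hazard.

    Event times are exponential with hazard ``baseline_hazard x HR^status``;
    censoring is an independent exponential clock.  Subtype covariates are
    attached if provided, else drawn from the default PAM50 mix.
    """
    s = cfg.survival
    samples = list(anchor_status.index)
    n = len(samples)
    a = anchor_status.to_numpy()
    hazard = s.baseline_hazard * np.where(a == 1, s.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if s.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / s.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    os_months = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    if subtypes is None:
        subtypes = draw_subtypes(samples, rng)
    rows = subtypes.copy()
    rows["os_months"] = os_months
    rows["os_event"] = os_event
    return CohortTable(rows.reset_index(drop=True))


def draw_subtypes(samples: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """PAM50 labels plus coupled ER/HER2 status for a toy cohort."""
    pam = rng.choice(_PAM50_LEVELS, size=len(samples), p=_PAM50_PROBS)
    er = np.where(np.isin(pam, ("LumA", "LumB", "Normal")), "ER+", "ER-")
    her2 = np.where(pam == "Her2", "HER2+", "HER2-")
    return pd.DataFrame({"sample_id": samples, "pam50": pam, "er": er, "her2": her2})


# ---------------------------------------------------------------------------
# whole cohort


@dataclass
class SimulatedCohort:
    bundle: CohortBundle
    truth: GroundTruth
    signature_matrices: list[SignatureMatrix]
    mixtures: ExpressionMatrix
    drug_response: DrugResponseTable
    feature_matrix: FeatureMatrix


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort: CN, mutations, expression, clinical,
    mixtures and drug response, all from one seed."""
    rngs = stage_rngs(cfg.seed)
    samples = _sample_ids(cfg.n_samples)
    subtypes = draw_subtypes(samples, rngs["subtypes"])

    if cfg.subtype_prevalence:
        prev = subtypes["pam50"].map(
            lambda p: cfg.subtype_prevalence.get(p, cfg.anchor_loss_prevalence)
        ).to_numpy(dtype=float)
    else:
        prev = cfg.anchor_loss_prevalence

    cn, annotation, truth = simulate_cn_profiles(cfg, rngs["cn"], anchor_prev=prev)
    mutations = simulate_mutations(
        cfg, truth.anchor_status, rngs["mutations"], annotation=annotation, truth=truth
    )
    expression = simulate_expression(cfg, cn, truth.anchor_status, rngs["expression"])
    sms, mixtures, mix_truth = simulate_bulk_mixtures(
        cfg, rngs["mixtures"], anchor_status=truth.anchor_status
    )
    truth.beta = mix_truth.beta
    drugs, fmat, drug_truth = simulate_drug_response(cfg, rngs["drugs"])
    truth.drug_effects = drug_truth.drug_effects
    clinical = simulate_survival(cfg, truth.anchor_status, rngs["survival"], subtypes=subtypes)
    truth.hazard_ratio = cfg.survival.hazard_ratio

    bundle = CohortBundle(
        cn=cn,
        mutations=mutations,
        clinical=clinical,
        annotation=annotation,
        expression=expression,
        provenance=[f"simulated cohort: seed={cfg.seed}, n={cfg.n_samples}"],
    )
    return SimulatedCohort(
        bundle=bundle,
        truth=truth,
        signature_matrices=sms,
        mixtures=mixtures,
        drug_response=drugs,
        feature_matrix=fmat,
    )
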