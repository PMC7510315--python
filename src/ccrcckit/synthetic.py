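"""Synthetic ccRCC-like cohort generator with known ground truth.

Every downstream stage of the pipeline (variant filtering, subtyping, immune
phenotyping, deconvolution, survival) is exercised against cohorts produced
here, where the planted structure is known exactly:

* expression cohorts whose genes carry ``k`` class-specific programs of
  configurable effect size, plus a 66-gene immune-marker axis with three
  activity tiers that is independent of the class structure;
* per-sample variant records that are a known mixture of true somatic calls,
  germline polymorphisms and technical artifacts, each kind violating a
  disjoint set of filter rules;
* bulk mixtures of reference cell-type profiles with known fractions;
* class-dependent exponential survival with right censoring.

Expression values follow a log-normal model: a per-gene baseline on the log2
scale plus additive class/tier shifts and Gaussian noise, exponentiated back
to a non-negative, right-skewed abundance scale resembling RSEM output.
Default cohort sizes mirror the study design this emulates: 55 tumors, 11
matched normals, 3 expression classes, immune tiers in roughly 17:34:4
proportion.  Effect sizes are expressed in z-units (multiples of the
log-scale noise SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .variants import VariantRecord

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "MARKER_GENES",
    "generate_expression_cohort",
    "generate_variant_records",
    "generate_mixture_profiles",
    "generate_survival",
    "default_reference_profiles",
    "DEFAULT_CELL_TYPES",
]

#: 66-gene immune-marker stand-in panel (synthetic marker ids; the real
#: pan-immune panel is supplied by the user as a gene list at analysis time).
MARKER_GENES: list[str] = [f"IMM{i:02d}" for i in range(1, 67)]

DEFAULT_CELL_TYPES = (
    "Bcells",
    "CD4_Tcells",
    "CD8_Tcells",
    "NKcells",
    "Macrophages",
    "Endothelial",
    "CAFs",
)

#: immune-tier activity over three marker-panel blocks (cytotoxic-like,
#: suppressive-like, and resting/tissue-resident markers), as multiples of
#: marker_effect_size.  Active tumors light up the first block strongly,
#: tolerant tumors the second; inactive tumors match the normal-tissue
#: distribution, which carries its own resting-immune pattern.  Mean marker
#: activity orders active > tolerant > inactive = normal, while the
#: differing patterns keep all tiers separable under correlation distance.
_TIER_PROFILES = {
    "active": (1.0, 0.4, 0.0),
    "tolerant": (0.2, 0.9, 0.0),
    "inactive": (0.0, 0.0, 0.7),
    "normal": (0.0, 0.0, 0.7),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the emulated study."""

    n_tumor: int = 55
    n_normal: int = 11
    n_genes: int = 5000
    k_classes: int = 3
    n_class_genes: int = 100  # planted DE genes per class
    class_effect_size: float = 2.0  # mean shift, z-units (log scale)
    marker_effect_size: float = 2.0
    noise_sd: float = 1.0  # log2-scale residual SD
    tier_proportions: tuple[float, ...] = (17 / 55, 34 / 55, 4 / 55)
    # variant mixture: expected records per tumor sample and kind probabilities
    mean_variants_per_sample: int = 100
    somatic_rate: float = 0.54
    germline_rate: float = 0.23
    artifact_rate: float = 0.23
    # survival: per-class event hazards (events/day) and censoring
    hazards: tuple[float, ...] = (
        np.log(2) / 2500.0,
        np.log(2) / 1230.0,
        np.log(2) / 4000.0,
    )
    censor_fraction: float = 0.2
    seed: int = 0
    #: seed for gene-level population parameters (baselines); cohorts sharing
    #: it are drawn from the same generating process and can be used as
    #: reference/query pairs.  None -> derived from ``seed``.
    population_seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_tumor, self.n_normal + 1, self.n_genes, self.n_class_genes) <= 0:
            raise ValueError("all counts must be positive (n_normal may be 0)")
        if self.k_classes < 2:
            raise ValueError("k_classes must be >= 2")
        if self.k_classes > self.n_tumor:
            raise ValueError("insufficient samples: k_classes > n_tumor")
        for name in ("somatic_rate", "germline_rate", "artifact_rate", "censor_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.somatic_rate + self.germline_rate + self.artifact_rate > 1.0 + 1e-9:
            raise ValueError("variant kind rates must sum to <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_genes < len(MARKER_GENES) + self.k_classes * self.n_class_genes:
            raise ValueError(
                "n_genes too small for the marker panel plus planted class genes"
            )


@dataclass
class CohortTruth:
    """Ground truth aligned one-to-one with the generated objects."""

    class_label: pd.Series | None = None  # sample -> 1..k (0 for normals)
    immune_tier: pd.Series | None = None  # sample -> active|tolerant|inactive|normal
    somatic_flag: list[bool] = field(default_factory=list)  # per variant record
    true_fractions: pd.DataFrame | None = None  # samples x cell types
    seed: int = 0
    class_genes: dict[int, list[str]] = field(default_factory=dict)
    marker_genes: list[str] = field(default_factory=list)


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    tumors = [f"T{i:03d}" for i in range(1, config.n_tumor + 1)]
    normals = [f"N{i:03d}" for i in range(1, config.n_normal + 1)]
    return tumors, normals


def generate_expression_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, CohortTruth]:
    """Simulate a tumor/normal expression cohort with planted structure.

    Returns the raw-scale matrix (genes x samples), a sample metadata table
    (``tissue``, ``class_label``, ``immune_tier``) and the aligned truth.
    Identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    tumors, normals = _sample_ids(config)
    samples = tumors + normals

    n_other = config.n_genes - len(MARKER_GENES)
    genes = MARKER_GENES + [f"G{i:05d}" for i in range(1, n_other + 1)]

    # round-robin class assignment shuffled once: every class is populated
    classes = np.array([(i % config.k_classes) + 1 for i in range(config.n_tumor)])
    rng.shuffle(classes)
    class_label = pd.Series(
        np.concatenate([classes, np.zeros(config.n_normal, dtype=int)]),
        index=samples,
        name="class_label",
    )

    tiers = rng.choice(
        ["active", "tolerant", "inactive"],
        size=config.n_tumor,
        p=np.asarray(config.tier_proportions) / np.sum(config.tier_proportions),
    )
    immune_tier = pd.Series(
        list(tiers) + ["normal"] * config.n_normal, index=samples, name="immune_tier"
    )

    # planted class-specific genes: disjoint blocks outside the marker panel
    class_genes = {
        c: genes[
            len(MARKER_GENES)
            + (c - 1) * config.n_class_genes : len(MARKER_GENES)
            + c * config.n_class_genes
        ]
        for c in range(1, config.k_classes + 1)
    }

    pop_seed = config.population_seed if config.population_seed is not None else config.seed
    pop_rng = np.random.default_rng(pop_seed + 10_000)
    baseline = pop_rng.normal(loc=3.0, scale=1.5, size=config.n_genes)
    log_expr = np.tile(baseline[:, None], (1, len(samples)))

    gene_pos = {g: i for i, g in enumerate(genes)}
    shift = config.class_effect_size * config.noise_sd
    for c, gset in class_genes.items():
        rows = [gene_pos[g] for g in gset]
        cols = np.flatnonzero(class_label.to_numpy() == c)
        log_expr[np.ix_(rows, cols)] += shift

    marker_rows = [gene_pos[g] for g in MARKER_GENES]
    n_mark = len(MARKER_GENES)
    loadings = pop_rng.uniform(0.7, 1.3, size=n_mark)
    block = np.minimum(np.arange(n_mark) * 3 // n_mark, 2)  # thirds of the panel
    profile = np.array(
        [[_TIER_PROFILES[t][b] for t in immune_tier] for b in (0, 1, 2)]
    )  # 3 x samples
    marker_shift = loadings[:, None] * profile[block, :]
    log_expr[marker_rows, :] += (
        config.marker_effect_size * config.noise_sd
    ) * marker_shift

    log_expr += rng.normal(scale=config.noise_sd, size=log_expr.shape)
    expr = np.maximum(np.exp2(log_expr) - 1.0, 0.0)

    matrix = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "tissue": ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
            "class_label": class_label.to_numpy(),
            "immune_tier": immune_tier.to_numpy(),
        }
    ).set_index("sample_id")
    truth = CohortTruth(
        class_label=class_label,
        immune_tier=immune_tier,
        seed=config.seed,
        class_genes=class_genes,
        marker_genes=list(MARKER_GENES),
    )
    return matrix, metadata, truth


def _gene_locus(gene_index: int) -> tuple[str, int, int]:
    """Dummy 1-based coordinate range for a panel gene."""
    chrom = f"chr{gene_index % 22 + 1}"
    start = gene_index * 10_000 + 1
    return chrom, start, start + 4_999


def _make_record(
    rng: np.random.Generator,
    kind: str,
    sample: str,
    gene: str,
    gene_index: int,
) -> VariantRecord:
    chrom, lo, hi = _gene_locus(gene_index)
    pos = int(rng.integers(lo, hi + 1))
    bases = ["A", "C", "G", "T"]
    ref = bases[int(rng.integers(4))]
    alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
    common = dict(
        sample_id=sample,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene_symbol=gene,
        region_class="exonic",
        consequence="protein-changing",
    )
    if kind == "somatic":
        return VariantRecord(
            filter_status="PASS",
            alt_depth=int(rng.integers(5, 101)),
            alt_rate=float(rng.uniform(0.25, 0.9)),
            **common,
        )
    if kind == "germline":
        # only the population rule is violated
        return VariantRecord(
            filter_status="PASS",
            alt_depth=int(rng.integers(5, 101)),
            alt_rate=float(rng.uniform(0.25, 0.9)),
            pop_freq_1kg=float(rng.uniform(0.006, 0.5)),
            **common,
        )
    # artifact: violate exactly one stage-1 rule
    mode = int(rng.integers(3))
    if mode == 0:
        return VariantRecord(
            filter_status="LowQual",
            alt_depth=int(rng.integers(5, 101)),
            alt_rate=float(rng.uniform(0.25, 0.9)),
            **common,
        )
    if mode == 1:
        return VariantRecord(
            filter_status="PASS",
            alt_depth=int(rng.integers(0, 5)),
            alt_rate=float(rng.uniform(0.25, 0.9)),
            **common,
        )
    common["alt"] = common["ref"] + "A"  # insertion
    return VariantRecord(
        filter_status="PASS",
        alt_depth=int(rng.integers(5, 101)),
        alt_rate=float(rng.uniform(0.01, 0.19)),
        is_indel=True,
        **common,
    )


def generate_variant_records(
    config: SimulationConfig, gene_panel: list[str]
) -> tuple[list[VariantRecord], CohortTruth]:
    """Simulate per-sample variant calls with a known kind mixture.

    Each tumor sample receives ``round(rate * mean_variants_per_sample)``
    records of each kind (somatic / germline / artifact), so planted totals
    are exact.  Somatic records satisfy every cascade rule; germline records
    violate only the population-frequency rule; artifacts violate exactly one
    quality rule.  ``truth.somatic_flag`` aligns with the returned list.
    """
    if not gene_panel:
        raise ValueError("gene panel must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    tumors, _ = _sample_ids(config)
    n = config.mean_variants_per_sample
    kind_counts = {
        "somatic": round(config.somatic_rate * n),
        "germline": round(config.germline_rate * n),
        "artifact": round(config.artifact_rate * n),
    }
    records: list[VariantRecord] = []
    flags: list[bool] = []
    for sample in tumors:
        for kind, count in kind_counts.items():
            for _ in range(count):
                gi = int(rng.integers(len(gene_panel)))
                records.append(_make_record(rng, kind, sample, gene_panel[gi], gi))
                flags.append(kind == "somatic")
    truth = CohortTruth(somatic_flag=flags, seed=config.seed)
    return records, truth


def default_reference_profiles(
    n_genes: int = 210, seed: int = 0, cell_types=DEFAULT_CELL_TYPES
) -> ExpressionMatrix:
    """Synthetic reference profiles (signature genes x cell types).

    Each cell type gets a block of genes it expresses highly, giving a
    well-conditioned deconvolution basis.  Gene ids ``SIG00001...``; these
    signature genes are assumed absent from the uncharacterized "other"
    compartment, the standard assumption of reference-based deconvolution.
    """
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    genes = [f"SIG{i:05d}" for i in range(1, n_genes + 1)]
    base = rng.uniform(0.5, 2.0, size=(n_genes, k))
    block = n_genes // k
    for j in range(k):
        base[j * block : (j + 1) * block, j] += rng.uniform(20.0, 40.0, size=block)
    return ExpressionMatrix(pd.DataFrame(base, index=genes, columns=list(cell_types)))


def generate_mixture_profiles(
    reference: ExpressionMatrix,
    fractions: pd.DataFrame,
    noise_sd: float = 0.0,
    other_profile: np.ndarray | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Bulk profiles as known mixtures of reference cell-type profiles.

    Each sample column is ``reference @ fractions_row + (1 - sum) * other +
    Gaussian(0, noise_sd)``, clipped at zero.  ``other_profile`` defaults to
    zero on the reference's signature genes (uncharacterized content assumed
    not to express them).  Row sums of ``fractions`` must be <= 1.
    """
    if list(fractions.columns) != list(reference.samples):
        raise ValueError(
            "fractions columns must match reference cell types "
            f"({list(reference.samples)})"
        )
    fr = fractions.to_numpy(dtype=float)
    if (fr < 0).any() or (fr.sum(axis=1) > 1.0 + 1e-9).any():
        raise ValueError("fractions must be >= 0 with row sums <= 1")
    ref = reference.values
    if other_profile is None:
        other_profile = np.zeros(ref.shape[0])
    other_profile = np.asarray(other_profile, dtype=float)
    if other_profile.shape != (ref.shape[0],):
        raise ValueError("other_profile length must equal reference gene count")
    rng = np.random.default_rng(seed)
    mix = ref @ fr.T + np.outer(other_profile, 1.0 - fr.sum(axis=1))
    if noise_sd > 0:
        mix = mix + rng.normal(scale=noise_sd, size=mix.shape)
    mix = np.clip(mix, 0.0, None)
    return ExpressionMatrix(
        pd.DataFrame(mix, index=reference.genes, columns=fractions.index)
    )


def generate_survival(
    labels: pd.Series,
    config: SimulationConfig,
    hazards: dict | None = None,
) -> pd.DataFrame:
    """Exponential event times per group with right censoring.

    ``labels`` maps sample -> group; ``hazards`` maps each distinct group to
    an event hazard (events/day).  When omitted, classes ``1..k`` take the
    config's per-class hazards.  A ``censor_fraction`` of samples is
    right-censored at a uniform time before their event.  Returns a DataFrame
    with ``time_days``, ``event`` and ``group`` indexed by sample.
    """
    labels = pd.Series(labels)
    if hazards is None:
        hazards = {c + 1: h for c, h in enumerate(config.hazards)}
    missing = sorted(set(labels.unique()) - set(hazards))
    if missing:
        raise ValueError(f"no hazard supplied for groups {missing}")
    for g, h in hazards.items():
        if h <= 0:
            raise ValueError(f"hazard for group {g!r} must be positive")
    rng = np.random.default_rng(config.seed + 2)
    n = len(labels)
    rates = np.array([hazards[g] for g in labels], dtype=float)
    times = rng.exponential(1.0 / rates)
    event = np.ones(n, dtype=int)
    n_censor = int(round(config.censor_fraction * n))
    if n_censor > 0:
        idx = rng.choice(n, size=n_censor, replace=False)
        times[idx] = rng.uniform(0.0, times[idx])
        event[idx] = 0
    return pd.DataFrame(
        {"time_days": times, "event": event, "group": labels.to_numpy()},
        index=labels.index,
    )
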