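"""Somatic-variant filter cascade for RNA-seq-derived calls.

Variant calls made from tumor RNA-seq without a matched normal are a mixture
of true somatic events, germline polymorphisms and technical artifacts.  The
cascade implemented here removes, in order:

1. low-quality calls — not ``PASS``, alternative allele depth < 5, or indels
   in a poly-N region or with alternative allele rate < 20%;
2. likely germline variants — observed in the 1000 Genomes or 6500 Exomes
   panels at > 0.5% population frequency;
3. non-functional calls — anything not exonic and protein-changing;
4. off-panel calls — genes outside a cancer consensus panel;
5. (optional) calls also present in the sample's matched normal.

The surviving records feed the mutation-load summary (per-sample counts and
their median) and per-gene mutation frequencies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VariantRecord",
    "FilterReport",
    "run_filter_cascade",
    "mutation_load",
    "gene_frequency",
]

ALT_DEPTH_MIN = 5
INDEL_ALT_RATE_MIN = 0.20
POP_FREQ_MAX = 0.005  # strict ">": exactly 0.5% is retained

STAGE_NAMES = ("input", "quality", "population", "functional", "panel", "matched_normal")


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one sample, with the attributes the cascade reads.

    Population frequencies of ``None`` mean "not observed in the panel" and
    are treated as 0 by the population filter.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    filter_status: str = "PASS"
    alt_depth: int = 0
    alt_rate: float = 0.0
    is_indel: bool = False
    in_polyN_region: bool = False
    pop_freq_1kg: float | None = None
    pop_freq_esp: float | None = None
    region_class: str = "exonic"
    consequence: str = "protein-changing"
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt_depth < 0:
            raise ValueError("alt_depth must be >= 0")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for name in ("pop_freq_1kg", "pop_freq_esp"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilterReport:
    """Record counts after each cascade stage plus the load summary."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    per_sample_retained: dict[str, int] = field(default_factory=dict)
    median_load: float = 0.0

    @property
    def counts(self) -> list[int]:
        return [self.stage_counts[s] for s in STAGE_NAMES if s in self.stage_counts]


def _passes_quality(r: VariantRecord) -> bool:
    if r.filter_status != "PASS":
        return False
    if r.alt_depth < ALT_DEPTH_MIN:
        return False
    if r.is_indel and (r.in_polyN_region or r.alt_rate < INDEL_ALT_RATE_MIN):
        return False
    return True


def _passes_population(r: VariantRecord) -> bool:
    for freq in (r.pop_freq_1kg, r.pop_freq_esp):
        if freq is not None and freq > POP_FREQ_MAX:
            return False
    return True


def _passes_functional(r: VariantRecord) -> bool:
    return r.region_class == "exonic" and r.consequence == "protein-changing"


def run_filter_cascade(
    records: Sequence[VariantRecord],
    panel: Iterable[str],
    matched_normals: Mapping[str, Sequence[VariantRecord]] | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Run the filter cascade, preserving input order.

    Parameters
    ----------
    records
        Candidate calls (typically tumor samples).
    panel
        Cancer-consensus gene symbols; stage 4 keeps only these.
    matched_normals
        Optional map from tumor ``sample_id`` to the variant records called in
        that sample's matched normal.  Stage 5 removes tumor calls whose
        (chrom, pos, ref, alt) also appears in the matched normal; samples
        without an entry are left untouched.

    Returns
    -------
    (retained records, FilterReport with per-stage counts)
    """
    panel_set = set(panel)
    if not panel_set:
        raise ValueError("gene panel must be non-empty")

    report = FilterReport()
    report.stage_counts["input"] = len(records)

    kept = [r for r in records if _passes_quality(r)]
    report.stage_counts["quality"] = len(kept)

    kept = [r for r in kept if _passes_population(r)]
    report.stage_counts["population"] = len(kept)

    kept = [r for r in kept if _passes_functional(r)]
    report.stage_counts["functional"] = len(kept)

    kept = [r for r in kept if r.gene_symbol in panel_set]
    report.stage_counts["panel"] = len(kept)

    if matched_normals is not None:
        normal_keys = {
            sample: {n.key for n in normals}
            for sample, normals in matched_normals.items()
        }
        kept = [
            r
            for r in kept
            if r.key not in normal_keys.get(r.sample_id, frozenset())
        ]
        report.stage_counts["matched_normal"] = len(kept)

    return kept, report


def mutation_load(
    retained: Sequence[VariantRecord],
    samples: Sequence[str],
    median_convention: str = "lower",
) -> tuple[dict[str, int], float]:
    """Per-sample retained-variant counts and their median.

    ``samples`` must list every sample of interest so that samples with zero
    retained calls contribute 0 to the median.  For even cohort sizes the
    default is the lower of the two middle values; ``median_convention="mid"``
    averages them instead.
    """
    counts = Counter(r.sample_id for r in retained)
    per_sample = {s: counts.get(s, 0) for s in samples}
    values = sorted(per_sample.values())
    if not values:
        return per_sample, 0.0
    n = len(values)
    if n % 2 == 1:
        med = float(values[n // 2])
    elif median_convention == "lower":
        med = float(values[n // 2 - 1])
    elif median_convention == "mid":
        med = (values[n // 2 - 1] + values[n // 2]) / 2.0
    else:
        raise ValueError(f"unknown median_convention {median_convention!r}")
    return per_sample, med


def _round_half_away(x: float, ndigits: int = 1) -> float:
    scale = 10.0**ndigits
    import math

    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def gene_frequency(
    retained: Sequence[VariantRecord], n_samples: int
) -> dict[str, tuple[int, float]]:
    """Per-gene mutated-sample counts and one-decimal percentages.

    A sample counts once per gene no matter how many distinct variants it
    carries there.  Percentages are ``100 * k / n_samples`` rounded
    half-away-from-zero to one decimal, matching how cohort frequency tables
    are conventionally printed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    gene_samples: dict[str, set[str]] = {}
    for r in retained:
        gene_samples.setdefault(r.gene_symbol, set()).add(r.sample_id)
    return {
        gene: (len(ss), _round_half_away(100.0 * len(ss) / n_samples))
        for gene, ss in sorted(gene_samples.items())
    }
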