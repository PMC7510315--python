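"""Cross-cohort driver-mutation frequency comparison.

Frequency tables for published cohorts usually print one-decimal percentages
rather than raw counts.  To run an exact test between two cohorts the integer
counts are first reconstructed from the printed percentages (possible exactly
whenever a unique integer reproduces the printed value), then each gene is
tested with a two-sided Fisher exact test on the 2x2 table

    [[mutated_1, wildtype_1],
     [mutated_2, wildtype_2]].

A bundled table ships the published driver-gene frequencies of a Chinese
ccRCC cohort (n=55) against the TCGA KIRC white subcohort; the Fisher
denominator consistent with that table's published p-values is n=451.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "AmbiguousPercentError",
    "InconsistentPercentError",
    "reconstruct_count",
    "fisher_exact_2x2",
    "compare_driver_frequencies",
    "load_published_driver_table",
    "CHINESE_COHORT_SIZE",
    "TCGA_WHITE_COHORT_SIZE",
]

CHINESE_COHORT_SIZE = 55
#: White TCGA KIRC samples with somatic-mutation data; pinned by the
#: degenerate published row 1.8% vs 0.0% with p = 55/506.
TCGA_WHITE_COHORT_SIZE = 451


class InconsistentPercentError(ValueError):
    """No integer count reproduces the printed percentage."""


class AmbiguousPercentError(ValueError):
    """More than one integer count reproduces the printed percentage."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # mutated, cohort 1
    b: int  # wildtype, cohort 1
    c: int  # mutated, cohort 2
    d: int  # wildtype, cohort 2

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency entries must be non-negative")

    def as_lists(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def _round_half_away(x: float, ndigits: int = 1) -> float:
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def reconstruct_count(percent: float, n: int) -> int:
    """Invert a one-decimal percentage back to the integer count.

    Returns ``k`` iff ``k`` is the unique integer in ``[0, n]`` with
    ``round(100 k / n, 1) == percent`` (half-away-from-zero rounding).
    Raises :class:`InconsistentPercentError` when no integer reproduces the
    percentage and :class:`AmbiguousPercentError` when several do.
    """
    if not (0.0 <= percent <= 100.0):
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    target = _round_half_away(percent)
    # 100k/n within 0.05 of target bounds the search window
    lo = max(0, math.floor((target - 0.06) * n / 100))
    hi = min(n, math.ceil((target + 0.06) * n / 100))
    hits = [k for k in range(lo, hi + 1) if _round_half_away(100.0 * k / n) == target]
    if not hits:
        raise InconsistentPercentError(
            f"no integer count in [0, {n}] prints as {percent}%"
        )
    if len(hits) > 1:
        raise AmbiguousPercentError(
            f"counts {hits} all print as {percent}% for n={n}"
        )
    return hits[0]


def fisher_exact_2x2(table: ContingencyTable2x2 | list[list[int]]) -> float:
    """Two-sided Fisher exact p-value.

    Sums hypergeometric point probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's (the
    convention of R and scipy, with a small relative slack for floating-point
    ties).
    """
    if isinstance(table, ContingencyTable2x2):
        table = table.as_lists()
    if min(min(row) for row in table) < 0:
        raise ValueError("contingency entries must be non-negative")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def compare_driver_frequencies(
    freq1: Mapping[str, float],
    n1: int,
    freq2: Mapping[str, float],
    n2: int,
    alpha: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene Fisher comparison of two cohorts given printed percentages.

    Genes present in only one table get 0.0% in the other.  Reconstruction
    failures are reported per gene (``error`` column) without aborting the
    remaining genes.  Significance is flagged at unadjusted ``p < alpha``;
    ``bh_adjust=True`` adds a Benjamini-Hochberg adjusted column and flags on
    it instead.

    Returns a DataFrame indexed by gene with columns
    ``percent1, percent2, count1, count2, p, significant, error``.
    """
    genes = sorted(set(freq1) | set(freq2))
    if not genes:
        raise ValueError("no genes to compare")
    rows = []
    for gene in genes:
        p1 = float(freq1.get(gene, 0.0))
        p2 = float(freq2.get(gene, 0.0))
        row: dict = {
            "gene": gene,
            "percent1": p1,
            "percent2": p2,
            "count1": pd.NA,
            "count2": pd.NA,
            "p": float("nan"),
            "error": "",
        }
        try:
            k1 = reconstruct_count(p1, n1)
            k2 = reconstruct_count(p2, n2)
        except (InconsistentPercentError, AmbiguousPercentError) as exc:
            row["error"] = str(exc)
        else:
            row["count1"] = k1
            row["count2"] = k2
            row["p"] = fisher_exact_2x2([[k1, n1 - k1], [k2, n2 - k2]])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene")
    ok = out["p"].notna()
    if bh_adjust:
        adj = pd.Series(float("nan"), index=out.index)
        if ok.any():
            adj[ok] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    out.loc[~ok, "significant"] = False
    return out


def load_published_driver_table() -> pd.DataFrame:
    """The bundled 84-gene published driver-frequency table.

    Columns: ``freq_chinese_pct``, ``freq_tcga_pct``, ``published_p``;
    indexed by gene symbol.
    """
    with resources.files("ccrcckit.data").joinpath(
        "driver_gene_frequencies.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", index_col="gene")
    return df
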