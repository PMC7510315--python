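"""Transcriptional immuno-phenotyping and bulk cell-fraction deconvolution.

Tumors are assigned a coarse immune state (active / tolerant / inactive) by
hierarchical clustering of a 66-gene immune-marker panel: samples cluster
into four groups; the group holding the majority of the normal tissues
defines the inactive pole (tumors inside it are immune-inactive), and the
remaining tumor groups are ranked by mean marker z-score into active and
tolerant.  Bulk cell-type composition is estimated by constrained least
squares against reference cell-type profiles (weights >= 0, sum <= 1, the
remainder reported as "other" — the uncharacterized, mostly malignant
content), a simplified member of the EPIC family of reference-based
deconvolution methods.  eTMB — the count of somatic variants surviving
matched-normal filtering — can be correlated against the inferred fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix
from .variants import VariantRecord, mutation_load

__all__ = [
    "ImmunePhenotype",
    "FractionComparison",
    "assign_immune_phenotypes",
    "deconvolve_fractions",
    "compare_fractions",
    "estimate_etmb",
    "correlate_etmb",
]


@dataclass
class ImmunePhenotype:
    labels: pd.Series  # sample -> active | tolerant | inactive | normal
    markers: list[str]
    group_mean_z: pd.Series  # assigned label -> mean marker z-score


@dataclass
class FractionComparison:
    """Per-cell-type group contrast (volcano-table contents)."""

    table: pd.DataFrame  # index cell type; log10_ratio, p, flag


def assign_immune_phenotypes(
    X: ExpressionMatrix,
    markers: list[str],
    tumor_flags: pd.Series,
    n_groups: int = 4,
) -> ImmunePhenotype:
    """Tier assignment by marker-panel clustering.

    ``tumor_flags`` maps sample -> True for tumor, False for normal.  Samples
    are clustered (correlation distance, average linkage, on per-gene
    z-scores of the markers) and cut into ``n_groups``; see the module
    docstring for the labeling rule.  When three tumor groups remain outside
    the normal pole, the largest gap in their mean marker z-scores splits
    them into active-side and tolerant-side; without any normal samples the
    lowest-scoring group is labeled inactive (with a warning).
    """
    present = [g for g in markers if g in X.genes]
    if not present:
        raise ValueError("none of the marker genes are present in the matrix")
    if len(present) < 0.5 * len(markers):
        raise ValueError(
            f"only {len(present)}/{len(markers)} markers present (need >= 50%)"
        )
    tumor_flags = pd.Series(tumor_flags).loc[X.samples]
    sub = X.subset_genes(present)
    Z = (sub.log2p1() if sub.scale == "raw" else sub).zscore()
    zv = Z.values
    corr = np.corrcoef(zv, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    Zl = linkage(squareform(dist, checks=False), method="average")
    groups = pd.Series(
        fcluster(Zl, t=n_groups, criterion="maxclust"), index=X.samples
    )
    sample_score = pd.Series(zv.mean(axis=0), index=X.samples)
    group_score = sample_score.groupby(groups).mean()

    n_normals = (~tumor_flags).sum()
    if n_normals > 0:
        normal_counts = groups[~tumor_flags].value_counts()
        normal_pole = int(normal_counts.idxmax())
    else:
        warnings.warn(
            "no normal samples: labeling the lowest-scoring group inactive",
            stacklevel=2,
        )
        normal_pole = int(group_score.idxmin())

    labels = pd.Series("", index=X.samples, dtype=object)
    labels[~tumor_flags] = "normal"
    in_pole = (groups == normal_pole) & tumor_flags
    labels[in_pole] = "inactive"

    remaining = sorted(
        (g for g in group_score.index if g != normal_pole),
        key=lambda g: -group_score[g],
    )
    if len(remaining) == 0:
        pass  # every tumor co-clusters with normals: all inactive
    elif len(remaining) == 1:
        # single tumor group: split at its median marker score
        members = groups.index[(groups == remaining[0]) & tumor_flags]
        cut = sample_score[members].median()
        labels[members] = np.where(
            sample_score[members] > cut, "active", "tolerant"
        )
    elif len(remaining) == 2:
        hi, lo = remaining
        labels[(groups == hi) & tumor_flags] = "active"
        labels[(groups == lo) & tumor_flags] = "tolerant"
    else:
        scores = group_score[remaining].to_numpy()
        gaps = scores[:-1] - scores[1:]
        split = int(np.argmax(gaps)) + 1
        for i, g in enumerate(remaining):
            labels[(groups == g) & tumor_flags] = (
                "active" if i < split else "tolerant"
            )

    group_mean = sample_score.groupby(labels).mean()
    return ImmunePhenotype(labels=labels, markers=present, group_mean_z=group_mean)


def _solve_constrained(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||A w - b|| s.t. w >= 0, sum(w) <= 1.

    Plain NNLS first; if its solution violates the simplex bound, re-solve
    with the sum pinned to 1 via a heavily weighted augmentation row (an
    exact equality in the limit; the residual of the constraint row is
    checked and the solution renormalized onto the simplex).
    """
    w, _ = nnls(A, b)
    if w.sum() <= 1.0 + 1e-9:
        return w
    lam = 1e6 * max(1.0, np.abs(A).max())
    A_aug = np.vstack([A, lam * np.ones((1, A.shape[1]))])
    b_aug = np.concatenate([b, [lam]])
    w, _ = nnls(A_aug, b_aug)
    s = w.sum()
    if s > 0:
        w = w / max(s, 1.0)
    return w


def deconvolve_fractions(
    X: ExpressionMatrix, reference: ExpressionMatrix, min_shared: int = 30
) -> pd.DataFrame:
    """Constrained least-squares deconvolution against reference profiles.

    Returns samples x (cell types + "other") with non-negative rows summing
    to 1.  Requires at least ``min_shared`` signature genes shared between
    the bulk matrix and the reference, and a full-rank reference.
    """
    shared = [g for g in reference.genes if g in X.genes]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} genes shared with the reference (need >= {min_shared})"
        )
    A = reference.data.loc[shared].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the collinear columns for the error message
        bad = []
        for j in range(A.shape[1]):
            others = np.delete(A, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(str(reference.samples[j]))
        raise ValueError(
            f"reference profiles are rank-deficient (collinear columns: {bad})"
        )
    B = X.data.loc[shared].to_numpy(dtype=float)
    rows = []
    for i in range(B.shape[1]):
        w = _solve_constrained(A, B[:, i])
        rows.append(np.concatenate([w, [max(0.0, 1.0 - w.sum())]]))
    cols = list(reference.samples) + ["other"]
    out = pd.DataFrame(rows, index=X.samples, columns=cols)
    # guard tiny numerical drift off the simplex
    out = out.clip(lower=0.0)
    out = out.div(out.sum(axis=1), axis=0)
    return out


def compare_fractions(
    fractions: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
) -> FractionComparison:
    """Volcano-style contrast of cell fractions between two sample groups.

    Per cell type: log10 of the group-A/group-B mean ratio and a two-sided
    Welch t-test p-value; flags ``elevated``/``depleted`` at ``p < alpha``,
    else ``ns``.  A zero group mean gives a missing log-ratio with a warning.
    """
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    rows = []
    for ct in fractions.columns:
        a = fractions.loc[ga, ct].to_numpy(dtype=float)
        b = fractions.loc[gb, ct].to_numpy(dtype=float)
        ma, mb = a.mean(), b.mean()
        if ma <= 0 or mb <= 0:
            warnings.warn(
                f"zero group mean for {ct}; log-ratio reported as missing",
                stacklevel=2,
            )
            ratio = float("nan")
        else:
            ratio = float(np.log10(ma / mb))
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if np.isnan(ratio) or p >= alpha:
            flag = "ns"
        else:
            flag = "elevated" if ratio > 0 else "depleted"
        rows.append({"cell_type": ct, "log10_ratio": ratio, "p": p, "flag": flag})
    return FractionComparison(table=pd.DataFrame(rows).set_index("cell_type"))


def estimate_etmb(
    paired_variants: list[VariantRecord], samples: list[str]
) -> pd.Series:
    """eTMB per sample: somatic calls surviving matched-normal filtering."""
    counts, _ = mutation_load(paired_variants, samples)
    return pd.Series(counts, name="etmb").loc[samples]


def correlate_etmb(
    etmb: pd.Series, fractions: pd.DataFrame, method: str = "pearson"
) -> pd.Series:
    """Correlation between eTMB and each cell-type fraction across samples."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    common = [s for s in fractions.index if s in etmb.index]
    if len(common) < 3:
        raise ValueError(
            f"correlation undefined with {len(common)} paired samples (need >= 3)"
        )
    e = etmb.loc[common].astype(float)
    if e.nunique() == 1:
        raise ValueError("eTMB is constant across samples; correlation undefined")
    out = {}
    for ct in fractions.columns:
        f = fractions.loc[common, ct].astype(float)
        if method == "pearson":
            out[ct] = float(stats.pearsonr(e, f)[0]) if f.nunique() > 1 else float("nan")
        else:
            out[ct] = float(stats.spearmanr(e, f)[0]) if f.nunique() > 1 else float("nan")
    return pd.Series(out, name=f"{method}_r")
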