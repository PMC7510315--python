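"""Consensus-NMF molecular subtyping and signature-based class transfer.

The classification procedure:

1. z-score the expression matrix per gene and keep the top ``n`` genes by a
   robust dispersion score (median absolute deviation by default);
2. split the z-scores into a non-negative matrix by stacking the positive and
   negative parts (doubling the rows), the standard trick for applying NMF to
   standardized data;
3. run consensus NMF — many random-start KL-divergence factorizations per
   candidate rank; the fraction of runs in which two samples share a dominant
   factor forms the consensus matrix, whose cophenetic correlation scores
   clustering stability — and pick the rank with the highest cophenetic
   coefficient (ties toward smaller k);
4. compress the class structure into a transferable signature: per-class
   one-vs-rest differential expression (Welch t on log2(x+1), BH-adjusted),
   pooled across classes, top 300 genes by adjusted p;
5. measure how well the signature alone recovers the full clustering
   (signature recall, agreement maximized over label matchings), and classify
   external cohorts by hierarchical clustering of the 1 - Spearman-correlation
   distance between samples over the signature genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, cophenet, fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "SubtypeModel",
    "TransferResult",
    "select_variable_genes",
    "to_nonnegative",
    "nmf_consensus",
    "choose_rank",
    "derive_signature",
    "signature_recall",
    "transfer_classify",
    "fit_subtypes",
]


@dataclass
class SubtypeModel:
    """Fitted classification state of a cohort."""

    selected_genes: list[str]
    rank: int
    W: np.ndarray  # (2 * selected genes) x rank, non-negative
    H: np.ndarray  # rank x samples, non-negative
    consensus: pd.DataFrame  # samples x samples, entries in [0, 1]
    cophenetics: dict[int, float]  # candidate rank -> cophenetic coefficient
    class_labels: pd.Series  # sample -> 1..rank
    signature: list[str] = field(default_factory=list)
    recall: float = float("nan")


@dataclass
class TransferResult:
    """Signature-based class transfer onto a combined reference+query cohort."""

    labels: pd.Series  # all samples (reference + query) -> class 1..k
    correlation: pd.DataFrame  # pairwise Spearman over signature genes
    distance: pd.DataFrame  # 1 - correlation
    linkage_method: str
    cluster_to_class: dict[int, int]


# ---------------------------------------------------------------------------
# gene selection and transforms


def select_variable_genes(
    X: ExpressionMatrix, n: int, method: str = "mad"
) -> list[str]:
    """Top ``n`` genes by dispersion of the z-scored matrix.

    ``method="mad"`` scores each gene by the median absolute deviation from
    its median; ``method="max"`` by the maximum absolute deviation from the
    mean.  Ties break lexicographically by gene id, so selection is
    deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > X.data.shape[0]:
        raise ValueError(f"n={n} exceeds gene count {X.data.shape[0]}")
    Z = X if X.scale == "zscore" else (X.log2p1().zscore() if X.scale == "raw" else X.zscore())
    vals = Z.values
    if method == "mad":
        med = np.median(vals, axis=1, keepdims=True)
        score = np.median(np.abs(vals - med), axis=1)
    elif method == "max":
        score = np.max(np.abs(vals - vals.mean(axis=1, keepdims=True)), axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    # mergesort is stable; pre-sorting the index makes ties lexicographic
    order = (
        pd.DataFrame({"score": score}, index=Z.genes)
        .sort_index()
        .sort_values(by="score", ascending=False, kind="mergesort")
    )
    return order.index[:n].tolist()


def to_nonnegative(Z: ExpressionMatrix) -> ExpressionMatrix:
    """Positive/negative row split of a z-scored matrix.

    Stacks ``max(Z, 0)`` (gene ids suffixed ``+``) over ``max(-Z, 0)``
    (suffixed ``-``); the original matrix is the top block minus the bottom
    block.  Row count doubles; every entry is >= 0.
    """
    vals = Z.values
    if not np.isfinite(vals).all():
        raise ValueError("non-finite entries in input")
    pos = np.maximum(vals, 0.0)
    neg = np.maximum(-vals, 0.0)
    genes = [f"{g}+" for g in Z.genes] + [f"{g}-" for g in Z.genes]
    return ExpressionMatrix(
        pd.DataFrame(np.vstack([pos, neg]), index=genes, columns=Z.samples),
        scale="raw",
    )


# ---------------------------------------------------------------------------
# consensus NMF


def _nmf_run(V: np.ndarray, k: int, seed: int, max_iter: int, tol: float):
    # single precision roughly triples throughput; partition labels and
    # consensus frequencies are unaffected at these tolerances
    V = np.asarray(V, dtype=np.float32)
    model = NMF(
        n_components=k,
        init="random",
        solver="mu",
        beta_loss="kullback-leibler",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(V)
    return W, model.components_, model.reconstruction_err_


def _labels_from_H(H: np.ndarray) -> np.ndarray:
    # dominant coefficient per sample; ties -> lowest factor index (argmax)
    return H.argmax(axis=0)


def nmf_consensus(
    V: ExpressionMatrix | pd.DataFrame,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, float]:
    """Consensus NMF at one rank.

    Runs ``n_runs`` random-start multiplicative-update factorizations with a
    KL-divergence objective; per run, samples are labeled by their dominant
    coefficient, and ``consensus[i, j]`` is the fraction of runs co-clustering
    samples i and j.  The cophenetic coefficient is the correlation between
    the consensus dissimilarity (1 - consensus) and the cophenetic distances
    of its average-linkage dendrogram.  Returns ``(W, H, consensus,
    cophenetic)`` with W, H from the lowest-objective run.  Seed-deterministic.
    """
    data = V.data if isinstance(V, ExpressionMatrix) else V
    arr = data.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("NMF input must be non-negative")
    n_samples = arr.shape[1]
    if not (2 <= k < n_samples):
        raise ValueError(f"rank k={k} must satisfy 2 <= k < n_samples={n_samples}")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    co = np.zeros((n_samples, n_samples))
    best = None
    for s in run_seeds:
        W, H, err = _nmf_run(arr, k, int(s), max_iter, tol)
        lab = _labels_from_H(H)
        co += lab[:, None] == lab[None, :]
        if best is None or err < best[2]:
            best = (W, H, err)
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)
    dist = 1.0 - consensus
    condensed = squareform(dist, checks=False)
    Zl = average(condensed)
    if np.allclose(condensed, condensed[0]):
        coph = 1.0 if condensed.size and np.allclose(condensed, 0) else 0.0
    else:
        coph = float(cophenet(Zl, condensed)[0])
        if np.isnan(coph):
            coph = 0.0
    consensus_df = pd.DataFrame(consensus, index=data.columns, columns=data.columns)
    return best[0], best[1], consensus_df, coph


def consensus_labels(consensus: pd.DataFrame, k: int) -> pd.Series:
    """Final class labels: average-linkage cut of the consensus matrix.

    Classes are renumbered 1..k in order of first appearance along the sample
    axis, making labels invariant to cluster-id arbitrariness.
    """
    dist = 1.0 - consensus.to_numpy()
    np.fill_diagonal(dist, 0.0)
    Zl = average(squareform(dist, checks=False))
    raw = fcluster(Zl, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
    return pd.Series([remap[r] for r in raw], index=consensus.index, name="class_label")


def _merge_degenerate_classes(labels: pd.Series, consensus: pd.DataFrame) -> pd.Series:
    """Fold classes with fewer than 2 members into their nearest class.

    A dendrogram cut can spend a cluster on a single outlying sample; such a
    class supports no differential-expression contrast, so its samples are
    reassigned to the class they co-cluster with most often.  Classes are
    renumbered 1..k' by first appearance afterwards.
    """
    counts = labels.value_counts()
    small = set(counts.index[counts < 2])
    if not small or len(small) == len(counts):
        return labels
    labels = labels.copy()
    keep = [c for c in counts.index if c not in small]
    for s in labels.index[labels.isin(small)]:
        aff = {
            c: consensus.loc[s, labels.index[(labels == c) & (labels.index != s)]].mean()
            for c in keep
        }
        labels[s] = max(aff, key=lambda c: (aff[c], -c))
    warnings.warn(
        f"merged {len(small)} singleton class(es) into their nearest class",
        stacklevel=3,
    )
    remap: dict[int, int] = {}
    for v in labels:
        if v not in remap:
            remap[v] = len(remap) + 1
    return labels.map(remap)


def choose_rank(cophenetics: dict[int, float]) -> int:
    """Arg-max cophenetic coefficient; ties broken toward smaller k."""
    if not cophenetics:
        raise ValueError("empty cophenetic map")
    return min(sorted(cophenetics), key=lambda k: (-cophenetics[k], k))


# ---------------------------------------------------------------------------
# signature derivation, recall, transfer


def derive_signature(
    X: ExpressionMatrix, labels: pd.Series, top_n: int = 300
) -> list[str]:
    """Top differential genes across classes, one-vs-rest, pooled.

    For each class, every gene gets a Welch two-sample t-test on log2(x+1)
    values (class vs all other tumor samples), BH-adjusted within that
    comparison.  All comparisons are pooled, ranked by adjusted p (ties by
    raw p then gene id), deduplicated keeping each gene's best rank, and the
    top ``top_n`` genes form the signature.
    """
    labels = labels.loc[X.samples]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    logX = X.log2p1() if X.scale == "raw" else X
    vals = logX.values
    frames = []
    for c in classes:
        in_c = (labels == c).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(
                vals[:, in_c], vals[:, ~in_c], axis=1, equal_var=False
            )
        p = np.where(np.isnan(p), 1.0, p)
        adj = multipletests(p, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame({"gene": X.genes, "p": p, "p_adj": adj, "cls": c})
        )
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled.sort_values(
        by=["p_adj", "p", "gene"], kind="mergesort"
    ).drop_duplicates(subset="gene", keep="first")
    return pooled["gene"].head(top_n).tolist()


def signature_recall(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Agreement between two labelings, maximized over one-to-one matchings."""
    labels_a, labels_b = pd.Series(labels_a), pd.Series(labels_b)
    if set(labels_a.index) != set(labels_b.index):
        raise ValueError("labelings cover different samples")
    labels_b = labels_b.loc[labels_a.index]
    conf = pd.crosstab(labels_a, labels_b)
    # pad to square so unmatched labels cost nothing
    m = max(conf.shape)
    mat = np.zeros((m, m))
    mat[: conf.shape[0], : conf.shape[1]] = conf.to_numpy()
    r, c = linear_sum_assignment(-mat)
    return float(mat[r, c].sum() / len(labels_a))


def _spearman_distance(data: pd.DataFrame) -> pd.DataFrame:
    ranks = data.rank(axis=0).to_numpy()
    rho = np.corrcoef(ranks, rowvar=False)
    return pd.DataFrame(1.0 - rho, index=data.columns, columns=data.columns)


def transfer_classify(
    X_ref: ExpressionMatrix,
    ref_labels: pd.Series,
    X_query: ExpressionMatrix,
    signature: list[str],
    linkage_method: str = "average",
    min_overlap: float = 0.8,
) -> TransferResult:
    """Classify a query cohort by signature-gene correlation clustering.

    Both cohorts are restricted to the signature genes (at least
    ``min_overlap`` of the signature must be present in each, else an error),
    combined, and clustered hierarchically on the 1 - Spearman-correlation
    distance between sample profiles, cut into k clusters (k = number of
    reference classes).  Each cluster takes the class of the majority of its
    reference samples; a cluster without reference samples falls back to the
    nearest reference-class centroid (with a warning).  Query samples inherit
    their cluster's class.
    """
    ref_labels = pd.Series(ref_labels)
    k = ref_labels.nunique()
    shared = [g for g in signature if g in X_ref.genes and g in X_query.genes]
    if len(shared) < min_overlap * len(signature):
        raise ValueError(
            f"only {len(shared)}/{len(signature)} signature genes present in "
            f"both cohorts (need >= {min_overlap:.0%})"
        )
    ref = X_ref.data.loc[shared]
    qry = X_query.data.loc[shared]
    combined = pd.concat([ref, qry], axis=1)
    if combined.columns.duplicated().any():
        raise ValueError("reference and query share sample ids")
    dist = _spearman_distance(combined)
    Zl = linkage(squareform(dist.to_numpy(), checks=False), method=linkage_method)
    clusters = fcluster(Zl, t=k, criterion="maxclust")
    clusters = pd.Series(clusters, index=combined.columns)

    is_ref = combined.columns.isin(ref_labels.index)
    cluster_to_class: dict[int, int] = {}
    orphans = []
    for cl in np.unique(clusters):
        members = clusters.index[(clusters == cl) & is_ref]
        if len(members):
            cluster_to_class[int(cl)] = int(ref_labels.loc[members].mode().iloc[0])
        else:
            orphans.append(int(cl))
    if orphans:
        warnings.warn(
            f"clusters {orphans} contain no reference samples; assigning by "
            "nearest reference-class centroid",
            stacklevel=2,
        )
        ranks = combined.rank(axis=0)
        centroids = {
            c: ranks[ref_labels.index[ref_labels == c]].mean(axis=1)
            for c in sorted(ref_labels.unique())
        }
        for cl in orphans:
            prof = ranks[clusters.index[clusters == cl]].mean(axis=1)
            best = min(
                centroids,
                key=lambda c: 1.0 - np.corrcoef(prof, centroids[c])[0, 1],
            )
            cluster_to_class[cl] = int(best)
    labels = clusters.map(cluster_to_class).rename("class_label")
    return TransferResult(
        labels=labels,
        correlation=1.0 - dist,
        distance=dist,
        linkage_method=linkage_method,
        cluster_to_class=cluster_to_class,
    )


# ---------------------------------------------------------------------------
# end-to-end fit


def fit_subtypes(
    X: ExpressionMatrix,
    n_genes: int = 3000,
    ranks: range | list[int] = range(2, 9),
    n_runs: int = 50,
    top_n: int = 300,
    seed: int = 0,
    gene_method: str = "mad",
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SubtypeModel:
    """Full subtyping fit: gene selection -> consensus NMF rank survey ->
    labels at the chosen rank -> 300-gene signature -> signature recall.

    The recall compares the consensus-NMF labeling against a re-clustering of
    the same cohort using only the signature genes (the transfer procedure
    applied to the cohort itself).
    """
    selected = select_variable_genes(X, n_genes, method=gene_method)
    Z = X.log2p1().zscore() if X.scale == "raw" else X.zscore()
    V = to_nonnegative(Z.subset_genes(selected))
    cophenetics: dict[int, float] = {}
    per_rank: dict[int, tuple] = {}
    for k in ranks:
        W, H, consensus, coph = nmf_consensus(
            V, k, n_runs=n_runs, seed=seed + 1000 * k, max_iter=max_iter, tol=tol
        )
        cophenetics[k] = coph
        per_rank[k] = (W, H, consensus)
    k_best = choose_rank(cophenetics)
    W, H, consensus = per_rank[k_best]
    labels = consensus_labels(consensus, k_best)
    labels = _merge_degenerate_classes(labels, consensus)
    signature = derive_signature(X, labels, top_n=top_n)
    sig_dist = _spearman_distance(
        (X.log2p1() if X.scale == "raw" else X).data.loc[
            [g for g in signature if g in X.genes]
        ]
    )
    Zl = average(squareform(sig_dist.to_numpy(), checks=False))
    sig_raw = fcluster(Zl, t=labels.nunique(), criterion="maxclust")
    sig_labels = pd.Series(sig_raw, index=X.samples)
    recall = signature_recall(labels, sig_labels)
    return SubtypeModel(
        selected_genes=selected,
        rank=k_best,
        W=W,
        H=H,
        consensus=consensus,
        cophenetics=cophenetics,
        class_labels=labels,
        signature=signature,
        recall=recall,
    )
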