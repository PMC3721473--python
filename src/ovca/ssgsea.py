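"""Single-sample gene-set enrichment scoring and subtype-specific set selection.

Per sample, genes are ranked by expression (descending, ties broken by gene
id ascending for cross-platform determinism) and the enrichment score of a
set is the summed difference between the weighted in-set ECDF and the
uniform out-of-set ECDF over the full ranked list. Sets enriched in one
subtype versus the rest are selected by a SAM-style moderated statistic with
permutation FDR and by ROC AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ovca.io_formats import ExpressionMatrix, GeneSetCollection

__all__ = [
    "EnrichmentMatrix",
    "SetSelection",
    "ssgsea_score",
    "sam_two_class",
    "roc_auc",
    "select_subtype_sets",
    "mean_set_activity",
]


@dataclass
class EnrichmentMatrix:
    """Gene-set-by-sample enrichment scores with the scoring parameters used."""

    set_names: list[str]
    sample_ids: list[str]
    values: np.ndarray
    alpha: float = 0.25
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValueError("enrichment matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite enrichment score")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.set_names, columns=self.sample_ids)


@dataclass
class SetSelection:
    """Per (set, subtype) selection statistics: d, q, AUC and the selected flag."""

    table: pd.DataFrame  # columns: set, subtype, d, q, auc, selected

    def selected_for(self, subtype: str) -> list[str]:
        t = self.table
        sub = t[(t["subtype"] == subtype) & t["selected"]]
        return sub.sort_values("auc", ascending=False)["set"].tolist()


def _rank_orders(expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample descending-order gene indices, ties broken by gene id."""
    id_order = np.argsort(np.asarray(expr.gene_ids, dtype=object), kind="stable")
    orders = np.empty((expr.n_genes, expr.n_samples), dtype=np.int64)
    for j in range(expr.n_samples):
        col = expr.values[id_order, j]
        # stable sort on negated values keeps the id-ascending tie order
        orders[:, j] = id_order[np.argsort(-col, kind="stable")]
    return orders


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    min_overlap: int = 1,
    normalize: bool = False,
) -> EnrichmentMatrix:
    """Score every gene set in every sample.

    The gene at descending rank position i (1-based) carries weight
    ``(N - i + 1) ** alpha``; the ES is ``sum_i [P_in(i) - P_out(i)]`` where
    P_in is the running in-set weight fraction and P_out the running
    out-of-set count fraction. Sets overlapping fewer than ``min_overlap``
    genes (or all genes) are skipped with a warning.
    """
    N = expr.n_genes
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    orders = _rank_orders(expr)
    # weight by rank-from-bottom: position i (0-based) gets (N - i) ** alpha
    rank_weight = (N - np.arange(N)).astype(float) ** alpha

    kept_names: list[str] = []
    rows: list[np.ndarray] = []
    membership = np.zeros(N, dtype=bool)
    for name, genes in sets.sets.items():
        idx = [gene_index[g] for g in genes if g in gene_index]
        if len(idx) < min_overlap:
            warnings.warn(f"set {name!r}: overlap {len(idx)} < {min_overlap}; skipped", stacklevel=2)
            continue
        if len(idx) == N:
            warnings.warn(f"set {name!r} covers every gene; skipped", stacklevel=2)
            continue
        membership[:] = False
        membership[idx] = True
        es = np.empty(expr.n_samples)
        for j in range(expr.n_samples):
            order = orders[:, j]
            hit = membership[order]
            w = np.where(hit, rank_weight, 0.0)
            p_in = np.cumsum(w)
            p_in /= p_in[-1]
            p_out = np.cumsum(~hit) / (N - len(idx))
            es[j] = np.sum(p_in - p_out)
        if normalize:
            es = es / N
        kept_names.append(name)
        rows.append(es)
    if not rows:
        raise ValueError("no gene set overlaps the expression matrix")
    return EnrichmentMatrix(
        kept_names, list(expr.sample_ids), np.vstack(rows), alpha=alpha, normalized=normalize
    )


def _sam_d(values: np.ndarray, labels01: np.ndarray, s0: float | None = None):
    in1 = labels01 == 1
    in0 = labels01 == 0
    n1, n0 = int(in1.sum()), int(in0.sum())
    m1 = values[:, in1].mean(axis=1)
    m0 = values[:, in0].mean(axis=1)
    ss1 = ((values[:, in1] - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((values[:, in0] - m0[:, None]) ** 2).sum(axis=1)
    pooled = (ss1 + ss0) / (n1 + n0 - 2)
    s = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
    if s0 is None:
        s0 = float(np.median(s))
    return (m1 - m0) / (s + s0), s0


def sam_two_class(
    values: np.ndarray,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """SAM-style moderated d-statistics with permutation q-values.

    ``values`` is feature-by-sample; ``labels`` binary (0/1 or two level
    strings). The exchangeability constant s0 is the median of the
    per-feature standard errors. The q-value of feature i is the FDR
    estimate at threshold |d_i|: the expected null exceedance count (mean
    over label permutations, pooled across features) divided by the observed
    number of calls, capped at 1 and made monotone in |d|; q = 0 requires
    that no permuted statistic anywhere reaches |d_i|.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("sam_two_class needs exactly two classes")
    y = (labels == levels[-1]).astype(int)
    if min(int(y.sum()), int((1 - y).sum())) < 2:
        raise ValueError("each class needs >= 2 samples")

    d, s0 = _sam_d(values, y)
    rng = np.random.default_rng(seed)
    n = len(y)
    n_feat = values.shape[0]
    abs_d = np.abs(d)
    order = np.argsort(-abs_d)
    thresholds = abs_d[order]
    exceed = np.empty((n_perm, n_feat))
    for b in range(n_perm):
        yp = y[rng.permutation(n)]
        dp, _ = _sam_d(values, yp, s0=s0)
        # count of null |d*| >= each observed threshold (pooled over features)
        null_sorted = np.sort(np.abs(dp))
        exceed[b] = n_feat - np.searchsorted(null_sorted, thresholds, side="left")
    mean_exceed = exceed.mean(axis=0)
    n_called = np.arange(1, n_feat + 1)
    fdr = np.minimum(mean_exceed / n_called, 1.0)
    # enforce monotone non-decreasing q along decreasing |d|
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n_feat)
    q[order] = q_sorted
    return pd.DataFrame({"d": d, "q": q})


def roc_auc(scores, labels) -> float:
    """AUC = Mann-Whitney U / (n1 * n0), ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("roc_auc needs both classes present")
    y = labels == levels[-1]
    pos, neg = scores[y], scores[~y]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def select_subtype_sets(
    enrichment: EnrichmentMatrix,
    subtype_labels,
    q_max: float = 0.0,
    auc_min: float = 0.85,
    n_perm: int = 1000,
    seed: int = 0,
) -> SetSelection:
    """One-vs-rest SAM + ROC selection of subtype-overexpressed gene sets.

    A set is selected for a subtype when its permutation q <= q_max, its
    one-vs-rest AUC > auc_min and its d-statistic is positive (overexpressed
    direction). Within each subtype, selected sets sort by descending AUC.
    """
    labels = np.asarray(subtype_labels)
    subtypes = np.unique(labels)
    if len(subtypes) < 2:
        raise ValueError("select_subtype_sets needs >= 2 subtypes")
    records = []
    for si, subtype in enumerate(subtypes):
        y = (labels == subtype).astype(int)
        sam = sam_two_class(enrichment.values, y, n_perm=n_perm, seed=seed + si)
        for i, name in enumerate(enrichment.set_names):
            auc = roc_auc(enrichment.values[i], y)
            d_i = float(sam["d"].iloc[i])
            q_i = float(sam["q"].iloc[i])
            selected = (q_i <= q_max) and (auc > auc_min) and (d_i > 0)
            records.append(
                {"set": name, "subtype": subtype, "d": d_i, "q": q_i, "auc": auc, "selected": selected}
            )
    table = pd.DataFrame.from_records(records).sort_values(
        ["subtype", "auc"], ascending=[True, False], kind="stable"
    )
    return SetSelection(table.reset_index(drop=True))


def mean_set_activity(enrichment: EnrichmentMatrix, set_subset) -> pd.Series:
    """Per-sample arithmetic mean ES over a subset of sets."""
    subset = list(set_subset)
    if not subset:
        raise ValueError("set subset must be non-empty")
    index = {s: i for i, s in enumerate(enrichment.set_names)}
    missing = [s for s in subset if s not in index]
    if missing:
        raise KeyError(f"unknown set name(s): {missing}")
    rows = [index[s] for s in subset]
    return pd.Series(enrichment.values[rows].mean(axis=0), index=enrichment.sample_ids)
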