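"""Pooled shRNA screen quantification and gene-level enrichment calling.

Reads are counted by exact match against the hairpin library, scaled to a
common depth, optionally compiled across screens with empirical-Bayes batch
adjustment, ranked per hairpin by a signal-to-noise metric, and rolled up to
genes with a weighted Kolmogorov-Smirnov running sum. Significance comes
from permuting the hairpin-to-gene assignment (preserving the
hairpins-per-gene multiset) with Benjamini-Hochberg FDR control per
direction.

The permutation null is POOLED across genes with the same hairpin count
(exchangeable under the null), which gives p-value resolution far below
1/n_perm — required for q thresholds like 0.005 at 1000 permutations.
The "hairpin score" used to filter supporting hairpins is the hairpin's
signal-to-noise metric itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from ovca.batch import combat_adjust
from ovca.io_formats import ExpressionMatrix, HairpinLibrary

__all__ = [
    "RigerResult",
    "count_hairpins",
    "normalize_counts",
    "combine_screens",
    "signal_to_noise",
    "riger_gene_scores",
    "riger_permutation_fdr",
    "riger",
    "call_subtype_genes",
    "cohens_d",
    "sirna_validation_call",
    "bh_qvalues",
]


@dataclass
class RigerResult:
    """Per-gene enrichment table plus the per-hairpin metrics behind it."""

    genes: pd.DataFrame  # gene, es, nes, p, q, direction, n_hairpins
    hairpins: pd.DataFrame  # hairpin_id, gene, metric (the "hairpin score")

    def __post_init__(self) -> None:
        q = self.genes["q"].to_numpy()
        if np.any((q < 0) | (q > 1)):
            raise ValueError("q-values must lie in [0, 1]")


def _read_format(path) -> str:
    path = str(path)
    if path.endswith((".fastq", ".fq")):
        return "fastq"
    return "fasta"


def count_hairpins(
    reads_path,
    library: HairpinLibrary,
    trim5: int = 0,
) -> tuple[pd.Series, int]:
    """Count reads matching library hairpins exactly.

    Each read is trimmed ``trim5`` bases from the 5' end, cut to the hairpin
    length, and must match a library sequence perfectly to count. Returns
    ``(counts indexed by hairpin_id, n_unmatched)``.
    """
    hp_len = len(library.sequences[0])
    seq_to_id = {s: h for s, h in zip(library.sequences, library.hairpin_ids)}
    counts = dict.fromkeys(library.hairpin_ids, 0)
    unmatched = 0
    n_reads = 0
    for record in SeqIO.parse(str(reads_path), _read_format(reads_path)):
        n_reads += 1
        window = str(record.seq)[trim5 : trim5 + hp_len].upper()
        hid = seq_to_id.get(window)
        if hid is None:
            unmatched += 1
        else:
            counts[hid] += 1
    if n_reads == 0:
        raise ValueError(f"{reads_path}: no reads")
    return pd.Series(counts, name="count"), unmatched


def normalize_counts(counts: pd.DataFrame, scale: float = 1e6, log2: bool = False) -> pd.DataFrame:
    """Scale each sample column so its total equals ``scale``.

    With ``log2=True``, returns log2(normalized + 1).
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-total sample column(s): {bad}")
    norm = counts / totals * scale
    if log2:
        norm = np.log2(norm + 1.0)
    return norm


def combine_screens(
    screens: dict[str, pd.DataFrame],
    scale: float = 1e6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compile raw count matrices from several screens into one adjusted matrix.

    Hairpins are intersected across screens (dropped hairpins reported),
    counts normalized to ``scale`` and log2(x+1) transformed, and screen
    batch effects removed by the empirical-Bayes location/scale adjustment.
    Returns ``(adjusted log2 matrix, report of excluded hairpins)``.
    """
    if not screens:
        raise ValueError("no screens given")
    names = list(screens)
    shared = set(screens[names[0]].index)
    for name in names[1:]:
        shared &= set(screens[name].index)
    if not shared:
        raise ValueError("empty hairpin intersection across screens")
    shared = sorted(shared)
    excluded = []
    for name in names:
        dropped = sorted(set(screens[name].index) - set(shared))
        excluded.extend({"screen": name, "hairpin_id": h} for h in dropped)
    report = pd.DataFrame(excluded, columns=["screen", "hairpin_id"])

    blocks, batches = [], []
    for name in names:
        norm = normalize_counts(screens[name].loc[shared], scale=scale, log2=True)
        blocks.append(norm)
        batches.extend([name] * norm.shape[1])
    merged = pd.concat(blocks, axis=1)
    if len(names) == 1:
        return merged, report
    expr = ExpressionMatrix(list(merged.index), list(merged.columns), merged.to_numpy())
    adjusted, _ = combat_adjust(expr, batches)
    return adjusted.to_frame(), report


def signal_to_noise(
    values_a: np.ndarray,
    values_b: np.ndarray,
    sd_floor_frac: float = 0.2,
    sd_floor_min: float = 0.2,
) -> np.ndarray:
    """Per-row (mean_A - mean_B) / (sd_A + sd_B) with a degeneracy floor.

    Each group SD is floored at ``max(sd_floor_frac * |mean|, sd_floor_min)``
    (the GenePattern convention for log-scale data). Rows are hairpins;
    1-D inputs are treated as a single row.
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("signal_to_noise needs >= 2 samples per group")
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    sa, sb = A.std(axis=1, ddof=1), B.std(axis=1, ddof=1)
    sa = np.maximum(sa, np.maximum(sd_floor_frac * np.abs(ma), sd_floor_min))
    sb = np.maximum(sb, np.maximum(sd_floor_frac * np.abs(mb), sd_floor_min))
    out = (ma - mb) / (sa + sb)
    return out if out.size > 1 else out.ravel()


def riger_gene_scores(
    metrics: pd.Series,
    library: HairpinLibrary,
    weight_exponent: int = 0,
) -> pd.DataFrame:
    """Weighted-KS gene enrichment scores from ranked hairpin metrics.

    Hairpins are ranked by metric descending. For a gene, hits increment the
    running sum by |metric|^p normalized over the gene's hairpins; misses
    decrement by 1/(N - n_gene). ``es_high`` is the maximum of the running
    sum (enrichment toward the high-metric end) and ``es_low`` the minimum
    (enrichment toward the low end). Genes absent from ``metrics`` are
    skipped with a warning.
    """
    if weight_exponent not in (0, 1):
        raise ValueError("weight_exponent must be 0 or 1")
    hp_ids = list(metrics.index)
    known = set(hp_ids)
    gene_map: dict[str, list[str]] = {}
    for g, hps in library.gene_to_hairpins.items():
        present = [h for h in hps if h in known]
        if not present:
            warnings.warn(f"gene {g!r} has no scored hairpins; skipped", stacklevel=2)
            continue
        gene_map[g] = present
    vals = metrics.to_numpy(dtype=float)
    order = np.argsort(-vals, kind="stable")
    rank_of = np.empty(len(vals), dtype=np.int64)
    rank_of[order] = np.arange(len(vals))
    pos_of_hp = {h: rank_of[i] for i, h in enumerate(hp_ids)}
    N = len(vals)
    sorted_vals = vals[order]

    # fully degenerate ranking (all metrics identical): positions are pure
    # tie-order artefacts, so there is no enrichment in either direction
    if np.ptp(vals) == 0:
        return pd.DataFrame(
            [
                {"gene": g, "es_high": 0.0, "es_low": 0.0, "n_hairpins": len(hps)}
                for g, hps in gene_map.items()
            ]
        ).set_index("gene")

    rows = []
    for gene, hps in gene_map.items():
        positions = np.sort(np.array([pos_of_hp[h] for h in hps]))
        m = len(positions)
        w = np.abs(sorted_vals[positions]) ** weight_exponent
        wsum = w.sum()
        if wsum == 0:
            w = np.full(m, 1.0 / m)
        else:
            w = w / wsum
        miss = 1.0 / (N - m)
        # running sum evaluated at each hit (after the increment) and just
        # before each hit; extremes over these points are the KS extrema
        cum_w = np.cumsum(w)
        before = np.concatenate([[0.0], cum_w[:-1]]) - (positions - np.arange(m)) * miss
        after = cum_w - (positions - np.arange(m)) * miss
        es_high = float(np.max(after))
        es_low = float(np.min(np.concatenate([before, [after[-1] - (N - 1 - positions[-1]) * miss]])))
        rows.append(
            {"gene": gene, "es_high": es_high, "es_low": es_low, "n_hairpins": m}
        )
    return pd.DataFrame(rows).set_index("gene")


def _random_position_sets(rng: np.random.Generator, n_draws: int, m: int, N: int) -> np.ndarray:
    """n_draws sorted m-subsets of range(N), drawn without replacement per row."""
    if m > N:
        raise ValueError("set size exceeds universe")
    pos = np.sort(rng.integers(0, N, size=(n_draws, m)), axis=1)
    if m > 1:
        bad = np.any(pos[:, 1:] == pos[:, :-1], axis=1)
        while bad.any():
            pos[bad] = np.sort(rng.integers(0, N, size=(int(bad.sum()), m)), axis=1)
            bad = np.any(pos[:, 1:] == pos[:, :-1], axis=1)
    return pos


def _batch_es(sorted_abs_weights: np.ndarray, N: int, positions: np.ndarray):
    """Vectorized es_high/es_low for rows of sorted hit positions."""
    m = positions.shape[1]
    w = sorted_abs_weights[positions]
    s = w.sum(axis=1, keepdims=True)
    w = np.where(s == 0, 1.0 / m, w / np.where(s == 0, 1.0, s))
    miss = 1.0 / (N - m)
    cum_w = np.cumsum(w, axis=1)
    offset = (positions - np.arange(m)[None, :]) * miss
    after = cum_w - offset
    before = np.concatenate([np.zeros((len(positions), 1)), cum_w[:, :-1]], axis=1) - offset
    tail = after[:, -1] - (N - 1 - positions[:, -1]) * miss
    highs = after.max(axis=1)
    lows = np.minimum(before.min(axis=1), tail)
    return highs, lows


def _null_es(
    sorted_abs_weights: np.ndarray,
    N: int,
    sizes: np.ndarray,
    rng: np.random.Generator,
    chunk: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Null es_high / es_low for random same-size hairpin sets (chunked)."""
    m = int(sizes[0])
    n_draws = len(sizes)
    highs = np.empty(n_draws)
    lows = np.empty(n_draws)
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        pos = _random_position_sets(rng, stop - start, m, N)
        highs[start:stop], lows[start:stop] = _batch_es(sorted_abs_weights, N, pos)
    return highs, lows


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in ranked p)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def riger_permutation_fdr(
    gene_scores: pd.DataFrame,
    metrics: pd.Series,
    library: HairpinLibrary,
    n_perm: int = 1000,
    weight_exponent: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation p-values and BH q-values for the gene enrichment scores.

    The null permutes the hairpin-to-gene assignment preserving the
    hairpins-per-gene multiset; null ES values pool across genes of the same
    size. p = (1 + #{null >= observed}) / (n_null + 1) toward each
    direction; BH is applied within direction. NES = ES / mean |null ES| of
    the size class.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    vals = metrics.to_numpy(dtype=float)
    order = np.argsort(-vals, kind="stable")
    sorted_abs = np.abs(vals[order]) ** weight_exponent
    N = len(vals)
    sizes = gene_scores["n_hairpins"].to_numpy()
    unique_sizes = np.unique(sizes)

    null_high: dict[int, np.ndarray] = {}
    null_low: dict[int, np.ndarray] = {}
    for m in unique_sizes:
        n_of_size = int(np.sum(sizes == m))
        draw_sizes = np.full(n_perm * n_of_size, m)
        highs, lows = _null_es(sorted_abs, N, draw_sizes, rng)
        null_high[m], null_low[m] = np.sort(highs), np.sort(lows)

    out = gene_scores.copy()
    p_high = np.empty(len(out))
    p_low = np.empty(len(out))
    nes_high = np.empty(len(out))
    nes_low = np.empty(len(out))
    for i, (m, eh, el) in enumerate(zip(sizes, out["es_high"], out["es_low"])):
        nh, nl = null_high[int(m)], null_low[int(m)]
        p_high[i] = (1 + len(nh) - np.searchsorted(nh, eh, side="left")) / (len(nh) + 1)
        p_low[i] = (1 + np.searchsorted(nl, el, side="right")) / (len(nl) + 1)
        nes_high[i] = eh / max(np.mean(np.abs(nh)), 1e-12)
        nes_low[i] = el / max(np.mean(np.abs(nl)), 1e-12)
    out["p_high"] = p_high
    out["p_low"] = p_low
    out["nes_high"] = nes_high
    out["nes_low"] = nes_low
    out["q_high"] = bh_qvalues(p_high)
    out["q_low"] = bh_qvalues(p_low)
    return out


def riger(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    library: HairpinLibrary,
    n_perm: int = 1000,
    weight_exponent: int = 0,
    seed: int = 0,
) -> RigerResult:
    """Full hairpin-to-gene pipeline for one binary comparison.

    ``values`` is the (log-scale, adjusted) hairpin-by-sample matrix;
    ``group_a`` / ``group_b`` name its columns. Depleted genes sink toward
    the low-metric end (group A abundance below group B), amplified genes
    rise toward the high end.
    """
    metrics = pd.Series(
        signal_to_noise(values[group_a].to_numpy(), values[group_b].to_numpy()),
        index=values.index,
        name="metric",
    )
    scores = riger_gene_scores(metrics, library, weight_exponent=weight_exponent)
    table = riger_permutation_fdr(
        scores, metrics, library, n_perm=n_perm, weight_exponent=weight_exponent, seed=seed
    )
    depleted = table["q_low"] <= table["q_high"]
    genes = pd.DataFrame(
        {
            "gene": table.index,
            "es": np.where(depleted, table["es_low"], table["es_high"]),
            "nes": np.where(depleted, table["nes_low"], table["nes_high"]),
            "p": np.where(depleted, table["p_low"], table["p_high"]),
            "q": np.where(depleted, table["q_low"], table["q_high"]),
            "p_low": table["p_low"].to_numpy(),
            "p_high": table["p_high"].to_numpy(),
            "q_low": table["q_low"].to_numpy(),
            "q_high": table["q_high"].to_numpy(),
            "direction": np.where(depleted, "depleted", "amplified"),
            "n_hairpins": table["n_hairpins"].to_numpy(),
        }
    ).set_index("gene")
    hp_to_gene = dict(zip(library.hairpin_ids, library.target_genes))
    hp = pd.DataFrame(
        {
            "hairpin_id": metrics.index,
            "gene": [hp_to_gene.get(h) for h in metrics.index],
            "metric": metrics.to_numpy(),
        }
    )
    return RigerResult(genes.reset_index(), hp)


def call_subtype_genes(
    result: RigerResult,
    q_max: float = 0.005,
    hairpin_score_min: float = 0.2,
) -> pd.DataFrame:
    """Significant genes (q < q_max) with their supporting hairpins.

    Supporting hairpins are those with |metric| >= hairpin_score_min.
    Returns one row per called gene with direction and the supporting
    hairpin ids.
    """
    genes = result.genes
    called = genes[genes["q"] < q_max]
    hp = result.hairpins
    rows = []
    for _, rec in called.iterrows():
        support = hp[
            (hp["gene"] == rec["gene"]) & (hp["metric"].abs() >= hairpin_score_min)
        ]["hairpin_id"].tolist()
        rows.append(
            {
                "gene": rec["gene"],
                "q": rec["q"],
                "es": rec["es"],
                "direction": rec["direction"],
                "supporting_hairpins": ",".join(support),
                "n_supporting": len(support),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "q", "es", "direction", "supporting_hairpins", "n_supporting"])


def cohens_d(values_a, values_b) -> float:
    """Standardized mean difference with the pooled (n-1 weighted) SD."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("cohens_d needs >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def sirna_validation_call(
    target_suppression: float,
    p_value: float,
    reference_suppression: float,
) -> bool:
    """Growth-suppression decision rule for follow-up knockdown hits.

    Pass requires >= 20% suppression on the target line at p < 0.001 AND
    >= 20 points more suppression than on the reference lines.
    """
    for v in (target_suppression, reference_suppression):
        if not -100 <= v <= 100:
            raise ValueError("suppression percentages must lie in [-100, 100]")
    if p_value is None or not np.isfinite(p_value):
        raise ValueError("p_value is required")
    return (
        target_suppression >= 20.0
        and p_value < 0.001
        and (target_suppression - reference_suppression) >= 20.0
    )
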