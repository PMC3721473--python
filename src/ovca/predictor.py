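"""One-vs-rest Bayesian probit metagene subtype classifiers.

Each subtype model takes the top core training samples (highest silhouette
width), ranks genes by absolute correlation with the one-vs-rest label,
projects the signature submatrix onto its leading singular vectors
("metagenes"), and fits a probit regression by truncated-normal
data-augmentation Gibbs sampling. New samples are projected onto the stored
basis and pushed through the probit link at the posterior-mean coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from ovca.io_formats import ExpressionMatrix
from ovca.subtyping import SubtypeAssignment

__all__ = [
    "PredictorConfig",
    "SignatureModel",
    "SubtypePrediction",
    "pick_core_training",
    "select_signature_genes",
    "metagene_decompose",
    "probit_fit",
    "predict_probability",
    "one_vs_rest",
    "cross_validate",
]


@dataclass
class PredictorConfig:
    n_per_subtype: int = 50
    n_genes: int = 100
    n_metagenes: int = 2
    n_mcmc: int = 2000
    burn_in: int = 500
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mcmc <= self.burn_in:
            raise ValueError("n_mcmc must exceed burn_in")


@dataclass
class SignatureModel:
    """Fitted one-vs-rest probit metagene model for a single subtype."""

    subtype: str
    genes: list[str]
    gene_scores: np.ndarray  # signed correlations, same order as genes
    gene_means: np.ndarray  # training means used for centering/imputation
    gene_sds: np.ndarray
    basis: np.ndarray  # genes x n_metagenes, orthonormal columns
    singular_values: np.ndarray
    coef_mean: np.ndarray  # intercept first
    coef_sd: np.ndarray
    training_samples: list[str]
    standardize: bool = True
    separation_detected: bool = False

    def __post_init__(self) -> None:
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.basis.shape[1]), atol=1e-8):
            raise ValueError("metagene basis columns must be orthonormal")


@dataclass
class SubtypePrediction:
    """Per-sample probabilities from every subtype model plus the argmax call."""

    sample_ids: list[str]
    probabilities: pd.DataFrame  # samples x subtypes
    assigned: pd.Series = field(init=False)
    low_confidence: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        p = self.probabilities
        if ((p.values < -1e-12) | (p.values > 1 + 1e-12)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        self.assigned = p.idxmax(axis=1)
        self.low_confidence = p.max(axis=1) < 0.5


def pick_core_training(
    assignment: SubtypeAssignment, n_per_subtype: int = 50, exclude=("Other",)
) -> dict[str, list[str]]:
    """Top-n core samples (largest SW, ties by lexicographically smaller id)."""
    out: dict[str, list[str]] = {}
    labels = assignment.labels
    for subtype in sorted(set(map(str, labels)) - set(exclude)):
        mask = (labels == subtype) & assignment.core
        ids = [assignment.sample_ids[i] for i in np.where(mask)[0]]
        sws = assignment.silhouette[mask]
        if not ids:
            raise ValueError(f"subtype {subtype!r} has no core samples")
        ranked = sorted(zip(ids, sws), key=lambda t: (-t[1], t[0]))
        if len(ranked) < n_per_subtype:
            warnings.warn(
                f"subtype {subtype!r}: only {len(ranked)} core samples "
                f"(< {n_per_subtype}); using all",
                stacklevel=2,
            )
        out[subtype] = [i for i, _ in ranked[:n_per_subtype]]
    return out


def select_signature_genes(expr: ExpressionMatrix, labels01, n_genes: int) -> pd.Series:
    """Genes ranked by |Pearson correlation| with the binary label.

    Returns a Series of signed correlations indexed by gene, length
    ``min(n_genes, n informative genes)``; constant genes score 0 and never
    reach the top ranks.
    """
    y = np.asarray(labels01, dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    X = expr.values
    yc = y - y.mean()
    xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom == 0, 0.0, (xc @ yc) / np.where(denom == 0, 1.0, denom))
    if n_genes > expr.n_genes:
        warnings.warn(
            f"n_genes {n_genes} > available {expr.n_genes}; using all", stacklevel=2
        )
        n_genes = expr.n_genes
    order = np.argsort(-np.abs(r), kind="stable")[:n_genes]
    return pd.Series(r[order], index=[expr.gene_ids[i] for i in order])


def metagene_decompose(values: np.ndarray, n_metagenes: int):
    """SVD metagene basis of a centered genes-x-samples signature submatrix.

    Returns ``(basis, singular_values, scores)`` where basis columns are the
    leading left singular vectors (oriented so each loading sum is >= 0) and
    ``scores`` are the per-sample projections (n_metagenes x samples).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("metagene decomposition needs >= 2 genes and >= 2 samples")
    centered = values - values.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    if S[0] == 0:
        raise ValueError("signature submatrix has rank 0")
    k = min(n_metagenes, int(np.sum(S > 1e-12 * S[0])))
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    flip = np.where(U.sum(axis=0) < 0, -1.0, 1.0)
    U = U * flip
    Vt = Vt * flip[:, None]
    scores = S[:, None] * Vt
    return U, S, scores


def probit_fit(
    scores: np.ndarray,
    labels01,
    n_mcmc: int = 2000,
    burn_in: int = 500,
    seed: int = 0,
    prior_var: float = 100.0,
):
    """Albert–Chib Gibbs sampler for probit regression with a vague normal prior.

    ``scores`` is covariates-by-samples; an intercept is prepended. Returns
    ``(coef_mean, coef_sd, separation_detected)`` with the intercept first.
    """
    y = np.asarray(labels01, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if n_mcmc <= burn_in:
        raise ValueError("n_mcmc must exceed burn_in")
    Xs = np.asarray(scores, dtype=float)
    if Xs.ndim == 1:
        Xs = Xs[None, :]
    n = len(y)
    X = np.column_stack([np.ones(n), Xs.T])  # n x (p+1)
    p = X.shape[1]

    rng = np.random.default_rng(seed)
    prior_prec = np.eye(p) / prior_var
    V = np.linalg.inv(X.T @ X + prior_prec)
    L = np.linalg.cholesky(V)
    beta = np.zeros(p)
    draws = np.empty((n_mcmc - burn_in, p))
    lo = np.where(y == 1, 0.0, -np.inf)
    hi = np.where(y == 1, np.inf, 0.0)
    for it in range(n_mcmc):
        mu = X @ beta
        a, b = (lo - mu), (hi - mu)
        z = mu + truncnorm.rvs(a, b, size=n, random_state=rng)
        mean = V @ (X.T @ z)
        beta = mean + L @ rng.standard_normal(p)
        if it >= burn_in:
            draws[it - burn_in] = beta
    coef_mean = draws.mean(axis=0)
    coef_sd = draws.std(axis=0, ddof=1)
    # perfect separation shows up as coefficient scale drifting to the prior SD
    separation = bool(np.any(np.abs(coef_mean[1:]) > 0.5 * np.sqrt(prior_var)))
    if separation:
        warnings.warn("possible complete separation: probit posterior is prior-dominated", stacklevel=2)
    return coef_mean, coef_sd, separation


def _train_one(
    expr: ExpressionMatrix,
    training_ids: list[str],
    labels01: np.ndarray,
    subtype: str,
    config: PredictorConfig,
    seed: int,
) -> SignatureModel:
    sub = expr.subset_samples(training_ids)
    corr = select_signature_genes(sub, labels01, config.n_genes)
    genes = list(corr.index)
    sig = sub.subset_genes(genes)
    means = sig.values.mean(axis=1)
    sds = sig.values.std(axis=1, ddof=1)
    sds = np.where(sds == 0, 1.0, sds)
    values = (sig.values - means[:, None]) / sds[:, None] if config.standardize else sig.values
    basis, svals, scores = metagene_decompose(values, config.n_metagenes)
    coef_mean, coef_sd, sep = probit_fit(
        scores, labels01, n_mcmc=config.n_mcmc, burn_in=config.burn_in, seed=seed
    )
    return SignatureModel(
        subtype=subtype,
        genes=genes,
        gene_scores=corr.to_numpy(),
        gene_means=means,
        gene_sds=sds,
        basis=basis,
        singular_values=svals,
        coef_mean=coef_mean,
        coef_sd=coef_sd,
        training_samples=list(training_ids),
        standardize=config.standardize,
        separation_detected=sep,
    )


def predict_probability(model: SignatureModel, expr: ExpressionMatrix) -> pd.Series:
    """Probit probability that each sample carries the model's subtype.

    Requires >= 80% of the signature genes; missing genes are imputed at the
    training mean with a warning.
    """
    present = [g for g in model.genes if g in set(expr.gene_ids)]
    coverage = len(present) / len(model.genes)
    if coverage < 0.8:
        raise ValueError(
            f"only {coverage:.0%} of signature genes present (< 80%) for {model.subtype}"
        )
    if coverage < 1.0:
        warnings.warn(
            f"{len(model.genes) - len(present)} signature gene(s) missing; "
            "imputed at training mean",
            stacklevel=2,
        )
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    values = np.empty((len(model.genes), expr.n_samples))
    for i, g in enumerate(model.genes):
        if g in gene_pos:
            values[i] = expr.values[gene_pos[g]]
        else:
            values[i] = model.gene_means[i]
    if model.standardize:
        values = (values - model.gene_means[:, None]) / model.gene_sds[:, None]
    else:
        values = values - model.gene_means[:, None]
    scores = model.basis.T @ values
    eta = model.coef_mean[0] + model.coef_mean[1:] @ scores
    return pd.Series(norm.cdf(eta), index=expr.sample_ids)


def one_vs_rest(
    expr: ExpressionMatrix,
    assignment: SubtypeAssignment,
    config: PredictorConfig | None = None,
    predict_on: ExpressionMatrix | None = None,
) -> tuple[dict[str, SignatureModel], SubtypePrediction]:
    """Train one model per subtype on its core samples and predict.

    ``predict_on`` defaults to the full training expression matrix; the
    returned prediction covers its samples (argmax assignment, flagging
    max-probability < 0.5 as low confidence).
    """
    config = config or PredictorConfig()
    cores = pick_core_training(assignment, config.n_per_subtype)
    subtypes = sorted(cores)
    if len(subtypes) < 2:
        raise ValueError("one_vs_rest needs >= 2 subtypes")
    all_training = sorted({s for ids in cores.values() for s in ids})
    models: dict[str, SignatureModel] = {}
    for si, subtype in enumerate(subtypes):
        labels01 = np.array([1 if s in set(cores[subtype]) else 0 for s in all_training])
        models[subtype] = _train_one(
            expr, all_training, labels01, subtype, config, seed=config.seed + si
        )
    target = predict_on if predict_on is not None else expr
    probs = pd.DataFrame(
        {subtype: predict_probability(models[subtype], target) for subtype in subtypes}
    )
    return models, SubtypePrediction(list(target.sample_ids), probs)


def cross_validate(
    expr: ExpressionMatrix,
    assignment: SubtypeAssignment,
    scheme: str = "kfold",
    k: int = 10,
    config: PredictorConfig | None = None,
    seed: int = 0,
    tuning_grid=None,
):
    """Stratified k-fold or three-way-split accuracy of the one-vs-rest scheme.

    Returns a DataFrame with one row per fold (accuracy = fraction of
    held-out samples whose argmax call matches their label) plus the mean.
    For ``three_way_split``, the tuning third picks (n_genes, n_metagenes)
    from ``tuning_grid`` before the test third is scored once.
    """
    config = config or PredictorConfig()
    labels = np.asarray(assignment.labels, dtype=object)
    usable = labels != "Other"
    ids = np.asarray(assignment.sample_ids, dtype=object)[usable]
    labs = labels[usable]
    sw = assignment.silhouette[usable]
    rng = np.random.default_rng(seed)

    label_of = dict(zip(ids, labs))

    def _fit_score(train_ids, test_ids, cfg):
        train_mask = np.isin(ids, train_ids)
        sub_assign = SubtypeAssignment(
            list(ids[train_mask]), labs[train_mask], sw[train_mask]
        )
        train_expr = expr.subset_samples(list(ids[train_mask]))
        test_expr = expr.subset_samples(list(test_ids))
        _, pred = one_vs_rest(train_expr, sub_assign, cfg, predict_on=test_expr)
        truth = np.array([label_of[s] for s in test_ids], dtype=object)
        return float(np.mean(pred.assigned.to_numpy() == truth))

    if scheme == "kfold":
        classes = np.unique(labs)
        if any((labs == c).sum() < k for c in classes):
            raise ValueError(f"k={k} exceeds the smallest class size")
        folds = [[] for _ in range(k)]
        for c in classes:
            members = np.where(labs == c)[0]
            rng.shuffle(members)
            for f, chunk in enumerate(np.array_split(members, k)):
                folds[f].extend(chunk.tolist())
        rows = []
        for f in range(k):
            test_ids = ids[np.asarray(folds[f], dtype=int)]
            train_ids = ids[~np.isin(np.arange(len(ids)), folds[f])]
            rows.append({"fold": f + 1, "accuracy": _fit_score(train_ids, test_ids, config)})
        table = pd.DataFrame(rows)
        table.loc[len(table)] = {"fold": "mean", "accuracy": table["accuracy"].mean()}
        return table

    if scheme == "three_way_split":
        grid = tuning_grid or [(config.n_genes, config.n_metagenes)]
        order = rng.permutation(len(ids))
        thirds = np.array_split(order, 3)
        train_ids, tune_ids, test_ids = (ids[t] for t in thirds)
        best_cfg, best_acc = None, -1.0
        for ng, nm in grid:
            cfg = PredictorConfig(
                n_per_subtype=config.n_per_subtype,
                n_genes=ng,
                n_metagenes=nm,
                n_mcmc=config.n_mcmc,
                burn_in=config.burn_in,
                standardize=config.standardize,
                seed=config.seed,
            )
            acc = _fit_score(train_ids, tune_ids, cfg)
            if acc > best_acc:
                best_cfg, best_acc = cfg, acc
        test_acc = _fit_score(np.concatenate([train_ids, tune_ids]), test_ids, best_cfg)
        return pd.DataFrame(
            [
                {"fold": "tune", "accuracy": best_acc},
                {"fold": "test", "accuracy": test_acc},
            ]
        )

    raise ValueError(f"unknown scheme {scheme!r}")
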