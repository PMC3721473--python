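"""Synthetic cohorts, gene sets, survival tables, screens and dose-response data.

Every generator is a pure function of (config, seed): the same seed yields
bit-identical output. Null configurations (all effects zero) produce data on
which downstream discovery should call nothing beyond nominal error rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ovca.io_formats import ClinicalTable, ExpressionMatrix, GeneSetCollection, HairpinLibrary

__all__ = [
    "CohortSimConfig",
    "ScreenSimConfig",
    "simulate_cohort",
    "simulate_gene_sets",
    "simulate_survival",
    "simulate_screen",
    "simulate_dose_response",
]


@dataclass
class CohortSimConfig:
    """Parameters of a multi-batch expression cohort with K latent subtypes.

    Subtype s shifts its ``genes_per_signature`` signature genes by
    ``signature_effect`` log2 units in samples of that subtype. Batch b adds a
    per-gene location offset drawn from ``batch_shift_range`` and multiplies
    residual noise by a scale drawn from ``batch_scale_range`` (matching the
    location/scale model of empirical-Bayes batch adjustment).
    """

    n_genes: int = 500
    n_samples: int = 200
    k_subtypes: int = 5
    genes_per_signature: int = 40
    signature_effect: float = 1.5
    n_batches: int = 1
    batch_shift_range: tuple[float, float] = (0.0, 0.0)
    batch_scale_range: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_subtypes < 2:
            raise ValueError("k_subtypes must be >= 2")
        if self.genes_per_signature * self.k_subtypes > self.n_genes:
            raise ValueError(
                "infeasible block allocation: genes_per_signature * k_subtypes "
                f"= {self.genes_per_signature * self.k_subtypes} > n_genes = {self.n_genes}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass
class ScreenSimConfig:
    """Parameters of a pooled shRNA screen with planted subtype-essential genes."""

    n_genes: int = 2000
    hairpins_per_gene: int = 5
    n_lines_target: int = 5
    n_lines_other: int = 9
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    n_essential_per_group: int = 100
    depletion_mean: float = 1.5
    depletion_sd: float = 0.5
    count_depth: int = 5_000_000
    hairpin_length: int = 21
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.hairpins_per_gene < 1:
            raise ValueError("hairpins_per_gene must be >= 1")
        if self.n_essential_per_group > self.n_genes:
            raise ValueError("more essential genes than genes")


def simulate_cohort(config: CohortSimConfig):
    """Generate ``(ExpressionMatrix, subtype_labels, batch_labels, signature_blocks)``.

    ``signature_blocks`` maps subtype label -> list of its signature gene ids.
    """
    rng = np.random.default_rng(config.rng_seed)
    g, n, k = config.n_genes, config.n_samples, config.k_subtypes

    gene_ids = [f"G{i:05d}" for i in range(g)]
    sample_ids = [f"S{j:04d}" for j in range(n)]
    subtypes = np.array([f"C{(j % k) + 1}" for j in range(n)])
    batches = np.array([f"B{(j % config.n_batches) + 1}" for j in range(n)])

    blocks: dict[str, list[str]] = {}
    for s in range(k):
        lo = s * config.genes_per_signature
        hi = lo + config.genes_per_signature
        blocks[f"C{s + 1}"] = gene_ids[lo:hi]

    values = rng.normal(0.0, config.noise_sd, size=(g, n))

    # batch location/scale effects on residuals (applied before subtype shift
    # so the biological signal survives adjustment exactly)
    # batch 1 is the reference (no shift, unit scale)
    lo_s, hi_s = config.batch_shift_range
    lo_c, hi_c = config.batch_scale_range
    for b in range(1, config.n_batches):
        cols = batches == f"B{b + 1}"
        gamma = rng.uniform(lo_s, hi_s, size=(g, 1))
        delta = rng.uniform(lo_c, hi_c, size=(g, 1))
        values[:, cols] = values[:, cols] * delta + gamma

    for s in range(k):
        lo = s * config.genes_per_signature
        hi = lo + config.genes_per_signature
        cols = subtypes == f"C{s + 1}"
        values[lo:hi, cols] += config.signature_effect

    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    return expr, subtypes, batches, blocks


def simulate_gene_sets(
    signature_blocks: dict[str, list[str]],
    gene_universe: list[str],
    n_decoy_sets: int = 10,
    set_size: int = 20,
    rng_seed: int = 0,
) -> GeneSetCollection:
    """One "true" set per subtype (subset of its signature) plus random decoys."""
    if set_size > len(gene_universe):
        raise ValueError(f"set_size {set_size} exceeds gene universe {len(gene_universe)}")
    rng = np.random.default_rng(rng_seed)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for subtype, genes in signature_blocks.items():
        size = min(set_size, len(genes))
        chosen = rng.choice(len(genes), size=size, replace=False)
        sets[f"TRUE_{subtype}"] = [genes[i] for i in sorted(chosen)]
        descriptions[f"TRUE_{subtype}"] = f"signature subset of {subtype}"
    universe = np.asarray(gene_universe, dtype=object)
    for d in range(n_decoy_sets):
        chosen = rng.choice(len(universe), size=set_size, replace=False)
        sets[f"DECOY_{d:03d}"] = [str(universe[i]) for i in sorted(chosen)]
        descriptions[f"DECOY_{d:03d}"] = "random decoy"
    return GeneSetCollection(sets, descriptions)


def simulate_survival(
    labels,
    baseline_hazard: float = 0.02,
    hazard_ratios: dict[str, float] | None = None,
    censoring_rate: float = 0.2,
    rng_seed: int = 0,
) -> ClinicalTable:
    """Exponential event times with per-subtype hazard ratios and uniform censoring.

    Censoring times are uniform on (0, c_max) with c_max chosen so the
    expected censored fraction approximates ``censoring_rate``;
    ``censoring_rate=0`` disables censoring entirely.
    """
    labels = np.asarray(labels, dtype=object)
    if hazard_ratios is None:
        hazard_ratios = {}
    hrs = np.array([float(hazard_ratios.get(lab, 1.0)) for lab in labels])
    if np.any(hrs <= 0):
        raise ValueError("hazard ratios must be > 0")
    if not 0 <= censoring_rate < 1:
        raise ValueError("censoring_rate must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    n = len(labels)
    haz = baseline_hazard * hrs
    event_times = rng.exponential(1.0 / haz)
    if censoring_rate > 0:
        # uniform(0, c) censor of exp(λ): P(censor) = 1 - (1-exp(-λc))/(λc);
        # solve crudely by bisection on the mean hazard
        lam = float(np.mean(haz))

        def censored_frac(c: float) -> float:
            # P(T > C), C ~ U(0, c), T ~ Exp(lam): decreasing in c
            return (1.0 - np.exp(-lam * c)) / (lam * c)

        lo, hi = 1e-9, 1e9
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if censored_frac(mid) > censoring_rate:
                lo = mid
            else:
                hi = mid
        c_max = np.sqrt(lo * hi)
        censor_times = rng.uniform(0.0, c_max, size=n)
        time = np.minimum(event_times, censor_times)
        event = (event_times <= censor_times).astype(int)
    else:
        time = event_times
        event = np.ones(n, dtype=int)
    time = np.maximum(time, 1e-9)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{j:04d}" for j in range(n)],
            "subtype": labels.astype(str),
            "os_time": time,
            "os_event": event,
        }
    )
    return ClinicalTable(df)


_BASES = np.array(list("ACGT"))


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seqs: set[str] = set()
    while len(seqs) < n:
        block = rng.integers(0, 4, size=(n - len(seqs), length))
        for row in block:
            seqs.add("".join(_BASES[row]))
            if len(seqs) == n:
                break
    return sorted(seqs)


def simulate_screen(config: ScreenSimConfig):
    """Generate ``(raw counts DataFrame, HairpinLibrary, essential gene list, group labels)``.

    Hairpin propensities are exponentiated Gaussian log-abundances; essential
    genes' hairpins are shifted down by a per-hairpin depletion effect
    (log2 units) in target-group samples only, then counts are multinomial at
    ``count_depth`` per sample. A negative ``depletion_mean`` plants
    amplified (growth-suppressing) genes instead.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_hp = config.n_genes * config.hairpins_per_gene
    genes = [f"GENE{i:05d}" for i in range(config.n_genes)]
    hairpin_ids = [
        f"HP{i:05d}_{j}" for i in range(config.n_genes) for j in range(config.hairpins_per_gene)
    ]
    target_genes = [g for g in genes for _ in range(config.hairpins_per_gene)]
    sequences = _random_sequences(rng, n_hp, config.hairpin_length)
    library = HairpinLibrary(hairpin_ids, target_genes, sequences)

    n_samples = config.n_lines_target + config.n_lines_other
    groups = np.array(
        ["target"] * config.n_lines_target + ["other"] * config.n_lines_other, dtype=object
    )
    sample_ids = [f"CL{j:02d}" for j in range(n_samples)]

    essential_idx = rng.choice(config.n_genes, size=config.n_essential_per_group, replace=False)
    essential = sorted(genes[i] for i in essential_idx)

    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_hp)
    log_abund = np.tile(base[:, None], (1, n_samples))
    target_cols = np.where(groups == "target")[0]
    hp_per = config.hairpins_per_gene
    for gi in essential_idx:
        rows = np.arange(gi * hp_per, (gi + 1) * hp_per)
        effect = rng.normal(config.depletion_mean, config.depletion_sd, size=hp_per)
        log_abund[np.ix_(rows, target_cols)] -= effect[:, None]

    prop = np.exp2(log_abund)
    prop /= prop.sum(axis=0, keepdims=True)
    if config.count_depth < 10 * n_hp:
        warnings.warn(
            f"count_depth {config.count_depth} is small relative to library size {n_hp}",
            stacklevel=2,
        )
    counts = np.column_stack(
        [rng.multinomial(config.count_depth, prop[:, j]) for j in range(n_samples)]
    )
    counts_df = pd.DataFrame(counts, index=hairpin_ids, columns=sample_ids)
    return counts_df, library, essential, groups


def simulate_dose_response(
    gi50_true: float,
    hill_slope: float,
    concentrations,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Hill-curve viability table: ``viability = 100 / (1 + (c/GI50)^hill)``.

    ``concentrations`` must be a positive geometric series (e.g. nine
    two-fold dilutions spanning a 256-fold range, or eight spanning 128-fold).
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(conc) >= 3:
        ratios = conc[1:] / conc[:-1]
        if not np.allclose(ratios, ratios[0], rtol=1e-6):
            raise ValueError("concentrations must form a geometric series")
    viability = 100.0 / (1.0 + (conc / gi50_true) ** hill_slope)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        viability = viability + rng.normal(0.0, noise_sd, size=len(conc))
    return pd.DataFrame({"concentration": conc, "viability": viability})
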