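import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovca.io_formats import HairpinLibrary
from ovca.screen import (
    bh_qvalues,
    call_subtype_genes,
    cohens_d,
    combine_screens,
    count_hairpins,
    normalize_counts,
    riger,
    riger_gene_scores,
    signal_to_noise,
    sirna_validation_call,
)
from ovca.simulate import ScreenSimConfig, simulate_screen


def brute_riger_es(metrics, positions_by_gene, N, p):
    """Explicit running-sum oracle: walk the full ranked list per gene."""
    order = np.argsort(-metrics, kind="stable")
    out = {}
    for gene, hit_idx in positions_by_gene.items():
        hits = set(hit_idx)
        weights = {i: abs(metrics[i]) ** p for i in hits}
        total = sum(weights.values())
        run = 0.0
        hi, lo = -np.inf, np.inf
        m = len(hits)
        for idx in order:
            if idx in hits:
                run += (weights[idx] / total) if total > 0 else 1.0 / m
            else:
                run -= 1.0 / (N - m)
            hi = max(hi, run)
            lo = min(lo, run)
        return_hi, return_lo = hi, lo
        out[gene] = (max(hi, 0.0), min(lo, 0.0))
    return out


def _library(n_genes, hp_per):
    ids = [f"h{g}_{i}" for g in range(n_genes) for i in range(hp_per)]
    genes = [f"G{g}" for g in range(n_genes) for _ in range(hp_per)]
    seqs = []
    k = 0
    bases = "ACGT"
    length = 12
    while len(seqs) < len(ids):
        s = "".join(bases[(k >> (2 * j)) & 3] for j in range(length))
        seqs.append(s)
        k += 1
    return HairpinLibrary(ids, genes, seqs)


class TestCounting:
    def test_exact_match_counting(self, tmp_path):
        lib = HairpinLibrary(["h1", "h2"], ["G1", "G2"], ["ACGTACGT", "TTTTAAAA"])
        reads = tmp_path / "r.fasta"
        reads.write_text(">r1\nACGTACGT\n>r2\nACGTACGT\n>r3\nTTTTAAAA\n>r4\nACGTACGA\n")
        counts, unmatched = count_hairpins(reads, lib)
        assert counts["h1"] == 2
        assert counts["h2"] == 1
        assert unmatched == 1  # one mismatch read rejected: perfect match only

    def test_trim5(self, tmp_path):
        lib = HairpinLibrary(["h1"], ["G1"], ["ACGTACGT"])
        reads = tmp_path / "r.fasta"
        reads.write_text(">r1\nNNACGTACGTXX\n")
        counts, unmatched = count_hairpins(reads, lib, trim5=2)
        assert counts["h1"] == 1 and unmatched == 0

    def test_fastq_supported(self, tmp_path):
        lib = HairpinLibrary(["h1"], ["G1"], ["ACGT"])
        reads = tmp_path / "r.fastq"
        reads.write_text("@r1\nACGT\n+\nIIII\n")
        counts, _ = count_hairpins(reads, lib)
        assert counts["h1"] == 1

    def test_empty_file_error(self, tmp_path):
        lib = HairpinLibrary(["h1"], ["G1"], ["ACGT"])
        reads = tmp_path / "r.fasta"
        reads.write_text("")
        with pytest.raises(ValueError, match="no reads"):
            count_hairpins(reads, lib)


class TestNormalize:
    def test_column_scaling(self):
        counts = pd.DataFrame({"s1": [2, 2]}, index=["h1", "h2"])
        norm = normalize_counts(counts, scale=1e6)
        assert norm["s1"].tolist() == [5e5, 5e5]

    def test_idempotent(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [1, 3]}, index=["h1", "h2"])
        once = normalize_counts(counts)
        twice = normalize_counts(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_ratios_preserved(self):
        counts = pd.DataFrame({"s1": [10, 40]}, index=["h1", "h2"])
        norm = normalize_counts(counts)
        assert norm.loc["h2", "s1"] / norm.loc["h1", "s1"] == pytest.approx(4.0)

    def test_zero_total_error(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["h1", "h2"])
        with pytest.raises(ValueError, match="zero-total"):
            normalize_counts(counts)


class TestCombine:
    def test_single_screen_passthrough(self):
        counts = pd.DataFrame({"s1": [5, 5], "s2": [2, 8]}, index=["h1", "h2"])
        merged, report = combine_screens({"A": counts})
        expected = normalize_counts(counts, log2=True)
        pd.testing.assert_frame_equal(merged, expected)
        assert report.empty

    def test_planted_offset_removed(self):
        rng = np.random.default_rng(4)
        hp = [f"h{i}" for i in range(200)]
        base = rng.normal(8, 1, size=(200, 1))
        a = np.round(2 ** (base + rng.normal(0, 0.1, (200, 4)))).astype(int)
        b = np.round(2 ** (base + 1.0 + rng.normal(0, 0.1, (200, 4)))).astype(int)
        screens = {
            "A": pd.DataFrame(a, index=hp, columns=[f"a{i}" for i in range(4)]),
            "B": pd.DataFrame(b, index=hp, columns=[f"b{i}" for i in range(4)]),
        }
        merged, _ = combine_screens(screens)
        ma = merged[[f"a{i}" for i in range(4)]].mean(axis=1)
        mb = merged[[f"b{i}" for i in range(4)]].mean(axis=1)
        assert np.abs(ma - mb).mean() < 0.12

    def test_intersection_reported(self):
        a = pd.DataFrame({"s1": [1, 2], "s2": [2, 3]}, index=["h1", "h2"])
        b = pd.DataFrame({"t1": [4, 5], "t2": [5, 6]}, index=["h1", "h3"])
        merged, report = combine_screens({"A": a, "B": b})
        assert list(merged.index) == ["h1"]
        assert set(report["hairpin_id"]) == {"h2", "h3"}

    def test_empty_intersection_error(self):
        a = pd.DataFrame({"s1": [1]}, index=["h1"])
        b = pd.DataFrame({"t1": [1]}, index=["h2"])
        with pytest.raises(ValueError, match="intersection"):
            combine_screens({"A": a, "B": b})


class TestSnr:
    def test_hand_value(self):
        out = signal_to_noise(np.array([[0.0, 2.0]]), np.array([[-2.0, 0.0]]))
        assert out[0] == pytest.approx(2 / (2 * np.sqrt(2)), abs=1e-12)

    def test_identical_groups_zero(self):
        out = signal_to_noise(np.array([[1.0, 2.0, 3.0]]), np.array([[1.0, 2.0, 3.0]]))
        assert out[0] == 0.0

    def test_antisymmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(5, 4)), rng.normal(size=(5, 6))
        np.testing.assert_allclose(signal_to_noise(a, b), -signal_to_noise(b, a))

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            signal_to_noise(np.array([[1.0]]), np.array([[1.0, 2.0]]))

    def test_sd_floor_prevents_blowup(self):
        out = signal_to_noise(np.array([[1.0, 1.0]]), np.array([[0.0, 0.0]]))
        assert np.isfinite(out[0])
        assert out[0] == pytest.approx(1.0 / (0.2 + 0.2))


class TestGeneScores:
    def test_top_block_max_es(self):
        lib = _library(20, 5)
        metrics = pd.Series(np.linspace(1, -1, 100), index=lib.hairpin_ids)
        # G0's hairpins hold ranks 1..5 by construction
        scores = riger_gene_scores(metrics, lib, weight_exponent=0)
        assert scores.loc["G0", "es_high"] == pytest.approx(1.0)

    def test_single_hairpin_bottom(self):
        lib = _library(3, 1)
        metrics = pd.Series([0.5, 0.2, -0.9], index=lib.hairpin_ids)
        scores = riger_gene_scores(metrics, lib, weight_exponent=0)
        assert scores.loc["G2", "es_low"] == pytest.approx(-1.0)

    def test_uniform_spread_small_es(self):
        # G0's 5 hairpins placed evenly (ranks 10, 30, 50, 70, 90 of 100)
        lib = _library(20, 5)
        ladder = np.linspace(1, -1, 100)
        spread = [9, 29, 49, 69, 89]
        g0 = [lib.hairpin_ids.index(h) for h in lib.gene_to_hairpins["G0"]]
        others = [i for i in range(100) if i not in g0]
        full = np.empty(100)
        full[g0] = ladder[spread]
        full[others] = np.delete(ladder, spread)
        metrics = pd.Series(full, index=lib.hairpin_ids)
        scores = riger_gene_scores(metrics, lib, weight_exponent=0)
        assert abs(scores.loc["G0", "es_high"]) < 0.3
        assert abs(scores.loc["G0", "es_low"]) < 0.3

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for rep in range(25):
            n_genes = int(rng.integers(5, 20))
            hp_per = int(rng.integers(1, 6))
            lib = _library(n_genes, hp_per)
            metrics_arr = rng.normal(size=len(lib.hairpin_ids))
            metrics = pd.Series(metrics_arr, index=lib.hairpin_ids)
            for p_exp in (0, 1):
                scores = riger_gene_scores(metrics, lib, weight_exponent=p_exp)
                for gene in scores.index:
                    idx = [lib.hairpin_ids.index(h) for h in lib.gene_to_hairpins[gene]]
                    oracle = brute_riger_es(metrics_arr, {gene: idx},
                                            len(metrics_arr), p_exp)[gene]
                    assert scores.loc[gene, "es_high"] == pytest.approx(oracle[0], abs=1e-12)
                    assert scores.loc[gene, "es_low"] == pytest.approx(oracle[1], abs=1e-12)


class TestBh:
    def test_hand_stepup(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.03, 1.0]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 1.0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_monotone_and_bounded(self, ps):
        p = np.array(ps)
        q = bh_qvalues(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRigerPipeline:
    @pytest.fixture(scope="class")
    def small_screen(self):
        cfg = ScreenSimConfig(n_genes=300, n_essential_per_group=20,
                              count_depth=2_000_000, rng_seed=5)
        counts, lib, essential, groups = simulate_screen(cfg)
        vals = normalize_counts(counts, log2=True)
        ga = [s for s, g in zip(counts.columns, groups) if g == "target"]
        gb = [s for s, g in zip(counts.columns, groups) if g == "other"]
        return vals, ga, gb, lib, essential

    def test_planted_genes_recovered(self, small_screen):
        vals, ga, gb, lib, essential = small_screen
        res = riger(vals, ga, gb, lib, n_perm=300, seed=1)
        calls = call_subtype_genes(res, q_max=0.03)
        dep = set(calls[calls["direction"] == "depleted"]["gene"])
        recall = len(dep & set(essential)) / len(essential)
        fdr = len(dep - set(essential)) / max(len(dep), 1)
        assert recall >= 0.8
        assert fdr <= 0.1

    def test_all_equal_metrics_p_near_one(self):
        lib = _library(10, 3)
        vals = pd.DataFrame(
            np.ones((30, 6)) * 5.0 + np.arange(30)[:, None] * 0.0,
            index=lib.hairpin_ids, columns=[f"s{i}" for i in range(6)],
        )
        res = riger(vals, ["s0", "s1", "s2"], ["s3", "s4", "s5"], lib,
                    n_perm=100, seed=0)
        assert (res.genes["p"] > 0.5).all()

    def test_direction_swap_on_negation(self, small_screen):
        vals, ga, gb, lib, _ = small_screen
        res_ab = riger(vals, ga, gb, lib, n_perm=150, seed=2)
        res_ba = riger(vals, gb, ga, lib, n_perm=150, seed=2)
        a = res_ab.genes.set_index("gene")["direction"]
        b = res_ba.genes.set_index("gene")["direction"]
        strong = res_ab.genes.set_index("gene").query("q < 0.01").index
        flipped = {"depleted": "amplified", "amplified": "depleted"}
        assert all(b[g] == flipped[a[g]] for g in strong)

    def test_q_threshold_monotonicity(self, small_screen):
        vals, ga, gb, lib, _ = small_screen
        res = riger(vals, ga, gb, lib, n_perm=150, seed=3)
        strict = set(call_subtype_genes(res, q_max=0.005)["gene"])
        loose = set(call_subtype_genes(res, q_max=0.03)["gene"])
        assert strict <= loose

    def test_hairpin_filter(self):
        genes = pd.DataFrame(
            {"gene": ["G1"], "es": [-0.9], "nes": [-2.0], "p": [0.001],
             "q": [0.004], "direction": ["depleted"], "n_hairpins": [2]}
        )
        hp = pd.DataFrame(
            {"hairpin_id": ["h1", "h2"], "gene": ["G1", "G1"], "metric": [0.25, 0.1]}
        )
        from ovca.screen import RigerResult

        calls = call_subtype_genes(RigerResult(genes, hp), q_max=0.005,
                                   hairpin_score_min=0.2)
        assert calls.iloc[0]["n_supporting"] == 1
        boundary = call_subtype_genes(RigerResult(genes.assign(q=0.006), hp),
                                      q_max=0.005)
        assert boundary.empty


class TestEffectSizes:
    def test_cohens_d_unit(self):
        # means 1 vs 0, each group variance 1 -> pooled SD 1 -> d = 1
        h = 1 / np.sqrt(2)
        assert cohens_d([1 - h, 1 + h], [-h, h]) == pytest.approx(1.0, abs=1e-12)

    def test_identical_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        assert cohens_d(2 * a, 2 * b) == pytest.approx(cohens_d(a, b), abs=1e-12)

    def test_zero_pooled_sd_error(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [0.0, 0.0])


class TestSirnaRule:
    def test_pass(self):
        assert sirna_validation_call(25.0, 1e-4, 2.0)

    def test_differential_fails(self):
        assert not sirna_validation_call(25.0, 1e-4, 10.0)

    def test_weak_target_fails(self):
        assert not sirna_validation_call(15.0, 1e-9, -50.0)

    def test_p_boundary(self):
        assert not sirna_validation_call(30.0, 0.001, 0.0)

    def test_missing_p_error(self):
        with pytest.raises(ValueError):
            sirna_validation_call(30.0, float("nan"), 0.0)
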