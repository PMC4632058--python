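import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldknni import (
    MISSING,
    GenotypeMatrix,
    MaskSet,
    SimConfig,
    allele_error,
    build_index,
    draw_mask,
    genotype_error,
    maf,
    maf_bias_experiment,
    masked_evaluation,
    neighbor_overlap,
    same_chromosome_probability,
    simulate,
)
from ldknni.evaluate import confusion_table

from conftest import make_random_gm
from reference import ref_impute, ref_taxicab


class TestErrorMetrics:
    def test_genotype_error_examples(self):
        assert genotype_error([0, 1, 2, 1], [0, 1, 2, 1]) == 0.0
        assert genotype_error([0, 2], [2, 0]) == 1.0
        assert genotype_error([0, 1, 2, 2], [0, 0, 2, 1]) == 0.5

    def test_allele_error_examples(self):
        assert allele_error([0, 1, 2, 2], [0, 0, 2, 1]) == pytest.approx(0.25)
        assert allele_error([0], [2]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            genotype_error([0, 1], [0])
        with pytest.raises(ValueError):
            allele_error([0, 1], [0])

    @given(
        st.lists(
            st.tuples(st.integers(0, 2), st.integers(0, 2)),
            min_size=1, max_size=50,
        )
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_allele_error_bracketed_by_genotype_error(self, pairs):
        truth = np.array([t for t, _ in pairs])
        pred = np.array([p for _, p in pairs])
        ge = genotype_error(truth, pred)
        ae = allele_error(truth, pred)
        assert ge / 2 - 1e-12 <= ae <= ge + 1e-12


class TestMaskedEvaluation:
    def test_clone_rich_fixture_perfect(self):
        # quadruplicated samples keep at least one clone observed at every
        # masked coordinate, so LD-kNNi with k=1 reconstructs all of them
        rng = np.random.default_rng(31)
        base = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        gm = GenotypeMatrix(
            np.vstack([base] * 4),
            [f"s{i}" for i in range(80)], [f"m{j}" for j in range(50)],
        )
        rep = masked_evaluation(gm, "ldknni", {"k": 1, "l": 10}, n_mask=100, seed=3)
        assert rep.genotype_error == 0.0
        assert rep.allele_error == 0.0

    def test_confusion_marginals_equal_mask_counts(self, small_gm):
        rep = masked_evaluation(small_gm, "mode", n_mask=120, seed=1)
        assert rep.confusion.sum() == 120
        for a in (0, 1, 2):
            assert rep.confusion[a].sum() == int(np.sum(rep.mask.truth == a))

    def test_mode_error_matches_expectation(self):
        # per-SNP expected mode error is 1 − modal-genotype frequency among
        # the masked draws; aggregated over many draws the observed error
        # must sit within binomial noise of the analytic expectation
        rng = np.random.default_rng(32)
        gm = make_random_gm(33, 80, 60, 0.0)
        rep = masked_evaluation(gm, "mode", n_mask=480, seed=9)
        masked = rep.mask.apply(gm)
        expected_wrong = 0.0
        for (s, p), truth in zip(rep.mask.coords, rep.mask.truth):
            col = masked.dosage[:, p]
            mode = np.argmax(np.bincount(col[col != MISSING], minlength=3))
            expected_wrong += float(mode != truth)
        assert rep.genotype_error == pytest.approx(expected_wrong / 480)

    def test_report_reproducible(self, small_gm):
        a = masked_evaluation(small_gm, "ldknni", {"k": 3, "l": 5}, n_mask=100, seed=5)
        b = masked_evaluation(small_gm, "ldknni", {"k": 3, "l": 5}, n_mask=100, seed=5)
        assert a.to_json() == b.to_json()
        assert np.array_equal(a.imputed.dosage, b.imputed.dosage)

    def test_per_maf_bin_totals(self, small_gm):
        rep = masked_evaluation(small_gm, "mode", n_mask=150, seed=2)
        assert rep.per_maf_bin["n_masked"].sum() == 150


class TestMafBias:
    def test_perfect_imputer_identity(self):
        # an injected truth oracle is unbiased by construction, so the
        # imputed MAF must equal the true MAF exactly
        gm = make_random_gm(34, 40, 30, 0.0)
        truth = gm.dosage.copy()
        oracle = lambda masked, coords: truth[coords[:, 0], coords[:, 1]]
        tables = maf_bias_experiment(gm, {"oracle": oracle}, 0.2, seed=4)
        tab = tables["oracle"]
        assert np.allclose(tab["true_maf"], tab["imputed_maf"], atol=1e-12)

    def test_mode_bias_is_downward(self):
        cfg = SimConfig(
            n_samples=300, n_snps=120, block_size=10, founder_pool=6,
            missing_rate=0.0, seed=35,
        )
        truth, _ = simulate(cfg)
        tables = maf_bias_experiment(truth, ["mode"], 0.2, seed=6)
        assert tables["mode"]["deviation"].mean() < 0

    def test_no_complete_snps_is_an_error(self):
        dos = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        gm = GenotypeMatrix(dos, ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError, match="complete"):
            maf_bias_experiment(gm, ["mode"], 0.2, seed=0)


class TestNeighborOverlap:
    def test_histogram_conserves_mask_size(self, small_gm):
        mask = draw_mask(small_gm, 60, seed=8)
        res = neighbor_overlap(small_gm, mask, k=3, l=6)
        assert res.histogram.sum() == 60
        assert res.histogram.shape == (4,)

    def test_clone_pair_shares_all_neighbors(self):
        rng = np.random.default_rng(36)
        base = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
        dos = np.vstack([base, base[0], base[0]])  # two extra clones of s0
        gm = GenotypeMatrix(
            dos, [f"s{i}" for i in range(12)], [f"m{j}" for j in range(40)]
        )
        mask = MaskSet(coords=np.array([[0, 3]]), truth=np.array([dos[0, 3]]))
        res = neighbor_overlap(gm, mask, k=2, l=5)
        assert res.histogram[2] == 1  # both clones chosen by both methods

    def test_matches_brute_force_neighbors(self):
        gm = make_random_gm(37, 20, 30, 0.15)
        mask = draw_mask(gm, 25, seed=1)
        res = neighbor_overlap(gm, mask, k=3, l=6)
        masked = mask.apply(gm)
        idx = build_index(masked, 6)
        hist = np.zeros(4, dtype=int)
        for s, p in mask.coords:
            col = masked.dosage[:, p]

            def top(metric):
                scored = []
                for t in range(masked.n_samples):
                    if t == s or col[t] == MISSING:
                        continue
                    d = metric(t)
                    if d is not None:
                        scored.append((d, t))
                scored.sort()
                return {t for _, t in scored[:3]}

            def knni_metric(t):
                d, n = ref_taxicab(masked.dosage, int(s), t)
                return d if n else None

            cols = idx.idx[int(p)]

            def ld_metric(t):
                d, n = ref_taxicab(masked.dosage, int(s), t, subset=cols)
                return 1.0 + (d if n else 0.0)

            hist[len(top(knni_metric) & top(ld_metric))] += 1
        assert np.array_equal(res.histogram, hist)

    def test_ld_neighbors_are_closer_in_dl(self, block_sim):
        _, truth, obs = block_sim
        mask = draw_mask(obs, 100, seed=3)
        res = neighbor_overlap(obs, mask, k=5, l=10)
        assert res.mean_dl_ldknni <= res.mean_dl_knni


class TestSameChromosome:
    def test_single_chromosome_degenerate(self):
        cfg = SimConfig(
            n_samples=60, n_snps=40, block_size=10, n_chromosomes=1,
            founder_pool=4, missing_rate=0.0, seed=38,
        )
        truth, _ = simulate(cfg)
        probs = same_chromosome_probability(truth, build_index(truth, 5))
        assert np.allclose(probs, 1.0)

    def test_within_chromosome_ld_dominates_rank_one(self):
        cfg = SimConfig(
            n_samples=400, n_snps=80, block_size=20, n_chromosomes=2,
            founder_pool=3, missing_rate=0.0, seed=39,
        )
        truth, _ = simulate(cfg)
        probs = same_chromosome_probability(truth, build_index(truth, 5))
        assert probs[0] > 0.5
        assert np.all((0 <= probs) & (probs <= 1))

    def test_requires_labels(self, small_gm):
        with pytest.raises(ValueError, match="chromosome"):
            same_chromosome_probability(small_gm, build_index(small_gm, 3))
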