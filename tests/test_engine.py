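"""Engine kernels: partials, rescaling, root/edge likelihoods, determinism."""

import math

import numpy as np
import pytest

from treelike import (
    Alignment,
    InstanceConfig,
    RateCategories,
    StateError,
    TreeLikelihood,
    ValidationError,
    build_model,
    compress_patterns,
    create_instance,
    discretize_gamma,
    eigendecompose,
    read_newick,
    set_instance_data,
    update_partials,
    update_transition_matrices,
    accumulate_scale_factors,
)
from treelike.scheduler import PartialOperation
from treelike.simulate import random_tree, simulate_alignment

from conftest import random_alignment, random_gtr, random_rates
from oracles import brute_force_loglik, scalar_partials


def driver(aln, tree, model, rates, **kw):
    return TreeLikelihood(compress_patterns(aln), tree, model, rates, **kw)


JC = build_model("JC", [0.25] * 4)
ONE_CAT = RateCategories(np.ones(1), np.ones(1))


class TestInstanceLifecycle:
    def test_minimal_config(self):
        cfg = InstanceConfig(tip_count=2, pattern_count=1, partials_buffer_count=3)
        inst = create_instance(cfg)
        assert inst.partials.shape == (3, 1, 1, 4)

    def test_zero_patterns_rejected(self):
        with pytest.raises(ValidationError):
            create_instance(
                InstanceConfig(tip_count=2, pattern_count=0, partials_buffer_count=3)
            )

    def test_subset_slots_independent(self):
        cfg = InstanceConfig(
            tip_count=2, pattern_count=4, partials_buffer_count=3,
            subset_count=10, category_count=4, eigen_buffer_count=10,
        )
        inst = create_instance(cfg)
        inst.set_category_rates(3, np.array([0.1, 0.2, 0.3, 3.4]))
        assert np.all(inst.category_rates[0] == 1.0)

    def test_wrong_pattern_weights_rejected(self):
        cfg = InstanceConfig(tip_count=2, pattern_count=4, partials_buffer_count=3)
        inst = create_instance(cfg)
        with pytest.raises(ValidationError, match="pattern_weights"):
            set_instance_data(inst, pattern_weights=np.ones(5))

    def test_tip_buffers_immutable(self):
        cfg = InstanceConfig(tip_count=2, pattern_count=2, partials_buffer_count=3)
        inst = create_instance(cfg)
        inst.set_tip_states(0, np.array([0, 1]))
        with pytest.raises(StateError, match="immutable"):
            inst.set_tip_states(0, np.array([1, 1]))


class TestTransitionMatrixUpdates:
    def _instance(self):
        cfg = InstanceConfig(
            tip_count=2, pattern_count=1, partials_buffer_count=3,
            matrix_buffer_count=4, category_count=1,
        )
        inst = create_instance(cfg)
        inst.set_eigen(0, eigendecompose(JC))
        return inst

    def test_zero_length_identity(self):
        inst = self._instance()
        update_transition_matrices(inst, 0, [0.0], [0])
        np.testing.assert_allclose(inst.matrices[0, 0], np.eye(4), atol=1e-12)

    def test_same_length_twice_bitwise_equal(self):
        inst = self._instance()
        update_transition_matrices(inst, 0, [0.37, 0.37], [0, 1])
        assert np.array_equal(inst.matrices[0], inst.matrices[1])

    def test_jc_closed_form(self):
        inst = self._instance()
        update_transition_matrices(inst, 0, [0.1], [2])
        e = math.exp(-4 * 0.1 / 3)
        assert inst.matrices[2, 0, 0, 0] == pytest.approx(0.25 + 0.75 * e, abs=1e-12)
        assert inst.matrices[2, 0, 0, 1] == pytest.approx(0.25 - 0.25 * e, abs=1e-12)

    def test_unset_eigen_is_state_error(self):
        cfg = InstanceConfig(tip_count=2, pattern_count=1, partials_buffer_count=3)
        inst = create_instance(cfg)
        with pytest.raises(StateError, match="eigen"):
            update_transition_matrices(inst, 0, [0.1], [0])

    def test_resetting_rates_changes_p_only_for_positive_t(self):
        cfg = InstanceConfig(
            tip_count=2, pattern_count=1, partials_buffer_count=3,
            matrix_buffer_count=2, category_count=2,
        )
        inst = create_instance(cfg)
        inst.set_eigen(0, eigendecompose(JC))
        inst.set_category_rates(0, np.array([0.5, 1.5]))
        update_transition_matrices(inst, 0, [0.0, 0.4], [0, 1])
        p0, p1 = inst.matrices[0].copy(), inst.matrices[1].copy()
        inst.set_category_rates(0, np.array([0.1, 1.9]))
        update_transition_matrices(inst, 0, [0.0, 0.4], [0, 1])
        np.testing.assert_array_equal(inst.matrices[0], p0)
        assert not np.array_equal(inst.matrices[1], p1)


class TestUpdatePartials:
    def test_cherry_zero_length_identical_tips(self):
        tree = read_newick("(A:0.0,B:0.0);")
        aln = Alignment(("A", "B"), ("A", "A"))
        tl = driver(aln, tree, JC, ONE_CAT)
        update_partials(tl.instance, tl.plan)
        np.testing.assert_allclose(
            tl.instance.partials[tree.root, 0, 0], [1, 0, 0, 0], atol=1e-12
        )

    def test_fully_ambiguous_tips_give_unit_partials(self):
        tree = read_newick("(A:0.3,B:0.7);")
        aln = Alignment(("A", "B"), ("N", "N"))
        tl = driver(aln, tree, JC, ONE_CAT)
        update_partials(tl.instance, tl.plan)
        np.testing.assert_allclose(
            tl.instance.partials[tree.root, 0, 0], np.ones(4), atol=1e-12
        )

    def test_unwritten_buffer_is_state_error(self):
        tree = read_newick("(A:0.1,B:0.1);")
        aln = Alignment(("A", "B"), ("A", "C"))
        tl = driver(aln, tree, JC, ONE_CAT)
        bad = [
            PartialOperation(
                dest_partials=2, child1_buffer=3, child2_buffer=1,
                child1_matrix=0, child2_matrix=1, dest_scale=0,
            )
        ]
        with pytest.raises(StateError, match="never written"):
            update_partials(tl.instance, bad)

    def test_partials_match_scalar_oracle(self, rng):
        # random 4-tip tree, HKY, 2 categories, 5 patterns; loop-free vs loops
        tree = random_tree(4, branch_mean=0.3, seed=42)
        aln = random_alignment(rng, 4, 5)
        model = build_model("HKY", rng.dirichlet(np.full(4, 10.0)), kappa=2.5)
        rates = discretize_gamma(0.7, 2)
        tl = TreeLikelihood(
            compress_patterns(aln), tree, model, rates, prefer_tip_states=False
        )
        update_partials(tl.instance, tl.plan)
        inst = tl.instance
        npat = inst.config.pattern_count
        for v in tree.postorder_internal():
            c1, c2 = (int(c) for c in tree.children[v])
            expected = scalar_partials(
                inst.matrices[c1],
                inst.matrices[c2],
                np.asarray(inst.full_partials(c1, 0, npat)),
                np.asarray(inst.full_partials(c2, 0, npat)),
            )
            np.testing.assert_allclose(inst.partials[v], expected, rtol=1e-12)


class TestRootLogLikelihood:
    def test_all_ambiguous_data_lnl_zero(self):
        tree = read_newick("(A:0.4,B:1.3);")
        aln = Alignment(("A", "B"), ("NNN", "NNN"))
        res = driver(aln, tree, JC, ONE_CAT).compute()
        assert res.total_log_likelihood == pytest.approx(0.0, abs=1e-12)

    def test_two_taxon_jc_closed_form(self):
        tree = read_newick("(A:0.1,B:0.1);")
        aln = Alignment(("A", "B"), ("AAAC", "AAAG"))  # 3 matches, 1 mismatch
        res = driver(aln, tree, JC, ONE_CAT).compute()
        e = math.exp(-4 * 0.2 / 3)
        expected = 3 * math.log(0.25 * (0.25 + 0.75 * e)) + math.log(
            0.25 * (0.25 - 0.25 * e)
        )
        assert res.total_log_likelihood == pytest.approx(expected, rel=1e-12)

    def test_per_pattern_values_sum_to_total(self, rng):
        tree = random_tree(6, seed=1)
        aln = random_alignment(rng, 6, 40)
        tl = driver(aln, tree, random_gtr(rng), discretize_gamma(0.5, 4))
        res = tl.compute(want_site_lnl=True)
        total = float(
            res.per_pattern_site_log_likelihood @ tl.patterns.weights
        )
        assert res.total_log_likelihood == pytest.approx(total, rel=1e-12)
        assert res.total_log_likelihood == pytest.approx(
            res.per_subset_log_likelihood.sum(), rel=1e-12
        )

    def test_matches_brute_force_small(self, rng):
        for trial in range(5):
            n = int(rng.integers(3, 6))
            tree = random_tree(n, branch_mean=0.2, seed=int(rng.integers(2**31)))
            aln = random_alignment(rng, n, 6, ambiguity=0.1)
            model = random_gtr(rng)
            rates = random_rates(rng)
            pats = compress_patterns(aln)
            res = TreeLikelihood(pats, tree, model, rates).compute()
            chars = ["".join(pats.patterns[p]) for p in range(pats.pattern_count)]
            expected = brute_force_loglik(
                tree, model.rate_matrix, model.frequencies,
                rates.rates, rates.weights, chars, pats.weights,
            )
            assert res.total_log_likelihood == pytest.approx(expected, rel=1e-10)

    def test_compression_consistency(self, rng):
        tree = random_tree(5, seed=9)
        aln = random_alignment(rng, 5, 60)
        compressed = driver(aln, tree, JC, ONE_CAT).compute().total_log_likelihood
        # uncompressed: every site its own pattern with weight one
        from treelike import PatternSet

        cols = np.array([list(s) for s in aln.sequences], dtype="U1").T
        pats = PatternSet(
            patterns=cols,
            weights=np.ones(aln.site_count, dtype=np.int64),
            subset_ranges=((0, aln.site_count),),
            subset_of_site=np.zeros(aln.site_count, dtype=int),
            taxon_names=aln.taxon_names,
        )
        uncompressed = TreeLikelihood(pats, tree, JC, ONE_CAT).compute()
        assert uncompressed.total_log_likelihood == pytest.approx(
            compressed, rel=1e-10
        )

    def test_root_invariance_under_rerooting(self, rng):
        from treelike.tree import unrooted_edges, root_on_edge

        tree = random_tree(8, branch_mean=0.2, seed=21)
        aln = random_alignment(rng, 8, 30)
        model = random_gtr(rng)
        base = driver(aln, tree, model, ONE_CAT).compute().total_log_likelihood
        _, edges = unrooted_edges(tree)
        for u, v, _ in edges:
            rerooted = root_on_edge(tree, (u, v))
            lnl = driver(aln, rerooted, model, ONE_CAT).compute().total_log_likelihood
            assert lnl == pytest.approx(base, rel=1e-10)


class TestEdgeLogLikelihood:
    def test_reproduces_root_total(self, rng):
        tree = random_tree(10, seed=3)
        aln = random_alignment(rng, 10, 50)
        tl = driver(aln, tree, random_gtr(rng), discretize_gamma(0.4, 4))
        root_lnl = tl.compute().total_log_likelihood
        edge = tl.edge_derivatives()
        assert edge.total_log_likelihood == pytest.approx(root_lnl, rel=1e-10)

    def test_identical_sequences_favor_zero_length(self):
        aln = Alignment(("A", "B"), ("ACGTACGT", "ACGTACGT"))
        for t in (0.05, 0.2, 1.0):
            tree = read_newick(f"(A:{t / 2},B:{t / 2});")
            d = driver(aln, tree, JC, ONE_CAT).edge_derivatives()
            assert d.d1 < 0

    def test_two_taxon_jc_analytic_derivative(self):
        # d/dt of m*ln(pm/4) + k*ln(px/4) at total t, differentiated by hand
        t, m, k = 0.2, 6, 2
        tree = read_newick(f"(A:{t / 2},B:{t / 2});")
        aln = Alignment(("A", "B"), ("ACGTACGT", "ACGAACGA"))
        d = driver(aln, tree, JC, ONE_CAT).edge_derivatives()
        e = math.exp(-4 * t / 3)
        pm, px = 0.25 + 0.75 * e, 0.25 - 0.25 * e
        expected = m * (-e) / pm + k * (e / 3) / px
        assert d.d1 == pytest.approx(expected, rel=1e-9)


class TestRescaling:
    def test_accumulate_zero_buffers_is_zero(self):
        cfg = InstanceConfig(
            tip_count=2, pattern_count=3, partials_buffer_count=3, scale_buffer_count=2
        )
        inst = create_instance(cfg)
        inst.scales[1] = 5.0
        accumulate_scale_factors(inst, [], 1)
        np.testing.assert_array_equal(inst.scales[1], 0.0)

    def test_accumulate_single_buffer_copies(self):
        cfg = InstanceConfig(
            tip_count=2, pattern_count=3, partials_buffer_count=3, scale_buffer_count=3
        )
        inst = create_instance(cfg)
        inst.scales[0] = [1.0, 2.0, 3.0]
        accumulate_scale_factors(inst, [0], 2)
        np.testing.assert_array_equal(inst.scales[2], inst.scales[0])

    def test_out_of_range_rejected(self):
        cfg = InstanceConfig(
            tip_count=2, pattern_count=3, partials_buffer_count=3, scale_buffer_count=2
        )
        with pytest.raises(ValidationError):
            accumulate_scale_factors(create_instance(cfg), [5], 0)

    def test_rescaled_matches_plain_16_tips(self, rng):
        tree = random_tree(16, branch_mean=0.2, seed=13)
        aln = random_alignment(rng, 16, 100)
        model = random_gtr(rng)
        rates = discretize_gamma(0.5, 4)
        plain = driver(aln, tree, model, rates, rescale="none").compute()
        scaled = driver(aln, tree, model, rates, rescale="always").compute()
        assert scaled.total_log_likelihood == pytest.approx(
            plain.total_log_likelihood, abs=1e-8
        )

    def test_deep_tree_underflows_without_rescaling(self):
        # deep enough that per-site likelihoods drop below the double range
        tree = random_tree(600, branch_mean=2.0, seed=2)
        model = JC
        aln = simulate_alignment(tree, model, None, 30, seed=3)
        plain = driver(aln, tree, model, ONE_CAT, rescale="none").compute()
        assert plain.total_log_likelihood == -np.inf
        assert len(plain.underflow_patterns) > 0
        scaled = driver(aln, tree, model, ONE_CAT, rescale="always").compute()
        assert np.isfinite(scaled.total_log_likelihood)


class TestDeterminism:
    def _lnl(self, aln, tree, impl, workers="auto", rescale="none"):
        return driver(
            aln, tree, JC, discretize_gamma(0.5, 4),
            implementation=impl, max_workers=workers, rescale=rescale,
        ).compute().total_log_likelihood

    def test_implementations_bitwise_identical(self, rng):
        tree = random_tree(12, seed=8)
        aln = random_alignment(rng, 12, 200)
        results = {
            self._lnl(aln, tree, "serial"),
            self._lnl(aln, tree, "vectorized"),
            self._lnl(aln, tree, "threaded", workers=1),
            self._lnl(aln, tree, "threaded", workers=2),
            self._lnl(aln, tree, "threaded", workers=4),
        }
        assert len(results) == 1

    def test_implementations_identical_with_rescaling(self, rng):
        tree = random_tree(10, seed=4)
        aln = random_alignment(rng, 10, 150)
        results = {
            self._lnl(aln, tree, impl, rescale="always")
            for impl in ("serial", "vectorized", "threaded")
        }
        assert len(results) == 1


class TestPartitions:
    def test_ten_subsets_additive(self, rng):
        # shared 10-subset instance vs ten separate single-subset instances
        tree = random_tree(8, branch_mean=0.15, seed=17)
        n_sub, sites_per = 10, 30
        models = [
            build_model("HKY", rng.dirichlet(np.full(4, 20.0)),
                        kappa=float(rng.uniform(1.5, 6.0)))
            for _ in range(n_sub)
        ]
        rates = [discretize_gamma(float(rng.uniform(0.3, 1.5)), 4) for _ in range(n_sub)]
        rel = rng.uniform(0.5, 2.0, size=n_sub)
        blocks = []
        for k in range(n_sub):
            scaled = tree.lengths * rel[k]
            t2 = type(tree)(tree.taxon_names, tree.parent, tree.children, scaled)
            blocks.append(simulate_alignment(t2, models[k], rates[k], sites_per, seed=50 + k))
        seqs = tuple(
            "".join(b.sequences[i] for b in blocks) for i in range(tree.tip_count)
        )
        aln = Alignment(tree.taxon_names, seqs)
        sub = np.repeat(np.arange(n_sub), sites_per)
        shared = TreeLikelihood(
            compress_patterns(aln, sub), tree, models, rates, subset_rates=rel
        ).compute()
        separate = 0.0
        for k in range(n_sub):
            res = TreeLikelihood(
                compress_patterns(blocks[k]), tree, models[k], rates[k],
                subset_rates=[rel[k]],
            ).compute()
            separate += res.total_log_likelihood
        assert shared.total_log_likelihood == pytest.approx(separate, rel=1e-10)
        assert shared.per_subset_log_likelihood.shape == (n_sub,)
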