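"""HMM transition structure, forward/backward, EM, and tract calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phylobias as pb
from phylobias.alignment_io import GenomicInterval
from phylobias.gbgc_hmm import BETA_FLOOR, Tract, emission_log_likelihoods
from phylobias.phylo_model import pattern_log_likelihoods
from conftest import brute_force_hmm


class TestTransitionMatrix:
    def test_all_zero_gives_identity(self):
        P = pb.build_transition_matrix(
            pb.HMMParams(mu=0.0, nu=0.0, alpha=0.0, beta=0.0)
        )
        assert np.allclose(P, np.eye(4))

    def test_cross_product_entries(self):
        P = pb.build_transition_matrix(pb.HMMParams(beta=1e-4))
        # n -> b: stay neutral, enter gBGC
        assert P[0, 1] == pytest.approx((1 - 0.0095) * 1e-4)
        # n -> cb: enter conserved AND enter gBGC
        assert P[0, 3] == pytest.approx(0.0095 * 1e-4)
        # b -> n: stay neutral, leave gBGC
        assert P[1, 0] == pytest.approx((1 - 0.0095) * 0.001)

    @given(
        vals=st.lists(st.floats(1e-6, 0.99), min_size=4, max_size=4)
    )
    @settings(max_examples=50, derandomize=True)
    def test_rows_sum_to_one(self, vals):
        P = pb.build_transition_matrix(pb.HMMParams(*vals))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_parameter_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pb.HMMParams(mu=1.5)
        with pytest.raises(ValueError):
            pb.HMMParams(beta=-0.1)


class TestInitialDistribution:
    def test_symmetric_conservation_marginal(self):
        d = pb.initial_distribution(pb.HMMParams(mu=0.3, nu=0.3, beta=1e-4))
        assert d[2] + d[3] == pytest.approx(0.5)

    def test_gbgc_marginal(self):
        d = pb.initial_distribution(pb.HMMParams(alpha=0.001, beta=1e-4))
        assert d[1] + d[3] == pytest.approx(1 / 11)

    def test_sums_to_one(self):
        d = pb.initial_distribution(pb.HMMParams())
        assert d.sum() == pytest.approx(1.0)


def _run_fb_on_logem(params, logem):
    """forward_backward on a raw emission matrix via a stub block."""
    block = pb.AlignmentBlock(
        species=["human", "chimpanzee", "orangutan", "rhesus"],
        seqs=np.zeros((4, logem.shape[0]), dtype=np.uint8),
        ref_coords=np.arange(logem.shape[0]),
    )
    return pb.forward_backward(block, None, params, logem=logem)


class TestForwardBackward:
    def test_length_one_posterior(self, toy_hmm):
        params, logem = toy_hmm
        track, ll, _ = _run_fb_on_logem(params, logem[:1])
        expect = pb.initial_distribution(params) * np.exp(logem[0])
        assert ll == pytest.approx(np.log(expect.sum()))
        assert np.allclose(track.state_posteriors[0], expect / expect.sum())

    def test_matches_path_enumeration(self, toy_hmm):
        params, logem = toy_hmm
        track, ll, xi = _run_fb_on_logem(params, logem)
        P = pb.build_transition_matrix(params)
        init = pb.initial_distribution(params)
        post, ll_ref, _ = brute_force_hmm(init, P, np.exp(logem))
        assert ll == pytest.approx(ll_ref, abs=1e-10)
        assert np.allclose(track.state_posteriors, post, atol=1e-10)
        # expected transition counts total L-1
        assert xi.sum() == pytest.approx(logem.shape[0] - 1)

    def test_posteriors_sum_to_one(self, toy_hmm):
        params, logem = toy_hmm
        track, _, _ = _run_fb_on_logem(params, logem)
        assert np.allclose(track.state_posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_loglik_invariant_to_pattern_caching(self, tree, neutral,
                                                 state_models):
        """Cached-pattern emissions equal direct per-column pruning."""
        rng = np.random.default_rng(3)
        seqs = rng.integers(0, 5, size=(4, 40)).astype(np.uint8)
        block = pb.AlignmentBlock(
            species=tree.leaf_names, seqs=seqs, ref_coords=np.arange(40)
        )
        cached = emission_log_likelihoods(block, state_models)
        direct = np.column_stack(
            [
                pattern_log_likelihoods(seqs.T.astype(np.int64), m)
                for m in state_models.models
            ]
        )
        assert np.allclose(cached, direct, atol=1e-12)
        params = pb.HMMParams()
        _, ll_a, _ = pb.forward_backward(block, state_models, params)
        _, ll_b, _ = pb.forward_backward(
            block, state_models, params, logem=direct
        )
        assert ll_a == pytest.approx(ll_b, abs=1e-10)


class TestViterbi:
    def test_deterministic_emissions_constant_path(self, tree, state_models):
        logem = np.full((8, 4), -100.0)
        logem[:, 2] = 0.0
        params = pb.HMMParams(beta=1e-4)
        P = pb.build_transition_matrix(params)
        init = pb.initial_distribution(params)
        from phylobias.gbgc_hmm import _viterbi_kernel
        with np.errstate(divide="ignore"):
            path = _viterbi_kernel(np.log(init), np.log(P), logem)
        assert np.all(path == 2)

    def test_matches_path_enumeration(self, toy_hmm):
        params, logem = toy_hmm
        P = pb.build_transition_matrix(params)
        init = pb.initial_distribution(params)
        _, _, best = brute_force_hmm(init, P, np.exp(logem))
        from phylobias.gbgc_hmm import _viterbi_kernel
        with np.errstate(divide="ignore"):
            path = _viterbi_kernel(np.log(init), np.log(P), logem)
        assert np.array_equal(path, best)


class TestEMFitBeta:
    def test_monotone_loglik(self, tree, neutral, state_models):
        cfg = pb.SimConfig(seed=5, n_columns=50_000, tract_length=1000,
                           B_sim=5.0, coverage=0.02)
        block, _, _ = pb.simulate_with_planted_tracts(tree, neutral, cfg)
        fitted, trace = pb.em_fit_beta(block, state_models, pb.HMMParams())
        diffs = np.diff(trace)
        assert np.all(diffs > -1e-8)
        assert fitted.beta > BETA_FLOOR

    def test_no_signal_clamps_to_floor(self, tree, state_models):
        block = pb.AlignmentBlock.from_strings(
            {n: "ACGT" * 1000 for n in tree.leaf_names}, target="human"
        )
        with pytest.warns(UserWarning, match="clamped"):
            fitted, _ = pb.em_fit_beta(block, state_models, pb.HMMParams())
        assert fitted.beta == BETA_FLOOR


def _track(posteriors, coords=None, chrom="chr1"):
    p = np.asarray(posteriors, dtype=float)
    sp = np.zeros((len(p), 4))
    sp[:, 1] = p
    sp[:, 0] = 1 - p
    coords = np.arange(len(p)) if coords is None else np.asarray(coords)
    return pb.PosteriorTrack(ref_coords=coords, state_posteriors=sp,
                             chrom=chrom)


class TestCallTracts:
    def test_simple_run(self):
        tracts = pb.call_tracts(_track([0.4, 0.6, 0.7, 0.3]))
        assert len(tracts) == 1
        assert (tracts[0].start, tracts[0].end) == (1, 3)
        assert tracts[0].score == pytest.approx(0.65)

    def test_all_below_threshold(self):
        assert pb.call_tracts(_track([0.1, 0.49, 0.2])) == []

    def test_threshold_inclusive(self):
        tracts = pb.call_tracts(_track([0.5, 0.5]))
        assert len(tracts) == 1
        assert (tracts[0].start, tracts[0].end) == (0, 2)

    def test_small_coordinate_gap_kept_in_one_run(self):
        tracts = pb.call_tracts(_track([0.9, 0.9], coords=[100, 600]))
        assert len(tracts) == 1
        assert (tracts[0].start, tracts[0].end) == (100, 601)

    def test_large_coordinate_gap_breaks_run(self):
        tracts = pb.call_tracts(_track([0.9, 0.9], coords=[100, 1200]))
        assert len(tracts) == 2

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            pb.call_tracts(_track([0.5]), threshold=1.5)


def _tract(chrom, start, end, score=0.8):
    return Tract(GenomicInterval(chrom, start, end, score), score=score)


class TestMergeTracts:
    def test_merge_within_gap(self):
        merged = pb.merge_tracts(
            [_tract("chr1", 0, 100), _tract("chr1", 600, 700)], max_gap=1000
        )
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 700)

    def test_gap_boundary(self):
        tracts = [_tract("chr1", 0, 100), _tract("chr1", 1101, 1200)]
        assert len(pb.merge_tracts(tracts, max_gap=1000)) == 2
        assert len(pb.merge_tracts(tracts, max_gap=1001)) == 1

    def test_zero_gap_identity(self):
        tracts = [_tract("chr1", 0, 100), _tract("chr1", 101, 200)]
        assert pb.merge_tracts(tracts, max_gap=0) == tracts

    def test_score_is_length_weighted(self):
        merged = pb.merge_tracts(
            [_tract("chr1", 0, 100, 1.0), _tract("chr1", 100, 400, 0.5)],
            max_gap=10,
        )
        assert merged[0].score == pytest.approx((100 * 1.0 + 300 * 0.5) / 400)

    def test_different_chroms_not_merged(self):
        tracts = [_tract("chr1", 0, 100), _tract("chr2", 100, 200)]
        assert len(pb.merge_tracts(tracts, max_gap=1000)) == 2

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError):
            pb.merge_tracts([_tract("chr1", 0, 100), _tract("chr1", 50, 150)])


@pytest.fixture(scope="module")
def sim(tree, neutral):
    cfg = pb.SimConfig(seed=21, n_columns=120_000, tract_length=2000,
                       B_sim=5.0, coverage=0.02)
    return pb.simulate_with_planted_tracts(tree, neutral, cfg)


class TestPipeline:
    def test_detects_planted_tracts(self, sim, tree):
        block, _, truth = sim
        res = pb.predict_tracts([block], tree, B=3.0, preprocess=False)
        acc = pb.prediction_accuracy(
            [t.interval for t in res.tracts], truth, block.n_columns
        )
        assert acc.tpr > 0.5
        assert acc.ppv is not None and acc.ppv > 0.5

    def test_identical_sequences_give_no_tracts(self, tree):
        row = "ACGTTGCA" * 2000
        block = pb.AlignmentBlock.from_strings(
            {n: row for n in tree.leaf_names}, target="human"
        )
        res = pb.predict_tracts([block], tree, B=3.0, preprocess=False)
        assert res.tracts == []
        # no substitutions: the fitted substitution rate collapses
        assert res.blocks[0].neutral.lam < 1e-3

    def test_viterbi_covers_no_more_than_posterior_calls(
        self, sim, tree, neutral
    ):
        """Max-product decoding misses tracts whose posterior is high."""
        block, _, _ = sim
        res = pb.predict_tracts([block], tree, B=3.0, preprocess=False)
        models = pb.build_state_models(res.blocks[0].neutral, B=3.0)
        path = pb.viterbi(block, models, res.blocks[0].params)
        viterbi_bases = int(np.isin(path, (1, 3)).sum())
        posterior_bases = sum(t.end - t.start for t in res.tracts)
        assert viterbi_bases <= posterior_bases

    def test_calls_robust_to_partition_choice(self, tree, neutral):
        """Tract calls barely move when the block size changes, since
        boundaries are restricted to runs uninformative about gBGC."""
        cfg = pb.SimConfig(seed=77, n_columns=400_000, tract_length=2000,
                           B_sim=5.0, coverage=0.02)
        block, _, truth = pb.simulate_with_planted_tracts(tree, neutral, cfg)
        # plant 2 kb unaligned runs (non-target rows missing) every 100 kb
        seqs = block.seqs.copy()
        for start in range(100_000, 400_000 - 2000, 100_000):
            seqs[1:, start : start + 2000] = 4  # 'N'
        block = pb.AlignmentBlock(
            species=block.species, seqs=seqs, ref_coords=block.ref_coords
        )
        masks = []
        for bs in (100_000, 400_000):
            res = pb.predict_tracts([block], tree, B=3.0, block_size=bs)
            m = np.zeros(cfg.n_columns, dtype=bool)
            for t in res.tracts:
                m[t.start : t.end] = True
            masks.append(m)
        inter = (masks[0] & masks[1]).sum()
        union = (masks[0] | masks[1]).sum()
        assert union > 0
        assert inter / union > 0.8

    def test_deterministic_outputs(self, sim, tree, tmp_path):
        block, _, _ = sim
        from phylobias.alignment_io import write_maf
        maf = tmp_path / "in.maf"
        write_maf(block, str(maf))
        outs = []
        for run in ("a", "b"):
            prefix = str(tmp_path / run)
            pb.run_pipeline(str(maf), "human", prefix, format="maf", B=3.0)
            outs.append(
                (prefix + ".tracts.bed", prefix + ".posterior.wig")
            )
        for fa, fb in zip(*outs):
            pass
        assert (
            open(outs[0][0]).read() == open(outs[1][0]).read()
        )
        assert (
            open(outs[0][1]).read() == open(outs[1][1]).read()
        )
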