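"""Model initialization, training, chunked inference, decoding, polishing."""

import numpy as np
import pytest

from polishnet import network, pileup, simgen, tensorize
from polishnet.network import ConsensusModel, ModelConfig, decode, init_model, predict, train


def _toy_data(n=6000, seed=0):
    """Error-free pileup over a random genome: a separable identity task."""
    genome = simgen.simulate_genome(n, 0.5, seed=seed)
    prof = simgen.ErrorProfile(sub_rate=0, ins_rate=0, del_rate=0, homopolymer_del_boost=1.0)
    reads = simgen.simulate_reads(genome, 10.0, prof, mean_len=400, seed=seed + 1)
    pl = pileup.build_pileup(genome, pileup.to_aligned_reads(reads, "contig"))
    tensors = tensorize.window_tensors(pl)
    labels, _ = tensorize.make_labels(genome, genome, [("=", n)])
    return tensors, labels


class TestInitModel:
    def test_seeded_init_is_bitwise_identical(self):
        m1 = init_model(ModelConfig(seed=1))
        m2 = init_model(ModelConfig(seed=1))
        for k in m1.net.params:
            assert (m1.net.params[k] == m2.net.params[k]).all()
        m3 = init_model(ModelConfig(seed=2))
        assert any((m1.net.params[k] != m3.net.params[k]).any() for k in m1.net.params)

    def test_hidden_size_monotone_in_parameters(self):
        small = init_model(ModelConfig(hidden_size=64)).parameter_count()
        large = init_model(ModelConfig(hidden_size=128)).parameter_count()
        assert large > small

    def test_inconsistent_feature_dim_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(window=3, feature_dim=21)

    def test_forward_posteriors_normalized_on_zero_input(self):
        model = init_model(ModelConfig(seed=3))
        X = np.zeros((50, model.config.feature_dim), dtype=np.float32)
        p1, p2f, p2s = predict(model, X)
        for p in (p1, p2f, p2s):
            assert np.isfinite(p).all()
            assert p.sum(axis=1) == pytest.approx(1.0, abs=1e-6)

    def test_checkpoint_round_trip(self, tmp_path):
        model = init_model(ModelConfig(seed=4))
        path = tmp_path / "m.npz"
        model.save(path)
        back = ConsensusModel.load(path)
        assert back.config == model.config
        for k in model.net.params:
            assert (back.net.params[k] == model.net.params[k]).all()


class TestTrain:
    def test_learns_separable_identity_task(self):
        tensors, labels = _toy_data(n=10_000)
        model = init_model(ModelConfig(seed=1))
        model, report = train(model, tensors, labels, epochs=5, seed=1, batch_size=4)
        assert all(np.isfinite(l) for l in report.epoch_losses)
        assert report.val_accuracy[-1] > 0.99

    def test_same_seed_reproducible(self):
        tensors, labels = _toy_data(n=2000)
        runs = []
        for _ in range(2):
            model = init_model(ModelConfig(seed=2))
            model, report = train(model, tensors, labels, epochs=2, seed=2)
            runs.append(report.epoch_losses[-1])
        assert runs[0] == runs[1]

    def test_shuffled_labels_learn_chance_level(self):
        tensors, labels = _toy_data(n=4000)
        rng = np.random.default_rng(0)
        shuffled = labels.copy()
        rng.shuffle(shuffled[:, 0])
        model = init_model(ModelConfig(seed=3))
        model, report = train(model, tensors, shuffled, epochs=3, seed=3)
        chance = np.bincount(shuffled[:, 0], minlength=5).max() / len(shuffled)
        assert report.val_accuracy[-1] < chance + 0.1

    def test_empty_dataset_rejected(self):
        model = init_model(ModelConfig(seed=1))
        with pytest.raises(ValueError):
            train(model, np.zeros((0, model.config.feature_dim), np.float32),
                  np.zeros((0, 3), np.int8))


class TestPredict:
    def test_short_input_single_chunk(self):
        model = init_model(ModelConfig(seed=5))
        X = np.random.default_rng(0).random((300, model.config.feature_dim)).astype(np.float32)
        p1, _, _ = predict(model, X)
        assert p1.shape == (300, 5)

    def test_chunked_matches_whole_sequence(self):
        """Stitched chunk predictions equal a single whole-sequence pass."""
        cfg = ModelConfig(seed=6)
        model = init_model(cfg)
        n = 3000
        X = np.random.default_rng(1).random((n, cfg.feature_dim)).astype(np.float32)
        p_chunked = predict(model, X)
        whole = model.net.predict_proba(X[None].astype(np.float32))
        for pc, pw in zip(p_chunked, whole):
            assert np.abs(pc - pw[0]).max() < 1e-5

    def test_dimension_mismatch_rejected(self):
        model = init_model(ModelConfig(seed=7))
        with pytest.raises(ValueError):
            predict(model, np.zeros((10, 7), np.float32))


class TestDecode:
    def test_one_hot_round_trip(self):
        truth = "ACGTACGT"  # one missing base, one extra draft base
        script = [("=", 2), ("D", 1), ("=", 3), ("I", "A"), ("=", 2)]
        from polishnet.edits import replay
        draft = replay(truth, script)
        assert draft == "ACTACAGT"
        labels, info = tensorize.make_labels(draft, truth, script)
        assert info.truncated_bases == 0
        assert decode(tensorize.one_hot_posteriors(labels)) == truth

    def test_all_del_decodes_empty(self):
        n = 5
        p1 = np.zeros((n, 5), np.float32)
        p1[:, tensorize.DEL] = 1.0
        p2 = np.zeros((n, 5), np.float32)
        p2[:, 0] = 1.0
        assert decode((p1, p2, p2)) == ""

    def test_output_length_formula_fuzz(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 200))
            p1 = rng.random((n, 5)).astype(np.float32)
            p2f = rng.random((n, 5)).astype(np.float32)
            p2s = rng.random((n, 5)).astype(np.float32)
            for p in (p1, p2f, p2s):
                p /= p.sum(axis=1, keepdims=True)
            seq = decode((p1, p2f, p2s))
            keep = p1.argmax(1) != tensorize.DEL
            ins1 = p2f[:, 0] < 0.5
            ins2 = ins1 & (p2s[:, 0] < 0.5)
            assert len(seq) == int(keep.sum() + ins1.sum() + ins2.sum())

    def test_phase1_only_decoding(self):
        labels = np.array([[0, 2, 0], [1, 0, 0]], dtype=np.int8)
        posts = tensorize.one_hot_posteriors(labels)
        assert decode(posts) == "ACC"
        assert decode(posts, use_phase2=False) == "AC"


class TestPolish:
    def test_k1_equals_predict_decode(self, tiny_genome):
        prof = simgen.ErrorProfile(sub_rate=0, ins_rate=0, del_rate=0,
                                   homopolymer_del_boost=1.0)
        reads = simgen.simulate_reads(tiny_genome, 8.0, prof, mean_len=300, seed=9)
        aligned = pileup.to_aligned_reads(reads, "contig")
        model = init_model(ModelConfig(seed=8))
        res = network.polish(tiny_genome, aligned, model, iterations=1)
        pl = pileup.build_pileup(tiny_genome, aligned)
        direct = decode(predict(model, tensorize.window_tensors(pl)))
        assert res.sequence == direct

    def test_invalid_iterations(self, tiny_genome):
        model = init_model(ModelConfig(seed=8))
        with pytest.raises(ValueError):
            network.polish(tiny_genome, [], model, iterations=0)


class TestPipelineInvariants:
    """Invariants of the polish loop on the seeded 100 kb benchmark."""

    def test_iteration_identity_non_decreasing(self, bench_polish):
        idents = bench_polish.identities
        assert idents[1] >= idents[0] - 0.001

    def test_polish_beats_draft(self, bench_polish):
        assert bench_polish.identities[-1] > bench_polish.draft_identity

    def test_input_agnostic_start(self, bench_model, bench_scenario, bench_polish):
        """Starting from the majority-vote consensus instead of the raw draft
        converges to the same accuracy (within 0.2%)."""
        from polishnet import evaluate

        baseline = bench_polish.baseline_sequence
        reads = pileup.map_reads(bench_scenario.aligned, baseline, contig_id="draft")
        res = network.polish(baseline, reads, bench_model, iterations=2,
                             truth=bench_scenario.truth)
        assert res.identities[-1] == pytest.approx(bench_polish.identities[-1], abs=0.002)
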