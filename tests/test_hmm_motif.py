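import numpy as np
import pytest
import yaml

from cliptome.annotation_io import GenomeSequence
from cliptome.hmm_motif import (
    CompositeMotifHMM,
    MotifAnnotation,
    annotate_genome,
    annotate_sequence,
    build_hmm,
    count_motifs_per_transcript,
    decode_motifs,
    encode_observations,
    merge_composites,
    path_log_probability,
    viterbi,
    viterbi_batch,
)
from cliptome.annotation_io import TranscriptModel
from cliptome.synthetic_data import SyntheticConfig, composite_template


@pytest.fixture(scope="module")
def hmm():
    return build_hmm()


def brute_force_best_paths(hmm, seq, tol=1e-9):
    """Independent oracle: enumerate every state path, vectorized scoring
    with the same left-to-right accumulation order as the decoder."""
    obs = encode_observations(seq)
    S, T = hmm.n_states, len(seq)
    grids = np.meshgrid(*([np.arange(S)] * T), indexing="ij")
    paths = np.stack([g.ravel() for g in grids], axis=1)  # (S^T, T)
    score = hmm.log_initial[paths[:, 0]] + hmm._log_emit[paths[:, 0], obs[0]]
    for t in range(1, T):
        score = score + hmm._log_trans[paths[:, t - 1], paths[:, t]]
        score = score + hmm._log_emit[paths[:, t], obs[t]]
    best = score.max()
    return best, {tuple(p) for p in paths[score >= best - tol]}


class TestBuildHmm:
    def test_rows_sum_to_one(self, hmm):
        assert np.allclose(hmm.transitions.sum(axis=1), 1.0)
        assert np.allclose(hmm.emissions.sum(axis=1), 1.0)

    def test_emission_probabilities(self, hmm):
        c_ca = hmm.state_names.index("C_ca")
        assert hmm.emissions[c_ca, 1] == pytest.approx(0.9)  # C
        assert np.allclose(np.delete(hmm.emissions[c_ca], 1), 0.1 / 3)

    def test_module_exit_probability(self, hmm):
        b = hmm.state_names.index("B")
        for s, name in enumerate(hmm.state_names):
            if hmm.modules[s] is not None:
                assert hmm.transitions[s, b] == pytest.approx(0.05)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            build_hmm(t1=1.5)
        with pytest.raises(ValueError):
            build_hmm(emit_main=0.2)

    def test_config_round_trip(self, hmm):
        text = yaml.safe_dump(hmm.to_dict())
        back = CompositeMotifHMM.from_dict(yaml.safe_load(text))
        assert np.array_equal(back.transitions, hmm.transitions)
        assert np.array_equal(back.emissions, hmm.emissions)
        assert back.state_names == hmm.state_names


class TestViterbi:
    def test_empty_sequence(self, hmm):
        assert viterbi(hmm, "").size == 0

    def test_poly_g_is_background(self, hmm):
        path = viterbi(hmm, "G" * 50)
        assert (path == hmm.state_names.index("B")).all()

    def test_oracle_equivalence_random_sequences(self, hmm):
        # exhaustive path enumeration on >=100 random short sequences
        rng = np.random.default_rng(30)
        alphabet = np.array(list("ACGU"))
        n_checked = 0
        for _ in range(110):
            T = int(rng.integers(1, 8))
            seq = "".join(alphabet[rng.integers(0, 4, T)])
            v = viterbi(hmm, seq)
            score = path_log_probability(hmm, seq, v)
            best, argmax_paths = brute_force_best_paths(hmm, seq)
            assert score == pytest.approx(best, abs=1e-9)
            assert tuple(v) in argmax_paths
            n_checked += 1
        assert n_checked >= 100

    def test_oracle_equivalence_longer_sequences(self, hmm):
        rng = np.random.default_rng(31)
        alphabet = np.array(list("ACGU"))
        for _ in range(4):
            seq = "".join(alphabet[rng.integers(0, 4, 9)])
            v = viterbi(hmm, seq)
            best, argmax_paths = brute_force_best_paths(hmm, seq)
            assert path_log_probability(hmm, seq, v) == pytest.approx(best, abs=1e-9)
            assert tuple(v) in argmax_paths

    def test_batch_matches_single(self, hmm):
        rng = np.random.default_rng(32)
        alphabet = np.array(list("ACGU"))
        seqs = ["".join(alphabet[rng.integers(0, 4, int(rng.integers(5, 60)))])
                for _ in range(20)]
        batch = viterbi_batch(hmm, seqs)
        for s, p in zip(seqs, batch):
            assert np.array_equal(p, viterbi(hmm, s))

    def test_long_sequence_finite(self, hmm):
        rng = np.random.default_rng(33)
        seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 1_000_000)])
        path = viterbi(hmm, seq)
        assert path.size == 1_000_000
        assert np.isfinite(path_log_probability(hmm, seq, path))


class TestDecodeMotifs:
    def test_simple_ca_run(self, hmm):
        b = hmm.state_names.index("B")
        c, a = hmm.state_names.index("C_ca"), hmm.state_names.index("A_ca")
        path = np.array([b] * 5 + [c, a] * 4 + [b] * 5)
        out = decode_motifs(hmm, path)
        assert [(m.start, m.end, m.motif_type) for m in out] == [(5, 13, "CA")]

    def test_short_run_discarded(self, hmm):
        b = hmm.state_names.index("B")
        u = hmm.state_names.index("U_ua")
        path = np.array([b] * 5 + [u] * 3 + [b] * 5)
        assert decode_motifs(hmm, path) == []

    def test_bridging_across_tiny_background_gap(self, hmm):
        b = hmm.state_names.index("B")
        c, a = hmm.state_names.index("C_ca"), hmm.state_names.index("A_ca")
        path = np.array([c, a] * 3 + [b] * 2 + [c, a] * 3)
        out = decode_motifs(hmm, path)
        assert [(m.start, m.end) for m in out] == [(0, 14)]


class TestMergeComposites:
    def _i(self, a, b, t):
        return MotifAnnotation(a, b, t)

    def test_alternating_within_gap(self):
        out = merge_composites([self._i(10, 20, "CA"), self._i(40, 48, "UA")])
        assert [(m.start, m.end, m.motif_type) for m in out] == \
            [(10, 48, "composite")]

    def test_gap_boundary_inclusive(self):
        merged = merge_composites([self._i(0, 10, "CA"), self._i(60, 70, "UA")])
        assert len(merged) == 1  # gap exactly 50
        dropped = merge_composites([self._i(0, 10, "CA"), self._i(61, 70, "UA")])
        assert dropped == []     # gap 51: both filtered as singles

    def test_same_type_pair_never_composite(self):
        out = merge_composites([self._i(0, 10, "CA"), self._i(20, 30, "CA")])
        assert out == []

    def test_single_instance_filtered(self):
        assert merge_composites([self._i(5, 15, "UA")]) == []

    def test_no_unmerged_instance_survives_sweep(self):
        rng = np.random.default_rng(34)
        for _ in range(200):
            pos = 0
            inst = []
            for _ in range(int(rng.integers(0, 8))):
                pos += int(rng.integers(1, 80))
                ln = int(rng.integers(4, 15))
                inst.append(self._i(pos, pos + ln,
                                    "CA" if rng.random() < 0.5 else "UA"))
                pos += ln
            out = merge_composites(inst)
            for m in out:
                assert m.motif_type == "composite"
                assert len(m.components) >= 2 or m.components == ()


class TestPlantAndRecover:
    def test_recovery_rate(self, hmm):
        # >=95% of planted composites recovered with >=80% interval overlap
        rng = np.random.default_rng(42)
        cfg = SyntheticConfig()
        alphabet = np.array(list("ACGU"))
        recovered = 0
        n = 500
        for _ in range(n):
            seq = "".join(alphabet[rng.integers(0, 4, 600)])
            tmpl, _ = composite_template(cfg, rng)
            off = int(rng.integers(0, 600 - len(tmpl) + 1))
            seq = seq[:off] + tmpl + seq[off + len(tmpl):]
            span = (off, off + len(tmpl))
            anns = annotate_sequence(hmm, seq)
            ok = any(
                (min(a.end, span[1]) - max(a.start, span[0])) / (span[1] - span[0])
                >= 0.8
                for a in anns
            )
            recovered += ok
        assert recovered / n >= 0.95


class TestAnnotateGenome:
    def _write_genome(self, tmp_path, seq, name="chrA"):
        fa = tmp_path / "g.fa"
        fa.write_text(f">{name}\n{seq}\n")
        return GenomeSequence(fa)

    def test_planted_composite_found_once(self, tmp_path, hmm):
        rng = np.random.default_rng(35)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
        tmpl, _ = composite_template(SyntheticConfig(), rng)
        t = tmpl.replace("U", "T")
        seq = seq[:2000] + t + seq[2000 + len(t):]
        genome = self._write_genome(tmp_path, seq)
        anns = annotate_genome(hmm, genome, chunk_size=1500, overlap=300)
        plus = [a for a in anns if a.strand == "+"
                and min(a.end, 2000 + len(t)) - max(a.start, 2000) > 0.8 * len(t)]
        assert len(plus) == 1

    def test_chunk_boundary_does_not_lose_composite(self, tmp_path, hmm):
        rng = np.random.default_rng(36)
        tmpl, _ = composite_template(SyntheticConfig(), rng)
        t = tmpl.replace("U", "T")
        # place the composite straddling the 1500-chunk step boundary
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 4000)])
        pos = 1490
        seq = seq[:pos] + t + seq[pos + len(t):]
        genome = self._write_genome(tmp_path, seq)
        anns = annotate_genome(hmm, genome, chunk_size=1500, overlap=300)
        hits = [a for a in anns if a.strand == "+"
                and min(a.end, pos + len(t)) - max(a.start, pos) > 0.8 * len(t)]
        assert len(hits) == 1

    def test_all_g_chromosome_empty(self, tmp_path, hmm):
        genome = self._write_genome(tmp_path, "G" * 3000)
        assert annotate_genome(hmm, genome) == []

    def test_minus_strand_mapping(self, tmp_path, hmm):
        rng = np.random.default_rng(37)
        tmpl, _ = composite_template(SyntheticConfig(), rng)
        from cliptome.annotation_io import reverse_complement
        t = reverse_complement(tmpl.replace("U", "T"))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        pos = 1200
        seq = seq[:pos] + t + seq[pos + len(t):]
        genome = self._write_genome(tmp_path, seq)
        anns = annotate_genome(hmm, genome)
        minus = [a for a in anns if a.strand == "-"
                 and min(a.end, pos + len(t)) - max(a.start, pos) > 0.8 * len(t)]
        assert len(minus) == 1


class TestCountMotifs:
    def _model(self):
        return TranscriptModel("t", "g", "chrA", "+", ((0, 300),), (50, 250))

    def test_composite_in_3utr(self):
        anns = [MotifAnnotation(260, 290, "composite", "+", "chrA")]
        stats, tracks = count_motifs_per_transcript(anns, {"t": self._model()})
        assert stats["t"]["n_3utr"] == 1 and stats["t"]["n_cds"] == 0
        assert tracks["t"][260:290].sum() == 30

    def test_straddling_majority_assignment(self):
        # 10 bases in CDS, 30 in 3'UTR -> assigned to 3'UTR
        anns = [MotifAnnotation(240, 280, "composite", "+", "chrA")]
        stats, _ = count_motifs_per_transcript(anns, {"t": self._model()})
        assert stats["t"]["n_3utr"] == 1 and stats["t"]["n_cds"] == 0

    def test_no_annotations(self):
        stats, tracks = count_motifs_per_transcript([], {"t": self._model()})
        assert stats["t"]["n_3utr"] == 0
        assert tracks["t"].sum() == 0
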