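import hashlib

import numpy as np
import pandas as pd
import pytest

from cliptome.annotation_io import load_annotation
from cliptome.coverage import LibraryIndex, count_base_calls
from cliptome.synthetic_data import (
    SyntheticConfig,
    generate_dataset,
    generate_transcriptome,
    simulate_rip,
    simulate_rnaseq,
)


def small_config(**kw):
    base = dict(n_genes=40, n_true_targets=8, rnaseq_library_size=50_000,
                clip_library_size=20_000, rip_library_size=20_000, seed=5)
    base.update(kw)
    return SyntheticConfig(**base)


class TestGenerateTranscriptome:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = small_config(seed=7)
        generate_transcriptome(cfg, tmp_path / "a")
        generate_transcriptome(cfg, tmp_path / "b")
        h = [hashlib.md5((tmp_path / d / "genome.fa").read_bytes()).hexdigest()
             for d in ("a", "b")]
        assert h[0] == h[1]

    def test_planted_motifs_inside_3utr(self, tmp_path):
        models, genome, truth = generate_transcriptome(small_config(), tmp_path)
        by_id = {m.transcript_id: m for m in models}
        assert len(truth.targets) == 8
        for tid, (a, b) in truth.motif_spans.items():
            m = by_id[tid]
            u3 = m.region_interval(2)
            assert u3[0] <= a and b <= u3[1]

    def test_planted_motif_reads_in_transcript_orientation(self, tmp_path):
        models, genome, truth = generate_transcriptome(small_config(), tmp_path)
        by_id = {m.transcript_id: m for m in models}
        checked_minus = False
        for tid in truth.targets:
            m = by_id[tid]
            seq = genome.transcript_sequence(m)
            a, b = truth.motif_spans[tid]
            assert seq[a:a + 12] == "CA" * 6
            assert seq[slice(*truth.ua_core_spans[tid])] == "UUAUU"
            checked_minus |= m.strand == "-"
        assert checked_minus  # both strands exercised

    def test_no_planted_targets_background_rate(self, tmp_path):
        cfg = small_config(n_true_targets=0)
        models, genome, truth = generate_transcriptome(cfg, tmp_path)
        # analytic expectation for a fixed 12-mer in iid uniform sequence
        total = sum(genome.chrom_length(c) for c in genome.chroms)
        expect = 2 * total * 0.25 ** 12  # both strands
        count = 0
        for c in genome.chroms:
            for strand in "+-":
                count += genome.fetch(c, 0, genome.chrom_length(c), strand) \
                    .count("CACACACACACA")
        assert count <= max(5, 10 * expect)

    def test_gtf_round_trip(self, tmp_path):
        models, _, _ = generate_transcriptome(small_config(), tmp_path)
        parsed, _ = load_annotation(tmp_path / "annotation.gtf",
                                    tmp_path / "genome.fa")
        by_id = {m.transcript_id: m for m in parsed}
        assert len(parsed) == len(models)
        for m in models:
            p = by_id[m.transcript_id]
            assert p.exons == m.exons
            assert p.cds_span == m.cds_span
            assert p.region_lengths == m.region_lengths


class TestSimulateReads:
    def test_expression_proportionality(self, tmp_path):
        cfg = small_config(rnaseq_library_size=100_000)
        models, _, truth = generate_transcriptome(cfg, tmp_path)
        expr = truth.expression.copy()
        reads = simulate_rnaseq(models, expr, cfg, np.random.default_rng(1))
        assert len(reads) == 100_000
        L = {m.transcript_id: m.L for m in models}
        w = np.array([expr[t] * L[t] for t in expr.index])
        p = w / w.sum()
        # doubling one gene's expression roughly doubles its share
        expr2 = expr.copy()
        gene = expr.index[0]
        expr2[gene] *= 2
        reads2 = simulate_rnaseq(models, expr2, cfg, np.random.default_rng(2))
        m0 = next(m for m in models if m.transcript_id == gene)
        n1 = ((reads["chrom"] == m0.chrom) & (reads["start"] >= m0.span[0])
              & (reads["end"] <= m0.span[1])).sum()
        n2 = ((reads2["chrom"] == m0.chrom) & (reads2["start"] >= m0.span[0])
              & (reads2["end"] <= m0.span[1])).sum()
        expected = 2 * p[0] / (1 + p[0])  # renormalized doubled share
        assert n2 / n1 == pytest.approx(2 * (expected / (2 * p[0])), rel=0.2)

    def test_seeded_determinism(self, tmp_path):
        cfg = small_config()
        models, _, truth = generate_transcriptome(cfg, tmp_path)
        a = simulate_rnaseq(models, truth.expression, cfg, np.random.default_rng(9))
        b = simulate_rnaseq(models, truth.expression, cfg, np.random.default_rng(9))
        assert a.equals(b)

    def test_rip_factor_expectation_single_target(self, tmp_path):
        # one low-abundance target among many: IP/input ratio ~ enrichment
        cfg = small_config(n_genes=60, n_true_targets=1,
                           target_expression_margin=0.0,
                           rip_library_size=200_000)
        models, _, truth = generate_transcriptome(cfg, tmp_path)
        ip, inp = simulate_rip(models, truth, cfg, np.random.default_rng(3))
        tid = next(iter(truth.targets))
        m = next(x for x in models if x.transcript_id == tid)
        ipt = count_base_calls(LibraryIndex(ip), m, library_role="rip_ip")
        int_ = count_base_calls(LibraryIndex(inp), m, library_role="rip_input")
        factor = (ipt.counts.sum() / len(ip)) / (int_.counts.sum() / len(inp))
        # target mass fraction shifts the library normalizer slightly
        assert factor == pytest.approx(5.0, rel=0.25)


class TestEnrichmentContract:
    def test_target_vs_nontarget_enrichment_ratio(self, small_dataset):
        # mean CLIP enrichment over target 3'UTRs ~ binding_enrichment
        from cliptome.coverage import enrichment, mean_region_enrichment
        data = small_dataset
        models = {m.transcript_id: m for m in data["models"]}
        truth = data["truth"]
        clip = LibraryIndex(data["reads"]["iclip_rep1"])
        rna = LibraryIndex(data["reads"]["rnaseq_rep1"])
        vals = {}
        for tid, m in models.items():
            ct = count_base_calls(clip, m, library_role="clip")
            rt = count_base_calls(rna, m, library_role="rnaseq")
            e = enrichment(ct, rt, m)
            if e.defined:
                vals[tid] = mean_region_enrichment(e, m, region=2)
        t = np.nanmean([v for k, v in vals.items() if k in truth.targets])
        nt = np.nanmean([v for k, v in vals.items() if k not in truth.targets])
        assert t / nt == pytest.approx(5.0, rel=0.3)

    def test_crosslink_pileup_at_cores(self, small_dataset):
        # more than half of a target's read starts fall within +-5 of the core
        from cliptome.coverage import crosslink_starts
        data = small_dataset
        truth = data["truth"]
        clip = LibraryIndex(data["reads"]["iclip_rep1"])
        models = {m.transcript_id: m for m in data["models"]}
        frac = []
        for tid in truth.targets:
            m = models[tid]
            st = crosslink_starts(clip, m)
            if st.total < 50:
                continue
            c0, c1 = truth.ua_core_spans[tid]
            center = (c0 + c1) // 2
            lo, hi = max(0, center - 5), min(m.L, center + 6)
            frac.append(st.starts[lo:hi].sum() / st.total)
        assert np.mean(frac) > 0.5


class TestCooperativeMode:
    def test_length_dependent_binding_correlation(self, tmp_path):
        # tag rate per nt ~ sqrt(3'UTR length): expression-normalized
        # density correlates positively with UTR length
        from cliptome.motif_stats import utr_length_correlation
        from cliptome.synthetic_data import simulate_clip
        cfg = small_config(n_genes=300, cooperative_alpha=0.5,
                           clip_library_size=150_000)
        models, _, truth = generate_transcriptome(
            cfg, tmp_path, np.random.default_rng(2))
        reads = simulate_clip(models, truth, cfg, np.random.default_rng(3))
        index = LibraryIndex(reads)
        dens, lens = [], []
        for m in models:
            a, b = m.region_interval(2)
            t = count_base_calls(index, m, library_role="clip")
            dens.append(t.counts[a:b].sum() / (b - a)
                        / truth.expression[m.transcript_id])
            lens.append(b - a)
        rho, p = utr_length_correlation(dens, lens)
        assert rho > 0.5 and p < 1e-6


class TestDataset:
    def test_layout_and_manifest(self, small_dataset):
        data = small_dataset
        assert set(data["reads"]) == {
            f"{n}_rep{r}" for n in
            ("rnaseq", "iclip", "pariclip", "rip_ip", "rip_input")
            for r in (1, 2)
        }
        truth_df = data["truth"].to_frame()
        assert truth_df["is_target"].sum() == 25
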