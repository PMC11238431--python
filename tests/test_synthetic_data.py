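"""Generator: determinism, ground-truth correspondence, planted-effect
calibration at reduced problem sizes."""

import numpy as np
import pandas as pd
import pytest

from triplimeth import genome_io as gio
from triplimeth.synthetic_data import (
    DMRPlan,
    DuplicationPlan,
    M6APlan,
    SimulationConfig,
    dmr_recovery_config,
    duplication_plan_config,
    m6a_metagene_config,
    simulate_annotation,
    simulate_expression,
    simulate_m6a,
    simulate_methylome,
    simulate_svs,
    sv_breakpoint_config,
)


def small_dmr_cfg(seed, **kw):
    kw.setdefault("genome_size", 200_000)
    kw.setdefault("n_dmrs", 20)
    return dmr_recovery_config(seed, **kw)


# ---------------------------------------------------------------------------
# Determinism
# ---------------------------------------------------------------------------

def test_same_seed_reproduces_everything():
    a = simulate_annotation(small_dmr_cfg(5))
    b = simulate_annotation(small_dmr_cfg(5))
    assert a.seqs == b.seqs
    assert a.truth.dmrs == b.truth.dmrs
    pd.testing.assert_frame_equal(simulate_methylome(a, "B", 0),
                                  simulate_methylome(b, "B", 0))


def test_different_seed_changes_outputs():
    a = simulate_annotation(small_dmr_cfg(5))
    b = simulate_annotation(small_dmr_cfg(6))
    assert a.seqs != b.seqs


def test_annotation_determinism_with_genes():
    a = simulate_annotation(duplication_plan_config(3))
    b = simulate_annotation(duplication_plan_config(3))
    assert a.seqs == b.seqs
    assert [(g, a.annotation.genes[g].interval) for g in sorted(a.annotation.genes)] \
        == [(g, b.annotation.genes[g].interval) for g in sorted(b.annotation.genes)]
    pd.testing.assert_frame_equal(a.truth.pairs, b.truth.pairs)


# ---------------------------------------------------------------------------
# Plan realization
# ---------------------------------------------------------------------------

def test_duplication_plan_realized(dup_genome):
    truth = dup_genome.truth
    plan = dup_genome.config.duplication
    from collections import Counter

    counts = Counter(truth.gene_classes.values())
    assert counts["singleton"] == plan.n_singleton
    assert counts["tandem"] == 2 * plan.n_tandem_pairs
    assert counts["proximal"] == 2 * plan.n_proximal_pairs
    assert counts["dispersed"] == 2 * plan.n_dispersed_pairs
    assert counts["wgt"] == plan.n_wgt_genes
    assert len(dup_genome.annotation.genes) == plan.total_genes
    # every planted paralog pair names existing genes
    for row in truth.pairs.itertuples():
        assert row.gene_a in dup_genome.annotation.genes
        assert row.gene_b in dup_genome.annotation.genes


def test_tandem_pairs_adjacent_and_proximal_within_gap(dup_genome):
    from triplimeth.duplication import rank_genes

    ranks = rank_genes(dup_genome.annotation.genes)
    plan = dup_genome.config.duplication
    for row in dup_genome.truth.pairs.itertuples():
        cls = dup_genome.truth.gene_classes[row.gene_a]
        ra, rb = ranks[row.gene_a], ranks[row.gene_b]
        if cls == "tandem":
            assert ra.chrom == rb.chrom and abs(ra.rank - rb.rank) == 1
        elif cls == "proximal":
            gap = abs(ra.rank - rb.rank) - 1
            assert ra.chrom == rb.chrom and 1 <= gap <= plan.proximal_gap_max + 1
        elif cls == "dispersed":
            assert ra.chrom != rb.chrom


def test_three_copy_segments_give_triplet_groups(dup_genome):
    triplets = [g for g in dup_genome.truth.wgt_groups if len(g) == 3]
    assert len(triplets) == 10  # one 10-gene segment copied to 3 loci
    for trio in triplets:
        assert {dup_genome.truth.wgt_copy_number[g] for g in trio} == {3}


def test_infeasible_plan_rejected_before_writing():
    cfg = SimulationConfig(n_chroms=2, duplication=DuplicationPlan())
    with pytest.raises(ValueError, match="infeasible"):
        simulate_annotation(cfg)


# ---------------------------------------------------------------------------
# Methylome structure
# ---------------------------------------------------------------------------

def test_zero_baselines_give_fully_unmethylated_calls():
    cfg = small_dmr_cfg(9, n_dmrs=0, genome_size=50_000)
    for ctx in cfg.methylation.baselines:
        for cls in cfg.methylation.baselines[ctx]:
            cfg.methylation.baselines[ctx][cls] = 0.0
    g = simulate_annotation(cfg)
    calls = simulate_methylome(g, "A", 0)
    assert (calls["count_methylated"] == 0).all()
    assert (calls["count_unmethylated"] > 0).any()


def test_baseline_outside_unit_interval_errors():
    cfg = small_dmr_cfg(9, n_dmrs=0, genome_size=10_000)
    cfg.methylation.baselines["CG"]["gene"] = 1.2
    with pytest.raises(ValueError, match="baseline"):
        simulate_annotation(cfg)


def test_planted_dmr_group_difference_near_delta():
    """Observed window-mean group difference within +-0.1 of the planted
    0.6 at depth 20 with 3 replicates (binomial/beta SE bound)."""
    cfg = small_dmr_cfg(1, n_dmrs=20, delta=0.6)
    g = simulate_annotation(cfg)
    reps_a = [simulate_methylome(g, "A", r) for r in range(3)]
    reps_b = [simulate_methylome(g, "B", r) for r in range(3)]

    def span_level(reps, chrom, start, end):
        levels = []
        for rep in reps:
            sub = rep[(rep["chrom"] == chrom) & (rep["context"] == "CG")
                      & (rep["pos"] > start) & (rep["pos"] <= end)]
            levels.append(sub["count_methylated"].sum()
                          / (sub["count_methylated"].sum() + sub["count_unmethylated"].sum()))
        return float(np.mean(levels))

    for chrom, start, end, ctx, delta, _ in g.truth.dmrs:
        diff = span_level(reps_b, chrom, start, end) - span_level(reps_a, chrom, start, end)
        assert abs(diff - delta) < 0.1


def test_cytosine_contexts_match_sequence():
    g = simulate_annotation(small_dmr_cfg(4, n_dmrs=0, genome_size=20_000))
    calls = simulate_methylome(g, "A", 0)
    seq = g.seqs["Chr1"]
    sample = calls.sample(200, random_state=0)
    for row in sample.itertuples():
        i = row.pos - 1
        if row.strand == "+":
            assert seq[i] == "C"
            trio = seq[i:i + 3]
        else:
            assert seq[i] == "G"
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            trio = "".join(comp[b] for b in seq[i - 2:i + 1][::-1])
        if row.context == "CG":
            assert trio[1] == "G"
        elif row.context == "CHG":
            assert trio[1] != "G" and trio[2] == "G"
        else:
            assert trio[1] != "G" and trio[2] != "G"


# ---------------------------------------------------------------------------
# SVs
# ---------------------------------------------------------------------------

def test_empty_sv_plan_gives_header_only_vcf(tmp_path):
    g = simulate_annotation(small_dmr_cfg(2, n_dmrs=0, genome_size=30_000))
    records = simulate_svs(g)
    assert records == []
    out = tmp_path / "empty.vcf"
    gio.write_sv_vcf(records, out, contigs=g.chrom_lengths)
    assert gio.parse_sv_vcf(out) == []


def test_sv_breakpoints_recorded_in_truth():
    cfg = sv_breakpoint_config(3, genome_size=400_000, n_ins=50)
    g = simulate_annotation(cfg)
    records = simulate_svs(g)
    assert len(records) == 50
    assert len(g.truth.sv_breakpoints) == 50  # one breakpoint per INS
    assert all(flag for _, _, flag in g.truth.sv_breakpoints)
    for rec in records:
        assert 0 < rec.pos <= g.chrom_lengths[rec.chrom]


def test_breakpoint_chh_elevation_in_expectation():
    """Mean CHH near flagged breakpoints exceeds the far-field mean by
    ~delta (+-0.05)."""
    cfg = sv_breakpoint_config(8, genome_size=600_000, n_ins=60,
                               chh_delta=0.3, half_width=500)
    g = simulate_annotation(cfg)
    simulate_svs(g)
    calls = simulate_methylome(g, "A", 0)
    chh = calls[calls["context"] == "CHH"]
    pos = chh["pos"].to_numpy() - 1
    near = np.zeros(len(chh), dtype=bool)
    for chrom, bp, flag in g.truth.sv_breakpoints:
        near |= np.abs(pos - bp) <= 500
    def lvl(sub):
        return sub["count_methylated"].sum() / (
            sub["count_methylated"].sum() + sub["count_unmethylated"].sum())
    elevation = lvl(chh[near]) - lvl(chh[~near])
    assert abs(elevation - 0.3) < 0.05


# ---------------------------------------------------------------------------
# Expression and m6A
# ---------------------------------------------------------------------------

def test_expression_deterministic_and_positive(dup_genome):
    e1 = simulate_expression(dup_genome)
    e2 = simulate_expression(dup_genome)
    pd.testing.assert_frame_equal(e1, e2)
    assert (e1["fpkm"] > 0).all()
    assert set(e1["gene_id"]) == set(dup_genome.annotation.genes)


def test_m6a_perfect_detection_consensus_equals_truth():
    g = simulate_annotation(m6a_metagene_config(2, n_genes=60))
    tables = simulate_m6a(g)
    truth = {(t, p) for t, s in g.truth.m6a_sites.items() for p, _ in s}
    for table in tables:
        assert set(zip(table["transcript_id"], table["position"])) == truth
        assert (table["probability"] >= 0.9).all()


def test_m6a_utr3_bias_recovered():
    g = simulate_annotation(m6a_metagene_config(5, n_genes=700))
    simulate_m6a(g)
    n3 = n_tot = 0
    for tid, sites in g.truth.m6a_sites.items():
        tx = g.annotation.transcripts[tid]
        for pos, _ in sites:
            n_tot += 1
            n3 += pos >= tx.utr5_len + tx.cds_len
    assert n_tot > 1500
    assert abs(n3 / n_tot - 0.67) < 0.03


def test_m6a_detection_probability_thins_replicates():
    cfg = m6a_metagene_config(6, n_genes=150)
    cfg.m6a.detection_probability = 0.6
    g = simulate_annotation(cfg)
    tables = simulate_m6a(g)
    n_true = sum(len(v) for v in g.truth.m6a_sites.values())
    for table in tables:
        frac = len(table) / n_true
        assert 0.45 < frac < 0.75  # ~Binomial(n_true, 0.6)


def test_m6a_kmers_have_central_A():
    g = simulate_annotation(m6a_metagene_config(3, n_genes=60))
    for sites in g.truth.m6a_sites.values():
        for _, kmer in sites:
            assert len(kmer) == 5 and kmer[2] == "A"


# ---------------------------------------------------------------------------
# Output files parse cleanly
# ---------------------------------------------------------------------------

def test_dataset_files_round_trip_through_parsers(tmp_path):
    cfg = duplication_plan_config(21)
    cfg.duplication = DuplicationPlan(10, 4, 4, 4, 2, 1, 5)
    cfg.n_chroms = 9
    cfg.te_count = 20
    cfg.methylation.n_replicates = 1
    cfg.svs.counts = {"INS": 5, "DEL": 5}
    cfg.svs.end_margin = 100
    from triplimeth.synthetic_data import simulate_all

    ds = simulate_all(cfg)
    ds.write(tmp_path)
    ann = gio.parse_gff3(tmp_path / "annotation.gff3")
    assert len(ann.genes) == cfg.duplication.total_genes
    assert len(gio.parse_sv_vcf(tmp_path / "svs.vcf")) == 10
    cx = gio.parse_cx_report(tmp_path / "cx_A_rep1.tsv")
    assert set(cx["context"]) <= {"CG", "CHG", "CHH"}
    fa = gio.parse_fasta(tmp_path / "genome.fa")
    assert {len(s) for s in fa.values()} == set(ds.genome.chrom_lengths.values())
    pairs = gio.read_homolog_pairs(tmp_path / "pairs.tsv")
    assert len(pairs) == len(ds.genome.truth.pairs)
    expr = gio.read_expression(tmp_path / "expression.tsv")
    assert len(expr) == len(ds.expression)
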