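"""DMR calling against hand-computed ANOVA, window filtering, merging,
annotation categories, metaprofiles."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import constant_cx, make_cx
from triplimeth.genome_io import GenomicInterval
from triplimeth.methylome import (
    associate_dmrs_to_genes,
    call_dmrs,
    dmr_genomic_distribution,
    fold_change,
    global_context_mean,
    metaprofile,
    weighted_level,
)
from triplimeth.stats import one_way_anova


class FakeGene:
    def __init__(self, gene_id, chrom, start, end, strand="+"):
        self.gene_id = gene_id
        self.interval = GenomicInterval(chrom, start, end, strand)


class FakeTE:
    def __init__(self, chrom, start, end):
        self.interval = GenomicInterval(chrom, start, end, ".")


# ---------------------------------------------------------------------------
# weighted level
# ---------------------------------------------------------------------------

def test_weighted_level_pooled_ratio():
    calls = make_cx([("c", 1, "+", 3, 7, "CG"), ("c", 5, "+", 7, 3, "CG")])
    assert weighted_level(calls) == pytest.approx(0.5)


def test_weighted_level_all_unmethylated_is_zero():
    calls = make_cx([("c", 1, "+", 0, 9, "CG")])
    assert weighted_level(calls) == 0.0


def test_weighted_level_without_coverage_is_nan_not_zero():
    calls = make_cx([("c", 1, "+", 0, 0, "CG")])
    assert math.isnan(weighted_level(calls))


def test_global_context_mean_and_fold_change():
    calls = make_cx([("c", 1, "+", 7, 3, "CG"), ("c", 2, "+", 2, 8, "CHH")])
    assert global_context_mean(calls, "CG") == pytest.approx(0.7)
    assert fold_change(0.7, 0.2) == pytest.approx(3.5)
    with pytest.raises(ValueError):
        global_context_mean(calls, "CHG")
    with pytest.raises(ZeroDivisionError):
        fold_change(1.0, 0.0)


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def _replicate(levels_by_site, coverage=400):
    """One replicate with 4 CG sites inside the window [0, 200)."""
    rows = []
    for pos, level in zip((11, 51, 91, 131), levels_by_site):
        meth = int(round(level * coverage))
        rows.append(("Chr1", pos, "+", meth, coverage - meth, "CG"))
    return make_cx(rows)


def test_single_window_hand_anova_example():
    """Replicate levels A=[0.90, 0.95, 0.92] vs B=[0.10, 0.12, 0.08]:
    one hyper DMR with delta ~0.823 and the exact ANOVA p of those six
    levels."""
    a_levels = [0.90, 0.95, 0.92]
    b_levels = [0.10, 0.12, 0.08]
    group_a = [_replicate([l] * 4) for l in a_levels]
    group_b = [_replicate([l] * 4) for l in b_levels]
    res = call_dmrs(group_a, group_b, "CG")
    assert res.n_tested_windows == 1
    (dmr,) = res.dmrs
    assert dmr.direction == "hyper"
    assert dmr.delta == pytest.approx(np.mean(a_levels) - np.mean(b_levels), abs=1e-9)
    assert dmr.delta >= 0.5
    ref = one_way_anova([a_levels, b_levels])
    assert dmr.p_value == pytest.approx(ref.p_value, rel=1e-9)
    assert dmr.q_value == dmr.p_value  # single tested window
    assert dmr.p_value < 0.001


def test_identical_groups_give_no_dmrs():
    reps = [_replicate([0.5] * 4) for _ in range(3)]
    res = call_dmrs(reps, [r.copy() for r in reps], "CG")
    assert res.dmrs == []


def test_windows_below_min_sites_untested():
    group_a = [_replicate([0.9] * 4) for _ in range(2)]
    group_b = [_replicate([0.1] * 4) for _ in range(2)]
    # drop one site from a single replicate -> the window fails min_sites
    group_a[0] = group_a[0].iloc[:3]
    res = call_dmrs(group_a, group_b, "CG", min_sites=4)
    assert res.n_tested_windows == 0 and res.dmrs == []


def test_low_coverage_sites_excluded():
    group_a = [_replicate([0.9] * 4, coverage=3) for _ in range(2)]
    group_b = [_replicate([0.1] * 4, coverage=3) for _ in range(2)]
    res = call_dmrs(group_a, group_b, "CG", min_cov=4)
    assert res.n_tested_windows == 0


def test_single_replicate_group_rejected():
    reps = [_replicate([0.5] * 4)]
    with pytest.raises(ValueError, match="replicates"):
        call_dmrs(reps, reps * 2, "CG")


def test_chh_cutoff_is_smaller():
    """A 0.3 difference is called for CHH (cutoff 0.1) but not CG (0.5)."""
    def rep(level):
        rows = [("Chr1", p, "+", int(round(level * 400)), 400 - int(round(level * 400)), ctx)
                for ctx in ("CG", "CHH") for p in (11, 51, 91, 131)]
        return make_cx(rows)

    group_a = [rep(l) for l in (0.40, 0.42, 0.38)]
    group_b = [rep(l) for l in (0.10, 0.12, 0.08)]
    assert call_dmrs(group_a, group_b, "CG").dmrs == []
    chh = call_dmrs(group_a, group_b, "CHH").dmrs
    assert len(chh) == 1 and chh[0].direction == "hyper"


def test_adjacent_candidate_windows_merge_idempotently():
    """A contiguous high-delta region yields a single merged DMR; DMRs are
    separated by more than one step (re-merging would change nothing)."""
    positions = list(range(11, 600, 40))

    def rep(level):
        cov = 400
        meth = int(round(level * cov))
        return make_cx([("Chr1", p, "+", meth, cov - meth, "CG")
                        for p in positions])

    group_a = [rep(l) for l in (0.90, 0.95, 0.92)]
    group_b = [rep(l) for l in (0.10, 0.12, 0.08)]
    res = call_dmrs(group_a, group_b, "CG")
    assert len(res.dmrs) == 1
    dmr = res.dmrs[0]
    assert dmr.interval.start == 0 and dmr.interval.end >= 500
    # stored values satisfy the thresholds exactly as reported
    assert abs(dmr.delta) >= res.cutoff and dmr.q_value < res.fdr


def test_dmrs_respect_stored_thresholds_on_synthetic_genome():
    from triplimeth.synthetic_data import (dmr_recovery_config,
                                           simulate_annotation,
                                           simulate_methylome)

    cfg = dmr_recovery_config(3, genome_size=150_000, n_dmrs=15)
    g = simulate_annotation(cfg)
    group_a = [simulate_methylome(g, "A", r) for r in range(3)]
    group_b = [simulate_methylome(g, "B", r) for r in range(3)]
    res = call_dmrs(group_a, group_b, "CG")
    assert res.dmrs
    ends = {}
    for d in res.dmrs:
        assert abs(d.delta) >= res.cutoff
        assert d.q_value < res.fdr
        assert d.direction == ("hyper" if d.delta > 0 else "hypo")
        # same-direction DMRs are farther than one step apart (merge is
        # exhaustive, hence idempotent)
        key = (d.interval.chrom, d.direction)
        if key in ends:
            assert d.interval.start > ends[key] + 100
        ends[key] = max(ends.get(key, 0), d.interval.end)


# ---------------------------------------------------------------------------
# DMR annotation
# ---------------------------------------------------------------------------

@pytest.fixture
def annotation_toy():
    genes = [FakeGene("g1", "c", 10_000, 14_000, "+")]
    tes = [FakeTE("c", 30_000, 33_000)]
    return genes, tes


def test_distribution_category_examples(annotation_toy):
    genes, tes = annotation_toy
    inside_gene = GenomicInterval("c", 11_000, 11_300)
    inside_te = GenomicInterval("c", 31_000, 31_200)
    far = GenomicInterval("c", 50_000, 50_200)
    fractions = dmr_genomic_distribution([inside_gene, inside_te, far], genes, tes)
    assert fractions["gene_body"] == pytest.approx(1 / 3)
    assert fractions["TE"] == pytest.approx(1 / 3)
    assert fractions["intergenic"] == pytest.approx(1 / 3)
    assert sum(fractions.values()) == pytest.approx(1.0)


def test_distribution_upstream_is_strand_aware():
    plus = [FakeGene("g1", "c", 10_000, 14_000, "+")]
    minus = [FakeGene("g1", "c", 10_000, 14_000, "-")]
    before_start = [GenomicInterval("c", 9_000, 9_200)]
    assert dmr_genomic_distribution(before_start, plus, [])["upstream_2kb"] == 1.0
    assert dmr_genomic_distribution(before_start, minus, [])["downstream_2kb"] == 1.0


def test_association_respects_flank_distance(annotation_toy):
    genes, _ = annotation_toy
    near = GenomicInterval("c", 8_400, 8_500)    # 1,500 bp upstream
    far = GenomicInterval("c", 7_400, 7_500)     # 2,500 bp upstream
    out = associate_dmrs_to_genes([near, far], genes, flank=2000)
    assert out == {"g1": [near]}


def test_dmr_in_two_flanks_listed_under_both():
    genes = [FakeGene("g1", "c", 10_000, 14_000),
             FakeGene("g2", "c", 15_000, 18_000)]
    between = GenomicInterval("c", 14_400, 14_600)
    out = associate_dmrs_to_genes([between], genes, flank=2000)
    assert set(out) == {"g1", "g2"}


# ---------------------------------------------------------------------------
# Metaprofiles
# ---------------------------------------------------------------------------

def _uniform_calls(chrom, length, level, coverage=20, spacing=7):
    return constant_cx(chrom, range(1, length, spacing), level, coverage)


def test_metaprofile_flat_on_constant_methylome():
    calls = _uniform_calls("c", 120_000, 0.5)
    feats = [GenomicInterval("c", s, s + 2000, "+")
             for s in range(3000, 110_000, 1000)]
    prof = metaprofile(calls, feats, "CG")
    assert prof.levels.size == 60
    assert np.nanmax(np.abs(prof.levels - 0.5)) < 0.02
    assert prof.n_used == len(feats) and prof.n_skipped == 0
    assert (prof.feature_counts <= len(feats)).all()


def test_metaprofile_minus_strand_mirrors_plus():
    rng = np.random.default_rng(0)
    rows = []
    for p in range(1, 30_000, 5):
        meth = int(rng.integers(0, 21))
        rows.append(("c", p, "+", meth, 20 - meth, "CG"))
    calls = make_cx(rows)
    plus = [GenomicInterval("c", 10_000, 14_000, "+")]
    minus = [GenomicInterval("c", 10_000, 14_000, "-")]
    p_prof = metaprofile(calls, plus, "CG")
    m_prof = metaprofile(calls, minus, "CG")
    np.testing.assert_allclose(p_prof.levels, m_prof.levels[::-1], rtol=1e-12)


def test_metaprofile_planted_tss_dip_recovered():
    """First 2 body bins at level/4 show up exactly there."""
    feats = [GenomicInterval("c", s, s + 2000, "+")
             for s in range(3000, 110_000, 2500)]
    dip = np.zeros(120_000, dtype=bool)
    for f in feats:
        dip[f.start:f.start + 200] = True  # first 10% of a 2-kb body
    rows = []
    for p in range(1, 120_000, 7):
        level = 0.125 if dip[p - 1] else 0.5
        meth = int(round(level * 40))
        rows.append(("c", p, "+", meth, 40 - meth, "CG"))
    prof = metaprofile(make_cx(rows), feats, "CG")
    body = prof.levels[20:40]
    assert np.all(body[:2] < 0.2)
    assert np.all(body[2:] > 0.4)


def test_metaprofile_short_features_skipped_in_scaled_mode():
    calls = _uniform_calls("c", 10_000, 0.5)
    feats = [GenomicInterval("c", 3000, 3010), GenomicInterval("c", 5000, 7000)]
    prof = metaprofile(calls, feats, "CG", body_bins=20)
    assert prof.n_used == 1 and prof.n_skipped == 1
    assert prof.n_used + prof.n_skipped == len(feats)


def test_metaprofile_coverage_scaling_invariance():
    calls = _uniform_calls("c", 50_000, 0.35)
    doubled = calls.copy()
    doubled["count_methylated"] *= 2
    doubled["count_unmethylated"] *= 2
    feats = [GenomicInterval("c", 5000, 9000, "+"), GenomicInterval("c", 20_000, 30_000, "-")]
    p1 = metaprofile(calls, feats, "CG")
    p2 = metaprofile(doubled, feats, "CG")
    np.testing.assert_allclose(p1.levels, p2.levels, rtol=1e-12)
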