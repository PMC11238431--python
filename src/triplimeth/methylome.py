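"""Methylation-level computation, sliding-window DMR calling, DMR
annotation, and the generic feature metaprofile engine.

The DMR procedure: 200-bp sliding windows (100-bp step), per-replicate
weighted methylation levels over context cytosines with coverage >=
``min_cov``; windows with fewer than ``min_sites`` such cytosines in any
replicate are untested.  A one-way ANOVA across the two groups on the
replicate window levels gives the p-value, Benjamini-Hochberg across all
tested windows of the context gives the q-value, and windows passing the
context-specific mean-difference cutoff (0.5 for CG/CHG, 0.1 for CHH) at
FDR < 0.05 are merged (gap <= step, same direction) into DMRs with levels
recomputed over the merged span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as _spstats

from .genome_io import CONTEXTS, GenomicInterval
from .stats import benjamini_hochberg

__all__ = [
    "DMR",
    "MetaProfile",
    "DMRCallResult",
    "DEFAULT_CUTOFFS",
    "weighted_level",
    "call_dmrs",
    "dmr_genomic_distribution",
    "associate_dmrs_to_genes",
    "metaprofile",
    "global_context_mean",
    "fold_change",
]

# context-specific mean methylation-difference cutoffs
DEFAULT_CUTOFFS = {"CG": 0.5, "CHG": 0.5, "CHH": 0.1}


@dataclass(frozen=True)
class DMR:
    """A merged differentially methylated region.

    ``delta = mean_a - mean_b``; ``direction`` is relative to group A
    (``hyper`` when A is more methylated).
    """

    interval: GenomicInterval
    context: str
    mean_a: float
    mean_b: float
    delta: float
    p_value: float
    q_value: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")
        if self.direction != ("hyper" if self.delta > 0 else "hypo"):
            raise ValueError("direction inconsistent with delta sign")


@dataclass
class DMRCallResult:
    """DMRs plus the per-window test table they were merged from."""

    dmrs: list
    windows: pd.DataFrame  # all tested windows with p, q, delta
    n_tested_windows: int
    context: str
    cutoff: float
    fdr: float


@dataclass
class MetaProfile:
    """Pooled positional methylation profile over many features.

    ``levels`` holds one weighted level per bin (NaN where no covered
    cytosine fell); ``feature_counts`` the number of features contributing
    to each bin.  Bin 0 is the 5'-most upstream flank bin.
    """

    levels: np.ndarray
    feature_counts: np.ndarray
    flank_bins: int
    body_bins: int
    mode: str
    n_used: int
    n_skipped: int


def weighted_level(calls: pd.DataFrame) -> float:
    """Pooled weighted methylation level: sum(methylated) / sum(coverage)
    over covered calls.  NaN (undefined, distinct from 0) when nothing is
    covered."""
    mc = int(calls["count_methylated"].sum())
    cov = mc + int(calls["count_unmethylated"].sum())
    return mc / cov if cov else float("nan")


def global_context_mean(calls: pd.DataFrame, context: str) -> float:
    """Genome-wide weighted level for one context; raises when the context
    has no covered call."""
    sub = calls[calls["context"] == context]
    level = weighted_level(sub)
    if math.isnan(level):
        raise ValueError(f"no covered {context} calls")
    return level


def fold_change(a: float, b: float) -> float:
    if b == 0:
        raise ZeroDivisionError("fold change undefined for a zero denominator")
    return a / b


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def _index_replicate(rep: pd.DataFrame, context: str, min_cov: int) -> dict:
    """Per-chromosome sorted positions with cumulative methylated/total
    sums for context calls with coverage >= min_cov (0-based positions)."""
    sub = rep[(rep["context"] == context)
              & (rep["count_methylated"] + rep["count_unmethylated"] >= min_cov)]
    out = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        srt = grp.sort_values("pos")
        pos0 = srt["pos"].to_numpy() - 1
        m = srt["count_methylated"].to_numpy(dtype=float)
        t = m + srt["count_unmethylated"].to_numpy(dtype=float)
        out[chrom] = (pos0, np.concatenate([[0.0], np.cumsum(m)]),
                      np.concatenate([[0.0], np.cumsum(t)]))
    return out


def _window_stats(indexed: dict, window: int, step: int, nbins: dict):
    """Sliding-window (meth, total, n_sites) sums for one indexed
    replicate."""
    k = window // step
    out = {}
    for chrom, (pos0, cum_m, cum_t) in indexed.items():
        nb = nbins[chrom]
        b = pos0 // step
        meth = np.bincount(b, weights=np.diff(cum_m), minlength=nb)
        tot = np.bincount(b, weights=np.diff(cum_t), minlength=nb)
        cnt = np.bincount(b, minlength=nb)
        cs_m = np.concatenate([[0.0], np.cumsum(meth)])
        cs_t = np.concatenate([[0.0], np.cumsum(tot)])
        cs_c = np.concatenate([[0.0], np.cumsum(cnt)])
        nwin = nb - k + 1
        if nwin <= 0:
            continue
        out[chrom] = (
            cs_m[k:k + nwin] - cs_m[:nwin],
            cs_t[k:k + nwin] - cs_t[:nwin],
            cs_c[k:k + nwin] - cs_c[:nwin],
        )
    return out


def _vector_anova_two_group(levels: np.ndarray, n_a: int):
    """Row-wise one-way ANOVA for a (reps x windows) level matrix split
    into the first n_a rows (group A) and the rest (group B)."""
    a = levels[:n_a]
    b = levels[n_a:]
    n_b = b.shape[0]
    ma = a.mean(axis=0)
    mb = b.mean(axis=0)
    gm = (a.sum(axis=0) + b.sum(axis=0)) / (n_a + n_b)
    ssb = n_a * (ma - gm) ** 2 + n_b * (mb - gm) ** 2
    ssw = ((a - ma) ** 2).sum(axis=0) + ((b - mb) ** 2).sum(axis=0)
    df_w = n_a + n_b - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / 1.0) / (ssw / df_w)
        p = _spstats.f.sf(f, 1, df_w)
    degenerate = ssw == 0.0
    f = np.where(degenerate & (ssb == 0.0), 0.0, f)
    p = np.where(degenerate, np.where(ssb == 0.0, 1.0, 0.0), p)
    return ma, mb, f, p


def call_dmrs(group_a, group_b, context: str, window: int = 200, step: int = 100,
              min_sites: int = 4, min_cov: int = 4, cutoff: float | None = None,
              fdr: float = 0.05) -> DMRCallResult:
    """Call DMRs between two replicate groups for one cytosine context.

    ``group_a``/``group_b`` are lists of CX-report DataFrames (one per
    replicate, >= 2 each).  Group A is the treatment: a DMR is ``hyper``
    when group A is more methylated.  Returns merged DMRs plus the full
    tested-window table.
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(
            "each group needs >= 2 replicates for the ANOVA; a paired "
            "single-replicate fallback is unsupported"
        )
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    if cutoff is None:
        cutoff = DEFAULT_CUTOFFS[context]

    reps = list(group_a) + list(group_b)
    n_a = len(group_a)

    indexed = [_index_replicate(rep, context, min_cov) for rep in reps]

    # shared bin space per chromosome
    nbins: dict = {}
    for idx_rep in indexed:
        for chrom, (pos0, _, _) in idx_rep.items():
            if pos0.size:
                nbins[chrom] = max(nbins.get(chrom, 0), int(pos0[-1] // step) + 1)

    per_rep = [_window_stats(idx_rep, window, step, nbins) for idx_rep in indexed]

    rows = []
    k = window // step
    for chrom in sorted(nbins):
        stats = [pr.get(chrom) for pr in per_rep]
        if any(s is None for s in stats):
            continue
        nwin = min(s[0].size for s in stats)
        meth = np.stack([s[0][:nwin] for s in stats])
        tot = np.stack([s[1][:nwin] for s in stats])
        cnt = np.stack([s[2][:nwin] for s in stats])
        tested = (cnt >= min_sites).all(axis=0) & (tot > 0).all(axis=0)
        if not tested.any():
            continue
        idx = np.nonzero(tested)[0]
        levels = meth[:, idx] / tot[:, idx]
        ma, mb, f, p = _vector_anova_two_group(levels, n_a)
        starts = idx * step
        for j in range(idx.size):
            rows.append((chrom, int(starts[j]), int(starts[j]) + window,
                         float(ma[j]), float(mb[j]), float(ma[j] - mb[j]),
                         float(p[j])))

    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "mean_a", "mean_b", "delta", "p"])
    n_tested = len(windows)
    if n_tested == 0:
        return DMRCallResult([], windows.assign(q=pd.Series(dtype=float)),
                             0, context, cutoff, fdr)
    windows["q"] = benjamini_hochberg(windows["p"].to_numpy())

    cand = windows[(windows["delta"].abs() >= cutoff) & (windows["q"] < fdr)]
    dmrs = _merge_candidates(cand, indexed, n_a, context, step, cutoff)
    return DMRCallResult(dmrs, windows, n_tested, context, cutoff, fdr)


def _span_group_means(indexed, n_a, chrom, start, end):
    means = []
    for idx_rep in indexed:
        if chrom not in idx_rep:
            means.append(float("nan"))
            continue
        pos0, cum_m, cum_t = idx_rep[chrom]
        lo = np.searchsorted(pos0, start)
        hi = np.searchsorted(pos0, end)
        tot = cum_t[hi] - cum_t[lo]
        means.append((cum_m[hi] - cum_m[lo]) / tot if tot > 0 else float("nan"))
    means = np.asarray(means)
    return float(np.nanmean(means[:n_a])), float(np.nanmean(means[n_a:]))


def _merge_candidates(cand: pd.DataFrame, indexed, n_a, context, step, cutoff):
    if cand.empty:
        return []
    dmrs = []
    cand = cand.sort_values(["chrom", "start"])
    for chrom, grp in cand.groupby("chrom", sort=False):
        cur = None
        for row in grp.itertuples():
            direction = "hyper" if row.delta > 0 else "hypo"
            if (cur is not None and row.start <= cur["end"] + step
                    and direction == cur["direction"]):
                cur["end"] = max(cur["end"], row.end)
                cur["p"] = min(cur["p"], row.p)
                cur["q"] = min(cur["q"], row.q)
            else:
                if cur is not None:
                    dmrs.append(cur)
                cur = {"chrom": chrom, "start": row.start, "end": row.end,
                       "p": row.p, "q": row.q, "direction": direction}
        if cur is not None:
            dmrs.append(cur)

    out = []
    for d in dmrs:
        ma, mb = _span_group_means(indexed, n_a, d["chrom"], d["start"], d["end"])
        delta = ma - mb
        if abs(delta) < cutoff:  # merged span diluted below the cutoff
            continue
        out.append(DMR(
            GenomicInterval(d["chrom"], d["start"], d["end"]), context,
            ma, mb, delta, d["p"], d["q"],
            "hyper" if delta > 0 else "hypo",
        ))
    return out


# ---------------------------------------------------------------------------
# DMR annotation
# ---------------------------------------------------------------------------

def _merged_intervals(ivs):
    """Per-chrom sorted, merged (start, end) lists."""
    by_chrom: dict = {}
    for chrom, start, end in ivs:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged = {}
    for chrom, lst in by_chrom.items():
        lst.sort()
        acc = [list(lst[0])]
        for s, e in lst[1:]:
            if s <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[chrom] = acc
    return merged


def _overlap_with(merged: dict, chrom: str, start: int, end: int) -> int:
    total = 0
    for s, e in merged.get(chrom, ()):
        if s >= end:
            break
        total += max(0, min(e, end) - max(s, start))
    return total


_CATEGORY_PRECEDENCE = ("gene_body", "upstream_2kb", "downstream_2kb", "TE", "intergenic")


def dmr_genomic_distribution(dmrs, genes, tes, flank: int = 2000) -> dict:
    """Fraction of DMRs per genomic category: gene body, 2-kb upstream of
    the TSS, 2-kb downstream of the TTS, TEs, and intergenic space
    excluding TEs.  Each DMR is assigned to the category with the largest
    overlap; ties break by the precedence gene_body > upstream > downstream
    > TE > intergenic.  Fractions sum to 1 over the input DMRs."""
    gene_ivs, up_ivs, down_ivs = [], [], []
    for g in genes.values() if isinstance(genes, dict) else genes:
        iv = g.interval
        gene_ivs.append((iv.chrom, iv.start, iv.end))
        if iv.strand == "-":
            up = (iv.chrom, iv.end, iv.end + flank)
            down = (iv.chrom, max(0, iv.start - flank), iv.start)
        else:
            up = (iv.chrom, max(0, iv.start - flank), iv.start)
            down = (iv.chrom, iv.end, iv.end + flank)
        if up[1] < up[2]:
            up_ivs.append(up)
        if down[1] < down[2]:
            down_ivs.append(down)
    te_ivs = [(t.interval.chrom, t.interval.start, t.interval.end)
              for t in tes]
    merged = {
        "gene_body": _merged_intervals(gene_ivs),
        "upstream_2kb": _merged_intervals(up_ivs),
        "downstream_2kb": _merged_intervals(down_ivs),
        "TE": _merged_intervals(te_ivs),
    }
    all_merged = _merged_intervals(gene_ivs + up_ivs + down_ivs + te_ivs)

    counts = {cat: 0 for cat in _CATEGORY_PRECEDENCE}
    for dmr in dmrs:
        iv = dmr.interval if isinstance(dmr, DMR) else dmr
        overlaps = {cat: _overlap_with(merged[cat], iv.chrom, iv.start, iv.end)
                    for cat in merged}
        covered = _overlap_with(all_merged, iv.chrom, iv.start, iv.end)
        overlaps["intergenic"] = len(iv) - covered
        best = max(_CATEGORY_PRECEDENCE, key=lambda c: overlaps[c])
        counts[best] += 1
    n = max(sum(counts.values()), 1)
    return {cat: counts[cat] / n for cat in _CATEGORY_PRECEDENCE}


def associate_dmrs_to_genes(dmrs, genes, flank: int = 2000) -> dict:
    """Map gene -> list of DMRs overlapping the gene body +- ``flank`` by
    at least 1 bp.  A DMR overlapping several genes' flanks is listed under
    each."""
    trees: dict = {}
    for g in genes.values() if isinstance(genes, dict) else genes:
        iv = g.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            max(0, iv.start - flank), iv.end + flank, g.gene_id)
    out: dict = {}
    for dmr in dmrs:
        iv = dmr.interval if isinstance(dmr, DMR) else dmr
        for hit in trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end):
            out.setdefault(hit.data, []).append(dmr)
    return out


# ---------------------------------------------------------------------------
# Metaprofiles
# ---------------------------------------------------------------------------

def _feature_interval(feature) -> GenomicInterval:
    return feature.interval if hasattr(feature, "interval") else feature


def metaprofile(calls: pd.DataFrame, features, context: str, flank: int = 2000,
                flank_bin: int = 100, body_bins: int = 20,
                mode: str = "scaled_body") -> MetaProfile:
    """Average methylation profile across features: fixed 100-bp flank bins
    over ``flank`` bp on each side and a length-scaled (or fixed-bin) body.

    Minus-strand features are flipped so bin 0 is always 5'-most.  In
    ``scaled_body`` mode features shorter than ``body_bins`` bp are skipped
    (counted in ``n_skipped``).  Per-bin level is the weighted level over
    all covered cytosines of all contributing features.
    """
    if mode not in ("scaled_body", "absolute"):
        raise ValueError("mode must be 'scaled_body' or 'absolute'")
    if flank % flank_bin != 0:
        raise ValueError("flank must be a multiple of flank_bin")
    features = list(features)
    if not features:
        raise ValueError("features must be non-empty")
    nf = flank // flank_bin

    sub = calls[(calls["context"] == context)
                & (calls["count_methylated"] + calls["count_unmethylated"] > 0)]
    by_chrom = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        srt = grp.sort_values("pos")
        by_chrom[chrom] = (
            srt["pos"].to_numpy() - 1,
            srt["count_methylated"].to_numpy(dtype=float),
            (srt["count_methylated"] + srt["count_unmethylated"]).to_numpy(dtype=float),
        )

    ivs = [_feature_interval(f) for f in features]
    if mode == "scaled_body":
        used = [iv for iv in ivs if len(iv) >= body_bins]
        nb_total = body_bins
    else:
        used = list(ivs)
        nb_total = max(-(-len(iv) // flank_bin) for iv in used) if used else 0
    n_skipped = len(ivs) - len(used)
    total_bins = 2 * nf + nb_total
    meth = np.zeros(total_bins)
    tot = np.zeros(total_bins)
    fcount = np.zeros(total_bins, dtype=int)

    for iv in used:
        if iv.chrom not in by_chrom:
            data = None
        else:
            data = by_chrom[iv.chrom]
        length = len(iv)
        nb = body_bins if mode == "scaled_body" else -(-length // flank_bin)
        # per-feature contribution counts
        fcount[:nf] += 1
        fcount[nf:nf + nb] += 1
        fcount[nf + nb_total:] += 1
        if data is None:
            continue
        pos, m_arr, t_arr = data
        lo = np.searchsorted(pos, iv.start - flank)
        hi = np.searchsorted(pos, iv.end + flank)
        if hi <= lo:
            continue
        p = pos[lo:hi]
        m = m_arr[lo:hi]
        t = t_arr[lo:hi]
        if iv.strand == "-":
            up = p >= iv.end
            body = (p >= iv.start) & (p < iv.end)
            down = p < iv.start
            bins = np.empty(p.size, dtype=int)
            bins[up] = (iv.end + flank - 1 - p[up]) // flank_bin
            dist = iv.end - 1 - p[body]
            if mode == "scaled_body":
                bins[body] = nf + np.minimum(
                    (dist * body_bins) // length, body_bins - 1)
            else:
                bins[body] = nf + dist // flank_bin
            bins[down] = nf + nb_total + (iv.start - 1 - p[down]) // flank_bin
        else:
            up = p < iv.start
            body = (p >= iv.start) & (p < iv.end)
            down = p >= iv.end
            bins = np.empty(p.size, dtype=int)
            bins[up] = (p[up] - (iv.start - flank)) // flank_bin
            dist = p[body] - iv.start
            if mode == "scaled_body":
                bins[body] = nf + np.minimum(
                    (dist * body_bins) // length, body_bins - 1)
            else:
                bins[body] = nf + dist // flank_bin
            bins[down] = nf + nb_total + (p[down] - iv.end) // flank_bin
        ok = (bins >= 0) & (bins < total_bins)
        np.add.at(meth, bins[ok], m[ok])
        np.add.at(tot, bins[ok], t[ok])

    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(tot > 0, meth / np.maximum(tot, 1e-300), np.nan)
    return MetaProfile(levels, fcount, nf, nb_total, mode, len(used), n_skipped)
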