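"""Structural-variant summarization, PAV boundary-density enrichment
around genes/TEs, and breakpoint-anchored DNA methylation profiles.

PAVs (presence/absence variations) are the INS + DEL subset of SVs.
Breakpoint reduction: an insertion contributes its POS; DEL/DUP/INV
contribute POS and END; a translocation contributes both mates'
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import SV_TYPES
from .methylome import global_context_mean
from .stats import TestResult, percent_half_up, wilcoxon_signed_rank

__all__ = [
    "SVSummary",
    "BoundaryProfile",
    "BreakpointProfile",
    "sv_summary",
    "extract_breakpoints",
    "breakpoint_methylation_profile",
    "boundary_density",
]


@dataclass(frozen=True)
class SVSummary:
    counts: dict            # per sv_type
    total: int
    pav_count: int          # INS + DEL
    pav_fraction: float | None  # percent, 2 dp half-up; None when total == 0

    def __post_init__(self) -> None:
        assert self.total == sum(self.counts.values()), "total != sum of parts"


@dataclass
class BreakpointProfile:
    """Methylation level per bin around breakpoints, a genome baseline, and
    a paired signed-rank test of per-breakpoint central vs distal levels."""

    bin_offsets: np.ndarray   # bin start offsets relative to the breakpoint
    levels: np.ndarray
    baseline: float
    test: TestResult
    n_breakpoints: int
    n_dropped: int


@dataclass
class BoundaryProfile:
    """Mean breakpoint density (count/feature/bin) around left and right
    feature boundaries; axis runs outside -> inside.  Per-feature zone
    counts are retained for the paired boundary-vs-distal test."""

    bin_offsets: np.ndarray
    left_density: np.ndarray
    right_density: np.ndarray
    test: TestResult
    n_features: int
    n_skipped: int


def sv_summary(records_or_counts) -> SVSummary:
    """Summarize SVs: counts per type, total, and the PAV percentage
    (INS + DEL over total, rounded half-up to 2 dp).  Accepts a list of
    SVRecords or a {type: count} dict."""
    counts = {t: 0 for t in SV_TYPES}
    if isinstance(records_or_counts, dict):
        for t, c in records_or_counts.items():
            if t not in SV_TYPES:
                raise ValueError(f"unknown sv_type {t!r}")
            counts[t] = int(c)
    else:
        for rec in records_or_counts:
            counts[rec.sv_type] += 1
    total = sum(counts.values())
    pav = counts["INS"] + counts["DEL"]
    frac = percent_half_up(pav, total) if total else None
    return SVSummary(counts, total, pav, frac)


def extract_breakpoints(records, which: str = "pav_only"):
    """Reduce SV records to (chrom, pos0) breakpoints.

    INS contributes POS; DEL/DUP/INV contribute POS and END; TRANS
    contributes both mates.  ``pav_only`` keeps INS + DEL records.
    """
    if which not in ("pav_only", "all"):
        raise ValueError("which must be 'pav_only' or 'all'")
    out = []
    for rec in records:
        if which == "pav_only" and rec.sv_type not in ("INS", "DEL"):
            continue
        out.append((rec.chrom, rec.pos - 1))
        if rec.sv_type == "INS":
            continue
        if rec.end is not None:
            out.append((rec.chrom2 or rec.chrom, rec.end - 1))
    return out


def _sorted_calls_by_chrom(calls: pd.DataFrame, context: str):
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
    return by_chrom


def breakpoint_methylation_profile(breakpoints, calls: pd.DataFrame, context: str,
                                   flank: int = 8000, bin: int = 200,
                                   central: int = 400, distal: int = 400,
                                   chrom_sizes: dict | None = None) -> BreakpointProfile:
    """Pooled methylation levels in ``bin``-bp bins across +-``flank`` of
    each breakpoint, compared to the genome-wide baseline of the context.

    The paired test contrasts, per breakpoint, the weighted level within
    +-``central`` bp against the level in the outermost ``distal`` bp of
    its flanks (Wilcoxon signed-rank).  Breakpoints within ``flank`` of a
    contig end are dropped (partial windows bias the bin means).
    """
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    breakpoints = list(breakpoints)
    if not breakpoints:
        raise ValueError("at least one breakpoint is required")

    by_chrom = _sorted_calls_by_chrom(calls, context)
    if chrom_sizes is None:
        chrom_sizes = {c: int(arr[0].max()) + 1 for c, arr in by_chrom.items()}

    nbins = 2 * flank // bin
    meth = np.zeros(nbins)
    tot = np.zeros(nbins)
    central_pairs = []
    n_used = 0
    n_dropped = 0
    for chrom, bp in breakpoints:
        size = chrom_sizes.get(chrom, 0)
        if bp - flank < 0 or bp + flank > size or chrom not in by_chrom:
            n_dropped += 1
            continue
        n_used += 1
        pos, m_arr, t_arr = by_chrom[chrom]
        lo = np.searchsorted(pos, bp - flank)
        hi = np.searchsorted(pos, bp + flank)
        off = pos[lo:hi] - bp + flank  # 0 .. 2*flank-1
        b = off // bin
        np.add.at(meth, b, m_arr[lo:hi])
        np.add.at(tot, b, t_arr[lo:hi])
        # per-breakpoint central vs distal weighted levels
        absoff = np.abs(pos[lo:hi] - bp)
        c_mask = absoff <= central
        d_mask = absoff > flank - distal
        ct = t_arr[lo:hi][c_mask].sum()
        dt = t_arr[lo:hi][d_mask].sum()
        if ct > 0 and dt > 0:
            central_pairs.append((m_arr[lo:hi][c_mask].sum() / ct,
                                  m_arr[lo:hi][d_mask].sum() / dt))
    if n_used == 0:
        raise ValueError("no breakpoint had a full +-flank window with calls")

    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(tot > 0, meth / np.maximum(tot, 1e-300), np.nan)
    baseline = global_context_mean(calls, context)
    if central_pairs:
        c, d = np.array(central_pairs).T
        if np.all(c == d):  # perfectly flat: no evidence either way
            test = TestResult(0.0, 1.0, "exact", 0)
        else:
            test = wilcoxon_signed_rank(c, d, alternative="two_sided")
    else:
        test = TestResult(0.0, 1.0, "exact", 0)
    offsets = np.arange(nbins) * bin - flank
    return BreakpointProfile(offsets, levels, baseline, test, n_used, n_dropped)


def boundary_density(breakpoints, features, flank: int = 2000,
                     bin: int = 100) -> BoundaryProfile:
    """Breakpoint density around feature boundaries.

    For each feature, breakpoints are counted in ``bin``-bp bins spanning
    +-``flank`` of the left and the right boundary; the right boundary is
    flipped so negative offsets are always outside the feature.  The
    paired test contrasts each feature's boundary-zone count
    (|offset| <= 2 bins, both boundaries) with its distal-zone count
    (|offset| > flank - 2 bins) by Wilcoxon signed-rank.  Features shorter
    than 2 bins are skipped.
    """
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    features = list(features)
    if not features:
        raise ValueError("at least one feature is required")

    bp_by_chrom: dict = {}
    for chrom, pos in breakpoints:
        bp_by_chrom.setdefault(chrom, []).append(pos)
    bp_by_chrom = {c: np.sort(np.asarray(v)) for c, v in bp_by_chrom.items()}

    nbins = 2 * flank // bin
    left = np.zeros(nbins)
    right = np.zeros(nbins)
    zone = 2 * bin
    boundary_counts = []
    distal_counts = []
    n_used = 0
    n_skipped = 0
    for feat in features:
        iv = feat.interval if hasattr(feat, "interval") else feat
        if len(iv) < zone:
            n_skipped += 1
            continue
        n_used += 1
        pos = bp_by_chrom.get(iv.chrom, np.empty(0, dtype=int))
        n_b = 0
        n_d = 0
        for boundary, sign, target in ((iv.start, 1, left), (iv.end, -1, right)):
            lo = np.searchsorted(pos, boundary - flank)
            hi = np.searchsorted(pos, boundary + flank)
            off = (pos[lo:hi] - boundary) * sign  # negative = outside
            b = (off + flank) // bin
            ok = (b >= 0) & (b < nbins)
            np.add.at(target, b[ok], 1.0)
            n_b += int((np.abs(off) <= zone).sum())
            n_d += int((np.abs(off) > flank - zone).sum())
        boundary_counts.append(n_b)
        distal_counts.append(n_d)
    if n_used == 0:
        raise ValueError("every feature was shorter than the boundary zone")

    if boundary_counts == distal_counts:  # includes the zero-breakpoint case
        test = TestResult(0.0, 1.0, "exact", 0)
    else:
        test = wilcoxon_signed_rank(np.asarray(boundary_counts, dtype=float),
                                    np.asarray(distal_counts, dtype=float),
                                    alternative="two_sided")
    offsets = np.arange(nbins) * bin - flank
    return BoundaryProfile(offsets, left / n_used, right / n_used,
                           test, n_used, n_skipped)
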