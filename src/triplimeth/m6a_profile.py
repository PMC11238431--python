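"""Consensus m6A site filtering, k-mer/DRACH analysis, metagene
distribution, and integration with duplication classes and expression.

Sites come from per-replicate tables (transcript, 0-based spliced
position, modification probability, 5-mer with the modified A at the
center).  A consensus site must be present with probability >= the
threshold in every replicate (exact position match).  The metagene axis
concatenates the normalized 5' UTR, CDS and 3' UTR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, wilcoxon_rank_sum

__all__ = [
    "MetageneDistribution",
    "consensus_sites",
    "site_count_histogram",
    "kmer_frequency",
    "is_drach",
    "metagene_distribution",
    "m6a_fraction_by_class",
    "expression_by_m6a",
]

_D = set("AGU")
_R = set("AG")
_H = set("ACU")


@dataclass
class MetageneDistribution:
    """Binned site density over the 5'UTR / CDS / 3'UTR metagene axis.

    ``region_fractions`` sum to 1 over binned sites; ``density``
    integrates to 1 with each region scaled to unit length.
    """

    density: np.ndarray
    bin_edges: np.ndarray  # on the 0..3 concatenated-region axis
    region_fractions: dict  # {"utr5": f, "cds": f, "utr3": f}
    n_sites: int
    n_excluded: int


def _check_replicate(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=["transcript_id", "position"])
    if dup.any():
        t, p = df.loc[dup.idxmax(), ["transcript_id", "position"]]
        raise ValueError(f"duplicate site ({t}, {p}) within one replicate")


def consensus_sites(replicates, probability_threshold: float = 0.9) -> pd.DataFrame:
    """Sites detected with probability >= threshold in *every* replicate.

    Returns a frame (transcript_id, position, probability, kmer) where
    probability is the minimum across replicates and the kmer comes from
    the first replicate.  Raises on duplicate (transcript, position)
    entries within one replicate, and on fewer than two replicates.
    """
    replicates = list(replicates)
    if len(replicates) < 2:
        raise ValueError("consensus requires >= 2 replicate tables")
    for df in replicates:
        _check_replicate(df)
    passing = []
    for df in replicates:
        sub = df[df["probability"] >= probability_threshold]
        passing.append(sub.set_index(["transcript_id", "position"]))
    index = passing[0].index
    for sub in passing[1:]:
        index = index.intersection(sub.index)
    if len(index) == 0:
        return pd.DataFrame(columns=["transcript_id", "position", "probability", "kmer"])
    min_prob = np.min(
        np.stack([sub.loc[index, "probability"].to_numpy() for sub in passing]),
        axis=0,
    )
    out = passing[0].loc[index].reset_index()
    out["probability"] = min_prob
    out = out[["transcript_id", "position", "probability", "kmer"]]
    return out.sort_values(["transcript_id", "position"]).reset_index(drop=True)


def site_count_histogram(sites: pd.DataFrame) -> pd.Series:
    """Histogram of sites per transcript (index = site count, value =
    number of transcripts)."""
    counts = sites.groupby("transcript_id").size()
    return counts.value_counts().sort_index()


def kmer_frequency(sites: pd.DataFrame) -> pd.Series:
    """Relative 5-mer frequencies at modified positions, descending, ties
    broken lexicographically.  Frequencies sum to 1."""
    kmers = sites["kmer"]
    if kmers.isna().any() or (kmers.str.len() != 5).any():
        raise ValueError("every site must carry a 5-mer kmer")
    freq = kmers.value_counts(normalize=True)
    order = sorted(freq.index, key=lambda k: (-freq[k], k))
    return freq.reindex(order)


def is_drach(kmer: str) -> bool:
    """True iff the 5-mer matches DRACH (D = A/G/U, R = A/G, H = A/C/U)
    with the modified A at position 3.  T is treated as U."""
    if len(kmer) != 5:
        raise ValueError("kmer must have length 5")
    k = kmer.upper().replace("T", "U")
    if any(b not in "ACGU" for b in k):
        raise ValueError(f"invalid base in kmer {kmer!r}")
    return (k[0] in _D) and (k[1] in _R) and (k[2] == "A") and (k[3] == "C") and (k[4] in _H)


def metagene_distribution(sites: pd.DataFrame, transcripts: dict,
                          bins: tuple = (10, 20, 20)) -> MetageneDistribution:
    """Map consensus sites to the normalized 5'UTR / CDS / 3'UTR metagene
    axis.

    Sites on transcripts lacking any of the three regions are excluded and
    counted.  A site position beyond its transcript length raises.
    """
    b5, bc, b3 = bins
    counts = np.zeros(b5 + bc + b3)
    region_counts = {"utr5": 0, "cds": 0, "utr3": 0}
    n_excluded = 0
    for row in sites.itertuples():
        tx = transcripts[row.transcript_id]
        if row.position >= tx.length:
            raise ValueError(
                f"site position {row.position} >= transcript length {tx.length} "
                f"({row.transcript_id})"
            )
        if tx.utr5_len == 0 or tx.cds_len == 0 or tx.utr3_len == 0:
            n_excluded += 1
            continue
        pos = row.position
        if pos < tx.utr5_len:
            frac = pos / tx.utr5_len
            counts[min(int(frac * b5), b5 - 1)] += 1
            region_counts["utr5"] += 1
        elif pos < tx.utr5_len + tx.cds_len:
            frac = (pos - tx.utr5_len) / tx.cds_len
            counts[b5 + min(int(frac * bc), bc - 1)] += 1
            region_counts["cds"] += 1
        else:
            frac = (pos - tx.utr5_len - tx.cds_len) / tx.utr3_len
            counts[b5 + bc + min(int(frac * b3), b3 - 1)] += 1
            region_counts["utr3"] += 1
    n_binned = int(counts.sum())
    widths = np.concatenate([np.full(b5, 1.0 / b5), np.full(bc, 1.0 / bc),
                             np.full(b3, 1.0 / b3)])
    density = (counts / n_binned) / widths if n_binned else counts
    edges = np.concatenate([np.linspace(0, 1, b5, endpoint=False),
                            1 + np.linspace(0, 1, bc, endpoint=False),
                            2 + np.linspace(0, 1, b3, endpoint=False),
                            [3.0]])
    fractions = {k: (v / n_binned if n_binned else 0.0)
                 for k, v in region_counts.items()}
    return MetageneDistribution(density, edges, fractions, n_binned, n_excluded)


def m6a_fraction_by_class(sites: pd.DataFrame, transcripts: dict,
                          labels: dict) -> pd.DataFrame:
    """Fraction of genes per duplication class with >= 1 modified
    transcript; denominators reported."""
    modified_genes = {transcripts[t].gene_id
                      for t in sites["transcript_id"].unique() if t in transcripts}
    per_class: dict = {}
    for gene, lab in labels.items():
        name = lab if isinstance(lab, str) else lab.label
        tot, mod = per_class.get(name, (0, 0))
        per_class[name] = (tot + 1, mod + (1 if gene in modified_genes else 0))
    rows = [(cls, mod, tot, mod / tot if tot else 0.0)
            for cls, (tot, mod) in sorted(per_class.items())]
    return pd.DataFrame(rows, columns=["label", "n_modified", "n_genes", "fraction"])


def expression_by_m6a(sites: pd.DataFrame, expression: pd.DataFrame,
                      groups, transcripts: dict) -> tuple:
    """Split each homoeologous group into m6A-modified (High) and
    unmodified (Low) members and compare pooled expression.

    Groups that are entirely modified or entirely unmodified are excluded
    from the split.  Returns (high_values, low_values, TestResult) with
    per-gene mean FPKM; raises when no group qualifies.
    """
    modified_genes = {transcripts[t].gene_id
                      for t in sites["transcript_id"].unique() if t in transcripts}
    per_gene = expression.groupby("gene_id")["fpkm"].mean()
    high, low = [], []
    for group in groups:
        members = [g for g in group if g in per_gene.index]
        mod = [g for g in members if g in modified_genes]
        unmod = [g for g in members if g not in modified_genes]
        if not mod or not unmod:
            continue
        high.extend(float(per_gene[g]) for g in mod)
        low.extend(float(per_gene[g]) for g in unmod)
    if not high or not low:
        raise ValueError("no homoeologous group has both modified and "
                         "unmodified members")
    res = wilcoxon_rank_sum(high, low, "two_sided")
    return np.asarray(high), np.asarray(low), res
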