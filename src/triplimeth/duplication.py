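"""Collinear-block chaining and the five-way duplicate-gene
classification with whole-genome-triplication (WGT) copy-number grouping.

Gene classes follow the small-scale/WGT scheme used for paleopolyploid
crop genomes: a gene anchored in any collinear block is ``wgt``; otherwise
a rank-adjacent same-chromosome paralog makes it ``tandem``; a paralog
within ``proximal_gap`` intervening genes makes it ``proximal``; any other
paralog makes it ``dispersed``; genes without paralogs are ``singleton``.
WGT genes are joined into groups by transitive closure over block anchors;
the number of distinct loci in a group is its retained copy number (2-copy
vs 3-copy after the triplication).

Chaining is MCScanX-like: dynamic programming on the gene-rank dot-plot,
both orientations, rank gaps bounded in either genome, greedy extraction
without anchor reuse.  Same-chromosome anchors within ``max_gap`` ranks of
the diagonal (tandem/proximal self-hits) are excluded from chaining so
local duplication arrays do not masquerade as syntenic segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, percent_half_up, wilcoxon_rank_sum

__all__ = [
    "GeneRank",
    "CollinearBlock",
    "DuplicationClassLabel",
    "rank_genes",
    "chain_collinear_blocks",
    "classify_duplicates",
    "wgt_copy_groups",
    "summarize_fraction",
    "compare_expression_by_class",
]

CLASS_LABELS = ("singleton", "wgt", "tandem", "proximal", "dispersed")


@dataclass(frozen=True)
class GeneRank:
    gene_id: str
    chrom: str
    rank: int


@dataclass(frozen=True)
class CollinearBlock:
    """A chained run of homolog anchors: gene_a ranks strictly increasing,
    gene_b ranks strictly monotone (either orientation)."""

    chrom_a: str
    chrom_b: str
    anchors: tuple  # ((gene_a, rank_a, gene_b, rank_b), ...)
    orientation: int  # +1 or -1

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def genes(self):
        for ga, _, gb, _ in self.anchors:
            yield ga
            yield gb


@dataclass(frozen=True)
class DuplicationClassLabel:
    gene_id: str
    label: str
    wgt_group_id: int | None = None
    copy_number: int | None = None

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}")


def rank_genes(genes) -> dict:
    """Dense 0-based ordinals by start position within each chromosome.

    Ties on start break by end, then by gene id, so ranking is
    deterministic.  Returns {gene_id: GeneRank}.
    """
    by_chrom: dict = {}
    for g in genes.values() if isinstance(genes, dict) else genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    out = {}
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda g: (g.interval.start, g.interval.end, g.gene_id))
        for rank, g in enumerate(lst):
            out[g.gene_id] = GeneRank(g.gene_id, chrom, rank)
    return out


def _anchors_by_chrom_pair(pairs: pd.DataFrame, ranks: dict, max_gap: int):
    """Group anchors by canonical chromosome pair; same-chromosome anchors
    near the diagonal are dropped (local-duplication self-hits)."""
    grouped: dict = {}
    for row in pairs.itertuples():
        for gene in (row.gene_a, row.gene_b):
            if gene not in ranks:
                raise KeyError(f"gene {gene!r} in pairs but absent from the annotation")
        ra, rb = ranks[row.gene_a], ranks[row.gene_b]
        if (ra.chrom, ra.rank) > (rb.chrom, rb.rank):
            ra, rb = rb, ra
        if ra.chrom == rb.chrom and abs(ra.rank - rb.rank) <= max_gap:
            continue
        grouped.setdefault((ra.chrom, rb.chrom), []).append(
            (ra.gene_id, ra.rank, rb.gene_id, rb.rank))
    return grouped


def _best_chain(anchors, max_gap: int, orientation: int):
    """Longest chain by DP; anchors sorted by rank_a, strict monotonicity
    in both genomes, rank gaps <= max_gap."""
    n = len(anchors)
    score = [1] * n
    prev = [-1] * n
    for i in range(n):
        _, rai, _, rbi = anchors[i]
        for j in range(i - 1, -1, -1):
            _, raj, _, rbj = anchors[j]
            if rai - raj - 1 > max_gap:
                break  # sorted by rank_a: earlier anchors are even farther
            if raj >= rai:
                continue
            db = (rbi - rbj) * orientation
            if db < 1 or db - 1 > max_gap:
                continue
            if score[j] + 1 > score[i]:
                score[i] = score[j] + 1
                prev[i] = j
    best = int(np.argmax(score))
    chain = []
    k = best
    while k != -1:
        chain.append(k)
        k = prev[k]
    return chain[::-1], score[best]


def chain_collinear_blocks(pairs: pd.DataFrame, ranks: dict,
                           min_anchors: int = 5, max_gap: int = 25) -> list:
    """Chain homolog anchors into collinear blocks.

    Blocks are extracted greedily (best chain first, no anchor reuse) per
    chromosome pair and orientation until no chain reaches
    ``min_anchors``.
    """
    blocks = []
    for (ca, cb), anchors in _anchors_by_chrom_pair(pairs, ranks, max_gap).items():
        remaining = sorted(anchors, key=lambda a: (a[1], a[3]))
        while len(remaining) >= min_anchors:
            best_chain, best_len, best_orient = None, 0, 0
            for orientation in (1, -1):
                chain, length = _best_chain(remaining, max_gap, orientation)
                if length > best_len:
                    best_chain, best_len, best_orient = chain, length, orientation
            if best_len < min_anchors:
                break
            chosen = [remaining[i] for i in best_chain]
            blocks.append(CollinearBlock(ca, cb, tuple(chosen), best_orient))
            chosen_set = set(best_chain)
            remaining = [a for i, a in enumerate(remaining) if i not in chosen_set]
    return blocks


def classify_duplicates(genes, pairs: pd.DataFrame, blocks, ranks: dict | None = None,
                        proximal_gap: int = 10) -> dict:
    """Assign every gene exactly one duplication class.

    Precedence: wgt (block anchor) > tandem (rank-adjacent paralog on the
    same chromosome) > proximal (paralog within ``proximal_gap``
    intervening genes) > dispersed (any other paralog) > singleton (no
    paralog).  Returns {gene_id: DuplicationClassLabel}; WGT group ids and
    copy numbers are attached from the blocks.
    """
    gene_ids = set(genes.keys() if isinstance(genes, dict) else
                   (g.gene_id for g in genes))
    if ranks is None:
        ranks = rank_genes(genes)

    partners: dict = {g: set() for g in gene_ids}
    for row in pairs.itertuples():
        if row.gene_a not in gene_ids or row.gene_b not in gene_ids:
            missing = row.gene_a if row.gene_a not in gene_ids else row.gene_b
            raise KeyError(f"gene {missing!r} in pairs but absent from the annotation")
        partners[row.gene_a].add(row.gene_b)
        partners[row.gene_b].add(row.gene_a)

    groups = wgt_copy_groups(blocks)
    group_of: dict = {}
    copy_of: dict = {}
    for gid, (members, copy_number) in enumerate(groups):
        for g in members:
            group_of[g] = gid
            copy_of[g] = copy_number

    labels = {}
    for g in sorted(gene_ids):
        if not partners[g]:
            labels[g] = DuplicationClassLabel(g, "singleton")
            continue
        if g in group_of:
            labels[g] = DuplicationClassLabel(g, "wgt", group_of[g], copy_of[g])
            continue
        rg = ranks[g]
        gaps = [abs(ranks[p].rank - rg.rank) - 1
                for p in partners[g] if ranks[p].chrom == rg.chrom]
        if any(gap == 0 for gap in gaps):
            labels[g] = DuplicationClassLabel(g, "tandem")
        elif any(1 <= gap <= proximal_gap for gap in gaps):
            labels[g] = DuplicationClassLabel(g, "proximal")
        else:
            labels[g] = DuplicationClassLabel(g, "dispersed")
    return labels


def wgt_copy_groups(blocks, fold_high_copy: bool = False) -> list:
    """Join block-anchor genes into groups by transitive closure; a
    group's copy number is its count of distinct syntenic loci (= genes).

    Groups with >= 4 loci are reported as-is and excluded from the 2/3-copy
    dichotomy unless ``fold_high_copy`` folds them into 3-copy.  Returns
    [(sorted gene tuple, copy_number), ...].
    """
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for block in blocks:
        for ga, _, gb, _ in block.anchors:
            union(ga, gb)

    members: dict = {}
    for g in parent:
        members.setdefault(find(g), set()).add(g)
    groups = []
    for mset in members.values():
        copy_number = len(mset)
        if copy_number >= 4 and fold_high_copy:
            copy_number = 3
        groups.append((tuple(sorted(mset)), copy_number))
    groups.sort()
    return groups


def summarize_fraction(numerator: int, denominator: int) -> float:
    """Percent numerator/denominator, 2 dp, half-up (787/4612 -> 17.06)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be > 0")
    return percent_half_up(numerator, denominator, 2)


def compare_expression_by_class(expression: pd.DataFrame, labels: dict,
                                copy_number: dict | None = None,
                                split_wgt: bool = True) -> pd.DataFrame:
    """Per-class expression medians and BH-adjusted pairwise rank-sum
    p-values.

    ``expression`` is the long-format FPKM table; per-gene expression is
    the mean over samples.  With ``split_wgt`` the wgt class is divided
    into 2-copy and 3-copy using ``copy_number`` (or the labels' own copy
    numbers).  Genes without expression are excluded (counted in the
    attrs).  Classes present with < 2 genes raise.
    """
    per_gene = expression.groupby("gene_id")["fpkm"].mean()

    def class_of(g):
        lab = labels[g]
        name = lab.label if isinstance(lab, DuplicationClassLabel) else lab
        if split_wgt and name == "wgt":
            cn = None
            if isinstance(lab, DuplicationClassLabel):
                cn = lab.copy_number
            if cn is None and copy_number:
                cn = copy_number.get(g)
            return f"wgt_{cn}copy" if cn in (2, 3) else "wgt"
        return name

    values: dict = {}
    n_missing = 0
    for g in labels:
        if g not in per_gene.index:
            n_missing += 1
            continue
        values.setdefault(class_of(g), []).append(float(per_gene[g]))
    if len(values) < 2:
        raise ValueError("need >= 2 classes with expression")
    for cls, v in values.items():
        if len(v) < 2:
            raise ValueError(f"class {cls!r} has < 2 genes with expression")

    classes = sorted(values)
    rows = []
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            res = wilcoxon_rank_sum(values[a], values[b], "two_sided")
            rows.append((a, b, float(np.median(values[a])),
                         float(np.median(values[b])), res.p_value))
    out = pd.DataFrame(rows, columns=["class_a", "class_b", "median_a",
                                      "median_b", "p"])
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out.attrs["n_genes_without_expression"] = n_missing
    out.attrs["class_sizes"] = {c: len(v) for c, v in values.items()}
    out.attrs["medians"] = {c: float(np.median(v)) for c, v in values.items()}
    return out
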