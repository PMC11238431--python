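"""Seeded generator of genomes, annotations, methylomes, structural
variants, expression tables and m6A site tables with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume:

* two-group replicate methylomes with context- and feature-class-specific
  baselines, beta-binomial replicate noise, and planted DMRs that shift the
  group-B mean inside known intervals;
* SV sets whose breakpoints optionally carry a localized CHH elevation;
* gene arrangements realizing every duplication class - tandem pairs
  adjacent in gene rank, proximal pairs separated by a bounded number of
  intervening genes, dispersed pairs on different chromosomes, and
  order-preserving syntenic segments copied to two or three loci
  (whole-genome-triplication remnants);
* class-shifted log-normal expression;
* replicate m6A site tables with DRACH 5-mer contexts, a 3'-UTR placement
  bias, per-replicate detection probability and false positives.

Every sub-generator draws from its own RNG stream derived from the master
seed, so adding one generator does not perturb the others, and the same
seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genome_io import (
    Annotation,
    GeneModel,
    GenomicInterval,
    RepeatFeature,
    SVRecord,
    TranscriptModel,
    write_cx_report,
    write_expression,
    write_fasta,
    write_gff3,
    write_homolog_pairs,
    write_sv_vcf,
)

__all__ = [
    "DuplicationPlan",
    "MethylationPlan",
    "DMRPlan",
    "SVPlan",
    "ExpressionPlan",
    "M6APlan",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedGenome",
    "simulate_annotation",
    "simulate_svs",
    "simulate_methylome",
    "simulate_expression",
    "simulate_m6a",
    "simulate_all",
    "dmr_recovery",
    "dmr_recovery_config",
    "sv_breakpoint_config",
    "duplication_plan_config",
    "m6a_metagene_config",
]

# RNG stream ids (one stream per sub-generator)
_STREAM_SEQ = 1
_STREAM_LAYOUT = 2
_STREAM_TE = 3
_STREAM_DMR = 4
_STREAM_SV = 5
_STREAM_METH = 6
_STREAM_EXPR = 7
_STREAM_M6A = 8

FEATURE_CLASSES = ("intergenic", "gene", "Copia", "Gypsy", "LINE", "DNA_TE", "other")
_CLASS_CODE = {name: i for i, name in enumerate(FEATURE_CLASSES)}
_CONTEXT_CODE = {"CG": 0, "CHG": 1, "CHH": 2}

# D = A/G/U, R = A/G, H = A/C/U with the methylated A at position 3
_DRACH_KMERS = tuple(
    d + r + "A" + "C" + h
    for d in "AGU" for r in "AG" for h in "ACU"
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class DuplicationPlan:
    """Counts of genes per duplication class and of syntenic segments.

    Segment genes are copied in order to 2 or 3 loci; every copy pair is
    emitted in the homolog-pair table, so a 3-copy segment of g genes
    yields g groups of 3 collinear copies.
    """

    n_singleton: int = 100
    n_tandem_pairs: int = 50
    n_proximal_pairs: int = 50
    n_dispersed_pairs: int = 50
    n_two_copy_segments: int = 6
    n_three_copy_segments: int = 1
    genes_per_segment: int = 10
    proximal_gap_max: int = 9  # intervening genes drawn from [1, this]

    @property
    def n_wgt_genes(self) -> int:
        return self.genes_per_segment * (
            2 * self.n_two_copy_segments + 3 * self.n_three_copy_segments
        )

    @property
    def total_genes(self) -> int:
        return (
            self.n_singleton
            + 2 * (self.n_tandem_pairs + self.n_proximal_pairs + self.n_dispersed_pairs)
            + self.n_wgt_genes
        )


@dataclass
class MethylationPlan:
    """Per (context x feature-class) mean levels plus noise parameters.

    ``baselines[context][feature_class]`` in [0, 1]; ``dispersion`` is the
    beta concentration (larger = less replicate overdispersion); coverage
    is Poisson with mean ``depth``.
    """

    baselines: dict = field(default_factory=lambda: {
        "CG":  {"intergenic": 0.35, "gene": 0.45, "Copia": 0.85, "Gypsy": 0.85,
                "LINE": 0.75, "DNA_TE": 0.70, "other": 0.60},
        "CHG": {"intergenic": 0.15, "gene": 0.08, "Copia": 0.60, "Gypsy": 0.65,
                "LINE": 0.50, "DNA_TE": 0.45, "other": 0.40},
        "CHH": {"intergenic": 0.06, "gene": 0.04, "Copia": 0.12, "Gypsy": 0.15,
                "LINE": 0.10, "DNA_TE": 0.10, "other": 0.08},
    })
    dispersion: float = 60.0
    depth: float = 20.0
    n_replicates: int = 3

    def validate(self) -> None:
        for ctx, per_class in self.baselines.items():
            for cls, value in per_class.items():
                if not (0.0 <= value <= 1.0):
                    raise ValueError(
                        f"baseline for ({ctx}, {cls}) outside [0, 1]: {value}"
                    )


@dataclass
class DMRPlan:
    """Plant ``count`` DMRs of one context: group B mean shifted by delta
    inside intervals of the given width."""

    count: int = 0
    context: str = "CG"
    delta: float = 0.6
    width: int = 400


@dataclass
class SVPlan:
    counts: dict = field(default_factory=lambda: {
        "INS": 0, "DEL": 0, "DUP": 0, "INV": 0, "TRANS": 0})
    length_range: tuple = (50, 2000)
    boundary_fraction: float = 0.0   # fraction of PAVs placed at feature boundaries
    boundary_jitter: int = 60
    chh_delta: float = 0.0           # CHH elevation at flagged breakpoints
    chh_half_width: int = 500
    chh_effect_fraction: float = 0.0  # fraction of INS/DEL flagged
    end_margin: int = 8_200          # keep breakpoints clear of contig ends


@dataclass
class ExpressionPlan:
    log_mu: float = 2.3       # log FPKM grand mean (~10 FPKM)
    log_sigma: float = 1.0    # between-gene log-scale SD
    sample_sigma: float = 0.1
    n_samples: int = 3
    class_shifts: dict = field(default_factory=lambda: {
        "singleton": 0.0, "tandem": 0.2, "proximal": 0.2, "dispersed": 0.1,
        "wgt_2copy": 0.7, "wgt_3copy": 1.0})
    m6a_shift: float = 0.8    # additive log shift for m6A-modified genes


@dataclass
class M6APlan:
    modification_probability: dict = field(default_factory=lambda: {
        "singleton": 0.05, "tandem": 0.08, "proximal": 0.07,
        "dispersed": 0.06, "wgt": 0.1152})
    sites_per_transcript_mean: float = 2.0  # 1 + Poisson(mean - 1)
    utr5_fraction: float = 0.08
    utr3_fraction: float = 0.67
    drach_fraction: float = 0.95
    detection_probability: float = 0.9
    false_positive_rate: float = 0.05  # per replicate, relative to n true sites
    n_replicates: int = 3


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 9
    chrom_lengths: dict | None = None  # explicit lengths for gene-free genomes
    gene_length_range: tuple = (1200, 3000)
    intergenic_gap_range: tuple = (800, 3000)
    utr5_fraction: float = 0.12
    utr3_fraction: float = 0.25
    te_count: int = 120
    te_class_weights: dict = field(default_factory=lambda: {
        "Copia": 0.35, "Gypsy": 0.4, "LINE": 0.1, "DNA_TE": 0.15})
    te_length_range: tuple = (500, 4000)
    duplication: DuplicationPlan = field(default_factory=DuplicationPlan)
    methylation: MethylationPlan = field(default_factory=MethylationPlan)
    dmrs: list = field(default_factory=list)
    svs: SVPlan = field(default_factory=SVPlan)
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)
    m6a: M6APlan = field(default_factory=M6APlan)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (("duplication", DuplicationPlan), ("methylation", MethylationPlan),
                         ("svs", SVPlan), ("expression", ExpressionPlan), ("m6a", M6APlan)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "dmrs" in kwargs:
            kwargs["dmrs"] = [DMRPlan(**d) if isinstance(d, dict) else d
                              for d in kwargs["dmrs"]]
        for key in ("gene_length_range", "intergenic_gap_range", "te_length_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def rng(self, *stream) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), *stream])


@dataclass
class GroundTruth:
    """Planted structure; every entry maps to a generated record."""

    gene_classes: dict = field(default_factory=dict)      # gene -> class label
    wgt_groups: list = field(default_factory=list)        # [tuple(genes), ...]
    wgt_copy_number: dict = field(default_factory=dict)   # gene -> 2 or 3
    pairs: pd.DataFrame | None = None
    dmrs: list = field(default_factory=list)   # (chrom, start0, end0, context, delta, direction)
    sv_breakpoints: list = field(default_factory=list)    # (chrom, pos0, effect_flag)
    m6a_sites: dict = field(default_factory=dict)         # transcript -> [(pos, kmer), ...]

    def to_jsonable(self) -> dict:
        return {
            "gene_classes": self.gene_classes,
            "wgt_groups": [list(g) for g in self.wgt_groups],
            "wgt_copy_number": self.wgt_copy_number,
            "dmrs": [list(d) for d in self.dmrs],
            "sv_breakpoints": [list(b) for b in self.sv_breakpoints],
            "m6a_sites": {t: [[int(p), k] for p, k in v]
                          for t, v in self.m6a_sites.items()},
        }


@dataclass
class SimulatedGenome:
    """Annotation-stage output: sequences, gene/TE models, ground truth."""

    config: SimulationConfig
    seqs: dict
    annotation: Annotation
    truth: GroundTruth
    _site_cache: dict = field(default_factory=dict, repr=False)
    _class_cache: dict = field(default_factory=dict, repr=False)

    @property
    def chrom_lengths(self) -> dict:
        return {name: len(seq) for name, seq in self.seqs.items()}


# ---------------------------------------------------------------------------
# Annotation (genome + genes + TEs + duplication structure + planted DMRs)
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length).tobytes().decode()


def _validate_plan(cfg: SimulationConfig) -> None:
    plan = cfg.duplication
    has_wgt = plan.n_two_copy_segments + plan.n_three_copy_segments > 0
    has_small = (plan.n_singleton + plan.n_tandem_pairs + plan.n_proximal_pairs
                 + plan.n_dispersed_pairs) > 0
    n_wgt_chroms = 3 if has_wgt else 0
    n_small_chroms = cfg.n_chroms - n_wgt_chroms
    if has_wgt and cfg.n_chroms < 3:
        raise ValueError("infeasible plan: syntenic segments need >= 3 chromosomes")
    if has_small and n_small_chroms < 1:
        raise ValueError("infeasible plan: no chromosomes left for small-scale genes")
    if plan.n_dispersed_pairs:
        if n_small_chroms < 2:
            raise ValueError("infeasible plan: dispersed pairs need >= 2 chromosomes")
        n_chrom_pairs = n_small_chroms * (n_small_chroms - 1) // 2
        if plan.n_dispersed_pairs > 4 * n_chrom_pairs:
            raise ValueError(
                "infeasible plan: too many dispersed pairs; at most 4 per "
                "chromosome pair are placed to keep them off collinear blocks"
            )
    if has_wgt and plan.genes_per_segment < 1:
        raise ValueError("infeasible plan: segments need >= 1 gene")


def _build_gene_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Return (per-chrom ordered gene-id lists, truth scaffolding, pairs)."""
    plan = cfg.duplication
    has_wgt = plan.n_two_copy_segments + plan.n_three_copy_segments > 0
    chroms = [f"Chr{i + 1}" for i in range(cfg.n_chroms)]
    wgt_chroms = chroms[:3] if has_wgt else []
    small_chroms = chroms[len(wgt_chroms):]

    order = {c: [] for c in chroms}
    classes: dict = {}
    groups: list = []
    copy_number: dict = {}
    pair_rows: list = []

    def add_pair(a, b):
        pair_rows.append((a, b, float(rng.uniform(50.0, 100.0))))

    # --- whole-genome-triplication segments -------------------------------
    uid = itertools.count()
    two_copy_pairs = list(itertools.combinations(range(3), 2))
    for s in range(plan.n_two_copy_segments):
        ca, cb = two_copy_pairs[s % len(two_copy_pairs)]
        run_a, run_b = [], []
        for _ in range(plan.genes_per_segment):
            i = next(uid)
            ga, gb = f"WGT{i}a", f"WGT{i}b"
            run_a.append(ga)
            run_b.append(gb)
            add_pair(ga, gb)
            groups.append((ga, gb))
            for g in (ga, gb):
                classes[g] = "wgt"
                copy_number[g] = 2
        order[wgt_chroms[ca]].extend(run_a)
        order[wgt_chroms[cb]].extend(run_b)
    for s in range(plan.n_three_copy_segments):
        runs = [[], [], []]
        for _ in range(plan.genes_per_segment):
            i = next(uid)
            trio = tuple(f"WGT{i}{suffix}" for suffix in "abc")
            for k, g in enumerate(trio):
                runs[k].append(g)
                classes[g] = "wgt"
                copy_number[g] = 3
            for ga, gb in itertools.combinations(trio, 2):
                add_pair(ga, gb)
            groups.append(trio)
        for k in range(3):
            order[wgt_chroms[k]].extend(runs[k])

    # --- small-scale units -------------------------------------------------
    # dispersed mates are pinned to chromosome pairs, at most 4 per pair, so
    # they can never assemble into a collinear block
    units = {c: [] for c in small_chroms}
    if plan.n_dispersed_pairs:
        chrom_pairs = list(itertools.combinations(small_chroms, 2))
        per_pair = {cp: 0 for cp in chrom_pairs}
        cp_cycle = itertools.cycle(chrom_pairs)
        for i in range(plan.n_dispersed_pairs):
            while True:
                cp = next(cp_cycle)
                if per_pair[cp] < 4:
                    per_pair[cp] += 1
                    break
            a, b = f"DSP{i}a", f"DSP{i}b"
            classes[a] = classes[b] = "dispersed"
            add_pair(a, b)
            units[cp[0]].append(("single", [a]))
            units[cp[1]].append(("single", [b]))

    small_units = []
    for i in range(plan.n_singleton):
        g = f"SGL{i}"
        classes[g] = "singleton"
        small_units.append(("single", [g]))
    for i in range(plan.n_tandem_pairs):
        a, b = f"TDM{i}a", f"TDM{i}b"
        classes[a] = classes[b] = "tandem"
        add_pair(a, b)
        small_units.append(("tandem", [a, b]))
    for i in range(plan.n_proximal_pairs):
        a, b = f"PRX{i}a", f"PRX{i}b"
        classes[a] = classes[b] = "proximal"
        add_pair(a, b)
        small_units.append(("proximal", [a, b]))
    rng.shuffle(small_units)
    if small_chroms:
        for i, unit in enumerate(small_units):
            units[small_chroms[i % len(small_chroms)]].append(unit)

    # lay out each small chromosome; proximal mates are deferred by a drawn
    # countdown of intervening genes, flushed only at unit boundaries so
    # tandem mates always stay adjacent
    for chrom in small_chroms:
        chrom_units = units[chrom]
        rng.shuffle(chrom_units)
        # a proximal unit must not be last (its mate needs >= 1 gene after it)
        for idx in range(len(chrom_units) - 1, -1, -1):
            if chrom_units and chrom_units[-1][0] == "proximal":
                for j in range(len(chrom_units) - 2, -1, -1):
                    if chrom_units[j][0] != "proximal":
                        chrom_units[-1], chrom_units[j] = chrom_units[j], chrom_units[-1]
                        break
            break
        placed = order[chrom]
        pending: list = []  # [mate_gene_id, countdown]
        for kind, genes in chrom_units:
            if kind == "proximal":
                placed.append(genes[0])
                for p in pending:
                    p[1] -= 1
                gap = int(rng.integers(1, cfg.duplication.proximal_gap_max + 1))
                pending.append([genes[1], gap])
            else:
                for g in genes:
                    placed.append(g)
                    for p in pending:
                        p[1] -= 1
            ready = [p for p in pending if p[1] <= 0]
            for p in ready:
                placed.append(p[0])
                pending.remove(p)
                for q in pending:
                    q[1] -= 1
        for p in pending:  # flush; >= 1 gene has always followed the mate
            placed.append(p[0])

    pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "score"])
    return order, classes, groups, copy_number, pairs


def simulate_annotation(cfg: SimulationConfig) -> SimulatedGenome:
    """Generate genome sequences, gene/transcript/TE annotation and the
    duplication-class ground truth; plant the configured DMR intervals.

    Raises before building anything if the duplication plan cannot be
    realized on the configured chromosomes.
    """
    _validate_plan(cfg)
    cfg.methylation.validate()
    layout_rng = cfg.rng(_STREAM_LAYOUT)
    seq_rng = cfg.rng(_STREAM_SEQ)

    order, classes, groups, copy_number, pairs = _build_gene_layout(cfg, layout_rng)

    ann = Annotation()
    chrom_lengths: dict = {}
    lo_len, hi_len = cfg.gene_length_range
    lo_gap, hi_gap = cfg.intergenic_gap_range
    for chrom, gene_ids in order.items():
        cursor = int(layout_rng.integers(lo_gap, hi_gap + 1))
        for gid in gene_ids:
            length = int(layout_rng.integers(lo_len, hi_len + 1))
            strand = "+" if layout_rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, cursor, cursor + length, strand)
            tid = f"{gid}.1"
            utr5 = int(round(cfg.utr5_fraction * length))
            utr3 = int(round(cfg.utr3_fraction * length))
            ann.transcripts[tid] = TranscriptModel(tid, gid, utr5, length - utr5 - utr3, utr3)
            ann.genes[gid] = GeneModel(gid, iv, (tid,))
            cursor = iv.end + int(layout_rng.integers(lo_gap, hi_gap + 1))
        chrom_lengths[chrom] = cursor + int(layout_rng.integers(lo_gap, hi_gap + 1))
    if cfg.chrom_lengths:
        for chrom, length in cfg.chrom_lengths.items():
            chrom_lengths[chrom] = max(length, chrom_lengths.get(chrom, 0))

    seqs = {chrom: _random_sequence(seq_rng, length)
            for chrom, length in chrom_lengths.items()}

    # --- transposable elements in intergenic space -------------------------
    te_rng = cfg.rng(_STREAM_TE)
    if cfg.te_count:
        te_classes = list(cfg.te_class_weights)
        weights = np.array([cfg.te_class_weights[c] for c in te_classes], dtype=float)
        weights /= weights.sum()
        gene_ivs = {c: sorted((g.interval.start, g.interval.end)
                              for g in ann.genes.values() if g.interval.chrom == c)
                    for c in seqs}
        chrom_names = list(seqs)
        sizes = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
        placed = 0
        attempts = 0
        while placed < cfg.te_count and attempts < cfg.te_count * 200:
            attempts += 1
            chrom = chrom_names[int(te_rng.choice(len(chrom_names), p=sizes / sizes.sum()))]
            length = int(te_rng.integers(*cfg.te_length_range))
            if chrom_lengths[chrom] <= length + 2:
                continue
            start = int(te_rng.integers(0, chrom_lengths[chrom] - length))
            if any(s < start + length and start < e for s, e in gene_ivs[chrom]):
                continue
            cls = te_classes[int(te_rng.choice(len(te_classes), p=weights))]
            ann.repeats.append(
                RepeatFeature(GenomicInterval(chrom, start, start + length, "."), cls))
            placed += 1

    truth = GroundTruth(gene_classes=classes, wgt_groups=groups,
                        wgt_copy_number=copy_number, pairs=pairs)
    genome = SimulatedGenome(cfg, seqs, ann, truth)

    # --- planted DMR intervals ---------------------------------------------
    dmr_rng = cfg.rng(_STREAM_DMR)
    occupied: dict = {c: [] for c in seqs}
    margin = 400  # keep planted regions apart so merged calls stay 1:1
    for plan in cfg.dmrs:
        if plan.context not in _CONTEXT_CODE:
            raise ValueError(f"unknown context {plan.context!r}")
        base = cfg.methylation.baselines[plan.context]
        n_placed = 0
        attempts = 0
        chrom_names = list(seqs)
        sizes = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
        while n_placed < plan.count:
            attempts += 1
            if attempts > 1000 * max(plan.count, 1):
                raise ValueError("could not place planted DMRs; genome too crowded")
            chrom = chrom_names[int(dmr_rng.choice(len(chrom_names), p=sizes / sizes.sum()))]
            if chrom_lengths[chrom] <= plan.width + 2 * margin:
                continue
            start = int(dmr_rng.integers(margin, chrom_lengths[chrom] - plan.width - margin))
            end = start + plan.width
            if any(s - margin < end and start < e + margin for s, e in occupied[chrom]):
                continue
            # the shifted group-B mean must stay in [0, 1] without clipping
            cls_codes = _feature_class_codes(genome, chrom)[start:end]
            local = max(base[FEATURE_CLASSES[c]] for c in np.unique(cls_codes))
            lo = min(base[FEATURE_CLASSES[c]] for c in np.unique(cls_codes))
            if not (0.0 <= lo + plan.delta and local + plan.delta <= 1.0):
                continue
            occupied[chrom].append((start, end))
            direction = "hypo" if plan.delta > 0 else "hyper"  # relative to group A
            truth.dmrs.append((chrom, start, end, plan.context, plan.delta, direction))
            n_placed += 1
    return genome


# ---------------------------------------------------------------------------
# Feature painting and cytosine site extraction (cached per chromosome)
# ---------------------------------------------------------------------------

def _feature_class_codes(genome: SimulatedGenome, chrom: str) -> np.ndarray:
    """Per-bp feature-class code; TE class overrides genic overrides
    intergenic."""
    if chrom in genome._class_cache:
        return genome._class_cache[chrom]
    codes = np.zeros(len(genome.seqs[chrom]), dtype=np.int8)
    for g in genome.annotation.genes.values():
        if g.interval.chrom == chrom:
            codes[g.interval.start:g.interval.end] = _CLASS_CODE["gene"]
    for r in genome.annotation.repeats:
        if r.interval.chrom == chrom:
            codes[r.interval.start:r.interval.end] = _CLASS_CODE[r.repeat_class]
    genome._class_cache[chrom] = codes
    return codes


def _cytosine_sites(genome: SimulatedGenome, chrom: str):
    """(pos0, strand, context_code) arrays for every cytosine on both
    strands, ordered by position.  Terminal bases without full context are
    skipped."""
    if chrom in genome._site_cache:
        return genome._site_cache[chrom]
    b = np.frombuffer(genome.seqs[chrom].encode("ascii"), dtype=np.uint8)
    C, G = ord("C"), ord("G")
    # plus strand: C at i, context from b[i+1], b[i+2]
    plus = np.nonzero(b[:-2] == C)[0]
    ctx_p = np.full(plus.size, _CONTEXT_CODE["CHH"], dtype=np.int8)
    ctx_p[b[plus + 2] == G] = _CONTEXT_CODE["CHG"]
    ctx_p[b[plus + 1] == G] = _CONTEXT_CODE["CG"]
    # minus strand: G at i, context from complement of b[i-1], b[i-2]
    minus = np.nonzero(b[2:] == G)[0] + 2
    ctx_m = np.full(minus.size, _CONTEXT_CODE["CHH"], dtype=np.int8)
    ctx_m[b[minus - 2] == C] = _CONTEXT_CODE["CHG"]
    ctx_m[b[minus - 1] == C] = _CONTEXT_CODE["CG"]
    pos = np.concatenate([plus, minus])
    strand = np.concatenate([np.zeros(plus.size, dtype=np.int8),
                             np.ones(minus.size, dtype=np.int8)])
    ctx = np.concatenate([ctx_p, ctx_m])
    srt = np.argsort(pos, kind="mergesort")
    out = (pos[srt], strand[srt], ctx[srt])
    genome._site_cache[chrom] = out
    return out


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

def simulate_svs(genome: SimulatedGenome) -> list:
    """Generate SVRecords per the config's SVPlan; breakpoints and their
    CHH-effect flags are recorded in the ground truth (the methylome
    generator reads the flags, so call this before simulating methylomes).
    """
    cfg = genome.config
    plan = cfg.svs
    rng = cfg.rng(_STREAM_SV)
    chrom_names = list(genome.seqs)
    lengths = genome.chrom_lengths
    sizes = np.array([lengths[c] for c in chrom_names], dtype=float)

    boundaries: list = []
    for g in genome.annotation.genes.values():
        boundaries.append((g.interval.chrom, g.interval.start))
        boundaries.append((g.interval.chrom, g.interval.end))
    for r in genome.annotation.repeats:
        boundaries.append((r.interval.chrom, r.interval.start))
        boundaries.append((r.interval.chrom, r.interval.end))

    records: list = []
    counter = itertools.count()

    def draw_position():
        if boundaries and plan.boundary_fraction > 0 and rng.random() < plan.boundary_fraction:
            chrom, pos = boundaries[int(rng.integers(len(boundaries)))]
            pos += int(rng.integers(-plan.boundary_jitter, plan.boundary_jitter + 1))
        else:
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=sizes / sizes.sum()))]
            pos = int(rng.integers(plan.end_margin, max(lengths[chrom] - plan.end_margin, plan.end_margin + 1)))
        pos = int(np.clip(pos, plan.end_margin, max(lengths[chrom] - plan.end_margin, plan.end_margin)))
        return chrom, pos

    for sv_type, count in plan.counts.items():
        for _ in range(count):
            chrom, pos0 = draw_position()
            length = int(rng.integers(*plan.length_range))
            sid = f"sv{next(counter)}"
            effect = (sv_type in ("INS", "DEL")
                      and rng.random() < plan.chh_effect_fraction)
            if sv_type == "INS":
                records.append(SVRecord("INS", chrom, pos0 + 1, length, sid))
                bps = [(chrom, pos0)]
            elif sv_type in ("DEL", "DUP", "INV"):
                end0 = min(pos0 + length, lengths[chrom] - 1)
                records.append(SVRecord(sv_type, chrom, pos0 + 1, end0 - pos0, sid,
                                        end=end0 + 1))
                bps = [(chrom, pos0), (chrom, end0)]
            else:  # TRANS
                chrom2, pos2 = draw_position()
                records.append(SVRecord("TRANS", chrom, pos0 + 1, 1, sid,
                                        end=pos2 + 1, chrom2=chrom2))
                bps = [(chrom, pos0), (chrom2, pos2)]
            for bp in bps:
                genome.truth.sv_breakpoints.append((bp[0], bp[1], bool(effect)))
    return records


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------

_STRANDS = np.array(["+", "-"])
_CONTEXT_NAMES = np.array(["CG", "CHG", "CHH"])


def simulate_methylome(genome: SimulatedGenome, group: str, replicate: int) -> pd.DataFrame:
    """One replicate methylome for group "A" or "B" as a CX-report frame.

    Per cytosine: coverage ~ Poisson(depth); the site methylation
    probability is Beta-distributed around the baseline of the covering
    feature class (TE class overrides genic overrides intergenic);
    methylated counts are Binomial(coverage, p).  Planted DMRs shift the
    group-B mean by delta inside their intervals; flagged SV breakpoints
    add the configured CHH elevation in both groups.
    """
    if group not in ("A", "B"):
        raise ValueError("group must be 'A' or 'B'")
    cfg = genome.config
    meth = cfg.methylation
    meth.validate()
    rng = cfg.rng(_STREAM_METH, 0 if group == "A" else 1, int(replicate))

    base_lut = np.zeros((3, len(FEATURE_CLASSES)))
    for ctx, code in _CONTEXT_CODE.items():
        for cls, cc in _CLASS_CODE.items():
            base_lut[code, cc] = meth.baselines[ctx][cls]

    effect_bps: dict = {}
    if cfg.svs.chh_delta:
        for chrom, pos0, flag in genome.truth.sv_breakpoints:
            if flag:
                effect_bps.setdefault(chrom, []).append(pos0)

    frames = []
    for chrom in genome.seqs:
        pos, strand, ctx = _cytosine_sites(genome, chrom)
        codes = _feature_class_codes(genome, chrom)
        m = base_lut[ctx, codes[pos]].copy()
        if group == "B":
            for dchrom, start, end, dctx, delta, _ in genome.truth.dmrs:
                if dchrom != chrom:
                    continue
                mask = (pos >= start) & (pos < end) & (ctx == _CONTEXT_CODE[dctx])
                m[mask] += delta
        for bp in effect_bps.get(chrom, ()):
            half = cfg.svs.chh_half_width
            lo = np.searchsorted(pos, bp - half)
            hi = np.searchsorted(pos, bp + half + 1)
            sel = slice(lo, hi)
            chh = ctx[sel] == _CONTEXT_CODE["CHH"]
            m[sel] = np.where(chh, m[sel] + cfg.svs.chh_delta, m[sel])
        np.clip(m, 0.0, 1.0, out=m)

        p_site = np.zeros_like(m)
        interior = (m > 0.0) & (m < 1.0)
        nu = meth.dispersion
        p_site[interior] = rng.beta(m[interior] * nu, (1.0 - m[interior]) * nu)
        p_site[m >= 1.0] = 1.0
        cov = rng.poisson(meth.depth, size=m.size)
        mc = rng.binomial(cov, p_site)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos + 1,
            "strand": _STRANDS[strand],
            "count_methylated": mc,
            "count_unmethylated": cov - mc,
            "context": _CONTEXT_NAMES[ctx],
            "trinucleotide": _CONTEXT_NAMES[ctx],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _expression_class(genome: SimulatedGenome, gene: str) -> str:
    cls = genome.truth.gene_classes[gene]
    if cls == "wgt":
        return "wgt_3copy" if genome.truth.wgt_copy_number.get(gene) == 3 else "wgt_2copy"
    return cls


def simulate_expression(genome: SimulatedGenome) -> pd.DataFrame:
    """Log-normal FPKM per gene and sample with additive log-scale shifts
    per duplication class and for m6A-modified genes (call simulate_m6a
    first if the m6A shift should apply)."""
    cfg = genome.config
    plan = cfg.expression
    rng = cfg.rng(_STREAM_EXPR)
    modified_genes = {
        genome.annotation.transcripts[t].gene_id for t in genome.truth.m6a_sites
    }
    rows = []
    for gene in sorted(genome.annotation.genes):
        shift = plan.class_shifts.get(_expression_class(genome, gene), 0.0)
        if gene in modified_genes:
            shift += plan.m6a_shift
        gene_mu = plan.log_mu + shift + rng.normal(0.0, plan.log_sigma)
        for s in range(plan.n_samples):
            fpkm = float(np.exp(gene_mu + rng.normal(0.0, plan.sample_sigma)))
            rows.append((gene, f"sample{s + 1}", fpkm))
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "fpkm"])


# ---------------------------------------------------------------------------
# m6A site tables
# ---------------------------------------------------------------------------

def _random_kmer(rng: np.random.Generator, drach: bool) -> str:
    if drach:
        return _DRACH_KMERS[int(rng.integers(len(_DRACH_KMERS)))]
    alphabet = "ACGU"
    while True:
        kmer = "".join(alphabet[int(rng.integers(4))] for _ in range(4))
        kmer = kmer[:2] + "A" + kmer[2:]
        if not (kmer[0] in "AGU" and kmer[1] in "AG" and kmer[3] == "C" and kmer[4] in "ACU"):
            return kmer


def simulate_m6a(genome: SimulatedGenome) -> list:
    """Replicate m6A site tables (transcript_id, position, probability,
    kmer).  True sites are placed with the configured region bias (fraction
    in the 3' UTR), carry DRACH 5-mers (with a configurable non-DRACH
    remainder), and are observed in each replicate with the detection
    probability; false positives are added per replicate.  The true site
    set is recorded in the ground truth."""
    cfg = genome.config
    plan = cfg.m6a
    rng = cfg.rng(_STREAM_M6A)
    p_cds = 1.0 - plan.utr5_fraction - plan.utr3_fraction
    if p_cds < 0:
        raise ValueError("utr5_fraction + utr3_fraction must be <= 1")

    truth_sites = genome.truth.m6a_sites
    truth_sites.clear()
    for tid in sorted(genome.annotation.transcripts):
        tx = genome.annotation.transcripts[tid]
        gene_cls = genome.truth.gene_classes[tx.gene_id]
        p_mod = plan.modification_probability.get(gene_cls, 0.0)
        if rng.random() >= p_mod:
            continue
        n_sites = 1 + int(rng.poisson(max(plan.sites_per_transcript_mean - 1.0, 0.0)))
        positions: set = set()
        sites = []
        for _ in range(n_sites):
            u = rng.random()
            if u < plan.utr3_fraction:
                lo, hi = tx.utr5_len + tx.cds_len, tx.length
            elif u < plan.utr3_fraction + plan.utr5_fraction:
                lo, hi = 0, tx.utr5_len
            else:
                lo, hi = tx.utr5_len, tx.utr5_len + tx.cds_len
            lo, hi = max(lo, 2), min(hi, tx.length - 2)
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            if pos in positions:
                continue
            positions.add(pos)
            kmer = _random_kmer(rng, rng.random() < plan.drach_fraction)
            sites.append((pos, kmer))
        if sites:
            truth_sites[tid] = sorted(sites)

    all_tids = sorted(genome.annotation.transcripts)
    n_true = sum(len(v) for v in truth_sites.values())
    tables = []
    for _rep in range(plan.n_replicates):
        rows = []
        for tid, sites in truth_sites.items():
            for pos, kmer in sites:
                if rng.random() < plan.detection_probability:
                    rows.append((tid, pos, float(rng.uniform(0.9, 0.9999)), kmer))
        n_fp = int(rng.poisson(plan.false_positive_rate * n_true))
        taken = {(t, p) for t, s in truth_sites.items() for p, _ in s}
        for _ in range(n_fp):
            tid = all_tids[int(rng.integers(len(all_tids)))]
            tx = genome.annotation.transcripts[tid]
            if tx.length < 6:
                continue
            pos = int(rng.integers(2, tx.length - 2))
            if (tid, pos) in taken:
                continue
            taken.add((tid, pos))
            rows.append((tid, pos, float(rng.uniform(0.9, 0.9999)),
                         _random_kmer(rng, True)))
        df = pd.DataFrame(rows, columns=["transcript_id", "position",
                                         "probability", "kmer"])
        tables.append(df.sort_values(["transcript_id", "position"]).reset_index(drop=True))
    return tables


# ---------------------------------------------------------------------------
# Orchestration and file output
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    genome: SimulatedGenome
    svs: list
    m6a_tables: list
    expression: pd.DataFrame

    def methylome(self, group: str, replicate: int) -> pd.DataFrame:
        return simulate_methylome(self.genome, group, replicate)

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome.seqs, out / "genome.fa")
        write_gff3(self.genome.annotation, out / "annotation.gff3")
        write_sv_vcf(self.svs, out / "svs.vcf", contigs=self.genome.chrom_lengths)
        write_homolog_pairs(self.genome.truth.pairs, out / "pairs.tsv")
        write_expression(self.expression, out / "expression.tsv")
        for i, table in enumerate(self.m6a_tables):
            table.to_csv(out / f"m6a_rep{i + 1}.tsv", sep="\t", index=False)
        n_reps = self.genome.config.methylation.n_replicates
        for group in ("A", "B"):
            for rep in range(n_reps):
                write_cx_report(self.methylome(group, rep),
                                out / f"cx_{group}_rep{rep + 1}.tsv")
        (out / "truth.json").write_text(
            json.dumps(self.genome.truth.to_jsonable(), indent=1))


def simulate_all(cfg: SimulationConfig) -> SimulatedDataset:
    """Run every sub-generator in dependency order."""
    genome = simulate_annotation(cfg)
    svs = simulate_svs(genome)
    m6a_tables = simulate_m6a(genome)
    expression = simulate_expression(genome)
    return SimulatedDataset(genome, svs, m6a_tables, expression)


def dmr_recovery(dmrs, truth: GroundTruth) -> dict:
    """Score called DMRs against the planted truth.

    A planted DMR is recovered when a called DMR of the same context and
    direction overlaps it by >= 1 bp; a called DMR overlapping no planted
    interval is a false positive.  Returns sensitivity and empirical FDR.
    """
    def overlaps(d, t):
        chrom, start, end, ctx, _, direction = t
        return (d.interval.chrom == chrom and d.context == ctx
                and d.interval.start < end and start < d.interval.end)

    n_truth = len(truth.dmrs)
    recovered = sum(
        any(overlaps(d, t) and d.direction == t[5] for d in dmrs)
        for t in truth.dmrs
    )
    false_pos = sum(
        not any(overlaps(d, t) for t in truth.dmrs) for d in dmrs
    )
    return {
        "sensitivity": recovered / n_truth if n_truth else float("nan"),
        "fdr": false_pos / len(dmrs) if dmrs else 0.0,
        "n_called": len(dmrs),
        "n_truth": n_truth,
    }


# ---------------------------------------------------------------------------
# Scenario configurations (the study conditions used by the test suites)
# ---------------------------------------------------------------------------

def dmr_recovery_config(seed: int, genome_size: int = 1_000_000, n_dmrs: int = 200,
                        delta: float = 0.6, width: int = 400, depth: float = 20.0,
                        n_replicates: int = 3, context: str = "CG") -> SimulationConfig:
    """Gene-free genome with planted CG DMRs on a flat baseline (0.2 for
    CG/CHG, 0.05 for CHH)."""
    flat = {"CG": 0.2, "CHG": 0.2, "CHH": 0.05}
    baselines = {ctx: {cls: flat[ctx] for cls in FEATURE_CLASSES} for ctx in flat}
    return SimulationConfig(
        seed=seed, n_chroms=1, chrom_lengths={"Chr1": genome_size},
        te_count=0,
        duplication=DuplicationPlan(0, 0, 0, 0, 0, 0, 0),
        methylation=MethylationPlan(baselines=baselines, depth=depth,
                                    n_replicates=n_replicates),
        dmrs=[DMRPlan(count=n_dmrs, context=context, delta=delta, width=width)],
    )


def sv_breakpoint_config(seed: int, genome_size: int = 3_000_000, n_ins: int = 300,
                         chh_delta: float = 0.3, half_width: int = 500) -> SimulationConfig:
    """Gene-free genome with insertion breakpoints; flagged breakpoints get
    a localized CHH elevation (set chh_delta=0 for the homogeneous null)."""
    flat = {"CG": 0.3, "CHG": 0.15, "CHH": 0.1}
    baselines = {ctx: {cls: flat[ctx] for cls in FEATURE_CLASSES} for ctx in flat}
    return SimulationConfig(
        seed=seed, n_chroms=1, chrom_lengths={"Chr1": genome_size},
        te_count=0,
        duplication=DuplicationPlan(0, 0, 0, 0, 0, 0, 0),
        methylation=MethylationPlan(baselines=baselines),
        svs=SVPlan(counts={"INS": n_ins}, chh_delta=chh_delta,
                   chh_half_width=half_width,
                   chh_effect_fraction=1.0 if chh_delta else 0.0),
    )


def duplication_plan_config(seed: int) -> SimulationConfig:
    """The reference duplication plan: 100 singleton genes, 50 tandem, 50
    proximal and 50 dispersed pairs, and 150 WGT genes of which 30 sit in
    3-copy groups (one 10-gene segment copied to three loci)."""
    return SimulationConfig(seed=seed, n_chroms=9,
                            duplication=DuplicationPlan())


def m6a_metagene_config(seed: int, n_genes: int = 700,
                        utr3_fraction: float = 0.67) -> SimulationConfig:
    """Singleton-only annotation with every transcript modified; ~2,000
    true sites with the configured 3'-UTR placement bias."""
    return SimulationConfig(
        seed=seed, n_chroms=3, te_count=0,
        duplication=DuplicationPlan(n_singleton=n_genes, n_tandem_pairs=0,
                                    n_proximal_pairs=0, n_dispersed_pairs=0,
                                    n_two_copy_segments=0, n_three_copy_segments=0),
        m6a=M6APlan(modification_probability={"singleton": 1.0},
                    sites_per_transcript_mean=3.0,
                    utr3_fraction=utr3_fraction, utr5_fraction=0.08,
                    detection_probability=1.0, false_positive_rate=0.0),
    )
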