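"""Synthetic fixtures: a toy genome with planted SE/TE structure.

The generator emulates the statistical structure the pipeline assumes:

* a random softmasked genome with a configurable GC baseline and masked
  fraction;
* planted constituent enhancers in two classes — SE constituents grouped
  into clusters that stitch into one region (intra-cluster gaps well below
  the stitching distance) and TE constituents placed singly, all units
  separated by more than the stitching distance so each planted unit maps
  to exactly one stitched region;
* class-dependent constituent size (log-normal, SE median larger) and GC
  composition (SE shifted up), echoing the contrasts seen between SE and
  TE constituents in real chromatin data;
* per-factor read sets whose constituent read densities are
  class-separated with a controllable SE:TE effect-size ratio (effect 0
  gives a uniform, input-like library), placed by a multinomial split of a
  fixed library size (a conditioned-Poisson model: no fragment-length or
  GC-bias realism);
* TSS annotations placed in the gaps between planted units (except a
  configurable collision fraction placed inside constituents) and
  log-normal RPKM tables in which SE-adjacent genes are shifted up.

Every generator is a pure function of (config, seed); independent RNG
substreams per generator keep the outputs mutually deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from seforge.genomics_io import (
    ExpressionTable,
    FeatureMatrix,
    GenomeSequence,
    GenomicInterval,
    ReadAlignmentSet,
    TssAnnotation,
)

import pandas as pd

_BYTES = np.array([65, 67, 71, 84], dtype=np.uint8)  # A C G T


@dataclass
class SimulationConfig:
    seed: int = 1
    n_se_constituents: int = 60
    n_te_constituents: int = 600
    se_cluster_size: int = 3
    genome_size: int = 12_000_000
    n_chromosomes: int = 2
    # log-normal size models; medians echo real constituent sizes
    # (TE median ~700 bp, SE constituent median ~860 bp)
    te_size_median: float = 700.0
    se_size_median: float = 860.0
    size_sigma: float = 0.25
    gc_baseline: float = 0.42
    gc_shift: float = 0.05
    masked_fraction: float = 0.3
    # factor name -> SE:TE mean-density ratio; 0 = uniform input-like library
    factor_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"med1": 8.0, "input": 0.0}
    )
    n_reads_per_factor: int = 100_000
    read_length: int = 36
    background_fraction: float = 0.5
    n_genes: int = 200
    expression_log_fold_shift: float = 2.0
    expression_sigma: float = 1.0
    tss_collision_fraction: float = 0.0
    min_unit_gap: int = 13_000  # > stitching distance: planted units stay separate

    def __post_init__(self) -> None:
        if self.n_se_constituents < 2 or self.n_te_constituents < 2:
            raise ValueError("need at least 2 constituents per class")
        if self.n_se_constituents % self.se_cluster_size:
            raise ValueError("n_se_constituents must be a multiple of se_cluster_size")
        for name, effect in self.factor_effect_sizes.items():
            if effect < 0:
                raise ValueError(f"effect size for {name} must be >= 0")
        for frac in (self.gc_baseline, self.masked_fraction, self.background_fraction,
                     self.tss_collision_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class _Layout:
    """Deterministic placement plan shared by genome/constituent generators."""

    chrom_lengths: dict[str, int]
    constituents: list[GenomicInterval]  # named se_<cluster>_<i> / te_<i>
    labels: np.ndarray  # 1 = SE constituent
    se_regions: list[GenomicInterval]  # planted stitched-truth spans


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _sample_size(rng: np.random.Generator, median: float, sigma: float) -> int:
    return max(50, int(round(rng.lognormal(np.log(median), sigma))))


def _layout(cfg: SimulationConfig) -> _Layout:
    rng = _rng(cfg, 0)
    n_clusters = cfg.n_se_constituents // cfg.se_cluster_size
    chrom_len = cfg.genome_size // cfg.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    # shuffled unit order: SE clusters interleaved among TE constituents
    units = [("se", i) for i in range(n_clusters)] + [
        ("te", i) for i in range(cfg.n_te_constituents)
    ]
    rng.shuffle(units)
    constituents: list[GenomicInterval] = []
    labels: list[int] = []
    se_regions: list[GenomicInterval] = []
    per_chrom = int(np.ceil(len(units) / cfg.n_chromosomes))
    for c, chrom in enumerate(chrom_names):
        pos = cfg.min_unit_gap
        for kind, idx in units[c * per_chrom : (c + 1) * per_chrom]:
            if kind == "te":
                size = _sample_size(rng, cfg.te_size_median, cfg.size_sigma)
                iv = GenomicInterval(chrom, pos, pos + size, name=f"te_{idx}")
                constituents.append(iv)
                labels.append(0)
                pos = iv.end
            else:
                members = []
                for j in range(cfg.se_cluster_size):
                    if j > 0:
                        pos += int(rng.integers(500, 3000))
                    size = _sample_size(rng, cfg.se_size_median, cfg.size_sigma)
                    iv = GenomicInterval(chrom, pos, pos + size, name=f"se_{idx}_{j}")
                    members.append(iv)
                    constituents.append(iv)
                    labels.append(1)
                    pos = iv.end
                se_regions.append(
                    GenomicInterval(chrom, members[0].start, members[-1].end,
                                    name=f"se_region_{idx}")
                )
            pos += int(rng.integers(cfg.min_unit_gap, cfg.min_unit_gap + 5000))
            if pos > chrom_len:
                raise ValueError(
                    "genome too small to place all constituents; increase genome_size"
                )
    return _Layout(
        chrom_lengths={name: chrom_len for name in chrom_names},
        constituents=constituents,
        labels=np.asarray(labels),
        se_regions=se_regions,
    )


def _random_sequence(
    rng: np.random.Generator, n: int, gc: float, masked_fraction: float
) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = _BYTES[rng.choice(4, size=n, p=p)]
    mask = rng.random(n) < masked_fraction
    seq[mask] += 32  # lowercase
    return seq


def simulate_genome(cfg: SimulationConfig) -> tuple[GenomeSequence, list[TssAnnotation]]:
    """Random softmasked genome plus TSS annotations.

    TSS are placed in the gaps between planted units (never inside a
    constituent) except for a ``tss_collision_fraction`` placed inside
    randomly chosen constituents.
    """
    layout = _layout(cfg)
    rng = _rng(cfg, 1)
    chroms = {
        name: _random_sequence(rng, length, cfg.gc_baseline, cfg.masked_fraction)
        .tobytes()
        .decode("ascii")
        for name, length in layout.chrom_lengths.items()
    }
    genome = GenomeSequence(chroms)
    tss = _simulate_tss(cfg, layout, _rng(cfg, 2))
    return genome, tss


def _simulate_tss(
    cfg: SimulationConfig, layout: _Layout, rng: np.random.Generator
) -> list[TssAnnotation]:
    if cfg.n_genes == 0:
        return []
    # gaps between consecutive constituents per chromosome (with a margin)
    gaps: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for c in layout.constituents:
        by_chrom.setdefault(c.chrom, []).append(c)
    margin = 200
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda c: c.start)
        prev_end = 0
        for iv in ivs:
            if iv.start - prev_end > 2 * margin:
                gaps.append((chrom, prev_end + margin, iv.start - margin))
            prev_end = iv.end
    tss: list[TssAnnotation] = []
    n_collide = int(round(cfg.n_genes * cfg.tss_collision_fraction))
    for g in range(cfg.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        if g < n_collide:
            c = layout.constituents[rng.integers(len(layout.constituents))]
            pos = int(rng.integers(c.start, c.end))
            chrom = c.chrom
        else:
            chrom, lo, hi = gaps[rng.integers(len(gaps))]
            pos = int(rng.integers(lo, hi))
        tss.append(TssAnnotation(f"gene_{g}", chrom, pos, strand=strand))
    return tss


def simulate_constituents(
    cfg: SimulationConfig, genome: GenomeSequence | None = None
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Planted constituents and their class labels (1 = SE constituent).

    When *genome* is given, SE constituent spans are rewritten in place
    with GC composition ``gc_baseline + gc_shift`` (masking preserved in
    expectation), realizing the class GC contrast.
    """
    layout = _layout(cfg)
    if genome is not None:
        rng = _rng(cfg, 3)
        mutable = {name: bytearray(seq, "ascii") for name, seq in genome.chroms.items()}
        for iv, label in zip(layout.constituents, layout.labels):
            if label == 1:
                new = _random_sequence(
                    rng, iv.length(), cfg.gc_baseline + cfg.gc_shift, cfg.masked_fraction
                )
                mutable[iv.chrom][iv.start : iv.end] = new.tobytes()
        genome.chroms = {name: buf.decode("ascii") for name, buf in mutable.items()}
    return layout.constituents, layout.labels


def planted_se_regions(cfg: SimulationConfig) -> list[GenomicInterval]:
    """Ground-truth stitched SE spans implied by the placement plan."""
    return _layout(cfg).se_regions


def simulate_reads(
    cfg: SimulationConfig,
    constituents: list[GenomicInterval],
    labels: np.ndarray,
    factor: str,
) -> ReadAlignmentSet:
    """A read library for *factor* with class-separated constituent density.

    A ``background_fraction`` of the library is uniform genome-wide; the
    rest is split across constituents with per-constituent weight
    length x (effect_size for SE, 1 for TE), via one multinomial draw so
    the total read count is exactly ``n_reads_per_factor``.  Effect size 0
    makes the whole library uniform (an input/control).  Reads have fixed
    length, Bernoulli(0.5) strand, and 5' ends uniform in the constituent.
    """
    if factor not in cfg.factor_effect_sizes:
        raise ValueError(f"unknown factor {factor!r}")
    effect = cfg.factor_effect_sizes[factor]
    layout = _layout(cfg)
    stream = 10 + sorted(cfg.factor_effect_sizes).index(factor)
    rng = _rng(cfg, stream)
    labels = np.asarray(labels)
    n = cfg.n_reads_per_factor
    if effect == 0:
        probs = np.array([1.0])  # background only
        counts = np.r_[np.zeros(len(constituents), dtype=np.int64),
                       rng.multinomial(n, probs)]
    else:
        weights = np.array(
            [c.length() * (effect if lab == 1 else 1.0)
             for c, lab in zip(constituents, labels)],
            dtype=float,
        )
        probs = np.append(
            weights / weights.sum() * (1 - cfg.background_fraction),
            cfg.background_fraction,
        )
        counts = rng.multinomial(n, probs / probs.sum())
    chrom_names = list(layout.chrom_lengths)
    chrom_lens = np.array([layout.chrom_lengths[c] for c in chrom_names], dtype=float)
    reads: list[GenomicInterval] = []
    L = cfg.read_length
    for c, k in zip(constituents, counts[:-1]):
        if k == 0:
            continue
        hi = max(c.start + 1, c.end - L)
        starts = rng.integers(c.start, hi, size=k)
        strands = rng.random(k) < 0.5
        for s, plus in zip(starts, strands):
            end = min(s + L, layout.chrom_lengths[c.chrom])
            reads.append(GenomicInterval(c.chrom, int(s), int(end), "+" if plus else "-"))
    n_bg = counts[-1]
    if n_bg:
        which = rng.choice(len(chrom_names), size=n_bg, p=chrom_lens / chrom_lens.sum())
        for w in which:
            chrom = chrom_names[w]
            clen = layout.chrom_lengths[chrom]
            s = int(rng.integers(0, clen - L))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(GenomicInterval(chrom, s, s + L, strand))
    return ReadAlignmentSet(reads, total_mapped=n)


def simulate_feature_table(
    cfg: SimulationConfig,
    n_features: int = 45,
    n_informative: int = 6,
    delta_sd: float = 1.5,
) -> FeatureMatrix:
    """Class-conditional Gaussian table for classifier/ranking tests.

    The first ``n_informative`` columns have their SE-class mean shifted by
    ``delta_sd`` standard deviations; the rest are pure noise.  Row counts
    follow the configured constituent counts.
    """
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")
    rng = _rng(cfg, 4)
    n_pos, n_neg = cfg.n_se_constituents, cfg.n_te_constituents
    n = n_pos + n_neg
    X = rng.standard_normal((n, n_features))
    labels = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
    X[:n_pos, :n_informative] += delta_sd
    names = [f"informative_{j}" if j < n_informative else f"noise_{j}"
             for j in range(n_features)]
    ids = [f"se_row_{i}" for i in range(n_pos)] + [f"te_row_{i}" for i in range(n_neg)]
    return FeatureMatrix(pd.DataFrame(X, index=ids, columns=names), labels=labels)


def simulate_expression(
    cfg: SimulationConfig,
    genes: list[str],
    se_genes: set[str],
) -> ExpressionTable:
    """Log-normal RPKM; SE-associated genes shifted up by the configured
    natural-log fold."""
    rng = _rng(cfg, 5)
    rpkm = {}
    for gene in genes:
        mu = cfg.expression_log_fold_shift if gene in se_genes else 0.0
        rpkm[gene] = float(rng.lognormal(mu, cfg.expression_sigma))
    return ExpressionTable(rpkm)


@dataclass
class SimulatedDataset:
    genome: GenomeSequence
    tss: list[TssAnnotation]
    constituents: list[GenomicInterval]
    labels: np.ndarray
    reads: dict[str, ReadAlignmentSet]
    expression: ExpressionTable
    se_regions: list[GenomicInterval]
    se_genes: set[str]


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate the complete bundle: genome, constituents (with class GC),
    per-factor reads, TSS and an expression table with SE-gene upshift."""
    genome, tss = simulate_genome(cfg)
    constituents, labels = simulate_constituents(cfg, genome)
    reads = {
        factor: simulate_reads(cfg, constituents, labels, factor)
        for factor in cfg.factor_effect_sizes
    }
    se_regions = planted_se_regions(cfg)
    se_genes = set()
    for t in tss:
        for region in se_regions:
            if region.chrom == t.chrom and (
                region.start - 50_000 <= t.position < region.end + 50_000
            ):
                se_genes.add(t.gene)
                break
    expression = simulate_expression(cfg, [t.gene for t in tss], se_genes)
    return SimulatedDataset(
        genome=genome,
        tss=tss,
        constituents=constituents,
        labels=labels,
        reads=reads,
        expression=expression,
        se_regions=se_regions,
        se_genes=se_genes,
    )
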