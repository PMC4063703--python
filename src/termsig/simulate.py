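"""Synthetic genomes, tiling signal, and AP-MS matrices with ground truth.

The generator realizes the statistical structure the analysis modules
assume, with known labels:

* an annotation of same-strand gene chains per chromosome (UTRs included),
  into which it plants convergent overlapping gene pairs, genes with
  deliberately short upstream intergenic gaps, and genes fully covered by
  an antisense gene;
* triplicate two-genotype probe signal with log-normal noise, into which it
  injects whole-gene under-/over-expression effects and 3'UTR-restricted
  read-through effects (mutant genotype only);
* a bait x background x prey unique-peptide matrix with a planted
  mutually-dependent module, an unaffected core complex, and control
  contaminants.

Noise is log-normal on the log2 scale (the standard array noise model),
which makes injected folds exact in expectation and exactly recoverable in
the noise-free limit.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, GenomicInterval
from .copurification import PeptideMatrix
from .signal import SignalSet, SignalTrack

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_signal",
    "simulate_peptide_matrix",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome, signal, and AP-MS generators.

    Lengths are in bp, folds are linear-scale multipliers > 1, noise is the
    standard deviation of per-probe log2 intensity.  Defaults describe a
    compact fission-yeast-like genome: three chromosomes, short intergenic
    gaps, ~20 bp probe spacing, triplicate arrays.
    """

    seed: int = 0
    n_chroms: int = 3
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (600, 2000)  # ORF length
    utr5_length_range: tuple[int, int] = (60, 200)
    utr3_length_range: tuple[int, int] = (100, 300)
    gap_range: tuple[int, int] = (150, 700)  # ordinary intergenic gap
    probe_spacing: int = 20
    n_replicates: int = 3
    log2_noise_sd: float = 0.1
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.0
    background_log2: float = 6.0  # mean non-genic probe level
    background_log2_sd: float = 1.5  # per-probe background spread (fixed)
    probe_affinity_log2_sd: float = 0.5  # per-probe affinity (fixed across arrays)
    frac_convergent_overlapping: float = 0.15
    overlap_range: tuple[int, int] = (50, 250)
    n_de_down: int = 20
    n_de_up: int = 10
    de_fold: float = 3.0
    n_readthrough: int = 50
    readthrough_fold: float = 3.0
    short_igr_set_size: int = 47
    short_igr_range: tuple[int, int] = (5, 40)
    antisense_full_cover_frac: float = 0.10
    chrom_length: Optional[int] = None  # None: sized to fit the layout
    wt_label: str = "wt"
    mut_label: str = "mut"

    def __post_init__(self):
        counts = (
            self.n_de_down + self.n_de_up + self.n_readthrough
            + self.short_igr_set_size
        )
        if counts > self.n_genes:
            raise ValueError("flagged gene counts exceed n_genes")
        for fold in (self.de_fold, self.readthrough_fold):
            if not fold > 1:
                raise ValueError("folds must be > 1")
        for rng_ in (
            self.gene_length_range, self.utr5_length_range,
            self.utr3_length_range, self.gap_range, self.overlap_range,
            self.short_igr_range,
        ):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid range {rng_}")
        if self.probe_spacing < 1:
            raise ValueError("probe spacing must be >= 1 bp")


@dataclass
class GroundTruth:
    """Which genes carry which planted structure or effect."""

    de_down: list[str] = field(default_factory=list)
    de_up: list[str] = field(default_factory=list)
    readthrough: list[str] = field(default_factory=list)
    short_igr: list[str] = field(default_factory=list)
    antisense_covered: list[str] = field(default_factory=list)
    convergent: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _make_gene(
    gid: str, chrom: str, strand: str, start: int,
    l5: int, lorf: int, l3: int, biotype: str = "mRNA",
) -> GeneModel:
    """Lay a gene left-to-right from ``start`` respecting its strand."""
    if strand == "+":
        utr5 = GenomicInterval(chrom, start, start + l5, strand)
        orf = GenomicInterval(chrom, utr5.end, utr5.end + lorf, strand)
        utr3 = GenomicInterval(chrom, orf.end, orf.end + l3, strand)
    else:
        utr3 = GenomicInterval(chrom, start, start + l3, strand)
        orf = GenomicInterval(chrom, utr3.end, utr3.end + lorf, strand)
        utr5 = GenomicInterval(chrom, orf.end, orf.end + l5, strand)
    return GeneModel(gene_id=gid, biotype=biotype, strand=strand, orf=orf,
                     utr5=utr5, utr3=utr3)


def simulate_annotation(
    cfg: SimulationConfig,
) -> tuple[GenomeAnnotation, GroundTruth]:
    """Build a synthetic multi-chromosome annotation with planted structure.

    Baseline genes form non-overlapping same-strand chains (alternating
    strand per chromosome); convergent partners (ids ``*_rv``) overlap the
    3' end of flagged genes, antisense cover genes (ids ``*_as``) exactly
    span flagged genes on the opposite strand, and flagged short-gap genes
    sit unusually close downstream of their same-strand neighbour.
    """
    rng = np.random.default_rng([int(cfg.seed), 101])
    n = cfg.n_genes
    gene_ids = [f"g{i:04d}" for i in range(n)]
    # block assignment of baseline genes to chromosomes, alternating strand
    bounds = np.linspace(0, n, cfg.n_chroms + 1).astype(int)
    chrom_of: dict[str, str] = {}
    strand_of: dict[str, str] = {}
    slots: dict[str, list[str]] = {}
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        block = gene_ids[bounds[ci] : bounds[ci + 1]]
        slots[chrom] = block
        for gid in block:
            chrom_of[gid] = chrom
            strand_of[gid] = "+" if ci % 2 == 0 else "-"

    def transcription_upstream(gid: str) -> Optional[str]:
        chrom = chrom_of[gid]
        block = slots[chrom]
        j = block.index(gid)
        if strand_of[gid] == "+":
            return block[j - 1] if j > 0 else None
        return block[j + 1] if j + 1 < len(block) else None

    n_conv = int(round(cfg.frac_convergent_overlapping * n))
    n_as = int(round(cfg.antisense_full_cover_frac * n))
    pool = list(gene_ids)
    conv = (
        sorted(str(g) for g in rng.choice(pool, size=n_conv, replace=False))
        if n_conv else []
    )
    conv_set = set(conv)
    eligible_short = [
        g for g in gene_ids
        if g not in conv_set
        and transcription_upstream(g) is not None
        and transcription_upstream(g) not in conv_set
    ]
    if len(eligible_short) < cfg.short_igr_set_size:
        raise ValueError(
            "not enough eligible genes for the short-gap set; lower "
            "frac_convergent_overlapping or short_igr_set_size"
        )
    short = sorted(
        str(g)
        for g in rng.choice(eligible_short, size=cfg.short_igr_set_size,
                            replace=False)
    )
    taken = conv_set | set(short)
    rest = [g for g in gene_ids if g not in taken]
    if len(rest) < n_as + cfg.n_de_down + cfg.n_de_up + cfg.n_readthrough:
        raise ValueError(
            "not enough genes left for antisense/DE/read-through sets; "
            "increase n_genes"
        )
    picks = [
        str(g)
        for g in rng.choice(
            rest, size=n_as + cfg.n_de_down + cfg.n_de_up + cfg.n_readthrough,
            replace=False,
        )
    ]
    as_cov = sorted(picks[:n_as])
    de_down = sorted(picks[n_as : n_as + cfg.n_de_down])
    de_up = sorted(picks[n_as + cfg.n_de_down : n_as + cfg.n_de_down + cfg.n_de_up])
    readthrough = sorted(picks[n_as + cfg.n_de_down + cfg.n_de_up :])

    short_set, as_set = set(short), set(as_cov)

    def draw(lo_hi: tuple[int, int]) -> int:
        return int(rng.integers(lo_hi[0], lo_hi[1] + 1))

    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        strand = "+" if ci % 2 == 0 else "-"
        block = slots[chrom]
        cursor = draw(cfg.gap_range)
        prev_gid: Optional[str] = None
        for gid in block:
            if prev_gid is None:
                gap = draw(cfg.gap_range)
            elif strand == "+" and gid in short_set:
                gap = draw(cfg.short_igr_range)
            elif strand == "-" and prev_gid in short_set:
                gap = draw(cfg.short_igr_range)
            else:
                gap = draw(cfg.gap_range)
            l5, lorf, l3 = (
                draw(cfg.utr5_length_range),
                draw(cfg.gene_length_range),
                draw(cfg.utr3_length_range),
            )
            start = cursor + gap
            if strand == "-" and gid in conv_set:
                # convergent partner (+) placed first; focal overlaps its 3' end
                rv5, rvorf, rv3 = (
                    draw(cfg.utr5_length_range),
                    draw(cfg.gene_length_range),
                    draw(cfg.utr3_length_range),
                )
                rv = _make_gene(f"{gid}_rv", chrom, "+", start, rv5, rvorf, rv3)
                genes.append(rv)
                overlap = draw(cfg.overlap_range)
                start = rv.span.end - overlap
            gene = _make_gene(gid, chrom, strand, start, l5, lorf, l3)
            genes.append(gene)
            cursor = gene.span.end
            if strand == "+" and gid in conv_set:
                overlap = draw(cfg.overlap_range)
                rv5, rvorf, rv3 = (
                    draw(cfg.utr5_length_range),
                    draw(cfg.gene_length_range),
                    draw(cfg.utr3_length_range),
                )
                rv = _make_gene(
                    f"{gid}_rv", chrom, "-", gene.span.end - overlap,
                    rv5, rvorf, rv3,
                )
                genes.append(rv)
                cursor = rv.span.end
            if gid in as_set:
                span = gene.span
                total = span.length
                a5 = min(60, total // 10)
                a3 = min(120, total // 5)
                other = "-" if strand == "+" else "+"
                genes.append(
                    _make_gene(f"{gid}_as", chrom, other, span.start,
                               a5, total - a5 - a3, a3)
                )
            prev_gid = gid
        length = cursor + draw(cfg.gap_range)
        if cfg.chrom_length is not None:
            if length > cfg.chrom_length:
                max_fit = int(len(block) * cfg.chrom_length / length)
                raise ValueError(
                    f"{chrom}: layout needs {length} bp > chrom_length "
                    f"{cfg.chrom_length}; try n_genes <= "
                    f"{max_fit * cfg.n_chroms}"
                )
            length = cfg.chrom_length
        chrom_lengths[chrom] = length

    truth = GroundTruth(
        de_down=list(de_down),
        de_up=list(de_up),
        readthrough=list(readthrough),
        short_igr=list(short),
        antisense_covered=list(as_cov),
        convergent=list(conv),
    )
    return GenomeAnnotation(genes, chrom_lengths), truth


def simulate_signal(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> SignalSet:
    """Simulate probe intensities for both genotypes over the annotation.

    Per probe: intensity = 2 ** (gene baseline + probe affinity + effect +
    N(0, sd)).  The gene baseline is drawn once per gene; the probe
    affinity (and, for non-genic probes, a broad background level) is
    drawn once per probe and shared by every array, emulating sequence-
    dependent hybridization efficiency -- it cancels from fold changes and
    region ratios but makes the intensity distribution continuous, the
    regime quantile normalization assumes.  The DE effect is
    +-log2(de_fold) over the whole gene span (mutant only); the
    read-through effect is +log2(readthrough_fold) on 3'UTR probes only
    (mutant only).  Replicates differ only in their noise draws.
    """
    rng = np.random.default_rng([int(cfg.seed), 202])
    chroms = sorted(annotation.chrom_lengths)
    grid = {
        chrom: np.arange(
            cfg.probe_spacing // 2, annotation.chrom_lengths[chrom],
            cfg.probe_spacing, dtype=int,
        )
        for chrom in chroms
    }
    # per-gene baseline log2, drawn in gene_id order for determinism
    baselines = {
        g.gene_id: float(rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd))
        for g in annotation
    }
    de_down, de_up = set(truth.de_down), set(truth.de_up)
    rt = set(truth.readthrough)

    base: dict[tuple[str, str], np.ndarray] = {}
    effect_mut: dict[tuple[str, str], np.ndarray] = {}
    for strand in ("+", "-"):
        for chrom in chroms:
            pos = grid[chrom]
            b = cfg.background_log2 + rng.normal(
                0.0, cfg.background_log2_sd, size=pos.size
            )
            e = np.zeros(pos.size)
            for gene in annotation.genes_on(chrom, strand):
                span = gene.span
                lo = np.searchsorted(pos, span.start, side="left")
                hi = np.searchsorted(pos, span.end, side="left")
                b[lo:hi] = baselines[gene.gene_id]
                if gene.gene_id in de_down:
                    e[lo:hi] -= np.log2(cfg.de_fold)
                elif gene.gene_id in de_up:
                    e[lo:hi] += np.log2(cfg.de_fold)
                if gene.gene_id in rt and gene.utr3 is not None:
                    ulo = np.searchsorted(pos, gene.utr3.start, side="left")
                    uhi = np.searchsorted(pos, gene.utr3.end, side="left")
                    e[ulo:uhi] += np.log2(cfg.readthrough_fold)
            if cfg.probe_affinity_log2_sd > 0:
                b = b + rng.normal(0.0, cfg.probe_affinity_log2_sd, size=pos.size)
            base[(chrom, strand)] = b
            effect_mut[(chrom, strand)] = e

    tracks = []
    for genotype in sorted([cfg.wt_label, cfg.mut_label]):
        is_mut = genotype == cfg.mut_label
        for rep in range(1, cfg.n_replicates + 1):
            for strand in ("+", "-"):
                positions, values = {}, {}
                for chrom in chroms:
                    log2 = base[(chrom, strand)].copy()
                    if is_mut:
                        log2 = log2 + effect_mut[(chrom, strand)]
                    if cfg.log2_noise_sd > 0:
                        log2 = log2 + rng.normal(
                            0.0, cfg.log2_noise_sd, size=log2.size
                        )
                    positions[chrom] = grid[chrom].copy()
                    values[chrom] = np.exp2(log2)
                tracks.append(
                    SignalTrack(genotype, rep, strand, positions, values)
                )
    return SignalSet(tracks)


# ---------------------------------------------------------------------------
# AP-MS matrix

CORE_PREYS = ("Cft1", "Cft2", "Pfs2", "Pta1", "Ssu72", "Ysh1")
MODULE_PREYS = ("Dis2", "Ppn1", "Swd2.2")
CONTAMINANT_PREYS = ("Hsp104", "Rpl402", "Ssa2")


def simulate_peptide_matrix(
    cfg: SimulationConfig,
    bait: str = "Yth1",
    min_peptides: int = 2,
) -> tuple[PeptideMatrix, pd.DataFrame]:
    """A bait purification series with a planted mutually-dependent module.

    The bait is purified from the wild type and from one deletion
    background per module member.  Core-complex preys co-purify in every
    background; module preys vanish (0 peptides) whenever any *other*
    module member is deleted; contaminant preys appear in the no-tag
    control (and so must be removed by the specificity filter).  Returns
    the matrix and the exact dependency-edge table the inference must
    produce after filtering.
    """
    rng = np.random.default_rng([int(cfg.seed), 303])
    deletions = [p.lower().replace(".", "") for p in MODULE_PREYS]
    backgrounds = [cfg.wt_label] + deletions
    rows = []
    expected = []
    for bg in backgrounds:
        deleted = None
        for prey, d in zip(MODULE_PREYS, deletions):
            if bg == d:
                deleted = prey
        for prey in CORE_PREYS:
            count = max(min_peptides, int(rng.poisson(18)))
            rows.append((bait, bg, prey, count))
        for prey in MODULE_PREYS:
            if bg == cfg.wt_label:
                count = max(min_peptides, int(rng.poisson(8)))
            elif prey == deleted:
                count = 0
            else:
                count = 0  # module members co-dissociate
            rows.append((bait, bg, prey, count))
        for prey in CONTAMINANT_PREYS:
            rows.append((bait, bg, prey, max(1, int(rng.poisson(3)))))
    for prey in CONTAMINANT_PREYS:
        rows.append(("no_tag", cfg.wt_label, prey, max(1, int(rng.poisson(3)))))

    df = pd.DataFrame(rows, columns=["bait", "background", "prey", "unique_peptides"])
    matrix = PeptideMatrix(df, control_label="no_tag", wildtype_label=cfg.wt_label)

    wt_counts = {
        r.prey: r.unique_peptides
        for r in df[(df.bait == bait) & (df.background == cfg.wt_label)].itertuples()
    }
    for prey in MODULE_PREYS:
        for d, dprey in zip(deletions, MODULE_PREYS):
            if dprey == prey:
                continue
            expected.append(
                {
                    "prey": prey,
                    "bait": bait,
                    "requires": d,
                    "count_wt": int(wt_counts[prey]),
                    "count_del": 0,
                }
            )
    expected_df = (
        pd.DataFrame(expected)
        .sort_values(["prey", "bait", "requires"], kind="stable")
        .reset_index(drop=True)
    )
    return matrix, expected_df
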