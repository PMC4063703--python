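import numpy as np
import pytest

from termsig.annotation import GeneModel, GenomicInterval
from termsig.signal import SignalSet, SignalTrack
from termsig.simulate import SimulationConfig, simulate_annotation, simulate_signal


def make_gene(gid, chrom, strand, start, l5, lorf, l3, biotype="mRNA"):
    """Lay a gene left-to-right from start (0-based), respecting strand."""
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


def single_probe_set(wt_values, mut_values, chrom="chr1", strand="+", pos=100):
    """One probe per track; replicate r takes the r-th value of each list."""
    tracks = []
    for genotype, values in (("wt", wt_values), ("mut", mut_values)):
        for rep, v in enumerate(values, start=1):
            for s in ("+", "-"):
                tracks.append(
                    SignalTrack(genotype, rep, s,
                                {chrom: np.array([pos])},
                                {chrom: np.array([float(v)])})
                )
    return SignalSet(tracks)


def track_set(positions, per_track_values, strand_both=True, chrom="chr1"):
    """Build a SignalSet from {(genotype, rep): values} over shared positions."""
    positions = np.asarray(positions)
    tracks = []
    strands = ("+", "-") if strand_both else ("+",)
    for (genotype, rep), vals in per_track_values.items():
        for s in strands:
            tracks.append(
                SignalTrack(genotype, rep, s, {chrom: positions.copy()},
                            {chrom: np.asarray(vals, dtype=float)})
            )
    return SignalSet(tracks)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated study shared by read-only tests."""
    cfg = SimulationConfig(seed=11, n_genes=120, short_igr_set_size=12,
                           n_readthrough=12, n_de_down=6, n_de_up=6)
    annotation, truth = simulate_annotation(cfg)
    sset = simulate_signal(annotation, truth, cfg)
    return cfg, annotation, truth, sset
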