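"""Transcription-termination read-through statistics.

A gene transcribed past its normal terminator shows elevated signal in its
3'UTR relative to its ORF.  For every gene with an annotated 3'UTR we
compute, per genotype, the ratio of the average 3'UTR probe signal to the
average ORF probe signal (averaged over replicates), then the ratio of the
mutant ratio to the wild-type ratio.  A gene is flagged as having a
termination defect (a *gTERM* gene) when that ratio-of-ratios is at least
``rr_threshold`` (default 1.5, inclusive) and the ORF signal itself shows
no differential-expression call -- i.e. the coding region is unchanged and
only the region past the terminator gains signal.

The module also provides the size-normalized RT-PCR band ratio used to
quantify read-through products on gels:
``(band intensity / band size) / (reference intensity / reference size)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, GeneModel
from .signal import SignalSet, region_signal

__all__ = [
    "ReadthroughConfig",
    "BandMeasurement",
    "utr_orf_ratio",
    "call_readthrough",
    "band_ratio",
    "read_band_tsv",
    "RT_COLUMNS",
]

RT_COLUMNS = [
    "gene_id", "ratio_wt", "ratio_mut", "ratio_of_ratios", "orf_unchanged",
    "is_gterm",
]


@dataclass
class ReadthroughConfig:
    """Thresholds and gates for the read-through call."""

    rr_threshold: float = 1.5
    orf_gate: str = "de_call"  # or "log2fc_cap"
    orf_log2fc_cap: float = 0.5  # used only with orf_gate="log2fc_cap"
    probe_stat: str = "mean"  # region summary inside UTR/ORF

    def __post_init__(self):
        if not self.rr_threshold > 1:
            raise ValueError("rr_threshold must be > 1")
        if self.orf_gate not in ("de_call", "log2fc_cap"):
            raise ValueError(f"unknown orf_gate {self.orf_gate!r}")


@dataclass(frozen=True)
class BandMeasurement:
    """One gel band: intensity in arbitrary units and amplicon size in bp."""

    label: str
    intensity: float
    size_bp: float

    def __post_init__(self):
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if not self.size_bp > 0:
            raise ValueError("size_bp must be > 0")


def utr_orf_ratio(
    sset: SignalSet,
    gene: GeneModel,
    genotype: str,
    probe_stat: str = "mean",
) -> float:
    """Mean over replicates of (average 3'UTR signal / average ORF signal).

    Same-strand probes only.  Returns NaN when the gene has no annotated
    3'UTR or any replicate lacks probes in either region; such genes are
    excluded from the read-through universe.
    """
    if gene.utr3 is None:
        return float("nan")
    ratios = []
    for rep in sset.replicates:
        track = sset.track(genotype, rep, gene.strand)
        u = region_signal(track, gene.utr3, stat=probe_stat)
        o = region_signal(track, gene.orf, stat=probe_stat)
        if np.isnan(u) or np.isnan(o) or o <= 0:
            return float("nan")
        ratios.append(u / o)
    return float(np.mean(ratios))


def call_readthrough(
    sset: SignalSet,
    annotation: GenomeAnnotation,
    de_orf: pd.DataFrame,
    cfg: Optional[ReadthroughConfig] = None,
    wt: str = "wt",
    mut: str = "mut",
) -> pd.DataFrame:
    """Flag genes whose 3'UTR/ORF ratio rises >= rr_threshold in the mutant.

    ``de_orf`` must be a differential-expression table computed on the ORF
    intervals (``call_de(..., region="orf")``); its ``call`` column supplies
    the "no change in the coding region" gate.  Returns one row per gene
    with an annotated 3'UTR and measurable regions, gene_id ascending.  The
    set of rows with ``is_gterm`` True is the gTERM universe used by the
    genomic-context statistics.
    """
    cfg = cfg or ReadthroughConfig()
    de_idx = de_orf.set_index("gene_id")
    rows = []
    for gene in sorted(annotation, key=lambda g: g.gene_id):
        if gene.utr3 is None:
            continue
        r_wt = utr_orf_ratio(sset, gene, wt, probe_stat=cfg.probe_stat)
        r_mut = utr_orf_ratio(sset, gene, mut, probe_stat=cfg.probe_stat)
        if np.isnan(r_wt) or np.isnan(r_mut) or r_wt <= 0:
            continue
        rr = r_mut / r_wt
        if cfg.orf_gate == "de_call":
            try:
                orf_unchanged = de_idx.at[gene.gene_id, "call"] == "unchanged"
            except KeyError:
                continue
        else:
            try:
                fc = float(de_idx.at[gene.gene_id, "fc"])
            except KeyError:
                continue
            if np.isnan(fc):
                continue
            orf_unchanged = abs(np.log2(abs(fc))) <= cfg.orf_log2fc_cap
        rows.append(
            {
                "gene_id": gene.gene_id,
                "ratio_wt": r_wt,
                "ratio_mut": r_mut,
                "ratio_of_ratios": rr,
                "orf_unchanged": bool(orf_unchanged),
                "is_gterm": bool(rr >= cfg.rr_threshold and orf_unchanged),
            }
        )
    return pd.DataFrame(rows, columns=RT_COLUMNS)


def band_ratio(band: BandMeasurement, reference: BandMeasurement) -> float:
    """Size-normalized gel-band ratio to a reference amplicon.

    ``(band.intensity / band.size_bp) / (reference.intensity /
    reference.size_bp)``.  Scale-invariant in intensity units.
    """
    if reference.intensity <= 0:
        raise ValueError("reference band intensity must be > 0")
    return (band.intensity / band.size_bp) / (
        reference.intensity / reference.size_bp
    )


def read_band_tsv(path) -> list[BandMeasurement]:
    """Read band measurements from a 3-column TSV: label, intensity, size_bp."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "intensity", "size_bp"}
    if not required.issubset(df.columns):
        raise ValueError(f"band table needs columns {sorted(required)}")
    return [
        BandMeasurement(str(r.label), float(r.intensity), float(r.size_bp))
        for r in df.itertuples(index=False)
    ]
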