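"""Strand-specific probe signal: tracks, quantile normalization, summaries.

A :class:`SignalTrack` is one array's worth of signal on one strand
(genotype x replicate x strand); a :class:`SignalSet` collects the tracks of
a full experiment on a shared probe grid.  Intensities are linear-scale,
background-corrected values; log2 enters only for noise modelling and
fold-change display.

The summarization scheme is median-of-probes within a gene per replicate,
then the mean of the replicate medians (see :func:`gene_expression`); region
summaries for ratio statistics use the mean of in-region probes by default.
Probes are assigned to a region when their midpoint falls inside it
(half-open), the simplest strand-safe rule.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import GenomicInterval

__all__ = [
    "SignalTrack",
    "SignalSet",
    "INTENSITY_FLOOR",
    "quantile_normalize",
    "region_signal",
    "gene_expression",
    "read_signal_tsv",
    "write_signal_tsv",
]

#: intensities are floored here after normalization, before any ratio
INTENSITY_FLOOR = 1e-6


@dataclass
class SignalTrack:
    """Signal of one array on one strand over sorted, unique probe midpoints."""

    genotype: str
    replicate: int
    strand: str
    positions: dict[str, np.ndarray]  # chrom -> sorted probe midpoints
    values: dict[str, np.ndarray]     # chrom -> intensities, aligned

    def __post_init__(self):
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos)
            vals = np.asarray(self.values[chrom], dtype=float)
            if pos.shape != vals.shape:
                raise ValueError(f"{chrom}: positions/values length mismatch")
            if pos.size and (np.any(np.diff(pos) <= 0)):
                raise ValueError(f"{chrom}: probe positions must be sorted unique")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"{chrom}: non-finite intensities")
            self.positions[chrom] = pos
            self.values[chrom] = vals

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.genotype, self.replicate, self.strand)

    @property
    def n_probes(self) -> int:
        return sum(v.size for v in self.values.values())

    def chroms(self) -> list[str]:
        return sorted(self.positions)

    def vector(self) -> np.ndarray:
        """All intensities concatenated in (chrom, position) order."""
        return np.concatenate(
            [self.values[c] for c in self.chroms()]
        ) if self.positions else np.empty(0)

    def with_vector(self, vec: np.ndarray) -> "SignalTrack":
        """A copy of this track with intensities replaced from a flat vector."""
        out_vals = {}
        i = 0
        for c in self.chroms():
            n = self.values[c].size
            out_vals[c] = np.asarray(vec[i : i + n], dtype=float).copy()
            i += n
        return SignalTrack(
            self.genotype, self.replicate, self.strand,
            {c: p.copy() for c, p in self.positions.items()}, out_vals,
        )


class SignalSet:
    """All tracks of an experiment: both strands x replicates x genotypes."""

    def __init__(self, tracks: Iterable[SignalTrack]):
        self.tracks: list[SignalTrack] = sorted(tracks, key=lambda t: t.key)
        if not self.tracks:
            raise ValueError("empty signal set")
        self._by_key = {t.key: t for t in self.tracks}
        if len(self._by_key) != len(self.tracks):
            raise ValueError("duplicate track (genotype, replicate, strand)")
        # all tracks of one strand must share the probe grid
        grids: dict[str, dict[str, np.ndarray]] = {}
        for t in self.tracks:
            ref = grids.setdefault(t.strand, t.positions)
            if set(ref) != set(t.positions) or any(
                not np.array_equal(ref[c], t.positions[c]) for c in ref
            ):
                raise ValueError(f"tracks on strand {t.strand} have differing grids")
        reps: dict[str, set[int]] = {}
        for t in self.tracks:
            reps.setdefault(t.genotype, set()).add(t.replicate)
        if len({frozenset(v) for v in reps.values()}) > 1:
            raise ValueError("replicate sets differ across genotypes")

    @property
    def genotypes(self) -> list[str]:
        return sorted({t.genotype for t in self.tracks})

    @property
    def replicates(self) -> list[int]:
        return sorted({t.replicate for t in self.tracks})

    @property
    def strands(self) -> list[str]:
        return sorted({t.strand for t in self.tracks})

    def track(self, genotype: str, replicate: int, strand: str) -> SignalTrack:
        try:
            return self._by_key[(genotype, replicate, strand)]
        except KeyError:
            raise KeyError(
                f"no track ({genotype!r}, {replicate}, {strand!r})"
            ) from None


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(sset: SignalSet, floor: float = INTENSITY_FLOOR) -> SignalSet:
    """Quantile-normalize all tracks of a set against each other.

    Every track's value multiset becomes the across-track mean of order
    statistics; within-track ranks are preserved and tied values receive the
    mean of their tied quantile values.  Idempotent; requires >= 2 tracks
    with equal probe counts.
    """
    vectors = [t.vector() for t in sset.tracks]
    if len(vectors) < 2:
        raise ValueError("quantile normalization needs >= 2 tracks")
    n = vectors[0].size
    if any(v.size != n for v in vectors):
        raise ValueError("tracks have unequal probe counts")
    mat = np.stack(vectors, axis=1)  # probes x tracks
    reference = np.sort(mat, axis=0).mean(axis=1)
    out_tracks = []
    for j, track in enumerate(sset.tracks):
        col = mat[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = reference
        # average the reference values within each tied group
        s = pd.Series(mapped)
        mapped = s.groupby(col).transform("mean").to_numpy()
        out_tracks.append(track.with_vector(np.maximum(mapped, floor)))
    return SignalSet(out_tracks)


# ---------------------------------------------------------------------------
# region and gene summaries


def region_signal(
    track: SignalTrack, region: GenomicInterval, stat: str = "mean"
) -> float:
    """Summary of probes whose midpoints fall in ``region`` (half-open).

    Returns NaN (a flagged missing value) when no probe midpoint falls in
    the region; downstream callers exclude such regions rather than raise.
    """
    if region.strand != "." and region.strand != track.strand:
        raise ValueError(
            f"region strand {region.strand!r} does not match track {track.strand!r}"
        )
    pos = track.positions.get(region.chrom)
    if pos is None or pos.size == 0:
        return float("nan")
    lo = np.searchsorted(pos, region.start, side="left")
    hi = np.searchsorted(pos, region.end, side="left")
    if hi <= lo:
        return float("nan")
    vals = track.values[region.chrom][lo:hi]
    if stat == "mean":
        return float(np.mean(vals))
    if stat == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown stat {stat!r}")


def gene_expression(
    sset: SignalSet, gene, genotype: str, probe_stat: str = "median"
) -> float:
    """Mean over replicates of the per-replicate probe summary in the gene span.

    The default probe summary is the median, matching the convention of
    summarizing a gene by the median of its probes in each replicate and
    averaging the replicate medians.  Returns NaN (gene unmeasured) when any
    replicate has no probe in the span.
    """
    span = gene.span
    meds = []
    for rep in sset.replicates:
        track = sset.track(genotype, rep, gene.strand)
        m = region_signal(track, span, stat=probe_stat)
        if np.isnan(m):
            return float("nan")
        meds.append(m)
    return float(np.mean(meds))


# ---------------------------------------------------------------------------
# I/O: long-format TSV (chrom, position, strand, genotype, replicate, value)

_COLUMNS = ["chrom", "position", "strand", "genotype", "replicate", "value"]


def to_long_dataframe(sset: SignalSet) -> pd.DataFrame:
    frames = []
    for t in sset.tracks:
        for chrom in t.chroms():
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "position": t.positions[chrom],
                        "strand": t.strand,
                        "genotype": t.genotype,
                        "replicate": t.replicate,
                        "value": t.values[chrom],
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(
        ["strand", "chrom", "position", "genotype", "replicate"],
        kind="stable",
    ).reset_index(drop=True)


def from_long_dataframe(df: pd.DataFrame) -> SignalSet:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signal table missing columns: {missing}")
    tracks = []
    for (genotype, rep, strand), sub in df.groupby(
        ["genotype", "replicate", "strand"], sort=True
    ):
        positions = {}
        values = {}
        for chrom, chunk in sub.groupby("chrom", sort=True):
            chunk = chunk.sort_values("position", kind="stable")
            positions[chrom] = chunk["position"].to_numpy(dtype=int)
            values[chrom] = chunk["value"].to_numpy(dtype=float)
        tracks.append(SignalTrack(genotype, int(rep), strand, positions, values))
    return SignalSet(tracks)


def write_signal_tsv(sset: SignalSet, path: "str | os.PathLike[str]") -> None:
    # %.17g guarantees a lossless float round trip through the text format
    to_long_dataframe(sset).to_csv(path, sep="\t", index=False,
                                   float_format="%.17g")


def read_signal_tsv(path: "str | os.PathLike[str]") -> SignalSet:
    # round_trip parsing keeps the %.17g written floats bit-identical
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return from_long_dataframe(df)
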