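"""Genome annotation model and strand-aware interval arithmetic.

The unit of every downstream statistic is a :class:`GeneModel`: one coding
interval (ORF) with optional 5'/3' UTRs on a single strand.  This module
loads such models from GFF3, re-emits them, and finds the two gene pairings
the genomic-context statistics are built on:

* the *upstream same-strand neighbour* of a gene (the gene whose 3' end lies
  directly 5' of the focal gene's 5' end on the same strand), and
* the *first downstream reverse-orientation gene* (the nearest opposite-strand
  gene whose span extends past the focal gene's 3' end; convergent,
  possibly overlapping).

Internally all coordinates are 0-based half-open; GFF3 I/O converts at the
boundary (GFF3 is 1-based inclusive).  All reported base-pair distances are
therefore convention-independent integers.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import gffutils

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GenomeAnnotation",
    "GenePairing",
    "AnnotationError",
    "Gff3ParseError",
    "read_gff3",
    "write_gff3",
    "upstream_same_strand_partner",
    "downstream_reverse_partner",
    "antisense_overlap_bp",
]

VALID_STRANDS = ("+", "-", ".")

#: feature types recognised as UTR rows unless the caller overrides them
DEFAULT_UTR_FEATURES = frozenset(
    {"five_prime_UTR", "three_prime_UTR", "5'UTR", "3'UTR", "UTR"}
)


class AnnotationError(ValueError):
    """Invalid annotation content (duplicate ids, out-of-bounds genes ...)."""


class Gff3ParseError(ValueError):
    """Malformed GFF3 input; carries the offending line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"GFF3 line {line_number}: {message}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.start > self.end:
            # normalise to the internal convention rather than erroring
            object.__setattr__(self, "start", self.end)
            object.__setattr__(self, "end", self.start)
        if self.start < 0:
            raise ValueError("negative coordinate")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Bases shared with ``other`` (ignores strand), >= 0."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: ORF plus optional UTRs, all on one strand.

    ``span`` is the union of the ORF and whichever UTRs are present.  Genes
    lacking an annotated 3'UTR are retained (the expression analyses use the
    ORF) but are excluded from read-through and UTR-based distance universes.
    """

    gene_id: str
    biotype: str
    strand: str
    orf: GenomicInterval
    utr5: Optional[GenomicInterval] = None
    utr3: Optional[GenomicInterval] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for name, iv in (("utr5", self.utr5), ("utr3", self.utr3)):
            if iv is not None and iv.chrom != self.orf.chrom:
                raise AnnotationError(
                    f"gene {self.gene_id}: {name} on different chromosome"
                )

    @property
    def chrom(self) -> str:
        return self.orf.chrom

    @property
    def span(self) -> GenomicInterval:
        start = self.orf.start
        end = self.orf.end
        for iv in (self.utr5, self.utr3):
            if iv is not None:
                start = min(start, iv.start)
                end = max(end, iv.end)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def has_utr3(self) -> bool:
        return self.utr3 is not None

    def five_prime_interval(self) -> GenomicInterval:
        """The 5'-most annotated feature (5'UTR when present, else ORF)."""
        return self.utr5 if self.utr5 is not None else self.orf

    def three_prime_interval(self) -> GenomicInterval:
        """The 3'-most annotated feature (3'UTR when present, else ORF)."""
        return self.utr3 if self.utr3 is not None else self.orf


@dataclass(frozen=True)
class GenePairing:
    """A focal gene and a partner with a defined orientation relation.

    ``distance_bp`` is the intergenic distance for the pairing: for
    ``upstream_same_strand`` the UTR-boundary gap between the partner's 3'
    end and the focal gene's 5' end; for ``downstream_reverse`` the span gap
    between the focal gene's 3' end and the convergent partner.  Negative
    values mean the features overlap.
    """

    focal: str
    partner: str
    relation: str  # "upstream_same_strand" | "downstream_reverse"
    distance_bp: int

    def __post_init__(self):
        if self.relation not in ("upstream_same_strand", "downstream_reverse"):
            raise ValueError(f"unknown relation {self.relation!r}")


class GenomeAnnotation:
    """A set of gene models with chromosome lengths, indexable by id."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chrom_lengths: Mapping[str, int],
    ):
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g
        for g in self._genes.values():
            if g.chrom not in self.chrom_lengths:
                raise AnnotationError(
                    f"gene {g.gene_id}: unknown chromosome {g.chrom!r}"
                )
            if g.span.end > self.chrom_lengths[g.chrom]:
                raise AnnotationError(
                    f"gene {g.gene_id}: interval exceeds length of {g.chrom}"
                )
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self._genes.values():
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.span.start, g.span.end, g.gene_id))

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(sorted(self._genes.values(), key=lambda g: g.gene_id))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise KeyError(f"no gene {gene_id!r} in annotation") from None

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self._genes)

    def genes_on(self, chrom: str, strand: Optional[str] = None) -> list[GeneModel]:
        """Genes on a chromosome sorted by span start, optionally one strand."""
        genes = self._by_chrom.get(chrom, [])
        if strand is None:
            return list(genes)
        return [g for g in genes if g.strand == strand]

    def overlapping(self, region: GenomicInterval) -> list[GeneModel]:
        """Genes whose span shares >= 1 bp with ``region`` (strand ignored)."""
        return [
            g
            for g in self._by_chrom.get(region.chrom, [])
            if g.span.overlap_bp(region) > 0
        ]


# ---------------------------------------------------------------------------
# pairings


def _gap_5prime_side(focal: GeneModel, partner: GeneModel) -> int:
    """UTR-boundary gap between partner's 3' end and focal's 5' end."""
    f5 = focal.five_prime_interval()
    p3 = partner.three_prime_interval()
    if focal.strand == "+":
        return f5.start - p3.end
    return p3.start - f5.end


def _gap_3prime_side(focal: GeneModel, partner: GeneModel) -> int:
    """Span gap between focal's 3' end and a convergent partner."""
    if focal.strand == "+":
        return partner.span.start - focal.span.end
    return focal.span.start - partner.span.end


def upstream_same_strand_partner(
    annotation: GenomeAnnotation,
    gene_id: str,
    allow_intervening_antisense: bool = True,
) -> Optional[GenePairing]:
    """Nearest same-strand gene directly upstream of ``gene_id``.

    "Upstream" is orientation-aware: for a minus-strand gene it means larger
    coordinates.  By default genes on the opposite strand lying between the
    pair are ignored; with ``allow_intervening_antisense=False`` the pairing
    is suppressed when any opposite-strand gene span intersects the gap.
    Ties at equal distance resolve to the lexicographically smaller id.
    """
    focal = annotation[gene_id]
    best: Optional[GeneModel] = None
    best_key = None
    for g in annotation.genes_on(focal.chrom, focal.strand):
        if g.gene_id == gene_id:
            continue
        if focal.strand == "+":
            if g.span.end > focal.span.start:
                continue
            dist = focal.span.start - g.span.end
        else:
            if g.span.start < focal.span.end:
                continue
            dist = g.span.start - focal.span.end
        key = (dist, g.gene_id)
        if best_key is None or key < best_key:
            best, best_key = g, key
    if best is None:
        return None
    if not allow_intervening_antisense:
        lo = min(best.span.end, focal.span.end)
        hi = max(best.span.start, focal.span.start)
        if lo < hi:
            gap = GenomicInterval(focal.chrom, lo, hi)
            other = "-" if focal.strand == "+" else "+"
            if any(
                g.span.overlap_bp(gap) > 0
                for g in annotation.genes_on(focal.chrom, other)
            ):
                return None
    return GenePairing(
        focal=gene_id,
        partner=best.gene_id,
        relation="upstream_same_strand",
        distance_bp=_gap_5prime_side(focal, best),
    )


def downstream_reverse_partner(
    annotation: GenomeAnnotation, gene_id: str
) -> Optional[GenePairing]:
    """First gene beyond the focal gene's 3' end on the opposite strand.

    Candidates are opposite-strand genes whose span extends past the focal
    gene's 3' end (so convergent overlapping partners qualify); the nearest
    facing boundary wins, which gives a negative distance when the spans
    overlap.  Ties resolve to the lexicographically smaller id.
    """
    focal = annotation[gene_id]
    other = "-" if focal.strand == "+" else "+"
    best_key = None
    best = None
    for g in annotation.genes_on(focal.chrom, other):
        if focal.strand == "+":
            if g.span.end <= focal.span.end:
                continue
        else:
            if g.span.start >= focal.span.start:
                continue
        dist = _gap_3prime_side(focal, g)
        key = (dist, g.gene_id)
        if best_key is None or key < best_key:
            best, best_key = g, key
    if best is None:
        return None
    return GenePairing(
        focal=gene_id,
        partner=best.gene_id,
        relation="downstream_reverse",
        distance_bp=best_key[0],
    )


def antisense_overlap_bp(annotation: GenomeAnnotation, gene_id: str) -> int:
    """Bases of the gene's span covered by the union of opposite-strand spans."""
    focal = annotation[gene_id]
    other = "-" if focal.strand == "+" else "+"
    span = focal.span
    segments = []
    for g in annotation.genes_on(focal.chrom, other):
        lo = max(span.start, g.span.start)
        hi = min(span.end, g.span.end)
        if lo < hi:
            segments.append((lo, hi))
    if not segments:
        return 0
    segments.sort()
    covered = 0
    cur_lo, cur_hi = segments[0]
    for lo, hi in segments[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return covered


# ---------------------------------------------------------------------------
# GFF3 I/O


def _validate_gff3_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise Gff3ParseError(lineno, f"expected 9 columns, got {len(fields)}")
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise Gff3ParseError(lineno, "non-integer coordinates") from None
        if start < 1 or end < start:
            raise Gff3ParseError(lineno, f"bad coordinate range {start}-{end}")
        if fields[6] not in ("+", "-", ".", "?"):
            raise Gff3ParseError(lineno, f"bad strand {fields[6]!r}")


def _classify_utr(
    iv: GenomicInterval, orf: GenomicInterval, strand: str
) -> str:
    """Classify a UTR interval as 5' or 3' by its side of the ORF."""
    before = iv.end <= orf.start
    if strand == "+":
        return "utr5" if before else "utr3"
    return "utr3" if before else "utr5"


def read_gff3(
    path: "str | os.PathLike[str]",
    utr_feature_names: Optional[Iterable[str]] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> GenomeAnnotation:
    """Load a :class:`GenomeAnnotation` from a GFF3 file.

    Gene rows (feature type ``gene``) define ids (``ID=`` attribute) and
    biotypes (``biotype=`` attribute, default ``mRNA``); ``CDS`` children
    define the ORF; UTR children (any feature type in ``utr_feature_names``)
    are classified as 5' or 3' by which side of the ORF they lie on, given
    the strand.  Chromosome lengths come from ``##sequence-region`` pragmas
    unless supplied explicitly (a mapping or a two-column TSV path).
    """
    utr_types = frozenset(utr_feature_names) if utr_feature_names else DEFAULT_UTR_FEATURES
    with open(path) as fh:
        text = fh.read()
    _validate_gff3_lines(text)
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises ValueError on duplicate ids
        raise AnnotationError(f"GFF3 import failed: {exc}") from exc

    lengths: dict[str, int] = {}
    if chrom_lengths is not None:
        if isinstance(chrom_lengths, (str, os.PathLike)):
            with open(chrom_lengths) as fh:
                for line in fh:
                    if line.strip():
                        chrom, ln = line.split("\t")[:2]
                        lengths[chrom] = int(ln)
        else:
            lengths.update(chrom_lengths)
    else:
        for directive in db.directives:
            parts = directive.split()
            if parts and parts[0] == "sequence-region" and len(parts) >= 4:
                lengths[parts[1]] = int(parts[3])

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.id
        if gid in seen:
            raise AnnotationError(f"duplicate gene_id {gid!r}")
        seen.add(gid)
        biotype = feat.attributes.get("biotype", ["mRNA"])[0]
        strand = feat.strand
        if strand not in ("+", "-"):
            raise AnnotationError(f"gene {gid}: missing strand")
        orf = None
        utrs: list[GenomicInterval] = []
        for child in db.children(feat):
            iv = GenomicInterval(child.seqid, child.start - 1, child.end, strand)
            if child.featuretype == "CDS":
                if orf is None:
                    orf = iv
                else:  # multi-row CDS: take the hull (single-isoform model)
                    orf = GenomicInterval(
                        iv.chrom, min(orf.start, iv.start), max(orf.end, iv.end), strand
                    )
            elif child.featuretype in utr_types:
                utrs.append(iv)
        if orf is None:
            # gene without CDS children: treat the gene row itself as the ORF
            orf = GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
        utr5 = utr3 = None
        for iv in utrs:
            side = _classify_utr(iv, orf, strand)
            if side == "utr5":
                utr5 = iv
            else:
                utr3 = iv
        genes.append(
            GeneModel(gene_id=gid, biotype=biotype, strand=strand, orf=orf,
                      utr5=utr5, utr3=utr3)
        )

    if not lengths:
        # no pragma and none supplied: infer minimal lengths from content
        for g in genes:
            lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.span.end)
    return GenomeAnnotation(genes, lengths)


def write_gff3(annotation: GenomeAnnotation, path: "str | os.PathLike[str]") -> None:
    """Emit the annotation as GFF3 (1-based inclusive), deterministically."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for chrom in sorted(annotation.chrom_lengths):
        buf.write(f"##sequence-region {chrom} 1 {annotation.chrom_lengths[chrom]}\n")
    rows = sorted(
        (g for g in annotation),
        key=lambda g: (g.chrom, g.span.start, g.gene_id),
    )
    for g in rows:
        span = g.span
        attrs = f"ID={g.gene_id};biotype={g.biotype}"
        buf.write(
            "\t".join(
                [g.chrom, "termsig", "gene", str(span.start + 1), str(span.end),
                 ".", g.strand, ".", attrs]
            )
            + "\n"
        )
        parts = [("CDS", g.orf, "0")]
        if g.utr5 is not None:
            parts.append(("five_prime_UTR", g.utr5, "."))
        if g.utr3 is not None:
            parts.append(("three_prime_UTR", g.utr3, "."))
        parts.sort(key=lambda p: p[1].start)
        for ftype, iv, phase in parts:
            buf.write(
                "\t".join(
                    [g.chrom, "termsig", ftype, str(iv.start + 1), str(iv.end),
                     ".", g.strand, phase, f"Parent={g.gene_id}"]
                )
                + "\n"
            )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
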