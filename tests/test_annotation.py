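"""Gene models, GFF3 round trips, and strand-aware neighbour discovery."""

import numpy as np
import pytest

from termsig.annotation import (
    AnnotationError,
    GenomeAnnotation,
    GenomicInterval,
    Gff3ParseError,
    antisense_overlap_bp,
    downstream_reverse_partner,
    read_gff3,
    upstream_same_strand_partner,
    write_gff3,
)
from termsig.simulate import SimulationConfig, simulate_annotation

from conftest import make_gene

GFF_HEADER = "##gff-version 3\n##sequence-region chr1 1 100000\n"


def write(tmp_path, text, name="test.gff3"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGff3Reading:
    def test_gene_with_utr3_maps_fields(self, tmp_path):
        text = GFF_HEADER + "\n".join([
            "chr1\tsrc\tgene\t1001\t2200\t.\t+\t.\tID=geneA;biotype=mRNA",
            "chr1\tsrc\tCDS\t1001\t2000\t.\t+\t0\tParent=geneA",
            "chr1\tsrc\tthree_prime_UTR\t2001\t2200\t.\t+\t.\tParent=geneA",
        ]) + "\n"
        ann = read_gff3(write(tmp_path, text))
        g = ann["geneA"]
        assert g.orf == GenomicInterval("chr1", 1000, 2000, "+")
        assert g.utr3 == GenomicInterval("chr1", 2000, 2200, "+")
        assert g.utr5 is None
        assert g.span == GenomicInterval("chr1", 1000, 2200, "+")

    def test_gene_without_utr_rows_has_no_utr3(self, tmp_path):
        text = GFF_HEADER + "\n".join([
            "chr1\tsrc\tgene\t500\t900\t.\t-\t.\tID=geneB",
            "chr1\tsrc\tCDS\t500\t900\t.\t-\t0\tParent=geneB",
        ]) + "\n"
        g = read_gff3(write(tmp_path, text))["geneB"]
        assert not g.has_utr3 and g.utr5 is None
        assert g.biotype == "mRNA"

    def test_minus_strand_utr_classification(self, tmp_path):
        # on the minus strand the 3'UTR sits at lower coordinates
        text = GFF_HEADER + "\n".join([
            "chr1\tsrc\tgene\t1000\t2500\t.\t-\t.\tID=geneC",
            "chr1\tsrc\tthree_prime_UTR\t1000\t1199\t.\t-\t.\tParent=geneC",
            "chr1\tsrc\tCDS\t1200\t2300\t.\t-\t0\tParent=geneC",
            "chr1\tsrc\tfive_prime_UTR\t2301\t2500\t.\t-\t.\tParent=geneC",
        ]) + "\n"
        g = read_gff3(write(tmp_path, text))["geneC"]
        assert g.utr3.end <= g.orf.start and g.utr5.start >= g.orf.end

    def test_duplicate_gene_id_rejected(self, tmp_path):
        text = GFF_HEADER + "\n".join([
            "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=dup",
            "chr1\tsrc\tgene\t300\t400\t.\t+\t.\tID=dup",
        ]) + "\n"
        with pytest.raises(AnnotationError):
            read_gff3(write(tmp_path, text))

    def test_malformed_line_reports_line_number(self, tmp_path):
        text = GFF_HEADER + "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=x\nnot-a-gff-line\n"
        with pytest.raises(Gff3ParseError) as exc:
            read_gff3(write(tmp_path, text))
        assert exc.value.line_number == 4

    def test_gene_beyond_chromosome_length_rejected(self, tmp_path):
        text = "##gff-version 3\n##sequence-region chr1 1 150\n" + \
            "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=far\n"
        with pytest.raises(AnnotationError):
            read_gff3(write(tmp_path, text))

    def test_roundtrip_preserves_gene_models(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_genes=60, short_igr_set_size=6,
                               n_readthrough=6, n_de_down=3, n_de_up=3)
        ann, _ = simulate_annotation(cfg)
        path = tmp_path / "roundtrip.gff3"
        write_gff3(ann, path)
        back = read_gff3(path)
        assert back.chrom_lengths == ann.chrom_lengths
        assert back.gene_ids == ann.gene_ids
        for gid in ann.gene_ids:
            assert back[gid] == ann[gid]
        # second emission is byte-identical
        path2 = tmp_path / "again.gff3"
        write_gff3(back, path2)
        assert path.read_text() == path2.read_text()


# ---------------------------------------------------------------------------
# pairing oracles: independent exhaustive scans


def oracle_upstream(ann, gid):
    focal = ann[gid]
    best = None
    for g in ann.genes_on(focal.chrom):
        if g.gene_id == gid or g.strand != focal.strand:
            continue
        if focal.strand == "+" and g.span.end <= focal.span.start:
            d = focal.span.start - g.span.end
        elif focal.strand == "-" and g.span.start >= focal.span.end:
            d = g.span.start - focal.span.end
        else:
            continue
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    return None if best is None else best[1]


def oracle_downstream_reverse(ann, gid):
    focal = ann[gid]
    best = None
    for g in ann.genes_on(focal.chrom):
        if g.strand == focal.strand:
            continue
        if focal.strand == "+":
            if g.span.end <= focal.span.end:
                continue
            d = g.span.start - focal.span.end
        else:
            if g.span.start >= focal.span.start:
                continue
            d = focal.span.start - g.span.end
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    return None if best is None else best[1]


def oracle_antisense_bp(ann, gid):
    focal = ann[gid]
    mask = np.zeros(focal.span.length, dtype=bool)
    for g in ann.genes_on(focal.chrom):
        if g.strand == focal.strand:
            continue
        lo = max(g.span.start, focal.span.start) - focal.span.start
        hi = min(g.span.end, focal.span.end) - focal.span.start
        if hi > lo:
            mask[lo:hi] = True
    return int(mask.sum())


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_pairings_agree_with_exhaustive_scan(seed):
    cfg = SimulationConfig(seed=seed, n_genes=40, short_igr_set_size=5,
                           n_readthrough=5, n_de_down=3, n_de_up=3,
                           frac_convergent_overlapping=0.3,
                           antisense_full_cover_frac=0.2)
    ann, _ = simulate_annotation(cfg)
    for gid in ann.gene_ids:
        up = upstream_same_strand_partner(ann, gid)
        assert (up.partner if up else None) == oracle_upstream(ann, gid)
        dn = downstream_reverse_partner(ann, gid)
        assert (dn.partner if dn else None) == oracle_downstream_reverse(ann, gid)
        assert antisense_overlap_bp(ann, gid) == oracle_antisense_bp(ann, gid)


class TestUpstreamPartner:
    def build(self):
        genes = [
            make_gene("a", "chr1", "+", 1500, 50, 400, 50),   # ends at 2000
            make_gene("b", "chr1", "+", 3500, 50, 400, 50),   # ends at 4000
            make_gene("focal", "chr1", "+", 5000, 50, 900, 50),
        ]
        return GenomeAnnotation(genes, {"chr1": 20000})

    def test_nearest_upstream_chosen(self):
        pairing = upstream_same_strand_partner(self.build(), "focal")
        assert pairing.partner == "b"
        assert pairing.relation == "upstream_same_strand"
        assert pairing.distance_bp == 1000

    def test_first_gene_has_no_pairing(self):
        assert upstream_same_strand_partner(self.build(), "a") is None

    def test_minus_strand_upstream_is_rightward(self):
        genes = [
            make_gene("focal", "chr1", "-", 1000, 50, 400, 50),
            make_gene("up", "chr1", "-", 2000, 50, 400, 50),
        ]
        ann = GenomeAnnotation(genes, {"chr1": 10000})
        pairing = upstream_same_strand_partner(ann, "focal")
        assert pairing.partner == "up"
        assert pairing.distance_bp == 500

    def test_intervening_antisense_gene_can_suppress_pairing(self):
        genes = [
            make_gene("up", "chr1", "+", 1000, 50, 400, 50),
            make_gene("mid", "chr1", "-", 1600, 20, 100, 20),
            make_gene("focal", "chr1", "+", 2000, 50, 400, 50),
        ]
        ann = GenomeAnnotation(genes, {"chr1": 10000})
        assert upstream_same_strand_partner(ann, "focal").partner == "up"
        assert upstream_same_strand_partner(
            ann, "focal", allow_intervening_antisense=False
        ) is None


class TestDownstreamReversePartner:
    def test_convergent_overlap_gives_negative_distance(self):
        genes = [
            make_gene("focal", "chr1", "+", 0, 100, 800, 100),    # span 0-1000
            make_gene("rv", "chr1", "-", 899, 100, 701, 100),     # span 899-1800
        ]
        ann = GenomeAnnotation(genes, {"chr1": 10000})
        pairing = downstream_reverse_partner(ann, "focal")
        assert pairing.partner == "rv"
        assert pairing.distance_bp == -101

    def test_absent_when_no_reverse_gene_downstream(self):
        genes = [make_gene("only", "chr1", "+", 100, 50, 400, 50)]
        ann = GenomeAnnotation(genes, {"chr1": 10000})
        assert downstream_reverse_partner(ann, "only") is None

    def test_nearest_of_three_candidates(self):
        genes = [make_gene("focal", "chr1", "+", 0, 50, 400, 50)]
        for i, start in enumerate([900, 2000, 4000]):
            genes.append(make_gene(f"rv{i}", "chr1", "-", start, 50, 400, 50))
        ann = GenomeAnnotation(genes, {"chr1": 10000})
        assert downstream_reverse_partner(ann, "focal").partner == "rv0"


class TestAntisenseOverlap:
    def test_no_opposite_strand_overlap_is_zero(self):
        genes = [
            make_gene("g", "chr1", "+", 1000, 0, 1000, 0),
            make_gene("far", "chr1", "-", 5000, 0, 500, 0),
        ]
        ann = GenomeAnnotation(genes, {"chr1": 10000})
        assert antisense_overlap_bp(ann, "g") == 0

    def test_full_containment_covers_span(self):
        genes = [
            make_gene("g", "chr1", "+", 1000, 0, 1000, 0),
            make_gene("cover", "chr1", "-", 500, 0, 2500, 0),
        ]
        ann = GenomeAnnotation(genes, {"chr1": 10000})
        assert antisense_overlap_bp(ann, "g") == 1000

    def test_union_not_sum_of_overlapping_antisense(self):
        # two antisense genes covering 1501-1700 and 1601-1900 of a
        # 1001-2000 gene (1-based): union is 400 bp
        genes = [
            make_gene("g", "chr1", "+", 1000, 0, 1000, 0),
            make_gene("as1", "chr1", "-", 1500, 0, 200, 0),
            make_gene("as2", "chr1", "-", 1600, 0, 300, 0),
        ]
        ann = GenomeAnnotation(genes, {"chr1": 10000})
        assert antisense_overlap_bp(ann, "g") == 400
        assert antisense_overlap_bp(ann, "g") == oracle_antisense_bp(ann, "g")

    def test_symmetric_under_whole_annotation_strand_flip(self, small_sim):
        _, ann, _, _ = small_sim
        flipped = GenomeAnnotation(
            [
                type(g)(gene_id=g.gene_id, biotype=g.biotype,
                        strand="-" if g.strand == "+" else "+",
                        orf=GenomicInterval(g.orf.chrom, g.orf.start, g.orf.end,
                                            "-" if g.strand == "+" else "+"),
                        utr5=None if g.utr3 is None else GenomicInterval(
                            g.utr3.chrom, g.utr3.start, g.utr3.end,
                            "-" if g.strand == "+" else "+"),
                        utr3=None if g.utr5 is None else GenomicInterval(
                            g.utr5.chrom, g.utr5.start, g.utr5.end,
                            "-" if g.strand == "+" else "+"))
                for g in ann
            ],
            ann.chrom_lengths,
        )
        for gid in ann.gene_ids[:40]:
            assert antisense_overlap_bp(ann, gid) == antisense_overlap_bp(flipped, gid)
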