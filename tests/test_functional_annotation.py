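import numpy as np
import pytest
from Bio.Seq import Seq

from polycap.functional_annotation import (
    annotate_variant,
    classify_region,
    coding_effect,
    density_summary,
    indel_frame_class,
)
from polycap.io_formats import GeneModel, GenomicInterval
from polycap.synthetic_data import simulate_genome_and_genes


def two_exon_gene(strand="+"):
    """Gene on chr1: exons [100,160) and [220,280), all CDS."""
    exons = [GenomicInterval("chr1", 100, 160, strand),
             GenomicInterval("chr1", 220, 280, strand)]
    return GeneModel(
        gene_id="g1",
        interval=GenomicInterval("chr1", 100, 280, strand),
        exons=exons,
        cds=list(exons),
    )


class TestClassifyRegion:
    def test_deep_intron(self):
        res = classify_region("chr1", 191, [two_exon_gene()])  # pos0=190
        assert res.region == "intron"

    def test_splice_site_one_base_into_intron(self):
        # exon ends at 160 (0-based exclusive); intron bases 160,161 are splice
        assert classify_region("chr1", 161, [two_exon_gene()]).region == "splice_site"
        assert classify_region("chr1", 162, [two_exon_gene()]).region == "splice_site"
        assert classify_region("chr1", 163, [two_exon_gene()]).region == "intron"
        # acceptor side: intron bases 218,219 (0-based) before exon at 220
        assert classify_region("chr1", 219, [two_exon_gene()]).region == "splice_site"

    def test_intergenic(self):
        assert classify_region("chr1", 50, [two_exon_gene()]).region == "intergenic"
        assert classify_region("chr2", 150, [two_exon_gene()]).region == "intergenic"

    def test_exon(self):
        res = classify_region("chr1", 130, [two_exon_gene()])
        assert res.region == "exon"
        assert res.gene_id == "g1"

    def test_utr_beats_exon(self):
        gene = two_exon_gene()
        gene.cds = [GenomicInterval("chr1", 120, 160, "+"),
                    GenomicInterval("chr1", 220, 280, "+")]
        gene.utr5 = [GenomicInterval("chr1", 100, 120, "+")]
        res = classify_region("chr1", 110, [gene])
        assert res.region == "utr5"

    def test_overlapping_genes_primary_by_longest_cds(self):
        short = two_exon_gene()
        long_gene = GeneModel(
            gene_id="g2",
            interval=GenomicInterval("chr1", 90, 400, "+"),
            exons=[GenomicInterval("chr1", 90, 400, "+")],
            cds=[GenomicInterval("chr1", 90, 399, "+")],
        )
        res = classify_region("chr1", 130, [short, long_gene])
        assert res.gene_id == "g2"
        assert set(res.all_genes) == {"g1", "g2"}


def oracle_effect(model, genome, pos, ref, alt):
    """Translate-both-sequences oracle for coding effects."""
    chrom = model.interval.chrom
    mutated = dict(genome)
    seq = mutated[chrom]
    assert seq[pos - 1] == ref
    mutated[chrom] = seq[: pos - 1] + alt + seq[pos:]

    def protein(g):
        cds = "".join(g[chrom][c.start:c.end] for c in model.cds)
        if model.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return str(Seq(cds).translate())

    ref_p, alt_p = protein(genome), protein(mutated)
    # locate the changed codon
    changed = [i for i, (x, y) in enumerate(zip(ref_p, alt_p)) if x != y]
    if not changed:
        return "synonymous"
    i = changed[0]
    if i == 0 and ref_p[0] == "M":
        return "start_lost"
    if alt_p[i] == "*" and ref_p[i] != "*":
        return "stop_gained"
    return "nonsynonymous"


class TestCodingEffect:
    def _genome_for(self, model, cds_seq):
        """Build a genome placing cds_seq into the model's CDS intervals."""
        seq = list("A" * 500)
        genomic = cds_seq if model.strand == "+" else str(Seq(cds_seq).reverse_complement())
        offset = 0
        for c in model.cds:
            seq[c.start:c.end] = genomic[offset:offset + len(c)]
            offset += len(c)
        return {"chr1": "".join(seq)}

    def test_synonymous(self):
        gene = two_exon_gene()
        cds = "ATG" + "TTT" + "GGC" * 38  # 120 nt
        genome = self._genome_for(gene, cds)
        # codon 2 (TTT) occupies genomic 103..106; third base at pos0 105
        assert coding_effect("chr1", 106, "T", "C", gene, genome) == "synonymous"

    def test_stop_gained(self):
        gene = two_exon_gene()
        cds = "ATG" + "TAT" + "GGC" * 38
        genome = self._genome_for(gene, cds)
        assert coding_effect("chr1", 106, "T", "A", gene, genome) == "stop_gained"

    def test_start_lost(self):
        gene = two_exon_gene()
        cds = "ATG" + "GGC" * 39
        genome = self._genome_for(gene, cds)
        assert coding_effect("chr1", 101, "A", "G", gene, genome) == "start_lost"

    def test_minus_strand_effect_on_transcript(self):
        gene = two_exon_gene("-")
        cds = "ATG" + "TTT" + "GGC" * 38
        genome = self._genome_for(gene, cds)
        # transcript codon 2 third base maps to genomic position: CDS is
        # reverse-complemented; transcript offset 5 -> genomic pos0 = 280-1-5
        pos0 = 280 - 1 - 5
        ref = genome["chr1"][pos0]
        # genomic A corresponds to transcript T; change to G = transcript C (syn)
        assert ref == "A"
        assert coding_effect("chr1", pos0 + 1, "A", "G", gene, genome) == "synonymous"

    def test_random_snps_match_translate_oracle(self):
        rng = np.random.default_rng(77)
        genome, models = simulate_genome_and_genes(15, seed=42)
        checked = 0
        while checked < 300:
            model = models[int(rng.integers(len(models)))]
            cds_iv = model.cds[int(rng.integers(len(model.cds)))]
            pos0 = int(rng.integers(cds_iv.start, cds_iv.end))
            ref = genome["chr1"][pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            expected = oracle_effect(model, genome, pos0 + 1, ref, alt)
            got = coding_effect("chr1", pos0 + 1, ref, alt, model, genome)
            assert got == expected, (model.gene_id, pos0, ref, alt)
            checked += 1

    def test_non_triplet_cds_unknown(self):
        gene = two_exon_gene()
        gene.cds = [GenomicInterval("chr1", 100, 160, "+"),
                    GenomicInterval("chr1", 220, 281, "+")]
        gene.exons = list(gene.cds)
        genome = {"chr1": "ATG" * 200}
        assert coding_effect("chr1", 101, "A", "G", gene, genome) == "unknown"


class TestIndelFrameClass:
    def test_in_frame_deletion(self):
        assert indel_frame_class(130, "ATTT", "A", two_exon_gene()) == "in_frame"

    def test_frameshift_insertion(self):
        assert indel_frame_class(130, "A", "ATT", two_exon_gene()) == "frameshift"

    def test_outside_cds_none(self):
        gene = two_exon_gene()
        gene.cds = [GenomicInterval("chr1", 220, 280, "+")]
        gene.utr5 = [GenomicInterval("chr1", 100, 160, "+")]
        assert indel_frame_class(130, "ATTTT", "A", gene) == "none"

    def test_not_an_indel(self):
        with pytest.raises(ValueError):
            indel_frame_class(130, "A", "G", two_exon_gene())


class TestStrandReversalInvariance:
    def test_effects_invariant_under_fixture_reversal(self):
        # reverse-complement the genome and flip every model; effects persist
        genome, models = simulate_genome_and_genes(8, seed=9)
        chrom_seq = genome["chr1"]
        n = len(chrom_seq)
        rc_genome = {"chr1": str(Seq(chrom_seq).reverse_complement())}
        rng = np.random.default_rng(123)
        for _ in range(60):
            model = models[int(rng.integers(len(models)))]
            cds_iv = model.cds[int(rng.integers(len(model.cds)))]
            pos0 = int(rng.integers(cds_iv.start, cds_iv.end))
            ref = chrom_seq[pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            flipped = GeneModel(
                gene_id=model.gene_id,
                interval=GenomicInterval(
                    "chr1", n - model.interval.end, n - model.interval.start,
                    "-" if model.strand == "+" else "+",
                ),
                exons=[GenomicInterval("chr1", n - e.end, n - e.start,
                                       "-" if model.strand == "+" else "+")
                       for e in reversed(model.exons)],
                cds=[GenomicInterval("chr1", n - c.end, n - c.start,
                                     "-" if model.strand == "+" else "+")
                     for c in reversed(model.cds)],
            )
            rc_pos0 = n - 1 - pos0
            rc_ref = str(Seq(ref).complement())
            rc_alt = str(Seq(alt).complement())
            original = coding_effect("chr1", pos0 + 1, ref, alt, model, genome)
            mirrored = coding_effect("chr1", rc_pos0 + 1, rc_ref, rc_alt, flipped, rc_genome)
            assert original == mirrored


class TestAnnotateAndDensity:
    def test_region_classes_partition(self):
        genome, models = simulate_genome_and_genes(10, seed=5)
        rng = np.random.default_rng(6)
        positions = rng.integers(1, len(genome["chr1"]) + 1, size=200)
        results = [classify_region("chr1", int(p), models) for p in positions]
        assert all(
            r.region in ("exon", "intron", "utr5", "utr3", "splice_site", "intergenic")
            for r in results
        )

    def test_density_gene_arithmetic(self):
        gene = GeneModel("g", GenomicInterval("chr1", 0, 150),
                         exons=[GenomicInterval("chr1", 0, 150)])
        variants = [("chr1", p) for p in range(1, 151, 15)]  # 10 SNPs in 150 bp
        _, genes = density_summary(variants, window_size=1000, gene_models=[gene])
        assert genes.bases_per_variant.iloc[0] == pytest.approx(15.0)

    def test_density_empty(self):
        windows, genes = density_summary([], window_size=100)
        assert windows.empty

    def test_window_counts_sum_to_total(self, rng):
        variants = [("chr%d" % rng.integers(1, 4), int(rng.integers(1, 10_000)))
                    for _ in range(500)]
        windows, _ = density_summary(variants, window_size=1000)
        assert windows.n_variants.sum() == 500

    def test_annotate_indel(self):
        gene = two_exon_gene()
        res = annotate_variant("chr1", 130, "ATTT", "A", [gene])
        assert res.frame_class == "in_frame"
        assert res.coding_effect == "none"
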