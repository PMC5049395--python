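"""Annotation tests: location classes, codon effects (with a full-protein
translation oracle), the candidate funnel, and splice-edit consequences."""

import numpy as np
import pytest
from Bio.Seq import Seq

from poolmap import annotate as ann
from poolmap import mapping as mp
from poolmap import simcross as sc
from poolmap.errors import InvalidArgument, UnsupportedEdit
from poolmap.variantio import GeneModel, reverse_complement


def build_genome(seq: str, name="chr1") -> sc.Genome:
    return sc.Genome(((name, seq),))


def prec(records_pos, prop=0.9):
    return [mp.SnpProportionRecord(v, "supp", prop, 100) for v in records_pos]


@pytest.fixture(scope="module")
def plus_gene():
    """Hand-built 2-exon plus-strand gene on a tiny chromosome.

    Layout: 10 bp lead-in, exon1 = CDS 11..40, intron 41..100,
    exon2 = CDS 101..130, 10 bp tail. CDS length 60 (20 codons incl. stop).
    """
    cds = "ATG" + "CCAGTTAAGCTGGATCGATACCCTGAAGCTATCAGGGTTCATCGAAGCCTT"[:51] \
        + "TTCTAA"
    assert len(cds) == 60 and "*" not in str(Seq(cds).translate())[:-1]
    exon1, exon2 = cds[:30], cds[30:]
    intron = "GT" + "A" * 56 + "AG"
    seq = "T" * 10 + exon1 + intron + exon2 + "T" * 10
    genome = build_genome(seq)
    model = GeneModel("toy1", "chr1", "+", exons=[(11, 40), (101, 130)],
                      cds=[(11, 40), (101, 130)])
    return model, genome


class TestClassifyLocation:
    def test_splice_junction_is_two_intronic_bases(self, plus_gene):
        model, genome = plus_gene
        for pos in (41, 42, 99, 100):       # GT..AG positions
            v = sc.Variant("chr1", pos, genome.base("chr1", pos),
                           "A" if genome.base("chr1", pos) != "A" else "C")
            assert ann.classify_location(v, [model])[0][1] == "splice_junction"
        v = sc.Variant("chr1", 43, "A", "G")  # third intronic base
        assert ann.classify_location(v, [model])[0][1] == "intron"

    def test_cds_and_intergenic(self, plus_gene):
        model, genome = plus_gene
        v = sc.Variant("chr1", 20, genome.base("chr1", 20),
                       "A" if genome.base("chr1", 20) != "A" else "C")
        assert ann.classify_location(v, [model])[0] == ("toy1", "cds")
        v = sc.Variant("chr1", 5, "T", "C")
        assert ann.classify_location(v, [model]) == [(None, "intergenic")]

    def test_utr_in_generated_models(self, genic_genome):
        models, genome = genic_genome
        m = models[0]
        # generated genes carry UTR stubs on the terminal exons
        utr_pos = m.exons[0][0] if m.exons[0][0] < m.cds[0][0] \
            else m.exons[-1][1]
        ref = genome.base(m.chrom, utr_pos)
        v = sc.Variant(m.chrom, utr_pos, ref, "A" if ref != "A" else "C")
        classes = dict((g, c) for g, c in ann.classify_location(v, models))
        assert classes[m.gene_id] == "utr_or_noncoding_exon"


class TestCodingEffect:
    def test_proline_to_leucine(self):
        # C->T at codon position 2 of CCA: CCA(Pro) -> CTA(Leu)
        seq = "ATGCCATAA" + "T" * 20
        genome = build_genome(seq)
        model = GeneModel("g", "chr1", "+", exons=[(1, 9)], cds=[(1, 9)])
        effect, aa = ann.coding_effect(
            sc.Variant("chr1", 5, "C", "T"), model, genome)
        assert (effect, aa) == ("nonsynonymous", "P2L")

    def test_synonymous_leucine(self):
        # G->A at codon position 3 of CTG: CTG(Leu) -> CTA(Leu)
        seq = "ATGCTGTAA" + "T" * 20
        genome = build_genome(seq)
        model = GeneModel("g", "chr1", "+", exons=[(1, 9)], cds=[(1, 9)])
        effect, aa = ann.coding_effect(
            sc.Variant("chr1", 6, "G", "A"), model, genome)
        assert (effect, aa) == ("synonymous", "L2L")

    def test_stop_gained(self):
        # C->T turning CGA(Arg) into TGA(stop)
        seq = "ATGCGATAA" + "T" * 20
        genome = build_genome(seq)
        model = GeneModel("g", "chr1", "+", exons=[(1, 9)], cds=[(1, 9)])
        effect, aa = ann.coding_effect(
            sc.Variant("chr1", 4, "C", "T"), model, genome)
        assert effect == "stop_gained"
        assert aa == "R2*"

    def test_variant_outside_cds_is_contract_violation(self, plus_gene):
        model, genome = plus_gene
        with pytest.raises(InvalidArgument):
            ann.coding_effect(sc.Variant("chr1", 50, "A", "G"), model, genome)

    def test_minus_strand_equals_reverse_complement_construction(self):
        """Strand symmetry: a minus-strand gene must give the same effect as
        the equivalent plus-strand gene on the reverse-complemented
        sequence."""
        cds = "ATGCCAGTTCGATAA"
        tail = "ACGTACGTAC"
        plus_seq = tail + cds + tail
        minus_seq = reverse_complement(plus_seq)
        L = len(plus_seq)
        plus = GeneModel("p", "chr1", "+", exons=[(11, 25)], cds=[(11, 25)])
        minus = GeneModel("m", "chr1", "-",
                          exons=[(L - 24, L - 10)], cds=[(L - 24, L - 10)])
        gp = build_genome(plus_seq)
        gm = build_genome(minus_seq)
        for pos in range(11, 26):
            ref = gp.base("chr1", pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                got_plus = ann.coding_effect(
                    sc.Variant("chr1", pos, ref, alt), plus, gp)
                mpos = L - pos + 1
                mref = reverse_complement(ref)
                malt = reverse_complement(alt)
                got_minus = ann.coding_effect(
                    sc.Variant("chr1", mpos, mref, malt), minus, gm)
                assert got_plus == got_minus

    def test_full_cds_scan_against_translation_oracle(self, genic_genome):
        """Place an EMS transition at every G/C CDS position of a generated
        gene; classification must agree with re-translating the entire
        mutated protein."""
        models, genome = genic_genome
        model = models[0]
        ref_protein = model.protein(genome)
        for cs, ce in model.cds:
            for pos in range(cs, ce + 1):
                ref = genome.base(model.chrom, pos)
                if ref not in "GC":
                    continue
                alt = sc.EMS_SPECTRUM[ref]
                variant = sc.Variant(model.chrom, pos, ref, alt)
                effect, aa_change = ann.coding_effect(variant, model, genome)
                # oracle: mutate the chromosome, rebuild, retranslate
                seq = genome.sequence(model.chrom)
                mutated = sc.Genome(
                    tuple((n, (seq[:pos - 1] + alt + seq[pos:])
                           if n == model.chrom else s)
                          for n, s in genome.chromosomes))
                alt_protein = model.protein(mutated)
                diffs = [(i, a, b) for i, (a, b)
                         in enumerate(zip(ref_protein, alt_protein))
                         if a != b]
                if not diffs:
                    assert effect == "synonymous"
                else:
                    (i, a, b), = diffs
                    assert aa_change == f"{a}{i + 1}{b}"
                    assert effect == ("stop_gained" if b == "*"
                                      else "nonsynonymous")


class TestCandidateFunnel:
    def test_enumerated_toy_table(self, plus_gene):
        model, genome = plus_gene
        # 3 nonsynonymous-ish CDS, 1 splice, 2 synonymous, 4 outside genes
        picks = []

        def ems_sites(lo, hi):
            return [p for p in range(lo, hi + 1)
                    if genome.base("chr1", p) in "GC"]

        cds_sites = []
        for pos in ems_sites(11, 40) + ems_sites(101, 130):
            ref = genome.base("chr1", pos)
            v = sc.Variant("chr1", pos, ref, sc.EMS_SPECTRUM[ref])
            eff, _ = ann.coding_effect(v, model, genome)
            cds_sites.append((v, eff))
        nonsyn = [v for v, e in cds_sites
                  if e in ("nonsynonymous", "stop_gained")][:3]
        syn = [v for v, e in cds_sites if e == "synonymous"][:2]
        assert len(nonsyn) == 3 and len(syn) == 2
        splice = [sc.Variant("chr1", 41, "G", "A")]
        intergenic = [sc.Variant("chr1", p, genome.base("chr1", p),
                                 sc.EMS_SPECTRUM.get(genome.base("chr1", p),
                                                     "A"))
                      for p in (2, 3, 135, 136)]
        records = prec(nonsyn + syn + splice + intergenic)
        candidates = ann.candidate_funnel(records, [model], genome)
        assert len(candidates) == 4
        kept = {c.variant.key for c in candidates}
        assert kept == {v.key for v in nonsyn + splice}

    def test_output_subset_and_idempotent(self, plus_gene):
        model, genome = plus_gene
        records = prec([sc.Variant("chr1", 41, "G", "A"),
                        sc.Variant("chr1", 5, "T", "C")])
        first = ann.candidate_funnel(records, [model], genome)
        keys = {c.variant.key for c in first}
        assert keys <= {r.variant.key for r in records}
        again = ann.candidate_funnel(
            [r for r in records if r.variant.key in keys], [model], genome)
        assert [c.variant.key for c in again] == \
            [c.variant.key for c in first]

    def test_sorted_by_proportion_then_position(self, plus_gene):
        model, genome = plus_gene
        records = [mp.SnpProportionRecord(sc.Variant("chr1", 41, "G", "A"),
                                          "supp", 0.9, 100),
                   mp.SnpProportionRecord(sc.Variant("chr1", 100, "G", "A"),
                                          "supp", 0.95, 100)]
        candidates = ann.candidate_funnel(records, [model], genome)
        assert [c.variant.pos for c in candidates] == [100, 41]


class TestSpliceConsequence:
    def test_cryptic_splice_22bp_frameshift_premature_stop(self, genic_genome):
        """Losing the intron plus 22 exonic bases (22 mod 3 = 1) shifts the
        frame and truncates the protein early."""
        models, genome = genic_genome
        model = next(m for m in models if len(m.exons) >= 2)
        out = ann.splice_consequence(
            model, genome, ann.TranscriptEdit("cryptic_splice", 0, 22))
        assert not out.frame_preserved
        assert out.premature_stop
        assert out.protein_length < len(model.protein(genome)) - 1

    def test_in_frame_intron_retention_without_stop(self):
        """A 90-base stop-free intron keeps the frame and just inserts 30
        residues."""
        cds = "ATGCCAGTTCGATAA"
        exon1, exon2 = cds[:6], cds[6:]
        intron = "GT" + "CAC" * 28 + "CAAG"  # 90 bases, stop-free in frame
        assert len(intron) == 90
        seq = "TTTTT" + exon1 + intron + exon2 + "TTTTT"
        genome = build_genome(seq)
        model = GeneModel("g", "chr1", "+",
                          exons=[(6, 11), (102, 110)],
                          cds=[(6, 11), (102, 110)])
        out = ann.splice_consequence(
            model, genome, ann.TranscriptEdit("intron_retention", 0))
        assert out.frame_preserved
        assert not out.premature_stop
        assert out.protein_length == (len(cds) + 90) // 3 - 1

    def test_identity_edit_recovers_reference_protein(self, genic_genome):
        models, genome = genic_genome
        model = next(m for m in models if len(m.exons) >= 2)
        out = ann.splice_consequence(
            model, genome, ann.TranscriptEdit("cryptic_splice", 0, 0))
        assert out.frame_preserved
        assert not out.premature_stop
        assert out.protein_length == len(model.protein(genome)) - 1

    def test_invalid_intron_index(self, genic_genome):
        models, genome = genic_genome
        model = models[0]
        with pytest.raises(InvalidArgument):
            ann.splice_consequence(
                model, genome,
                ann.TranscriptEdit("intron_retention", 99))

    def test_minus_strand_transcript_order(self, genic_genome):
        models, genome = genic_genome
        model = next(m for m in models
                     if m.strand == "-" and len(m.exons) >= 2)
        out = ann.splice_consequence(
            model, genome, ann.TranscriptEdit("cryptic_splice", 0, 0))
        assert out.protein_length == len(model.protein(genome)) - 1


class TestToyGeneModels:
    def test_models_valid_and_translatable(self, genic_genome):
        models, genome = genic_genome
        for m in models:
            m.validate()
            protein = m.protein(genome)
            assert protein.startswith("M")
            assert protein.endswith("*")
            assert "*" not in protein[:-1]
            for s, e in m.introns():
                intron = genome.sequence(m.chrom)[s - 1:e]
                if m.strand == "-":
                    intron = reverse_complement(intron)
                assert intron.startswith("GT") and intron.endswith("AG")

    def test_deterministic_per_seed(self, small_genome):
        a, ga = ann.make_toy_gene_models(small_genome, 3, seed=5)
        b, gb = ann.make_toy_gene_models(small_genome, 3, seed=5)
        assert [(m.gene_id, m.exons, m.cds) for m in a] == \
               [(m.gene_id, m.exons, m.cds) for m in b]
        assert ga.chromosomes == gb.chromosomes

    def test_infeasible_on_tiny_genome(self):
        g = build_genome("ACGT" * 300)
        with pytest.raises(Exception):
            ann.make_toy_gene_models(g, 5, seed=1)
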