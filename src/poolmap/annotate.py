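"""Candidate-gene funnel: variant location classes, codon effects, and
splice-edit consequence prediction.

High-proportion EMS variants are classified against gene models; candidates
are the non-synonymous (or stop-gain) coding variants plus variants at
exon-intron junctions, defined as the two canonical intronic bases at each
intron end (the GT donor / AG acceptor dinucleotides). Splice-site lesions
are followed through the transcript: retaining the mutated intron, or
activating a cryptic splice site that additionally removes downstream exonic
bases, shifts the reading frame unless the net length change is a multiple
of three, typically yielding a premature stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import InfeasibleRequest, InvalidArgument, ModelError, UnsupportedEdit
from .mapping import SnpProportionRecord
from .simcross import Genome, Variant
from .variantio import GeneModel, reverse_complement

LOCATION_PRECEDENCE = ["splice_junction", "cds", "utr_or_noncoding_exon",
                       "intron", "intergenic"]
EFFECT_SEVERITY = {"stop_gained": 0, "nonsynonymous": 1, "synonymous": 2}
SPLICE_WIDTH = 2  # canonical intronic bases at each intron boundary


@dataclass(frozen=True)
class CandidateVariant:
    """A funnel survivor: variant, its gene context and coding effect."""

    variant: Variant
    proportion: float
    gene_id: str | None
    location_class: str
    coding_effect: str = "not_applicable"
    aa_change: str = ""

    def __post_init__(self) -> None:
        if (self.coding_effect != "not_applicable") != \
                (self.location_class == "cds"):
            raise InvalidArgument(
                "coding_effect applies exactly when location_class is cds")


@dataclass(frozen=True)
class TranscriptEdit:
    """A splice outcome to model: which intron, and what happens to it.

    ``intron_index`` counts introns in transcription order (0-based).
    ``extra_exonic_bases_removed`` applies to cryptic_splice only: that many
    bases at the start (transcription order) of the following exon are lost
    together with the intron.
    """

    kind: str  # "intron_retention" | "cryptic_splice"
    intron_index: int
    extra_exonic_bases_removed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("intron_retention", "cryptic_splice"):
            raise InvalidArgument(f"unknown edit kind {self.kind!r}")
        if self.extra_exonic_bases_removed < 0:
            raise InvalidArgument("extra_exonic_bases_removed must be >= 0")
        if self.kind == "intron_retention" \
                and self.extra_exonic_bases_removed:
            raise InvalidArgument(
                "intron_retention does not remove exonic bases")


@dataclass(frozen=True)
class SpliceOutcome:
    frame_preserved: bool
    premature_stop: bool
    protein_length: int


def classify_location(
    variant: Variant,
    gene_models: Sequence[GeneModel],
) -> list[tuple[str | None, str]]:
    """Location class of a variant against every overlapping gene model.

    Returns ``(gene_id, class)`` pairs sorted by precedence
    (splice_junction > cds > utr_or_noncoding_exon > intron); a variant
    overlapping no gene yields ``[(None, "intergenic")]``.
    """
    hits: list[tuple[str | None, str]] = []
    for m in gene_models:
        if variant.chrom != m.chrom:
            continue
        s, e = m.span
        if not s <= variant.pos <= e:
            continue
        hits.append((m.gene_id, _classify_in_gene(variant.pos, m)))
    if not hits:
        return [(None, "intergenic")]
    hits.sort(key=lambda h: LOCATION_PRECEDENCE.index(h[1]))
    return hits


def _classify_in_gene(pos: int, m: GeneModel) -> str:
    for s, e in m.introns():
        if s <= pos <= e:
            near_donor = pos - s < SPLICE_WIDTH
            near_acceptor = e - pos < SPLICE_WIDTH
            return ("splice_junction" if near_donor or near_acceptor
                    else "intron")
    if any(s <= pos <= e for s, e in m.cds):
        return "cds"
    if any(s <= pos <= e for s, e in m.exons):
        return "utr_or_noncoding_exon"
    return "intron"  # unreachable for contiguous exon/intron structures


def coding_effect(
    variant: Variant,
    gene_model: GeneModel,
    genome: Genome,
) -> tuple[str, str]:
    """Amino-acid consequence of a CDS substitution.

    Builds the affected codon from spliced CDS coordinates (strand-aware),
    translates with the standard genetic code, and reports
    (effect, aa_change) with the protein position 1-based, e.g. ``P404L``.
    """
    if genome.base(variant.chrom, variant.pos) != variant.ref:
        raise ModelError(
            f"ref {variant.ref} at {variant.chrom}:{variant.pos} does not "
            "match the genome")
    offset = _cds_offset(variant.pos, gene_model)
    if offset is None:
        raise InvalidArgument(
            f"{variant.chrom}:{variant.pos} is not in the CDS of "
            f"{gene_model.gene_id}")
    cds = gene_model.cds_sequence(genome)
    alt_base = variant.alt
    if gene_model.strand == "-":
        alt_base = reverse_complement(alt_base)
    codon_i, within = divmod(offset, 3)
    ref_codon = cds[codon_i * 3:codon_i * 3 + 3]
    alt_codon = (ref_codon[:within] + alt_base + ref_codon[within + 1:])
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "stop_gained"
    else:
        effect = "nonsynonymous"
    return effect, f"{ref_aa}{codon_i + 1}{alt_aa}"


def _cds_offset(pos: int, m: GeneModel) -> int | None:
    """Offset of a genomic position within the spliced CDS (transcription
    order), or None if the position is not coding."""
    genomic = 0
    hit = None
    for s, e in m.cds:
        if s <= pos <= e:
            hit = genomic + (pos - s)
        genomic += e - s + 1
    if hit is None:
        return None
    return hit if m.strand == "+" else genomic - 1 - hit


def candidate_funnel(
    records: Sequence[SnpProportionRecord],
    gene_models: Sequence[GeneModel],
    genome: Genome,
) -> list[CandidateVariant]:
    """Reduce thresholded variants to gene candidates.

    Keeps exactly: CDS variants with a non-synonymous or stop-gain effect,
    and splice-junction variants. When a variant hits several transcripts
    the most severe consequence is reported. Output is sorted by proportion
    descending, then position.
    """
    out: list[CandidateVariant] = []
    by_id = {m.gene_id: m for m in gene_models}
    for rec in records:
        hits = classify_location(rec.variant, gene_models)
        gene_id, loc = hits[0]
        if loc == "splice_junction":
            out.append(CandidateVariant(rec.variant, rec.proportion,
                                        gene_id, "splice_junction"))
        elif loc == "cds":
            results = []
            for gid, klass in hits:
                if klass != "cds":
                    continue
                eff, aa = coding_effect(rec.variant, by_id[gid], genome)
                results.append((EFFECT_SEVERITY[eff], gid, eff, aa))
            _, gid, eff, aa = min(results)
            if eff in ("nonsynonymous", "stop_gained"):
                out.append(CandidateVariant(rec.variant, rec.proportion,
                                            gid, "cds", eff, aa))
    out.sort(key=lambda c: (-c.proportion, c.variant.chrom, c.variant.pos))
    return out


def splice_consequence(
    gene_model: GeneModel,
    genome: Genome,
    edit: TranscriptEdit,
) -> SpliceOutcome:
    """Consequence of a mis-splicing event on the encoded protein.

    ``intron_retention`` keeps the intron in the mature transcript;
    ``cryptic_splice`` removes the intron plus the stated number of bases
    from the start of the following exon. The frame is preserved iff the
    net inserted/deleted length is a multiple of three. ``premature_stop``
    is True when translation of the edited CDS terminates before reaching
    the reference protein's length; ``protein_length`` counts amino acids
    before the first stop (or the full translated length if none).
    """
    introns = gene_model.introns()
    tx_introns = introns if gene_model.strand == "+" \
        else list(reversed(introns))
    if not 0 <= edit.intron_index < len(tx_introns):
        raise InvalidArgument(
            f"intron_index {edit.intron_index} invalid for "
            f"{gene_model.gene_id} with {len(tx_introns)} introns")
    g_intron = tx_introns[edit.intron_index]

    # the edited intron must sit between coding sequence on both sides
    cds_lo, cds_hi = gene_model.cds[0][0], gene_model.cds[-1][1]
    if not (cds_lo < g_intron[0] and g_intron[1] < cds_hi):
        raise UnsupportedEdit(
            f"intron {edit.intron_index} of {gene_model.gene_id} is not "
            "spanned by the CDS")

    # CDS segments in transcription order, with the intron located between
    # two consecutive segments
    seq = genome.sequence(gene_model.chrom)
    segs = [seq[s - 1:e] for s, e in gene_model.cds]
    intron_seq = seq[g_intron[0] - 1:g_intron[1]]
    if gene_model.strand == "-":
        segs = [reverse_complement(s) for s in reversed(segs)]
        intron_seq = reverse_complement(intron_seq)
    cds_tx = gene_model.cds if gene_model.strand == "+" \
        else list(reversed(gene_model.cds))
    k = None
    for i in range(len(cds_tx) - 1):
        a, b = cds_tx[i], cds_tx[i + 1]
        if gene_model.strand == "+":
            between = a[1] < g_intron[0] and g_intron[1] < b[0]
        else:
            between = b[1] < g_intron[0] and g_intron[1] < a[0]
        if between:
            k = i
            break
    if k is None:
        raise UnsupportedEdit(
            f"intron {edit.intron_index} does not separate two CDS segments "
            f"of {gene_model.gene_id}")

    if edit.kind == "intron_retention":
        delta = len(intron_seq)
        edited = "".join(segs[:k + 1]) + intron_seq + "".join(segs[k + 1:])
    else:  # cryptic_splice
        removed = edit.extra_exonic_bases_removed
        if removed > len(segs[k + 1]):
            raise UnsupportedEdit(
                "cryptic splice would remove more than the following "
                "CDS segment")
        delta = -removed
        edited = ("".join(segs[:k + 1]) + segs[k + 1][removed:]
                  + "".join(segs[k + 2:]))

    ref_protein_len = sum(len(s) for s in segs) // 3 - 1  # minus stop codon
    translated = str(Seq(edited[:len(edited) - len(edited) % 3]).translate())
    stop_at = translated.find("*")
    if stop_at == -1:
        protein_length = len(translated)
        premature = False
    else:
        protein_length = stop_at
        premature = stop_at < ref_protein_len
    return SpliceOutcome(
        frame_preserved=(delta % 3 == 0),
        premature_stop=premature,
        protein_length=protein_length,
    )


# ---------------------------------------------------------------------------
# Toy gene-model generation (fixture generator, first-class code)
# ---------------------------------------------------------------------------

_SENSE_CODONS = [a + b + c
                 for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if str(Seq(a + b + c).translate()) != "*"]


def make_toy_gene_models(
    genome: Genome,
    n_genes: int,
    seed: int = 0,
    n_codons: tuple[int, int] = (40, 120),
    n_exons: tuple[int, int] = (1, 3),
    intron_length: tuple[int, int] = (60, 200),
    utr_length: int = 20,
    margin: int = 500,
) -> tuple[list[GeneModel], Genome]:
    """Plant syntactically valid genes into a genome.

    Each gene gets an ATG start, a run of sense codons (no internal stop),
    a stop codon, GT..AG introns, and short UTR extensions of the terminal
    exons. Because the coding sequence must actually be present in the
    reference, the genome is patched at the chosen loci; the patched genome
    is returned alongside the models. Deterministic per seed.
    """
    if n_genes < 1:
        raise InvalidArgument("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_seqs = {n: bytearray(s, "ascii") for n, s in genome.chromosomes}
    placements: dict[str, list[tuple[int, int]]] = {n: [] for n in genome.names}
    models: list[GeneModel] = []

    for gi in range(n_genes):
        m_codons = int(rng.integers(n_codons[0], n_codons[1] + 1))
        codons = [_SENSE_CODONS[i]
                  for i in rng.integers(len(_SENSE_CODONS), size=m_codons)]
        cds_seq = "ATG" + "".join(codons) + "TAA"
        k_exons = int(rng.integers(n_exons[0], n_exons[1] + 1))
        cuts = sorted(rng.choice(np.arange(1, len(cds_seq)),
                                 size=k_exons - 1, replace=False)) \
            if k_exons > 1 else []
        pieces = [cds_seq[a:b]
                  for a, b in zip([0] + list(cuts), list(cuts) + [len(cds_seq)])]
        introns = ["GT" + _random_bases(rng, int(
            rng.integers(intron_length[0] - 4, intron_length[1] - 3))) + "AG"
            for _ in range(k_exons - 1)]
        utr5 = _random_bases(rng, utr_length)
        utr3 = _random_bases(rng, utr_length)

        # local (0-based, transcription-orientation) layout
        local_exons, local_cds = [], []
        cursor = 0
        gene_seq_parts = []
        for i, piece in enumerate(pieces):
            ex_start = cursor
            if i == 0:
                gene_seq_parts.append(utr5)
                cursor += len(utr5)
            cds_start = cursor
            gene_seq_parts.append(piece)
            cursor += len(piece)
            local_cds.append((cds_start, cursor - 1))
            if i == len(pieces) - 1:
                gene_seq_parts.append(utr3)
                cursor += len(utr3)
            local_exons.append((ex_start, cursor - 1))
            if i < len(pieces) - 1:
                gene_seq_parts.append(introns[i])
                cursor += len(introns[i])
        gene_seq = "".join(gene_seq_parts)
        strand = "+" if rng.integers(2) == 0 else "-"
        if strand == "-":
            L = len(gene_seq)
            gene_seq = reverse_complement(gene_seq)
            local_exons = sorted((L - 1 - e, L - 1 - s)
                                 for s, e in local_exons)
            local_cds = sorted((L - 1 - e, L - 1 - s) for s, e in local_cds)

        placed = _place(rng, genome, placements, len(gene_seq), margin)
        if placed is None:
            raise InfeasibleRequest(
                f"genome too small to place gene {gi + 1} of {n_genes}")
        chrom, start0 = placed
        chrom_seqs[chrom][start0:start0 + len(gene_seq)] = \
            gene_seq.encode("ascii")
        models.append(GeneModel(
            gene_id=f"gene{gi + 1:03d}", chrom=chrom, strand=strand,
            exons=[(start0 + s + 1, start0 + e + 1) for s, e in local_exons],
            cds=[(start0 + s + 1, start0 + e + 1) for s, e in local_cds]))

    patched = Genome(tuple((n, chrom_seqs[n].decode("ascii"))
                           for n in genome.names),
                     map_density=genome.map_density)
    for m in models:
        assert "*" not in m.protein(patched)[:-1]
    return models, patched


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _place(rng, genome, placements, size, margin):
    """Find a non-overlapping slot (chrom, 0-based start) for a gene."""
    for _ in range(200):
        ci = int(rng.integers(len(genome.names)))
        chrom = genome.names[ci]
        L = len(genome.sequence(chrom))
        if L < size + 2 * margin:
            continue
        start = int(rng.integers(margin, L - size - margin))
        if all(start + size + margin <= s or e + margin <= start
               for s, e in placements[chrom]):
            placements[chrom].append((start, start + size))
            return chrom, start
    return None


def candidates_frame(candidates: Sequence[CandidateVariant]):
    import pandas as pd

    return pd.DataFrame(
        [{"chrom": c.variant.chrom, "pos": c.variant.pos,
          "ref": c.variant.ref, "alt": c.variant.alt,
          "proportion": c.proportion, "gene": c.gene_id or "",
          "location_class": c.location_class,
          "coding_effect": c.coding_effect, "aa_change": c.aa_change,
          "origin": c.variant.origin}
         for c in candidates],
        columns=["chrom", "pos", "ref", "alt", "proportion", "gene",
                 "location_class", "coding_effect", "aa_change", "origin"])
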