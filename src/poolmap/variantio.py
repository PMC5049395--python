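"""Readers and writers for the standard formats the pipeline touches.

All parsing is isolated here so that analysis code only ever sees validated
in-memory objects. Coordinates are 1-based closed intervals throughout,
matching VCF and GFF3. Pooled allele depths use the VCF ``AD`` FORMAT field
with the fixed convention (ref_depth, alt_depth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .errors import FormatError, InvalidArgument, ModelError
from .simcross import Genome, Variant

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Variant tables (VCF / TSV)
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One SNV with per-pool (ref_depth, alt_depth) allele counts."""

    variant: Variant
    depths: dict[str, tuple[int, int]]

    def total_depth(self, pool: str) -> int:
        r, a = self.depths[pool]
        return r + a


@dataclass
class VariantTable:
    """Ordered SNV records with pooled allele depths.

    Records are kept sorted by (contig order, position) and must be unique
    on (chrom, pos, ref, alt). ``contigs`` fixes the chromosome sort order
    and becomes the VCF header contig list.
    """

    pools: list[str]
    records: list[VariantRecord]
    contigs: list[str] = field(default_factory=list)
    contig_lengths: dict[str, int] = field(default_factory=dict)
    n_skipped_non_snv: int = 0

    def __post_init__(self) -> None:
        seen_contigs = list(dict.fromkeys(
            r.variant.chrom for r in self.records))
        if not self.contigs:
            self.contigs = seen_contigs
        missing = [c for c in seen_contigs if c not in self.contigs]
        if missing:
            raise FormatError(
                f"records on contigs absent from the header: {missing}")
        order = {c: i for i, c in enumerate(self.contigs)}
        self.records.sort(key=lambda r: (order[r.variant.chrom], r.variant.pos,
                                         r.variant.ref, r.variant.alt))
        keys = [r.variant.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (chrom, pos, ref, alt) records")

    def __len__(self) -> int:
        return len(self.records)

    def variants(self) -> list[Variant]:
        return [r.variant for r in self.records]

    def subset(self, keep) -> "VariantTable":
        """New table with records satisfying ``keep(record)``."""
        return VariantTable(
            pools=list(self.pools),
            records=[r for r in self.records if keep(r)],
            contigs=list(self.contigs),
            contig_lengths=dict(self.contig_lengths),
        )


def from_simulation(variants, counts_by_pool, genome: Genome) -> VariantTable:
    """Assemble a VariantTable from simcross output.

    ``counts_by_pool`` maps pool label to a :class:`~poolmap.simcross.PooledCounts`
    whose arrays align with ``variants``.
    """
    pools = list(counts_by_pool)
    records = []
    for i, v in enumerate(variants):
        depths = {p: (int(c.ref_depth[i]), int(c.alt_depth[i]))
                  for p, c in counts_by_pool.items()}
        records.append(VariantRecord(v, depths))
    return VariantTable(pools=pools, records=records,
                        contigs=list(genome.names),
                        contig_lengths=genome.lengths)


def write_vcf(table: VariantTable, path) -> None:
    """Write a minimal VCF 4.2 with one sample column per pool.

    FORMAT AD carries (ref_depth, alt_depth); INFO ORIGIN marks the causal
    variant of a simulated experiment so truth survives a round trip.
    """
    lines = ["##fileformat=VCFv4.2", "##source=poolmap"]
    lines.append('##INFO=<ID=ORIGIN,Number=1,Type=String,'
                 'Description="Simulated variant origin (causal/background)">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths in (ref,alt) order">')
    for c in table.contigs:
        L = table.contig_lengths.get(c)
        lines.append(f"##contig=<ID={c},length={L}>" if L
                     else f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"] + list(table.pools)
    lines.append("\t".join(header))
    for rec in table.records:
        v = rec.variant
        info = f"ORIGIN={v.origin}"
        samples = ["{},{}".format(*rec.depths[p]) for p in table.pools]
        lines.append("\t".join(
            [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", ".", info, "AD"]
            + samples))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> VariantTable:
    """Read SNVs with per-sample AD depths from a VCF.

    Multi-allelic rows are split into one record per alternative allele.
    Rows (or alleles) that are not single-base substitutions are skipped and
    counted. A sample without AD raises :class:`FormatError` naming the site.
    """
    vf = pysam.VariantFile(str(path))
    pools = list(vf.header.samples)
    contigs = list(vf.header.contigs)
    contig_lengths = {c: vf.header.contigs[c].length
                      for c in contigs
                      if vf.header.contigs[c].length is not None}
    records: list[VariantRecord] = []
    n_skipped = 0
    for rec in vf:
        if rec.ref is None or rec.alts is None:
            n_skipped += 1
            continue
        origin = rec.info.get("ORIGIN", "background")
        for ai, alt in enumerate(rec.alts):
            if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                n_skipped += 1
                continue
            depths = {}
            for s in pools:
                ad = rec.samples[s].get("AD")
                if ad is None or ad[0] is None:
                    raise FormatError(
                        f"missing AD for sample {s} at {rec.chrom}:{rec.pos}")
                depths[s] = (int(ad[0]), int(ad[ai + 1]))
            records.append(VariantRecord(
                Variant(rec.chrom, rec.pos, rec.ref, alt, origin=origin),
                depths))
    vf.close()
    if n_skipped:
        log.info("read_vcf(%s): skipped %d non-SNV rows/alleles",
                 path, n_skipped)
    return VariantTable(pools=pools, records=records, contigs=contigs,
                        contig_lengths=contig_lengths,
                        n_skipped_non_snv=n_skipped)


def write_counts_tsv(table: VariantTable, path) -> None:
    """Plain TSV: chrom, pos, ref, alt, origin, then <pool>.{ref,alt}_depth."""
    rows = []
    for rec in table.records:
        v = rec.variant
        row = {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
               "origin": v.origin}
        for p in table.pools:
            row[f"{p}.ref_depth"], row[f"{p}.alt_depth"] = rec.depths[p]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> VariantTable:
    """Inverse of :func:`write_counts_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pools = [c[:-len(".ref_depth")] for c in df.columns
             if c.endswith(".ref_depth")]
    if not pools:
        raise FormatError(f"no <pool>.ref_depth columns in {path}")
    records = []
    for d in df.to_dict("records"):
        depths = {p: (int(d[f"{p}.ref_depth"]), int(d[f"{p}.alt_depth"]))
                  for p in pools}
        records.append(VariantRecord(
            Variant(d["chrom"], int(d["pos"]), d["ref"], d["alt"],
                    origin=d.get("origin", "background")),
            depths))
    return VariantTable(pools=pools, records=records)


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One transcript's exon/CDS structure, 1-based closed intervals.

    Exons are stored in genomic order regardless of strand; strand decides
    transcription order. Total CDS length must be a whole number of codons.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        self.validate()

    def validate(self) -> None:
        gid = self.gene_id
        if self.strand not in "+-":
            raise ModelError(f"{gid}: strand must be + or -")
        for s, e in self.exons + self.cds:
            if s > e:
                raise ModelError(f"{gid}: interval [{s},{e}] inverted")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ModelError(f"{gid}: exons overlap or touch")
        for c in self.cds:
            if not any(e[0] <= c[0] and c[1] <= e[1] for e in self.exons):
                raise ModelError(
                    f"{gid}: CDS {c} not contained in any exon")
        total = sum(e - s + 1 for s, e in self.cds)
        if total == 0 or total % 3 != 0:
            raise ModelError(
                f"{gid}: CDS length {total} is not a positive multiple of 3")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic order."""
        return [(e1[1] + 1, e2[0] - 1)
                for e1, e2 in zip(self.exons, self.exons[1:])]

    def cds_sequence(self, genome: Genome) -> str:
        """Spliced coding sequence in translation (5'->3') orientation."""
        seq = genome.sequence(self.chrom)
        parts = [seq[s - 1:e] for s, e in self.cds]
        joined = "".join(parts)
        if self.strand == "-":
            joined = reverse_complement(joined)
        return joined

    def protein(self, genome: Genome) -> str:
        from Bio.Seq import Seq

        return str(Seq(self.cds_sequence(genome)).translate())


def reverse_complement(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).reverse_complement())


def read_gff3(path) -> list[GeneModel]:
    """Parse gene models from GFF3: one :class:`GeneModel` per mRNA.

    Requires gene/mRNA/exon/CDS features linked by Parent attributes.
    Structural violations raise :class:`ModelError` naming the transcript.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        exons = [(f.start, f.end)
                 for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons:
            raise ModelError(f"{mrna.id}: mRNA without exons")
        models.append(GeneModel(
            gene_id=mrna.id, chrom=mrna.seqid, strand=mrna.strand,
            exons=exons, cds=cds))
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon/CDS)."""
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda m: (m.chrom, m.span[0])):
        s, e = m.span
        gene_id = f"{m.gene_id}.gene"
        lines.append("\t".join(
            [m.chrom, "poolmap", "gene", str(s), str(e), ".", m.strand, ".",
             f"ID={gene_id}"]))
        lines.append("\t".join(
            [m.chrom, "poolmap", "mRNA", str(s), str(e), ".", m.strand, ".",
             f"ID={m.gene_id};Parent={gene_id}"]))
        for i, (xs, xe) in enumerate(m.exons, 1):
            lines.append("\t".join(
                [m.chrom, "poolmap", "exon", str(xs), str(xe), ".", m.strand,
                 ".", f"ID={m.gene_id}.exon{i};Parent={m.gene_id}"]))
        # phase: bases to skip to reach the next codon start, in
        # transcription order
        cds_tx = m.cds if m.strand == "+" else list(reversed(m.cds))
        done = 0
        phases = []
        for cs, ce in cds_tx:
            phases.append((-done) % 3)
            done += ce - cs + 1
        if m.strand == "-":
            phases = list(reversed(phases))
        for i, ((cs, ce), ph) in enumerate(zip(m.cds, phases), 1):
            lines.append("\t".join(
                [m.chrom, "poolmap", "CDS", str(cs), str(ce), ".", m.strand,
                 str(ph), f"ID={m.gene_id}.cds{i};Parent={m.gene_id}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
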