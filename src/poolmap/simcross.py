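"""Synthetic backcross-F2 mapping experiments.

Simulates the genetic structure a recessive-suppressor mapping-by-sequencing
experiment assumes: a mutagenized line homozygous for EMS-induced background
SNPs plus one recessive causal SNP, backcrossed to its (pre-mutagenesis)
parent; the F1 is heterozygous at every induced variant, and the F2
segregates 1 suppressed : 3 non-suppressed. Pools of phenotyped F2
individuals are "sequenced" as pooled allele counts at each variant.

The recombination model is Poisson crossovers per gamete per chromosome with
uniform crossover positions (so two-locus recombination fractions follow the
Haldane map function r = (1 - exp(-2d))/2 for map distance d in Morgans).
Map length comes from ``Genome.map_density`` in cM/Mb.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleRequest, InvalidArgument

SUPPRESSED = "suppressed"
NON_SUPPRESSED = "non_suppressed"

_BASES = np.frombuffer(b"ACGT", dtype="S1")
# EMS produces G:C -> A:T transitions; on the reference strand these read as
# G->A or C->T.
EMS_SPECTRUM = {"G": "A", "C": "T"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genome:
    """A reference genome: ordered chromosomes plus a genetic-map density.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, sequence)`` pairs; sequences over {A,C,G,T}.
    map_density
        Genetic map density in centimorgans per megabase. The default of
        4.0 cM/Mb is an Arabidopsis-like genome-wide average.
    """

    chromosomes: tuple[tuple[str, str], ...]
    map_density: float = 4.0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvalidArgument("chromosome names must be unique")
        if any(len(s) == 0 for _, s in self.chromosomes):
            raise InvalidArgument("chromosome sequences must be non-empty")
        if not self.map_density > 0:
            raise InvalidArgument("map_density must be > 0")
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes}

    def sequence(self, chrom: str) -> str:
        for n, s in self.chromosomes:
            if n == chrom:
                return s
        raise InvalidArgument(f"unknown chromosome {chrom!r}")

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.sequence(chrom)
        if not 1 <= pos <= len(seq):
            raise InvalidArgument(f"position {pos} outside {chrom}")
        return seq[pos - 1]

    def morgans(self, chrom: str) -> float:
        """Genetic length of a chromosome in Morgans."""
        return len(self.sequence(chrom)) / 1e6 * self.map_density / 100.0


@dataclass(frozen=True, order=True)
class Variant:
    """A single-nucleotide substitution, 1-based, on the reference strand."""

    chrom: str
    pos: int
    ref: str
    alt: str
    origin: str = "background"  # "causal" or "background"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvalidArgument("pos is 1-based and must be >= 1")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise InvalidArgument("only single-base substitutions supported")
        if self.ref == self.alt:
            raise InvalidArgument("ref and alt must differ")
        if self.origin not in ("causal", "background"):
            raise InvalidArgument(f"unknown origin {self.origin!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def is_ems_type(self) -> bool:
        return EMS_SPECTRUM.get(self.ref) == self.alt


@dataclass
class IndividualGenotype:
    """One F2 individual: alt-allele dosage at every experiment variant.

    ``dosages[i]`` is the number of alternative alleles (0, 1 or 2) at the
    i-th variant of the experiment's variant list. The phenotype follows the
    recessive rule: suppressed iff homozygous alt at the causal variant.
    """

    dosages: np.ndarray
    phenotype: str

    def dosage_at(self, index: int) -> int:
        return int(self.dosages[index])


@dataclass
class Pool:
    """A phenotyped pool of F2 individuals destined for pooled sequencing."""

    label: str
    intended_class: str
    members: list[IndividualGenotype]
    n_misclassified: int = 0

    def __post_init__(self) -> None:
        if self.n_misclassified < 0 or self.n_misclassified > len(self.members):
            raise InvalidArgument("n_misclassified must be in [0, pool size]")

    @property
    def size(self) -> int:
        return len(self.members)

    def dosage_sum(self) -> np.ndarray:
        return np.sum([m.dosages for m in self.members], axis=0)


@dataclass(frozen=True)
class PooledCounts:
    """Pooled read counts per variant (aligned with the variant list)."""

    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.ref_depth < 0) or np.any(self.alt_depth < 0):
            raise InvalidArgument("depths must be non-negative")

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth


@dataclass
class TruthSet:
    """Ground truth of a simulated experiment; round-trips through JSON."""

    causal: Variant
    variants: list[Variant]
    phenotypes: list[str]
    dosages: list[list[int]]
    seed: int
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def vd(v: Variant) -> dict:
            return {"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                    "alt": v.alt, "origin": v.origin}

        payload = {
            "causal": vd(self.causal),
            "variants": [vd(v) for v in self.variants],
            "phenotypes": self.phenotypes,
            "dosages": self.dosages,
            "seed": self.seed,
            "parameters": self.parameters,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        return cls(
            causal=Variant(**d["causal"]),
            variants=[Variant(**v) for v in d["variants"]],
            phenotypes=list(d["phenotypes"]),
            dosages=[list(map(int, row)) for row in d["dosages"]],
            seed=int(d["seed"]),
            parameters=dict(d["parameters"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TruthSet":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def __eq__(self, other) -> bool:  # dosage lists may arrive as arrays
        if not isinstance(other, TruthSet):
            return NotImplemented
        return self.to_json() == other.to_json()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def make_genome(
    n_chrom: int,
    lengths: Sequence[int],
    gc_fraction: float = 0.36,
    seed: int = 0,
    map_density: float = 4.0,
) -> Genome:
    """Generate a random genome with the requested base composition.

    Deterministic for a fixed seed. ``gc_fraction`` is the expected G+C
    proportion; G/C and A/T are split evenly within their classes.
    """
    if n_chrom < 1:
        raise InvalidArgument("n_chrom must be >= 1")
    if len(lengths) != n_chrom:
        raise InvalidArgument("need one length per chromosome")
    if any(L <= 0 for L in lengths):
        raise InvalidArgument("chromosome lengths must be positive")
    if not 0 < gc_fraction < 1:
        raise InvalidArgument("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    probs = [at, gc, gc, at]  # A C G T
    chroms = []
    for i, L in enumerate(lengths):
        seq = rng.choice(_BASES, size=L, p=probs).tobytes().decode("ascii")
        chroms.append((f"chr{i + 1}", seq))
    return Genome(tuple(chroms), map_density=map_density)


def apply_ems(
    genome: Genome,
    n_mutations: int,
    seed: int = 0,
    causal_candidates: set[tuple[str, int]] | None = None,
) -> list[Variant]:
    """Place EMS-style mutations (G->A, C->T) at distinct G/C sites.

    Exactly one of the returned variants is marked ``origin="causal"``,
    chosen uniformly among the mutations — or, if ``causal_candidates`` is
    given, uniformly among G/C sites in that set of ``(chrom, pos)`` pairs
    (used by the pipeline to plant the causal lesion inside a gene).
    Returned variants are sorted by chromosome order then position.
    """
    if n_mutations < 1:
        raise InvalidArgument(
            "n_mutations must be >= 1: every experiment carries one causal "
            "variant")
    sites: list[tuple[str, int]] = []
    for name, seq in genome.chromosomes:
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        idx = np.flatnonzero((arr == b"G") | (arr == b"C"))
        sites.extend((name, int(i) + 1) for i in idx)
    if len(sites) < n_mutations:
        raise InfeasibleRequest(
            f"genome has only {len(sites)} G/C sites; {n_mutations} requested")
    rng = np.random.default_rng(seed)

    chosen: list[tuple[str, int]]
    causal_site: tuple[str, int]
    if causal_candidates is not None:
        eligible = [s for s in sites if s in causal_candidates]
        if not eligible:
            raise InfeasibleRequest("no G/C site among causal_candidates")
        causal_site = eligible[rng.integers(len(eligible))]
        rest = [s for s in sites if s != causal_site]
        pick = rng.choice(len(rest), size=n_mutations - 1, replace=False)
        chosen = [causal_site] + [rest[i] for i in pick]
    else:
        pick = rng.choice(len(sites), size=n_mutations, replace=False)
        chosen = [sites[i] for i in pick]
        causal_site = chosen[rng.integers(len(chosen))]

    order = {name: i for i, name in enumerate(genome.names)}
    variants = []
    for chrom, pos in sorted(chosen, key=lambda s: (order[s[0]], s[1])):
        ref = genome.base(chrom, pos)
        variants.append(Variant(
            chrom, pos, ref, EMS_SPECTRUM[ref],
            origin="causal" if (chrom, pos) == causal_site else "background"))
    return variants


def causal_index(variants: Sequence[Variant]) -> int:
    """Index of the unique causal variant; errors if not exactly one."""
    idx = [i for i, v in enumerate(variants) if v.origin == "causal"]
    if len(idx) != 1:
        raise InvalidArgument(
            f"expected exactly one causal variant, found {len(idx)}")
    return idx[0]


def _gamete(
    rng: np.random.Generator,
    positions_by_chrom: list[np.ndarray],
    lengths: list[int],
    morgans: list[float],
    out: np.ndarray,
    offsets: list[int],
) -> None:
    """Fill ``out`` with one gamete's alt-allele indicators (0/1).

    The F1 carries one fully mutant haplotype (alt at every variant) and one
    fully parental haplotype. Crossovers per chromosome are Poisson with mean
    equal to the genetic length in Morgans; positions are uniform.
    """
    for positions, L, M, off in zip(positions_by_chrom, lengths, morgans, offsets):
        start = rng.integers(2)  # which haplotype at the chromosome start
        n_x = rng.poisson(M)
        if n_x == 0:
            hap = np.full(positions.shape, start, dtype=np.int8)
        else:
            xpos = np.sort(rng.uniform(0, L, size=n_x))
            crossings = np.searchsorted(xpos, positions)
            hap = ((start + crossings) % 2).astype(np.int8)
        out[off:off + len(positions)] = hap


def simulate_f2(
    variants: Sequence[Variant],
    genome: Genome,
    n_individuals: int,
    seed: int = 0,
) -> list[IndividualGenotype]:
    """Simulate F2 individuals of a backcross segregating the induced SNPs.

    Each individual is the fusion of two independent gametes from an F1 that
    is heterozygous at every variant. Phenotype is assigned by the recessive
    rule at the causal variant (before any pooling misclassification).
    """
    if n_individuals < 1:
        raise InvalidArgument("n_individuals must be >= 1")
    by_chrom: dict[str, list[tuple[int, Variant]]] = {}
    for i, v in enumerate(variants):
        if v.chrom not in genome.names:
            raise InvalidArgument(f"variant on unknown chromosome {v.chrom!r}")
        if genome.base(v.chrom, v.pos) != v.ref:
            raise InvalidArgument(
                f"variant ref {v.ref} at {v.chrom}:{v.pos} does not match "
                f"the genome")
        by_chrom.setdefault(v.chrom, []).append((i, v))
    ci = causal_index(variants)

    chrom_names = [c for c in genome.names if c in by_chrom]
    positions_by_chrom, index_maps, lengths, morgans = [], [], [], []
    for c in chrom_names:
        pairs = sorted(by_chrom[c], key=lambda p: p[1].pos)
        positions_by_chrom.append(
            np.array([v.pos for _, v in pairs], dtype=float))
        index_maps.append(np.array([i for i, _ in pairs]))
        lengths.append(len(genome.sequence(c)))
        morgans.append(genome.morgans(c))
    offsets = list(np.cumsum([0] + [len(p) for p in positions_by_chrom[:-1]])) \
        if positions_by_chrom else []
    flat_index = np.concatenate(index_maps) if index_maps else np.array([], int)
    nvar = len(variants)

    rng = np.random.default_rng(seed)
    population: list[IndividualGenotype] = []
    g1 = np.empty(len(flat_index), dtype=np.int8)
    g2 = np.empty(len(flat_index), dtype=np.int8)
    for _ in range(n_individuals):
        _gamete(rng, positions_by_chrom, lengths, morgans, g1, offsets)
        _gamete(rng, positions_by_chrom, lengths, morgans, g2, offsets)
        dos = np.zeros(nvar, dtype=np.int8)
        dos[flat_index] = g1 + g2
        phenotype = SUPPRESSED if dos[ci] == 2 else NON_SUPPRESSED
        population.append(IndividualGenotype(dos, phenotype))
    return population


def build_pools(
    population: Sequence[IndividualGenotype],
    pool_size: int,
    phenotype_class: str,
    n_misclassified: int = 0,
    seed: int = 0,
    label: str | None = None,
) -> Pool:
    """Draw a phenotyped pool, optionally with misscored members.

    Misclassified members are drawn uniformly from the *opposite* phenotype
    class of the actual F2, so for a suppressed pool they are heterozygous or
    wild type at the causal locus in the ~2:1 Mendelian proportion of the
    non-suppressed class.
    """
    if phenotype_class not in (SUPPRESSED, NON_SUPPRESSED):
        raise InvalidArgument(f"unknown class {phenotype_class!r}")
    if n_misclassified > pool_size:
        raise InfeasibleRequest("n_misclassified exceeds pool size")
    wanted = [m for m in population if m.phenotype == phenotype_class]
    other = [m for m in population if m.phenotype != phenotype_class]
    n_true = pool_size - n_misclassified
    if len(wanted) < n_true:
        raise InfeasibleRequest(
            f"only {len(wanted)} {phenotype_class} individuals; {n_true} needed")
    if len(other) < n_misclassified:
        raise InfeasibleRequest(
            f"only {len(other)} opposite-class individuals; "
            f"{n_misclassified} needed")
    rng = np.random.default_rng(seed)
    members = [wanted[i] for i in rng.choice(len(wanted), n_true, replace=False)]
    if n_misclassified:
        members += [other[i]
                    for i in rng.choice(len(other), n_misclassified,
                                        replace=False)]
    return Pool(label or phenotype_class, phenotype_class, members,
                n_misclassified)


def sequence_pool(
    pool: Pool,
    mean_depth: float = 50.0,
    error_rate: float = 0.005,
    seed: int = 0,
) -> PooledCounts:
    """Pooled short-read allele counts at every variant.

    Total depth per variant is Poisson(``mean_depth``). With true pooled alt
    frequency p, each read reports the alternative base with probability
    p(1-e) + (1-p)e, a symmetric per-read error flip.
    """
    if not mean_depth > 0:
        raise InvalidArgument("mean_depth must be > 0")
    if not 0 <= error_rate < 0.5:
        raise InvalidArgument("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    p = pool.dosage_sum() / (2.0 * pool.size)
    p_read = p * (1 - error_rate) + (1 - p) * error_rate
    depth = rng.poisson(mean_depth, size=p.shape)
    alt = rng.binomial(depth, p_read)
    return PooledCounts(ref_depth=depth - alt, alt_depth=alt)


def simulate_phenotype_table(
    genotype_means: Mapping[str, Sequence[float]],
    n_individuals: int,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-flower organ-retention counts for floral positions 1-15.

    ``genotype_means`` maps genotype label to 15 per-position mean retention
    counts in [0, 8]. Each simulated count is a rounded, clamped Gaussian
    around the position mean. Returns a tidy frame with columns
    (genotype, individual, position, retained).
    """
    if n_individuals < 1:
        raise InvalidArgument("n_individuals must be >= 1")
    for g, means in genotype_means.items():
        if len(means) != 15:
            raise InvalidArgument(f"{g}: need 15 per-position means")
        if any(not 0 <= m <= 8 for m in means):
            raise InvalidArgument(f"{g}: means must lie in [0, 8]")
    rng = np.random.default_rng(seed)
    rows = []
    for g, means in genotype_means.items():
        mu = np.asarray(means, dtype=float)
        noise = rng.normal(0.0, noise_sd, size=(n_individuals, 15)) \
            if noise_sd > 0 else np.zeros((n_individuals, 15))
        counts = np.clip(np.rint(mu + noise), 0, 8).astype(int)
        for ind in range(n_individuals):
            for p in range(15):
                rows.append((g, ind + 1, p + 1, counts[ind, p]))
    return pd.DataFrame(
        rows, columns=["genotype", "individual", "position", "retained"])


def stage_seeds(master_seed: int, n: int) -> list[int]:
    """Derive deterministic per-stage sub-seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def write_fasta(genome: Genome, path) -> None:
    """Write the reference as uncompressed FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_fasta(path) -> Genome:
    """Read a FASTA reference into a Genome (default map density)."""
    from Bio import SeqIO

    chroms = tuple((rec.id, str(rec.seq).upper())
                   for rec in SeqIO.parse(str(path), "fasta"))
    if not chroms:
        raise InvalidArgument(f"no sequences in {path}")
    return Genome(chroms)
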