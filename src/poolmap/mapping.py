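"""SNP Proportion mapping: the core statistic and its filtering funnel.

For each variant in a phenotyped pool, the SNP Proportion is the number of
reads carrying the alternative base divided by the total reads at that
position. In a pool of F2 individuals selected for a recessive phenotype it
approaches 1 at and near the causal variant (reaching exactly 1 with perfect
phenotyping and error-free reads) while staying near 0.5 elsewhere, since an
unselected backcross F2 is on average heterozygous at unlinked induced SNPs.

The funnel: restrict to EMS-consistent substitutions (G->A / C->T on the
reference strand, covering G:C->A:T on either strand), keep variants whose
proportion exceeds a threshold (default strictly > 0.85), and localize the
linked region by a sliding window of consecutive variants with elevated mean
proportion, optionally requiring a margin over an unselected control pool.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgument
from .simcross import Variant
from .variantio import VariantTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpProportionRecord:
    """One variant's SNP Proportion in one pool."""

    variant: Variant
    pool: str
    proportion: float
    total_depth: int

    def __post_init__(self) -> None:
        if self.total_depth < 1:
            raise InvalidArgument("total_depth must be >= 1")
        if not 0.0 <= self.proportion <= 1.0:
            raise InvalidArgument("proportion must lie in [0, 1]")


@dataclass(frozen=True)
class LinkedRegion:
    """A chromosomal interval of elevated SNP Proportion.

    ``start``/``end`` are the min/max positions of the member variants
    (1-based, closed). ``mean_delta`` is the mean excess over the control
    pool across shared variants, when a control was supplied.
    """

    chrom: str
    start: int
    end: int
    n_variants: int
    mean_proportion: float
    mean_delta: float | None = None

    def contains(self, variant: Variant) -> bool:
        return (variant.chrom == self.chrom
                and self.start <= variant.pos <= self.end)


def snp_proportion(ref_depth: int, alt_depth: int,
                   min_depth: int = 1) -> float | None:
    """Alt reads / total reads, or None for under-covered sites.

    A total depth below ``min_depth`` (or zero) is an excluded-record
    signal, not an error; callers count exclusions.
    """
    if ref_depth < 0 or alt_depth < 0:
        raise InvalidArgument("depths must be non-negative")
    total = ref_depth + alt_depth
    if total < max(min_depth, 1):
        return None
    return alt_depth / total


def compute_proportions(
    table: VariantTable,
    pool: str,
    min_depth: int = 1,
) -> tuple[list[SnpProportionRecord], int]:
    """SNP Proportion for every adequately covered variant of one pool.

    Returns the records (table order) and the count of excluded
    under-covered variants.
    """
    if pool not in table.pools:
        raise InvalidArgument(f"unknown pool {pool!r}")
    records: list[SnpProportionRecord] = []
    n_excluded = 0
    for rec in table.records:
        r, a = rec.depths[pool]
        p = snp_proportion(r, a, min_depth=min_depth)
        if p is None:
            n_excluded += 1
            continue
        records.append(SnpProportionRecord(rec.variant, pool, p, r + a))
    if n_excluded:
        log.info("pool %s: excluded %d variants below depth %d",
                 pool, n_excluded, min_depth)
    return records, n_excluded


def ems_filter(table: VariantTable) -> VariantTable:
    """Keep only EMS-consistent substitutions (G->A or C->T).

    Order-preserving and idempotent. Accepting both reference-strand
    readouts of a G:C->A:T event means no strand inference is needed.
    """
    return table.subset(lambda r: r.variant.is_ems_type())


def threshold_filter(
    records: Sequence[SnpProportionRecord],
    tau: float = 0.85,
) -> list[SnpProportionRecord]:
    """Keep records with proportion strictly greater than ``tau``."""
    if not 0.0 <= tau <= 1.0:
        raise InvalidArgument("tau must be in [0, 1]")
    return [r for r in records if r.proportion > tau]


def proportion_profile(
    records: Sequence[SnpProportionRecord],
    chrom: str,
) -> list[tuple[int, float]]:
    """(position, proportion) series for one chromosome, sorted by position.

    An unknown chromosome yields an empty series.
    """
    pts = [(r.variant.pos, r.proportion)
           for r in records if r.variant.chrom == chrom]
    return sorted(pts)


def detect_linked_region(
    suppressed: Sequence[SnpProportionRecord],
    control: Sequence[SnpProportionRecord] | None = None,
    window_n: int = 15,
    t_link: float = 0.75,
    delta_min: float = 0.2,
    min_snps: int = 10,
) -> list[LinkedRegion]:
    """Locate intervals of elevated SNP Proportion by a sliding window.

    Windows of ``window_n`` consecutive variants (per chromosome, position
    order) qualify when their mean proportion exceeds ``t_link``; when a
    control pool is given, the window must additionally exceed the control
    by more than ``delta_min`` on the variants shared between pools (a
    window sharing no variants with the control cannot qualify).
    Overlapping qualifying windows are merged; merged regions with fewer
    than ``min_snps`` variants are dropped. Regions are ranked by mean
    proportion, then variant count, then leftmost position.
    """
    if window_n < 1:
        raise InvalidArgument("window_n must be >= 1")
    ctrl_map = ({r.variant.key: r.proportion for r in control}
                if control is not None else None)
    by_chrom: dict[str, list[SnpProportionRecord]] = {}
    for r in suppressed:
        by_chrom.setdefault(r.variant.chrom, []).append(r)

    regions: list[LinkedRegion] = []
    any_scannable = False
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: r.variant.pos)
        n = len(recs)
        if n < window_n:
            continue
        any_scannable = True
        props = np.array([r.proportion for r in recs])
        qualifying: list[tuple[int, int]] = []  # inclusive index ranges
        for i in range(n - window_n + 1):
            w = slice(i, i + window_n)
            if props[w].mean() <= t_link:
                continue
            if ctrl_map is not None:
                deltas = [r.proportion - ctrl_map[r.variant.key]
                          for r in recs[w] if r.variant.key in ctrl_map]
                if not deltas or float(np.mean(deltas)) <= delta_min:
                    continue
            qualifying.append((i, i + window_n - 1))
        for lo, hi in _merge_ranges(qualifying):
            member = recs[lo:hi + 1]
            if len(member) < min_snps:
                continue
            mean_delta = None
            if ctrl_map is not None:
                shared = [r.proportion - ctrl_map[r.variant.key]
                          for r in member if r.variant.key in ctrl_map]
                mean_delta = float(np.mean(shared)) if shared else None
            regions.append(LinkedRegion(
                chrom=chrom,
                start=member[0].variant.pos,
                end=member[-1].variant.pos,
                n_variants=len(member),
                mean_proportion=float(np.mean([r.proportion for r in member])),
                mean_delta=mean_delta,
            ))
    if not any_scannable and suppressed:
        warnings.warn(
            f"fewer than window_n={window_n} variants on every chromosome; "
            "no windows scanned", stacklevel=2)
    regions.sort(key=lambda g: (-g.mean_proportion, -g.n_variants,
                                g.chrom, g.start))
    return regions


def _merge_ranges(ranges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent inclusive index ranges."""
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(ranges):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def in_any_region(records: Sequence[SnpProportionRecord],
                  regions: Sequence[LinkedRegion]) -> list[SnpProportionRecord]:
    """Records whose variant falls inside any of the given regions."""
    return [r for r in records
            if any(g.contains(r.variant) for g in regions)]


# ---------------------------------------------------------------------------
# Orchestration / reporting
# ---------------------------------------------------------------------------

@dataclass
class MappingReport:
    """Everything one mapping run produces, plus funnel counts."""

    proportions: list[SnpProportionRecord]
    control_proportions: list[SnpProportionRecord] | None
    thresholded: list[SnpProportionRecord]
    regions: list[LinkedRegion]
    in_region: list[SnpProportionRecord]
    counts: dict[str, int]


def proportions_frame(records: Sequence[SnpProportionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": r.variant.chrom, "pos": r.variant.pos,
          "ref": r.variant.ref, "alt": r.variant.alt, "pool": r.pool,
          "proportion": r.proportion, "total_depth": r.total_depth}
         for r in records],
        columns=["chrom", "pos", "ref", "alt", "pool", "proportion",
                 "total_depth"])


def regions_frame(regions: Sequence[LinkedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"rank": i + 1, "chrom": g.chrom, "start": g.start, "end": g.end,
          "n_variants": g.n_variants, "mean_proportion": g.mean_proportion,
          "mean_delta_vs_control": g.mean_delta}
         for i, g in enumerate(regions)],
        columns=["rank", "chrom", "start", "end", "n_variants",
                 "mean_proportion", "mean_delta_vs_control"])


def plot_profile(records: Sequence[SnpProportionRecord], chrom: str,
                 path, regions: Sequence[LinkedRegion] = (),
                 tau: float | None = 0.85) -> None:
    """Scatter of SNP Proportion by position for one chromosome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = proportion_profile(records, chrom)
    fig, ax = plt.subplots(figsize=(8, 3))
    if pts:
        xs, ys = zip(*pts)
        ax.scatter(np.array(xs) / 1e6, ys, s=8, alpha=0.7)
    for g in regions:
        if g.chrom == chrom:
            ax.axvspan(g.start / 1e6, g.end / 1e6, color="orange", alpha=0.2)
    if tau is not None:
        ax.axhline(tau, ls="--", lw=0.8, color="grey")
    ax.set_xlabel(f"{chrom} position (Mb)")
    ax.set_ylabel("SNP Proportion")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_mapping(
    table: VariantTable,
    suppressed_pool: str,
    control_pool: str | None = None,
    tau: float = 0.85,
    window_n: int = 15,
    t_link: float = 0.75,
    delta_min: float = 0.2,
    min_snps: int = 10,
    min_depth: int = 1,
    outdir: str | Path | None = None,
    make_plots: bool = True,
) -> MappingReport:
    """Full mapping stage: EMS filter -> proportions -> regions -> threshold.

    The proportion threshold is applied genome-wide; the report also carries
    the intersection of thresholded variants with the detected regions.
    Writes TSVs and per-chromosome plots when ``outdir`` is given;
    deterministic given identical inputs.
    """
    n_input = len(table)
    ems = ems_filter(table)
    supp, n_excl = compute_proportions(ems, suppressed_pool,
                                       min_depth=min_depth)
    ctrl = None
    if control_pool is not None:
        ctrl, _ = compute_proportions(ems, control_pool, min_depth=min_depth)
    regions = detect_linked_region(supp, ctrl, window_n=window_n,
                                   t_link=t_link, delta_min=delta_min,
                                   min_snps=min_snps)
    thresholded = threshold_filter(supp, tau=tau)
    in_region = in_any_region(thresholded, regions)
    counts = {
        "input_variants": n_input,
        "ems_variants": len(ems),
        "low_depth_excluded": n_excl,
        "scored_variants": len(supp),
        "thresholded_variants": len(thresholded),
        "regions": len(regions),
        "thresholded_in_region": len(in_region),
    }
    log.info("funnel: %s", counts)
    report = MappingReport(supp, ctrl, thresholded, regions, in_region, counts)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = {"float_format": "%.6g"}
        proportions_frame(supp).to_csv(out / "proportions.tsv", sep="\t",
                                       index=False, **fmt)
        if ctrl is not None:
            proportions_frame(ctrl).to_csv(
                out / "proportions_control.tsv", sep="\t", index=False, **fmt)
        proportions_frame(thresholded).to_csv(
            out / "thresholded.tsv", sep="\t", index=False, **fmt)
        regions_frame(regions).to_csv(out / "regions.tsv", sep="\t",
                                      index=False, **fmt)
        if make_plots:
            for chrom in table.contigs:
                plot_profile(supp, chrom,
                             out / f"proportion_{chrom}.png",
                             regions=regions, tau=tau)
    return report
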