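"""Abscission phenotype quantification and statistics.

Flowers are scored by the number of petals and sepals still attached after
mechanical brushing: a pre-abscission flower carries four of each, so the
per-flower score ranges from 0 to 8. Counts are recorded at floral positions
1-15 (position 1 = youngest flower after anthesis); abscission is complete
by position 8, so a genotype's summary score is the sum over positions 8-15
of the per-position means across individuals — a value in [0, 64].

Genotypes are compared by pairwise Welch t-tests (unequal variance) on
per-individual scores, with a Bonferroni-corrected significance threshold
alpha / number_of_pairs. Fluorescence quantification follows the same
arithmetic as the imaging workflow: region mean minus the mean of exactly
three background readings, normalized to the wild-type corrected value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgument

SCORE_POSITIONS = range(8, 16)  # positions summed into the summary score


@dataclass(frozen=True)
class RetentionSummary:
    """Per-position mean retention and the summed positions 8-15 score."""

    genotype: str
    position_means: dict[int, float]
    n_individuals: int

    @property
    def score(self) -> float:
        return float(sum(self.position_means[p] for p in SCORE_POSITIONS))


@dataclass
class PairwiseTestTable:
    """All pairwise Welch tests plus the Bonferroni threshold."""

    pairs: pd.DataFrame  # group1, group2, t, df, p, significant
    alpha: float
    n_comparisons: int

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_comparisons

    def p_matrix(self) -> pd.DataFrame:
        """Symmetric genotype x genotype matrix of p-values."""
        groups = sorted(set(self.pairs["group1"]) | set(self.pairs["group2"]))
        mat = pd.DataFrame(np.nan, index=groups, columns=groups)
        for row in self.pairs.itertuples(index=False):
            mat.loc[row.group1, row.group2] = row.p
            mat.loc[row.group2, row.group1] = row.p
        np.fill_diagonal(mat.values, 1.0)
        return mat


@dataclass(frozen=True)
class FluorescenceMeasurement:
    """Background-corrected, wild-type-normalized fluorescence intensity."""

    region_mean: float
    background_means: tuple[float, float, float]
    corrected: float
    normalized: float

    @property
    def negative_corrected(self) -> bool:
        return self.corrected < 0


def score_flower(petals: int, sepals: int) -> int:
    """Retained-organ score of one flower: petals + sepals, each 0-4."""
    if not (isinstance(petals, (int, np.integer))
            and isinstance(sepals, (int, np.integer))):
        raise InvalidArgument("petal and sepal counts must be integers")
    if not (0 <= petals <= 4 and 0 <= sepals <= 4):
        raise InvalidArgument(
            f"counts must be in [0, 4]; got petals={petals}, sepals={sepals}")
    return int(petals + sepals)


def _genotype_block(matrix: pd.DataFrame, genotype: str) -> pd.DataFrame:
    required = {"genotype", "individual", "position", "retained"}
    missing_cols = required - set(matrix.columns)
    if missing_cols:
        raise InvalidArgument(f"table lacks columns {sorted(missing_cols)}")
    block = matrix[matrix["genotype"] == genotype]
    if block.empty:
        raise InvalidArgument(f"no rows for genotype {genotype!r}")
    if (block["retained"] < 0).any() or (block["retained"] > 8).any():
        raise InvalidArgument("retained counts must lie in [0, 8]")
    return block


def retention_summary(matrix: pd.DataFrame, genotype: str) -> RetentionSummary:
    """Per-position means over individuals and the positions 8-15 score.

    ``matrix`` is tidy with columns (genotype, individual, position,
    retained); every individual must cover positions 1-15.
    """
    block = _genotype_block(matrix, genotype)
    missing = sorted(set(range(1, 16)) - set(block["position"].unique()))
    if missing:
        raise InvalidArgument(
            f"genotype {genotype!r} is missing positions {missing}")
    means = block.groupby("position")["retained"].mean()
    return RetentionSummary(
        genotype=genotype,
        position_means={int(p): float(m) for p, m in means.items()},
        n_individuals=block["individual"].nunique(),
    )


def individual_scores(matrix: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-individual summed retention over positions 8-15, per genotype."""
    scores: dict[str, np.ndarray] = {}
    for g in pd.unique(matrix["genotype"]):
        block = _genotype_block(matrix, g)
        block = block[block["position"].isin(SCORE_POSITIONS)]
        per_ind = block.groupby("individual")["retained"].sum()
        scores[g] = per_ind.to_numpy(dtype=float)
    return scores


def welch_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, p).

    Degenerate zero-variance groups follow the documented convention:
    equal means -> (0, inf, 1); unequal means -> (signed inf, inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InvalidArgument("each group needs >= 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, math.inf, 1.0
        return math.copysign(math.inf, np.mean(x) - np.mean(y)), math.inf, 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pairwise_welch(
    scores: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> PairwiseTestTable:
    """All unordered pairwise Welch tests with a Bonferroni threshold.

    ``scores`` maps genotype to per-individual summed 8-15 retention
    scores. The threshold is alpha divided by the number of pairs
    (e.g. 5 genotypes -> 10 pairs -> 0.005 at alpha = 0.05).
    """
    if not 0 < alpha < 1:
        raise InvalidArgument("alpha must be in (0, 1)")
    groups = list(scores)
    if len(groups) < 2:
        raise InvalidArgument("need at least two genotypes")
    pairs = list(itertools.combinations(groups, 2))
    threshold = alpha / len(pairs)
    rows = []
    for g1, g2 in pairs:
        t, df, p = welch_test(scores[g1], scores[g2])
        rows.append({"group1": g1, "group2": g2, "t": t, "df": df, "p": p,
                     "significant": p < threshold})
    return PairwiseTestTable(
        pairs=pd.DataFrame(rows,
                           columns=["group1", "group2", "t", "df", "p",
                                    "significant"]),
        alpha=alpha, n_comparisons=len(pairs))


def fluorescence_normalize(
    region_mean: float,
    background_means: Sequence[float],
    wt_corrected: float,
) -> FluorescenceMeasurement:
    """Background-subtract and wild-type-normalize one region intensity."""
    if len(background_means) != 3:
        raise InvalidArgument("exactly three background readings required")
    if not wt_corrected > 0:
        raise InvalidArgument("wt_corrected must be positive")
    corrected = float(region_mean) - float(np.mean(background_means))
    return FluorescenceMeasurement(
        region_mean=float(region_mean),
        background_means=tuple(float(b) for b in background_means),
        corrected=corrected,
        normalized=corrected / wt_corrected,
    )


def summaries_frame(matrix: pd.DataFrame) -> pd.DataFrame:
    """Tabulate retention summaries for every genotype in a tidy table."""
    rows = []
    for g in pd.unique(matrix["genotype"]):
        s = retention_summary(matrix, g)
        row = {"genotype": g, "n_individuals": s.n_individuals,
               "score": s.score}
        row.update({f"pos{p}_mean": s.position_means[p]
                    for p in range(1, 16)})
        rows.append(row)
    return pd.DataFrame(rows)
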