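"""Pairwise Boolean implication statistics, relation discovery, and FDR.

For a gene pair (A, B) the non-intermediate samples fall into four quadrants
``a00, a01, a10, a11`` (first index = state of A, second = state of B;
0 = LOW, 1 = HIGH).  Under independence the expected count in quadrant
``(i, j)`` is ``nhat = (row marginal) * (column marginal) / total``.  A
quadrant is sparse when the deficiency statistic

    S_ij = (nhat - a_ij) / sqrt(nhat)

is large and the error rate

    p_ij = 1/2 * (a_ij / row marginal + a_ij / column marginal)

is small.  One sparse quadrant yields an asymmetric implication; the two
off-diagonal (resp. diagonal) quadrants sparse together yield the symmetric
equivalent (resp. opposite) relation.
"""

from __future__ import annotations

import dataclasses
import enum
import itertools
import logging
import math

import numpy as np
import pandas as pd

from . import stepminer
from .errors import (
    DegenerateMarginalError,
    InvalidInputError,
    UndefinedFDRError,
)

logger = logging.getLogger(__name__)


class Relation(enum.Enum):
    """The six Boolean implication relation types plus NONE.

    Asymmetric names read "A <state> implies B <state>": e.g. ``LOW_HIGH``
    means A-low => B-high (sparse low-low quadrant).
    """

    LOW_LOW = "low=>low"
    LOW_HIGH = "low=>high"
    HIGH_HIGH = "high=>high"
    HIGH_LOW = "high=>low"
    EQUIVALENT = "equivalent"
    OPPOSITE = "opposite"
    NONE = "none"


#: sparse quadrant (state of A, state of B) -> asymmetric relation
_QUADRANT_RELATION = {
    (0, 0): Relation.LOW_HIGH,
    (0, 1): Relation.LOW_LOW,
    (1, 0): Relation.HIGH_HIGH,
    (1, 1): Relation.HIGH_LOW,
}

#: relation seen from B's side for the same quadrant table
CONVERSE = {
    Relation.LOW_HIGH: Relation.LOW_HIGH,
    Relation.LOW_LOW: Relation.HIGH_HIGH,
    Relation.HIGH_HIGH: Relation.LOW_LOW,
    Relation.HIGH_LOW: Relation.HIGH_LOW,
    Relation.EQUIVALENT: Relation.EQUIVALENT,
    Relation.OPPOSITE: Relation.OPPOSITE,
    Relation.NONE: Relation.NONE,
}

ASYMMETRIC = frozenset(
    {Relation.LOW_LOW, Relation.LOW_HIGH, Relation.HIGH_HIGH, Relation.HIGH_LOW}
)
SYMMETRIC = frozenset({Relation.EQUIVALENT, Relation.OPPOSITE})


@dataclasses.dataclass(frozen=True)
class QuadrantCounts:
    a00: int
    a01: int
    a10: int
    a11: int

    def __post_init__(self):
        if min(self.a00, self.a01, self.a10, self.a11) < 0:
            raise InvalidInputError("quadrant counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a00 + self.a01 + self.a10 + self.a11

    @property
    def na_low(self) -> int:
        return self.a00 + self.a01

    @property
    def na_high(self) -> int:
        return self.a10 + self.a11

    @property
    def nb_low(self) -> int:
        return self.a00 + self.a10

    @property
    def nb_high(self) -> int:
        return self.a01 + self.a11

    def swapped(self) -> "QuadrantCounts":
        """Counts for the pair seen as (B, A): transpose of the table."""
        return QuadrantCounts(self.a00, self.a10, self.a01, self.a11)

    def as_tuple(self):
        return (self.a00, self.a01, self.a10, self.a11)


@dataclasses.dataclass(frozen=True)
class ImplicationStats:
    """Sparsity statistics S, error rates p, expected counts, per quadrant.

    Each field is a mapping ``(i, j) -> value`` over the four quadrants.
    """

    s: dict
    p: dict
    expected: dict


@dataclasses.dataclass(frozen=True)
class DiscoveryParams:
    """Thresholds deciding when a quadrant counts as sparse."""

    s_min: float = 10.0
    p_max: float = 0.15

    def __post_init__(self):
        if self.s_min <= 0:
            raise InvalidInputError("s_min must be > 0")
        if not (0.0 < self.p_max < 1.0):
            raise InvalidInputError("p_max must lie in (0, 1)")


#: named presets: `network` for building implication networks on large
#: cohorts, `screen` for the more permissive candidate screen.
PRESETS = {
    "network": DiscoveryParams(s_min=10.0, p_max=0.15),
    "screen": DiscoveryParams(s_min=3.0, p_max=0.1),
}


@dataclasses.dataclass(frozen=True)
class ImplicationRecord:
    gene_a: str
    gene_b: str
    counts: QuadrantCounts
    stats: ImplicationStats
    relation: Relation


def count_quadrants(states_a, states_b) -> QuadrantCounts:
    """Tally joint LOW/HIGH states of two trivalent series.

    A sample contributes only when both genes are non-intermediate, so the
    quadrant total may be smaller than the series length.
    """
    a = np.asarray(states_a)
    b = np.asarray(states_b)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("state series must be 1-D and equal length")
    keep = (a != stepminer.MID) & (b != stepminer.MID)
    ah = a[keep] == stepminer.HIGH
    bh = b[keep] == stepminer.HIGH
    return QuadrantCounts(
        a00=int(np.count_nonzero(~ah & ~bh)),
        a01=int(np.count_nonzero(~ah & bh)),
        a10=int(np.count_nonzero(ah & ~bh)),
        a11=int(np.count_nonzero(ah & bh)),
    )


def implication_stats(counts: QuadrantCounts) -> ImplicationStats:
    """Evaluate the sparsity statistic and error rate for every quadrant.

    Raises
    ------
    DegenerateMarginalError
        Any row or column marginal is zero (a gene with no LOW or no HIGH
        samples among the jointly counted ones).
    """
    if counts.total == 0:
        raise DegenerateMarginalError("empty quadrant table")
    row = {0: counts.na_low, 1: counts.na_high}
    col = {0: counts.nb_low, 1: counts.nb_high}
    if min(row.values()) == 0 or min(col.values()) == 0:
        raise DegenerateMarginalError(f"zero marginal in counts {counts.as_tuple()}")
    a = {
        (0, 0): counts.a00,
        (0, 1): counts.a01,
        (1, 0): counts.a10,
        (1, 1): counts.a11,
    }
    total = counts.total
    s, p, expected = {}, {}, {}
    for q in a:
        i, j = q
        nhat = row[i] * col[j] / total
        expected[q] = nhat
        s[q] = (nhat - a[q]) / math.sqrt(nhat)
        p[q] = 0.5 * (a[q] / row[i] + a[q] / col[j])
    return ImplicationStats(s=s, p=p, expected=expected)


def sparse_quadrants(stats: ImplicationStats, params: DiscoveryParams) -> set:
    """Quadrants (i, j) passing both the S and p sparsity gates."""
    return {
        q
        for q in stats.s
        if stats.s[q] > params.s_min and stats.p[q] < params.p_max
    }


def classify_relation(stats: ImplicationStats, params: DiscoveryParams) -> Relation:
    """Map the sparse-quadrant pattern to one of the six relation types.

    Both off-diagonal quadrants sparse -> EQUIVALENT; both diagonal sparse ->
    OPPOSITE; exactly one sparse -> the corresponding asymmetric implication;
    no sparse quadrant -> NONE.  Any other pattern (adjacent pair, three or
    four sparse quadrants) has no place in the six-type taxonomy and is
    logged and reported as NONE.
    """
    sparse = sparse_quadrants(stats, params)
    if sparse == {(0, 1), (1, 0)}:
        return Relation.EQUIVALENT
    if sparse == {(0, 0), (1, 1)}:
        return Relation.OPPOSITE
    if len(sparse) == 1:
        return _QUADRANT_RELATION[next(iter(sparse))]
    if len(sparse) > 0:
        logger.debug("degenerate sparse pattern %s -> NONE", sorted(sparse))
    return Relation.NONE


def classify_counts(counts: QuadrantCounts, params: DiscoveryParams) -> Relation:
    """Convenience: classify straight from quadrant counts."""
    return classify_relation(implication_stats(counts), params)


def discover_implications(
    states: pd.DataFrame, params: DiscoveryParams = PRESETS["network"]
) -> list:
    """Evaluate every unordered gene pair of a trivalent matrix.

    Symmetric relations are emitted once per unordered pair (lexicographic
    gene order); asymmetric relations are emitted in both directions with
    converse types, since A-low => B-low and B-high => A-high describe the
    same sparse quadrant from the two ends.  Pairs classifying as NONE, and
    pairs whose joint table has a zero marginal, are omitted.
    """
    genes = list(states.index)
    if len(genes) < 2:
        raise InvalidInputError("need at least 2 genes to discover implications")
    order = np.argsort(np.asarray(genes, dtype=object))
    genes_sorted = [genes[i] for i in order]
    svals = states.to_numpy()[order]

    low = (svals == stepminer.LOW).astype(np.int32)
    high = (svals == stepminer.HIGH).astype(np.int32)
    a00m = low @ low.T
    a01m = low @ high.T
    a10m = high @ low.T
    a11m = high @ high.T

    records = []
    for i, j in itertools.combinations(range(len(genes_sorted)), 2):
        counts = QuadrantCounts(
            int(a00m[i, j]), int(a01m[i, j]), int(a10m[i, j]), int(a11m[i, j])
        )
        try:
            stats = implication_stats(counts)
        except DegenerateMarginalError:
            continue
        rel = classify_relation(stats, params)
        if rel is Relation.NONE:
            continue
        ga, gb = genes_sorted[i], genes_sorted[j]
        records.append(ImplicationRecord(ga, gb, counts, stats, rel))
        if rel in ASYMMETRIC:
            swapped = counts.swapped()
            records.append(
                ImplicationRecord(
                    gb, ga, swapped, implication_stats(swapped), CONVERSE[rel]
                )
            )
    records.sort(key=lambda r: (r.gene_a, r.gene_b))
    return records


def _pipeline_count(matrix: pd.DataFrame, params: DiscoveryParams, **kw) -> int:
    """Discoveries after the full threshold/discretize/filter pipeline."""
    thr = stepminer.threshold_matrix(matrix, margin=kw.get("margin", stepminer.DEFAULT_MARGIN))
    usable = thr.index[~thr["degenerate"]]
    sub = matrix.loc[usable]
    states = stepminer.discretize(sub, thr)
    kept = stepminer.filter_genes(
        sub,
        states,
        min_state_frac=kw.get("min_state_frac", 0.05),
        min_percentile_range=kw.get("min_percentile_range", 1.0),
    )
    if len(kept) < 2:
        return 0
    return len(discover_implications(states.loc[kept], params))


def estimate_fdr(
    matrix: pd.DataFrame,
    params: DiscoveryParams = PRESETS["network"],
    n_perm: int = 10,
    seed: int = 0,
    **pipeline_kw,
) -> float:
    """Permutation false-discovery estimate for implication discovery.

    Each permutation independently shuffles every gene's values across
    samples — destroying inter-gene structure while preserving each gene's
    marginal distribution (and hence its StepMiner threshold, since the fit
    is order-free) — then re-runs the full pipeline (threshold, discretize,
    filter, discover).  The returned ratio is the mean permuted discovery
    count divided by the observed discovery count.

    Raises
    ------
    InvalidInputError
        ``n_perm`` < 1.
    UndefinedFDRError
        The observed matrix yields zero discoveries.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    observed = _pipeline_count(matrix, params, **pipeline_kw)
    if observed == 0:
        raise UndefinedFDRError("no discoveries in the observed matrix")
    rng = np.random.default_rng(seed)
    vals = matrix.to_numpy(dtype=float)
    perm_counts = []
    for _ in range(n_perm):
        shuffled = np.array([rng.permutation(row) for row in vals])
        perm = pd.DataFrame(shuffled, index=matrix.index, columns=matrix.columns)
        perm_counts.append(_pipeline_count(perm, params, **pipeline_kw))
    return float(np.mean(perm_counts) / observed)
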