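"""Composite signature scores, classification, survival, and power.

Each signature gene is normalized by a modified Z score centered on its
StepMiner threshold, ``z = (expr - SThr) / (3 * stddev)``; cluster averages
of these z values, combined with +1/-1 weights, give one composite score
per sample.  Scores order samples along a Boolean path, classify sample
groups (ROC-AUC), and stratify survival: the score vector is itself split
at its StepMiner threshold and the two arms compared by a log-rank test.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from . import stepminer
from .errors import (
    DegenerateFitError,
    DegenerateSplitError,
    InvalidInputError,
    NonConvergenceError,
)


@dataclasses.dataclass(frozen=True)
class SignatureSpec:
    """Gene clusters with +1/-1 weights forming a composite signature."""

    clusters: tuple  # tuple of tuples of gene ids
    weights: tuple  # +1 / -1 per cluster

    def __post_init__(self):
        if len(self.clusters) != len(self.weights):
            raise InvalidInputError("one weight per cluster required")
        if any(len(c) == 0 for c in self.clusters):
            raise InvalidInputError("empty gene cluster in signature")
        if any(w not in (+1, -1) for w in self.weights):
            raise InvalidInputError("weights must be +1 or -1")

    @classmethod
    def make(cls, clusters, weights):
        return cls(tuple(tuple(c) for c in clusters), tuple(int(w) for w in weights))


def composite_score(
    matrix: pd.DataFrame, thresholds: pd.DataFrame, spec: SignatureSpec
) -> pd.Series:
    """Weighted sum of threshold-centered cluster-average z scores.

    Per gene ``z = (expr - threshold) / (3 * stddev)``; per cluster the mean
    z over its genes; the score is the weight-signed sum of cluster means.
    Sample order of the matrix is preserved.

    Raises
    ------
    KeyError
        A signature gene missing from the matrix or thresholds.
    InvalidInputError
        A signature gene with a degenerate threshold or zero stddev.
    """
    genes = [g for cluster in spec.clusters for g in cluster]
    missing = [g for g in genes if g not in matrix.index or g not in thresholds.index]
    if missing:
        raise KeyError(f"signature genes missing from matrix/thresholds: {missing[:5]}")
    sub = thresholds.loc[genes]
    if bool(sub["degenerate"].any()):
        raise InvalidInputError("signature gene with degenerate threshold")
    if bool((sub["stddev"] <= 0).any()):
        raise InvalidInputError("signature gene with zero stddev")

    score = pd.Series(0.0, index=matrix.columns)
    for cluster, w in zip(spec.clusters, spec.weights):
        expr = matrix.loc[list(cluster)]
        thr = thresholds.loc[list(cluster), "threshold"].to_numpy()[:, None]
        sd = thresholds.loc[list(cluster), "stddev"].to_numpy()[:, None]
        z = (expr.to_numpy(dtype=float) - thr) / (3.0 * sd)
        score += w * pd.Series(z.mean(axis=0), index=matrix.columns)
    score.name = "score"
    return score


def order_samples(scores: pd.Series) -> list:
    """Sample ids sorted ascending by score; ties keep input order."""
    idx = np.argsort(scores.to_numpy(), kind="stable")
    return [scores.index[i] for i in idx]


def roc_auc(scores: pd.Series, labels) -> float:
    """Area under the ROC curve of scores against binary labels.

    Equals the Mann-Whitney probability that a positive sample outranks a
    negative one, with ties counted 1/2.
    """
    y = np.asarray(labels)
    if y.shape[0] != scores.shape[0]:
        raise InvalidInputError("labels must match scores in length")
    if len(np.unique(y)) != 2:
        raise InvalidInputError("roc_auc needs both classes present")
    return float(roc_auc_score(y, scores.to_numpy()))


@dataclasses.dataclass(frozen=True)
class SurvivalSplit:
    """Result of a StepMiner-threshold survival stratification."""

    groups: pd.Series  # 'high' / 'low' per sample
    threshold: float
    statistic: float
    p_value: float


def stratify_survival(scores: pd.Series, surv: pd.DataFrame) -> SurvivalSplit:
    """Split samples at the StepMiner threshold of their scores; log-rank.

    The one-step fit is applied to the score vector itself; samples above
    the threshold form the high arm.  Events at time zero are retained.  The
    statistic is the standard two-group log-rank chi-square (1 df).

    Raises
    ------
    DegenerateSplitError
        Constant scores, or a split leaving one arm empty.
    InvalidInputError
        Sample ids not matched between scores and the survival table.
    """
    if set(scores.index) != set(surv.index):
        raise InvalidInputError("scores and survival table must cover the same samples")
    surv = surv.loc[scores.index]
    if (surv["time"] < 0).any():
        raise InvalidInputError("negative survival times")
    if not surv["event"].isin([0, 1]).all():
        raise InvalidInputError("event must be 0 or 1")
    try:
        fit = stepminer.fit_step(scores.to_numpy())
    except DegenerateFitError as exc:
        raise DegenerateSplitError("constant scores cannot be split") from exc
    except InvalidInputError:
        raise
    high = scores > fit.threshold
    if high.all() or (~high).all():
        raise DegenerateSplitError("all samples fell on one side of the threshold")
    res = logrank_test(
        surv.loc[high, "time"],
        surv.loc[~high, "time"],
        event_observed_A=surv.loc[high, "event"],
        event_observed_B=surv.loc[~high, "event"],
    )
    groups = pd.Series(np.where(high, "high", "low"), index=scores.index, name="group")
    return SurvivalSplit(
        groups=groups,
        threshold=fit.threshold,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )


def refine_signature(
    deg_a: pd.DataFrame,
    deg_b: pd.DataFrame,
    matrix: pd.DataFrame,
    treated,
    fc_min: float = 10.0,
    padj_max: float = 0.05,
    auc_min: float = 0.9,
) -> list:
    """Intersect two differential-expression screens and keep classifiers.

    Candidates must pass ``|log2fc| > fc_min`` and ``padj < padj_max`` in
    BOTH input tables (columns ``gene``, ``log2fc``, ``padj``).  A candidate
    is retained iff its single-gene ROC-AUC for treated-vs-control in the
    expression matrix, taken direction-agnostically as ``max(auc, 1-auc)``,
    reaches ``auc_min``.  Output is sorted; an empty candidate set yields an
    empty list.
    """
    def passing(df):
        for col in ("gene", "log2fc", "padj"):
            if col not in df.columns:
                raise InvalidInputError(f"DEG table lacks column {col!r}")
        mask = (df["log2fc"].abs() > fc_min) & (df["padj"] < padj_max)
        return set(df.loc[mask, "gene"])

    candidates = sorted(passing(deg_a) & passing(deg_b))
    if not candidates:
        return []
    missing = [g for g in candidates if g not in matrix.index]
    if missing:
        raise KeyError(f"candidate genes missing from matrix: {missing[:5]}")
    y = np.asarray(treated)
    retained = []
    for g in candidates:
        auc = roc_auc_score(y, matrix.loc[g].to_numpy(dtype=float))
        if max(auc, 1.0 - auc) >= auc_min:
            retained.append(g)
    return retained


@dataclasses.dataclass(frozen=True)
class PowerSpec:
    """Two-sample t-test power specification."""

    effect_size: float
    alpha: float = 0.05
    power: float = 0.80
    two_sided: bool = True

    def __post_init__(self):
        if self.effect_size <= 0:
            raise InvalidInputError("effect_size must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise InvalidInputError("alpha must lie in (0, 1)")
        if not (self.alpha < self.power < 1.0):
            raise InvalidInputError("power must lie in (alpha, 1)")


def _ttest_power(n: int, spec: PowerSpec) -> float:
    """Power of an equal-n two-sample t test at per-group size n."""
    df = 2 * n - 2
    nc = spec.effect_size * math.sqrt(n / 2.0)
    if spec.two_sided:
        tcrit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
        return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    tcrit = sps.t.ppf(1.0 - spec.alpha, df)
    return float(sps.nct.sf(tcrit, df, nc))


def sample_size_ttest(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest per-group n at which the t test attains the target power.

    Uses the noncentral t distribution with ``df = 2n - 2`` and
    noncentrality ``d * sqrt(n / 2)``, searching n = 2, 3, ... upward.
    """
    for n in itertools.count(2):
        if n > n_max:
            raise NonConvergenceError(f"power {spec.power} unreachable within n <= {n_max}")
        if _ttest_power(n, spec) >= spec.power:
            return n
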