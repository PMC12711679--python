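"""StepMiner one-step fits, thresholds, and trivalent discretization.

A gene's expression values across a cohort are sorted ascending and a single
step function is fitted: every split position is scored by the residual sum
of squares of the two segment means, and the split with the smallest SSE
wins.  The midpoint of the two segment means is the StepMiner threshold.
Values within a noise margin of the threshold (default +/-0.5 log2 units,
i.e. a 2-fold band) are called intermediate and ignored by downstream
Boolean analysis; everything below is LOW, everything above is HIGH.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, InvalidInputError, MissingThresholdError

#: trivalent state codes
LOW, MID, HIGH = 0, 1, 2

#: default half-width of the intermediate band, log2 units
DEFAULT_MARGIN = 0.5

#: default model degrees of freedom for the step-fit F statistic
#: (two segment means plus one step position)
DEFAULT_DF_MODEL = 3

_SSE_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class StepFit:
    """A fitted one-step function over an ascending-sorted series.

    ``step_index`` is the 1-based count of values in the low segment, so the
    step sits between sorted positions ``step_index - 1`` and ``step_index``.
    ``fstat`` is the adaptive-regression test statistic; it is reported as
    ``math.inf`` when the fit is exact (zero residual).
    """

    step_index: int
    low_mean: float
    high_mean: float
    sse: float
    fstat: float
    df_model: int
    threshold: float
    exact_fit: bool


def fit_step(values, df_model: int = DEFAULT_DF_MODEL) -> StepFit:
    """Fit a one-step function to a series of log2 intensities.

    The series is sorted ascending internally; every candidate step position
    ``k`` in ``1..n-1`` is evaluated and the fit minimizing the residual sum
    of squares is returned, ties broken toward the smallest ``k``.  The
    threshold is the midpoint of the two segment means.

    Parameters
    ----------
    values
        Sequence of at least 4 finite values.
    df_model
        Degrees of freedom ``m`` charged to the adaptive regression when
        computing the F statistic ``[sum (fitted - mean)^2 / (m-1)] /
        [SSE / (n-m)]``.

    Raises
    ------
    InvalidInputError
        Fewer than 4 values, or non-finite values.
    DegenerateFitError
        Constant series: every candidate fit is identical and the null model
        already has zero error, so no step exists.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError("fit_step expects a 1-D series")
    n = x.size
    if n < 4:
        raise InvalidInputError(f"fit_step needs at least 4 values, got {n}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("fit_step requires finite values")
    x = np.sort(x)
    if x[0] == x[-1]:
        raise DegenerateFitError("constant series has no step")

    # SSE(k) = [S2_k - P_k^2/k] + [(S2_n - S2_k) - (P_n - P_k)^2/(n-k)]
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)
    left_sum = csum[:-1]
    right_sum = csum[-1] - left_sum
    left_sq = csq[:-1]
    right_sq = csq[-1] - left_sq
    sse = (left_sq - left_sum**2 / k) + (right_sq - right_sum**2 / (n - k))
    sse = np.maximum(sse, 0.0)

    # ties (within float noise of the minimum) break toward the smallest k
    tol = 1e-9 * max(1.0, float(csq[-1]))
    best = int(np.flatnonzero(sse <= sse.min() + tol)[0])
    k_best = best + 1
    low_mean = float(left_sum[best] / k_best)
    high_mean = float(right_sum[best] / (n - k_best))
    best_sse = float(sse[best])
    exact = best_sse <= _SSE_TOL * max(1.0, float(csq[-1]))

    mean_all = float(csum[-1] / n)
    ssr = k_best * (low_mean - mean_all) ** 2 + (n - k_best) * (high_mean - mean_all) ** 2
    if exact:
        fstat = math.inf
    else:
        fstat = (ssr / (df_model - 1)) / (best_sse / (n - df_model))

    return StepFit(
        step_index=k_best,
        low_mean=low_mean,
        high_mean=high_mean,
        sse=best_sse,
        fstat=fstat,
        df_model=df_model,
        threshold=(low_mean + high_mean) / 2.0,
        exact_fit=exact,
    )


def threshold_matrix(
    matrix: pd.DataFrame,
    margin: float = DEFAULT_MARGIN,
    df_model: int = DEFAULT_DF_MODEL,
    ddof: int = 1,
) -> pd.DataFrame:
    """Fit a StepMiner threshold for every gene of an expression matrix.

    Parameters
    ----------
    matrix
        Genes x samples log2 expression values.
    margin
        Half-width of the intermediate band stored alongside each threshold.
    ddof
        Delta degrees of freedom for the per-gene standard deviation, taken
        across all samples of the matrix (1 = sample SD, the default).

    Returns
    -------
    DataFrame indexed by gene with columns ``threshold``, ``margin``,
    ``stddev`` and ``degenerate``.  Genes whose series is constant are
    flagged ``degenerate=True`` (threshold NaN) and must be excluded
    downstream.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise InvalidInputError("empty expression matrix")
    if margin < 0:
        raise InvalidInputError("margin must be >= 0")
    rows = []
    for gene, series in matrix.iterrows():
        vals = series.to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=ddof))
        try:
            fit = fit_step(vals, df_model=df_model)
            rows.append((gene, fit.threshold, margin, sd, False))
        except DegenerateFitError:
            rows.append((gene, np.nan, margin, sd, True))
    out = pd.DataFrame(
        rows, columns=["gene_id", "threshold", "margin", "stddev", "degenerate"]
    ).set_index("gene_id")
    return out


def discretize(matrix: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Convert log2 expression to trivalent states {LOW=0, MID=1, HIGH=2}.

    A value more than ``margin`` above a gene's threshold is HIGH, more than
    ``margin`` below is LOW, and anything inside the band (inclusive) is MID.

    Raises
    ------
    MissingThresholdError
        A gene of the matrix has no threshold row or is flagged degenerate.
    """
    missing = matrix.index.difference(thresholds.index)
    if len(missing) > 0:
        raise MissingThresholdError(f"no threshold for genes: {list(missing)[:5]}")
    sub = thresholds.loc[matrix.index]
    if bool(sub["degenerate"].any()):
        bad = sub.index[sub["degenerate"]].tolist()
        raise MissingThresholdError(f"degenerate thresholds for genes: {bad[:5]}")
    thr = sub["threshold"].to_numpy()[:, None]
    mar = sub["margin"].to_numpy()[:, None]
    vals = matrix.to_numpy(dtype=float)
    states = np.full(vals.shape, MID, dtype=np.int8)
    states[vals > thr + mar] = HIGH
    states[vals < thr - mar] = LOW
    return pd.DataFrame(states, index=matrix.index, columns=matrix.columns)


def filter_genes(
    matrix: pd.DataFrame,
    states: pd.DataFrame,
    min_state_frac: float = 0.05,
    min_percentile_range: float = 1.0,
) -> list:
    """Retain genes with usable dynamic range for Boolean analysis.

    A gene is kept iff at least ``min_state_frac`` of samples are HIGH, at
    least ``min_state_frac`` are LOW, and its 10th-90th percentile spread is
    at least ``min_percentile_range`` log2 units.  Order of the input matrix
    is preserved.
    """
    if not matrix.index.equals(states.index):
        raise InvalidInputError("matrix and states must share the same gene index")
    n = states.shape[1]
    kept = []
    svals = states.to_numpy()
    for i, gene in enumerate(matrix.index):
        row = svals[i]
        frac_high = np.count_nonzero(row == HIGH) / n
        frac_low = np.count_nonzero(row == LOW) / n
        if frac_high < min_state_frac or frac_low < min_state_frac:
            continue
        p10, p90 = np.percentile(matrix.iloc[i].to_numpy(dtype=float), [10, 90])
        if (p90 - p10) >= min_percentile_range:
            kept.append(gene)
    return kept
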