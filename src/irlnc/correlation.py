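"""Direct, partial and heuristic lncRNA-mRNA correlation.

The model
---------
A lncRNA can track an mRNA's expression directly, or the two can co-vary only
because both respond to the cellular composition of the bulk sample. Both
routes are biologically meaningful, so each lncRNA-mRNA pair receives

* a *direct* coefficient ``D = (R + S) / 2``, the mean of the Pearson (R) and
  Spearman (S) correlations across samples;
* a *partial* coefficient ``P``, the first-order partial correlation of the
  pair given tumor purity ``t`` (computed from the same combined D
  coefficients, ``P = (D_ml - D_mt * D_tl) / sqrt((1 - D_mt^2)(1 - D_tl^2))``),
  which removes linear co-variation explained by purity;
* a *heuristic* coefficient ``H = L(|beta*D + (1-beta)*P|)`` where ``beta`` in
  [0, 1] is chosen to maximize the magnitude of the convex combination and
  ``L(x) = 1 / (exp(c*x + d) + 1)`` is a steep logistic squashing. At the
  default parameters ``c = -15`` and ``d = ln(1999)``, ``L`` is ~0 below
  |corr| 0.3 and ~1 above 0.7, so H accentuates strong and suppresses weak
  correlations. Because the objective is linear in beta, the optimum sits at
  an endpoint and ``H = L(max(|D|, |P|))``; ties prefer the direct
  coefficient (``beta = 1``).

H is unsigned (the logistic acts on an absolute value); the sign of the
selected coefficient is kept in the output for diagnostics but downstream
ranking uses H only.

Pairs involving a zero-variance gene, or a purity correlation of exactly
±1, have no defined coefficient and are skipped (never scored as 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core_io import ExpressionMatrix
from .errors import (
    ConfigurationError,
    InsufficientSamplesError,
    UndefinedCorrelationError,
    UndefinedPartialError,
)

logger = logging.getLogger(__name__)

#: Tolerance within which a coefficient just outside [-1, 1] is treated as
#: floating-point noise and clamped silently.
CLAMP_TOL = 1e-12

TRIPLE_COLUMNS = ["lncrna_id", "mrna_id", "R", "S", "D", "P", "beta", "H"]


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the squashing logistic ``L(x) = 1/(exp(c*x + d) + 1)``.

    ``c`` must be negative so that L is strictly increasing on [0, 1];
    at the defaults ``L(0) = 1/2000`` and the midpoint ``L(x) = 0.5`` sits at
    ``x = ln(1999)/15`` (about 0.507).
    """

    c: float = -15.0
    d: float = math.log(1999.0)

    def __post_init__(self) -> None:
        if not self.c < 0:
            raise ConfigurationError(f"logistic c must be negative, got {self.c}")


DEFAULT_LOGISTIC = LogisticParams()


def logistic_transform(x, params: LogisticParams = DEFAULT_LOGISTIC):
    """Apply ``L(x) = 1/(exp(c*x + d) + 1)`` elementwise; x must lie in [0, 1]."""
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ConfigurationError("logistic_transform input must lie in [0, 1]")
    out = 1.0 / (np.exp(params.c * arr + params.d) + 1.0)
    return float(out) if np.isscalar(x) else out


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedCorrelationError("vectors must be 1-D with equal length")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance vector")


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two vectors (length >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    return float(scipy.stats.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Spearman correlation, computed as Pearson of mid-ranks (tie-safe)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("zero-variance ranks (all ties)")
    return float(scipy.stats.pearsonr(rx, ry).statistic)


def direct_correlation(r: float, s: float) -> float:
    """Combined direct coefficient: arithmetic mean of Pearson and Spearman."""
    return (r + s) / 2.0


def _clamp(value: float) -> float:
    if value > 1.0:
        if value > 1.0 + CLAMP_TOL:
            logger.debug("clamping partial correlation %.6g to 1", value)
        return 1.0
    if value < -1.0:
        if value < -1.0 - CLAMP_TOL:
            logger.debug("clamping partial correlation %.6g to -1", value)
        return -1.0
    return value


def partial_correlation(d_ml: float, d_mt: float, d_tl: float) -> float:
    """First-order partial correlation of (m, l) given tumor purity t.

    All three inputs are combined direct coefficients. Raises
    :class:`UndefinedPartialError` when either conditioning correlation is
    exactly ±1 (the denominator vanishes). The result is clamped to
    [-1, 1]; applied to averaged Pearson/Spearman coefficients the recursion
    formula is not guaranteed to stay inside the interval.
    """
    for v in (d_ml, d_mt, d_tl):
        if abs(v) > 1.0 + CLAMP_TOL:
            raise ConfigurationError(f"correlation input {v} outside [-1, 1]")
    if abs(abs(d_mt) - 1.0) <= CLAMP_TOL or abs(abs(d_tl) - 1.0) <= CLAMP_TOL:
        raise UndefinedPartialError("conditioning correlation is ±1")
    denom = math.sqrt((1.0 - d_mt * d_mt) * (1.0 - d_tl * d_tl))
    return _clamp((d_ml - d_mt * d_tl) / denom)


def optimal_beta(d: float, p: float) -> tuple[float, float]:
    """Weight beta maximizing ``|beta*D + (1-beta)*P|`` over [0, 1].

    The objective is linear in beta, so the optimum is an endpoint:
    ``beta = 1`` (direct) when ``|D| >= |P|`` (ties prefer direct), else
    ``beta = 0`` (partial). Returns ``(beta, combined)`` where ``combined``
    carries the sign of the selected coefficient.
    """
    if abs(d) >= abs(p):
        return 1.0, d
    return 0.0, p


def heuristic_correlation(
    d: float, p: float, params: LogisticParams = DEFAULT_LOGISTIC
) -> float:
    """Heuristic coefficient ``H = L(max(|D|, |P|))``, strictly inside (0, 1)."""
    _, combined = optimal_beta(d, p)
    return logistic_transform(abs(combined), params)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``.

    Rows with zero variance yield NaN in their row/column.
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac * ac).sum(axis=1))
    sb = np.sqrt((bc * bc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (ac @ bc.T) / np.outer(sa, sb)
    return np.clip(corr, -1.0, 1.0)


def _combined_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rowwise combined D = (Pearson + Spearman)/2 between rows of a and b."""
    r = _rowwise_pearson(a, b)
    s = _rowwise_pearson(
        scipy.stats.rankdata(a, axis=1), scipy.stats.rankdata(b, axis=1)
    )
    return r, s, (r + s) / 2.0


def heuristic_matrix(
    mrna: ExpressionMatrix,
    lncrna: ExpressionMatrix,
    purity: pd.Series,
    params: LogisticParams = DEFAULT_LOGISTIC,
) -> pd.DataFrame:
    """Compute the full correlation table for every lncRNA-mRNA pair.

    Samples are the intersection of the two matrices and the purity table
    (samples lacking purity are excluded with a warning); at least 3 shared
    samples are required. Purity correlations ``D(m, t)`` and ``D(t, l)`` use
    the same combined Pearson/Spearman form as ``D(m, l)``. Pairs for which
    any of R, S or P is not computable (zero-variance gene, |D_mt| = 1 or
    |D_tl| = 1) are skipped with a logged count.

    Returns a DataFrame with columns
    ``lncrna_id, mrna_id, R, S, D, P, beta, H`` sorted by the two ids.
    """
    purity_samples = set(purity.index)
    lnc_samples = set(lncrna.sample_ids)
    shared = [
        s for s in mrna.sample_ids if s in lnc_samples and s in purity_samples
    ]
    n_no_purity = len(set(mrna.sample_ids) & lnc_samples - purity_samples)
    if n_no_purity:
        logger.warning(
            "heuristic_matrix: excluding %d shared samples without purity",
            n_no_purity,
        )
    if len(shared) < 3:
        raise InsufficientSamplesError(
            f"only {len(shared)} shared samples with purity (need >= 3)"
        )

    m = mrna.data[shared].to_numpy(dtype=float)
    l = lncrna.data[shared].to_numpy(dtype=float)
    t = purity.loc[shared].to_numpy(dtype=float)[None, :]

    r_ml, s_ml, d_ml = _combined_matrix(m, l)
    _, _, d_mt = _combined_matrix(m, t)
    _, _, d_tl = _combined_matrix(t, l)
    d_mt = d_mt[:, 0]
    d_tl = d_tl[0, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt((1.0 - d_mt**2)[:, None] * (1.0 - d_tl**2)[None, :])
        p_ml = (d_ml - np.outer(d_mt, d_tl)) / denom
    p_ml = np.clip(p_ml, -1.0, 1.0)

    valid = (
        np.isfinite(r_ml)
        & np.isfinite(s_ml)
        & np.isfinite(p_ml)
        & np.isfinite(d_mt)[:, None]
        & np.isfinite(d_tl)[None, :]
    )
    n_skipped = int(valid.size - valid.sum())
    if n_skipped:
        logger.info(
            "heuristic_matrix: skipped %d/%d pairs with undefined coefficients",
            n_skipped,
            valid.size,
        )

    abs_d = np.abs(d_ml)
    abs_p = np.abs(p_ml)
    take_direct = abs_d >= abs_p
    beta = np.where(take_direct, 1.0, 0.0)
    combined = np.where(take_direct, d_ml, p_ml)
    with np.errstate(invalid="ignore"):
        h = 1.0 / (np.exp(params.c * np.abs(combined) + params.d) + 1.0)

    mi, li = np.nonzero(valid)
    mrna_ids = np.asarray(mrna.gene_ids, dtype=object)
    lnc_ids = np.asarray(lncrna.gene_ids, dtype=object)
    table = pd.DataFrame(
        {
            "lncrna_id": lnc_ids[li],
            "mrna_id": mrna_ids[mi],
            "R": r_ml[mi, li],
            "S": s_ml[mi, li],
            "D": d_ml[mi, li],
            "P": p_ml[mi, li],
            "beta": beta[mi, li],
            "H": h[mi, li],
        }
    )
    return table.sort_values(["lncrna_id", "mrna_id"], kind="mergesort").reset_index(
        drop=True
    )


def write_triples(table: pd.DataFrame, path) -> None:
    """Write a correlation table as TSV with 6-decimal numeric columns."""
    out = table.copy()
    for col in ["R", "S", "D", "P", "beta", "H"]:
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_triples(path) -> pd.DataFrame:
    """Read a correlation table written by :func:`write_triples`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIPLE_COLUMNS) - set(df.columns)
    if missing:
        from .errors import FormatError

        raise FormatError(f"{path}: missing correlation columns {sorted(missing)}")
    return df
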