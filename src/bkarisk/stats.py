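"""Nonparametric statistics used to validate the risk score.

Three procedures, implemented from first principles:

* :func:`mann_whitney` — two-group rank comparison.  U counts pairwise wins
  of the first group (ties count one half).  The exact two-sided p-value is
  the permutation p over all C(n1+n2, n1) group labelings, computed with a
  subset-sum dynamic program over midranks, so it stays feasible (and exact,
  ties included) well beyond what naive enumeration allows.  The normal
  approximation applies the standard tie correction to the variance and a
  0.5 continuity correction.
* :func:`roc_auc` — empirical ROC curve over all distinct score thresholds.
  The AUC equals the probability that a random positive outranks a random
  negative (ties half), i.e. U/(n₊·n₋); the trapezoidal area of the curve is
  the same number and is asserted to agree to 1e-12.
* :func:`spearman` — Pearson correlation of midranks, with an exact
  permutation p-value for n ≤ 8 and a t-approximation above.

:func:`interpret_correlation` maps |r| onto the conventional descriptive
bands (negligible/weak/moderate/strong/very strong) with half-open
intervals closed on the left, so every |r| lands in exactly one band.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import CapabilityError, ValidationError

__all__ = [
    "MannWhitneyResult",
    "RocResult",
    "SpearmanResult",
    "CorrelationBand",
    "mann_whitney",
    "roc_auc",
    "spearman",
    "interpret_correlation",
    "midranks",
]

# exact Mann-Whitney p is refused above this pooled size (int64 subset counts
# stay exact up to C(60,30) ≈ 1.2e17)
EXACT_POOLED_LIMIT = 60
# `auto` switches from exact to the normal approximation above this size
AUTO_EXACT_LIMIT = 14
# exact permutation Spearman p is used up to this n (8! = 40320 permutations)
SPEARMAN_EXACT_LIMIT = 8


def midranks(values) -> np.ndarray:
    """Ranks 1..n with tied values sharing the average of their positions."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValidationError("midranks expects a 1-d array")
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _check_finite(name: str, arr: np.ndarray) -> None:
    if arr.size == 0:
        raise ValidationError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")


@dataclass(frozen=True)
class MannWhitneyResult:
    """U for the first group, signed z, and a two-sided p-value.

    ``z_statistic`` carries the sign of (mean rank of group A − mean rank of
    group B); published tables sometimes print this signed deviate in a
    column labeled "U".
    """

    u_statistic: float
    z_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int


def _rank_sum_counts(dranks: np.ndarray, n1: int) -> np.ndarray:
    """Count size-``n1`` subsets of ``dranks`` by their sum.

    ``dranks`` are doubled midranks (integers).  Returns an int64 array
    ``counts`` where ``counts[s]`` is the number of subsets summing to s.
    """
    total = int(dranks.sum())
    counts = np.zeros((n1 + 1, total + 1), dtype=np.int64)
    counts[0, 0] = 1
    for d in dranks:
        d = int(d)
        # descending k so each element is used at most once
        for k in range(n1, 0, -1):
            counts[k, d:] += counts[k - 1, : total + 1 - d]
    return counts[n1]


def _exact_mw_pvalue(ranks: np.ndarray, n1: int, u1: float) -> float:
    """Two-sided permutation p for U, by distance from the null mean."""
    n = len(ranks)
    n2 = n - n1
    dranks = np.rint(2.0 * ranks).astype(np.int64)
    counts = _rank_sum_counts(dranks, n1)
    sums = np.arange(counts.size, dtype=np.int64)
    # doubled U for each achievable rank sum: 2U = S2 - n1(n1+1)
    du = sums - n1 * (n1 + 1)
    observed = abs(int(round(2.0 * u1)) - n1 * n2)
    extreme = int(counts[np.abs(du - n1 * n2) >= observed].sum())
    return extreme / math.comb(n, n1)


def mann_whitney(group_a, group_b, method: str = "auto") -> MannWhitneyResult:
    """Mann–Whitney U comparison of two independent samples.

    Parameters
    ----------
    group_a, group_b
        Non-empty 1-d sequences of real observations.
    method
        ``"exact"`` (permutation p, ties included), ``"normal_approx"``
        (tie-corrected, continuity-corrected), or ``"auto"`` which uses the
        exact distribution for pooled sizes up to 14 and the normal
        approximation beyond.

    Raises
    ------
    ValidationError
        on empty groups or non-finite values.
    CapabilityError
        if an exact p is requested above the feasible pooled-size limit.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    _check_finite("group_a", a)
    _check_finite("group_b", b)
    n1, n2 = len(a), len(b)
    n = n1 + n2

    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if method == "auto":
        use_exact = n <= AUTO_EXACT_LIMIT
    elif method == "exact":
        if n > EXACT_POOLED_LIMIT:
            raise CapabilityError(
                f"exact Mann-Whitney p is limited to pooled n <= "
                f"{EXACT_POOLED_LIMIT}; got {n}"
            )
        use_exact = True
    elif method == "normal_approx":
        use_exact = False
    else:
        raise ValidationError(f"unknown method {method!r}")

    # tie-corrected variance of U under the null
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0

    diff = u1 - mu
    if var <= 0:
        z = 0.0
    else:
        shrunk = math.copysign(max(abs(diff) - 0.5, 0.0), diff)
        z = shrunk / math.sqrt(var)

    if use_exact:
        p = _exact_mw_pvalue(ranks, n1, u1)
        used = "exact"
    else:
        p = math.erfc(abs(z) / math.sqrt(2.0)) if var > 0 else 1.0
        used = "normal_approx"

    return MannWhitneyResult(
        u_statistic=u1,
        z_statistic=z,
        p_value=min(p, 1.0),
        method=used,
        n1=n1,
        n2=n2,
    )


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with its area.

    ``points`` runs from (0, 0) to (1, 1) in (false-positive rate,
    true-positive rate) coordinates, one step per distinct score threshold.
    ``auc`` is the probability that a random positive outranks a random
    negative in the stated ``direction`` (ties count one half).
    """

    points: tuple
    auc: float
    positive_label: str
    direction: str

    @property
    def auc_complement(self) -> float:
        """AUC under the opposite orientation of the score axis."""
        return 1.0 - self.auc


_DIRECTIONS = ("higher_score_positive", "lower_score_positive")


def roc_auc(
    scores,
    labels,
    positive_label: str = "event",
    direction: str = "higher_score_positive",
) -> RocResult:
    """Empirical ROC curve and AUC of a score against a binary label.

    Both outcome classes must be present.  Flipping ``direction`` returns
    exactly ``1 - auc`` for the same data.
    """
    if direction not in _DIRECTIONS:
        raise ValidationError(
            f"direction must be one of {_DIRECTIONS}, got {direction!r}"
        )
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if len(s) != len(y):
        raise ValidationError("scores and labels must have equal length")
    _check_finite("scores", s)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both outcome classes must be present")

    # canonical AUC in the higher-score-positive orientation, from rank sums
    ranks = midranks(s)
    u_pos = float(ranks[y].sum()) - n_pos * (n_pos + 1) / 2.0
    auc_higher = u_pos / (n_pos * n_neg)
    auc = auc_higher if direction == "higher_score_positive" else 1.0 - auc_higher

    oriented = s if direction == "higher_score_positive" else -s
    order = np.argsort(-oriented, kind="mergesort")
    ys = y[order]
    ss = oriented[order]
    last_of_group = np.r_[np.diff(ss) != 0, True]
    tp = np.cumsum(ys)[last_of_group] / n_pos
    fp = np.cumsum(~ys)[last_of_group] / n_neg
    points = tuple([(0.0, 0.0)] + list(zip(fp.tolist(), tp.tolist())))

    trap = float(np.trapezoid([p[1] for p in points], [p[0] for p in points]))
    if abs(trap - auc) > 1e-12:
        raise AssertionError(
            f"trapezoidal AUC {trap} disagrees with pair-counting AUC {auc}"
        )
    return RocResult(points=points, auc=auc, positive_label=positive_label,
                     direction=direction)


class CorrelationBand(str, enum.Enum):
    NEGLIGIBLE = "negligible"
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"


def interpret_correlation(r: float) -> CorrelationBand:
    """Descriptive band for a correlation coefficient by |r|.

    [0, 0.10) negligible, [0.10, 0.40) weak, [0.40, 0.70) moderate,
    [0.70, 0.90) strong, [0.90, 1] very strong.
    """
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise ValidationError(f"|r| must be <= 1, got {r}")
    a = min(a, 1.0)
    if a < 0.10:
        return CorrelationBand.NEGLIGIBLE
    if a < 0.40:
        return CorrelationBand.WEAK
    if a < 0.70:
        return CorrelationBand.MODERATE
    if a < 0.90:
        return CorrelationBand.STRONG
    return CorrelationBand.VERY_STRONG


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    p_value: float
    n: int
    band: CorrelationBand


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValidationError(
            "correlation is undefined for a constant vector"
        )
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _exact_spearman_pvalue(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided permutation p over all n! orderings of one rank vector."""
    n = len(rx)
    rx_t = tuple(rx.tolist())
    observed = abs(float(rx @ ry) - n * rx.mean() * ry.mean())
    center = n * rx.mean() * ry.mean()
    extreme = 0
    total = 0
    for perm in itertools.permutations(ry.tolist()):
        s = sum(a * b for a, b in zip(rx_t, perm))
        total += 1
        if abs(s - center) >= observed - 1e-9:
            extreme += 1
    return extreme / total


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation: Pearson correlation of midranks.

    The p-value is an exact permutation p for n ≤ 8 and the usual
    t-approximation (df = n − 2) above.  Constant inputs raise a
    :class:`ValidationError` (the correlation is undefined).
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if len(xa) != len(ya):
        raise ValidationError("x and y must have equal length")
    _check_finite("x", xa)
    _check_finite("y", ya)
    n = len(xa)
    if n < 3:
        raise ValidationError(f"spearman needs n >= 3, got {n}")
    rx = midranks(xa)
    ry = midranks(ya)
    r = _pearson(rx, ry)

    if n <= SPEARMAN_EXACT_LIMIT:
        p = _exact_spearman_pvalue(rx, ry)
    else:
        if 1.0 - r * r <= 0.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * float(_sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(r=r, p_value=min(p, 1.0), n=n,
                          band=interpret_correlation(r))
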