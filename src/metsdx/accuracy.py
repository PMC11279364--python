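"""Empirical ROC analysis, Youden-optimal cut-offs, and accuracy measures.

Everything here operates on a vector of marker scores and a boolean
disease label per subject.  The ROC is the exact empirical curve over
the observed score values (no smoothing, no binormal fit); the AUC is
the trapezoidal area, which equals the Mann-Whitney concordance
probability with ties counted 1/2.  Cut-offs are selected by maximizing
the Youden index over observed values, so every reported cut-off is a
data value.

Confidence intervals: exact Clopper-Pearson for the binomial proportions
(Se, Sp, PPV, NPV); stratified percentile bootstrap for the AUC, the
Youden index (re-maximizing the cut-off in each replicate by default)
and the likelihood ratios.  AUC comparisons between two markers measured
on the same subjects use a paired bootstrap: one resample of subjects
drives both curves, and the observed difference is standardized by the
bootstrap standard deviation of the differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .markers import HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE

_ORIENTATIONS = (HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE)


# ---------------------------------------------------------------------------
# ROC construction

@dataclass
class RocCurve:
    """Empirical ROC: per-threshold sensitivity/specificity pairs.

    ``thresholds`` are the sorted unique observed scores plus one
    infinite sentinel so the curve reaches both (se, sp) = (1, 0) and
    (0, 1).  The unique values and per-class counts are retained for
    cut-off search and bootstrap resampling.
    """

    thresholds: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    orientation: str
    n_pos: int
    n_neg: int
    values: np.ndarray = field(repr=False, default=None)
    pos_counts: np.ndarray = field(repr=False, default=None)
    neg_counts: np.ndarray = field(repr=False, default=None)


def _tabulate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    values = np.unique(scores)
    idx = np.searchsorted(values, scores)
    pos_counts = np.bincount(idx[labels], minlength=values.size)
    neg_counts = np.bincount(idx[~labels], minlength=values.size)
    return values, pos_counts, neg_counts


def _se_sp_at_values(pos_counts, neg_counts, orientation):
    """Se/Sp at each unique value used as the positivity threshold.

    Works on 1-d count vectors or on (B, U) matrices of bootstrap counts;
    the threshold axis is the last one.
    """
    n_pos = pos_counts.sum(axis=-1, keepdims=True)
    n_neg = neg_counts.sum(axis=-1, keepdims=True)
    cpos = np.cumsum(pos_counts, axis=-1)
    cneg = np.cumsum(neg_counts, axis=-1)
    if orientation == HIGHER_IS_POSITIVE:
        # score >= t positive; exclusive cumulative = count strictly below t
        se = (n_pos - (cpos - pos_counts)) / n_pos
        sp = (cneg - neg_counts) / n_neg
    elif orientation == LOWER_IS_POSITIVE:
        se = cpos / n_pos
        sp = (n_neg - cneg) / n_neg
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return se, sp


def empirical_roc(scores, labels, orientation: str = HIGHER_IS_POSITIVE) -> RocCurve:
    """Build the exact empirical ROC curve.

    For ``higher_is_positive`` a threshold t classifies score >= t as
    positive; for ``lower_is_positive``, score <= t.  Both classes must
    be present.
    """
    values, pos_counts, neg_counts = _tabulate(scores, labels)
    n_pos, n_neg = int(pos_counts.sum()), int(neg_counts.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both a positive and a negative label are required")
    se, sp = _se_sp_at_values(pos_counts, neg_counts, orientation)
    if orientation == HIGHER_IS_POSITIVE:
        thresholds = np.append(values, np.inf)   # t = +inf -> (0, 1)
        se = np.append(se, 0.0)
        sp = np.append(sp, 1.0)
    else:
        thresholds = np.append(-np.inf, values)  # t = -inf -> (0, 1)
        se = np.append(0.0, se)
        sp = np.append(1.0, sp)
    return RocCurve(thresholds=thresholds, se=se, sp=sp, orientation=orientation,
                    n_pos=n_pos, n_neg=n_neg, values=values,
                    pos_counts=pos_counts, neg_counts=neg_counts)


def _auc_from_counts(pos_counts, neg_counts, orientation):
    """Mann-Whitney AUC (ties 1/2) from per-value class counts.

    Vectorized over leading axes; the value axis is the last one.
    Exact integer arithmetic: twice the concordance count is an integer.
    """
    pos_counts = np.asarray(pos_counts, dtype=np.int64)
    neg_counts = np.asarray(neg_counts, dtype=np.int64)
    n_pos = pos_counts.sum(axis=-1)
    n_neg = neg_counts.sum(axis=-1)
    cneg = np.cumsum(neg_counts, axis=-1)
    # negatives strictly below value j = cneg_j - n_j, so with half-ties
    # 2*conc = 2*sum(p*cneg) - sum(p*n); "above" is the mirror image.
    pc = 2 * np.einsum("...j,...j->...", pos_counts, cneg)
    pn = np.einsum("...j,...j->...", pos_counts, neg_counts)
    if orientation == HIGHER_IS_POSITIVE:
        twice_conc = pc - pn
    elif orientation == LOWER_IS_POSITIVE:
        twice_conc = 2 * n_pos * n_neg - pc + pn
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return twice_conc / (2.0 * n_pos * n_neg)


def auc(roc: RocCurve) -> float:
    """Trapezoidal area over (1 - sp, se); equals Mann-Whitney with ties 1/2.

    Integrates along the curve in threshold order (se and fpr are jointly
    monotone there), so tied scores contribute diagonal segments whose
    trapezoids implement the half-credit tie convention exactly.
    """
    return float(abs(np.trapezoid(roc.se, 1.0 - roc.sp)))


def optimal_cutoff(roc: RocCurve) -> tuple[float, float, float]:
    """Observed-value threshold maximizing Se + Sp - 1.

    Ties are broken toward the smallest threshold for
    ``higher_is_positive`` (maximal sensitivity among tied cut-offs) and
    the largest for ``lower_is_positive``.  Exact integer arithmetic on
    the confusion counts avoids float ties being broken arbitrarily.
    """
    se, sp = _se_sp_at_values(roc.pos_counts, roc.neg_counts, roc.orientation)
    # yi ~ tp * n_neg + tn * n_pos, an integer score sharing the argmax
    tp = np.rint(se * roc.n_pos).astype(np.int64)
    tn = np.rint(sp * roc.n_neg).astype(np.int64)
    score = tp * roc.n_neg + tn * roc.n_pos
    if roc.orientation == HIGHER_IS_POSITIVE:
        best = int(np.argmax(score))               # first (smallest) maximizer
    else:
        best = int(score.size - 1 - np.argmax(score[::-1]))  # last maximizer
    return float(roc.values[best]), float(se[best]), float(sp[best])


# ---------------------------------------------------------------------------
# Confusion counts and accuracy measures

@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 table; fractional counts are tolerated for identity checks."""

    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def n_pos(self) -> float:
        return self.tp + self.fn

    @property
    def n_neg(self) -> float:
        return self.tn + self.fp


def confusion_at(scores, labels, cutoff: float,
                 orientation: str = HIGHER_IS_POSITIVE) -> ConfusionCounts:
    """Count the 2x2 table at a cut-off under the orientation's rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if orientation == HIGHER_IS_POSITIVE:
        called = scores >= cutoff
    elif orientation == LOWER_IS_POSITIVE:
        called = scores <= cutoff
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return ConfusionCounts(
        tp=int(np.sum(called & labels)),
        fp=int(np.sum(called & ~labels)),
        tn=int(np.sum(~called & ~labels)),
        fn=int(np.sum(~called & labels)),
    )


@dataclass
class AccuracyReport:
    """One table row: cut-off, AUC, Se/Sp/PPV/NPV/LRs/Youden with 95% CIs.

    Se, Sp, PPV, NPV and the Youden index are on the percent scale; the
    likelihood ratios are plain ratios and the AUC a proportion.  CI
    fields are (lower, upper) tuples or ``None`` when not computed.
    """

    cutoff: Optional[float] = None
    orientation: str = HIGHER_IS_POSITIVE
    auc: Optional[float] = None
    se: float = math.nan
    sp: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    lrp: float = math.nan
    lrn: float = math.nan
    yi: float = math.nan
    auc_ci: Optional[tuple[float, float]] = None
    se_ci: Optional[tuple[float, float]] = None
    sp_ci: Optional[tuple[float, float]] = None
    ppv_ci: Optional[tuple[float, float]] = None
    npv_ci: Optional[tuple[float, float]] = None
    lrp_ci: Optional[tuple[float, float]] = None
    lrn_ci: Optional[tuple[float, float]] = None
    yi_ci: Optional[tuple[float, float]] = None
    n_pos: int = 0
    n_neg: int = 0
    counts: Optional[ConfusionCounts] = None


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def accuracy_measures(counts: ConfusionCounts, cutoff: Optional[float] = None,
                      orientation: str = HIGHER_IS_POSITIVE) -> AccuracyReport:
    """Point estimates from a 2x2 table.

    Undefined ratios (empty predicted class, Sp at a boundary) become
    inf/nan rather than raising; they are legitimate degenerate outputs.
    """
    if counts.n_pos <= 0 or counts.n_neg <= 0:
        raise ValueError("both classes must be non-empty")
    se = counts.tp / counts.n_pos
    sp = counts.tn / counts.n_neg
    return AccuracyReport(
        cutoff=cutoff,
        orientation=orientation,
        se=100.0 * se,
        sp=100.0 * sp,
        ppv=100.0 * _ratio(counts.tp, counts.tp + counts.fp),
        npv=100.0 * _ratio(counts.tn, counts.tn + counts.fn),
        lrp=_ratio(se, 1.0 - sp),
        lrn=_ratio(1.0 - se, sp),
        yi=100.0 * (se + sp - 1.0),
        n_pos=int(round(counts.n_pos)),
        n_neg=int(round(counts.n_neg)),
        counts=counts,
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI from beta quantiles; k=0 pins lower=0, k=n upper=1."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper


# ---------------------------------------------------------------------------
# Bootstrap

def _resample_class_counts(pos_counts, neg_counts, B, rng):
    """B stratified resamples, as per-value count matrices (B, U).

    Drawing subject indices and re-tabulating with one flat bincount is
    equivalent in distribution to a multinomial over the per-value
    empirical frequencies, and markedly faster on wide count vectors.
    """
    U = pos_counts.size

    def draw(counts):
        n = int(counts.sum())
        bins = np.repeat(np.arange(U, dtype=np.int64), counts)
        idx = rng.integers(0, n, size=(B, n))
        flat = bins[idx] + np.arange(B, dtype=np.int64)[:, None] * U
        return np.bincount(flat.ravel(), minlength=B * U).reshape(B, U)

    return draw(pos_counts), draw(neg_counts)


def _bootstrap_replicates(roc: RocCurve, B: int, rng, refit_cutoff: bool = True,
                          fixed_cutoff: Optional[float] = None):
    """Per-replicate AUC and (se, sp) at the Youden-optimal cut-off.

    Stratified: positives and negatives are resampled separately.
    Integer arithmetic throughout the (B, U) matrices: the Youden
    maximizer of a replicate is the argmax of tp*N + tn*P, an exact
    integer score.  Returns (auc_b, se_b, sp_b) arrays of length B.
    """
    bp, bn = _resample_class_counts(roc.pos_counts, roc.neg_counts, B, rng)
    auc_b = _auc_from_counts(bp, bn, roc.orientation)
    n_pos, n_neg = roc.n_pos, roc.n_neg
    cpos = np.cumsum(bp, axis=1)
    cneg = np.cumsum(bn, axis=1)
    if roc.orientation == HIGHER_IS_POSITIVE:
        tp_mat = n_pos - (cpos - bp)   # positives at or above each value
        tn_mat = cneg - bn             # negatives strictly below
    else:
        tp_mat = cpos
        tn_mat = n_neg - cneg
    if refit_cutoff:
        best = np.argmax(tp_mat * n_neg + tn_mat * n_pos, axis=1)
    else:
        best = np.full(B, int(np.searchsorted(roc.values, fixed_cutoff)))
    rows = np.arange(B)
    se_b = tp_mat[rows, best] / n_pos
    sp_b = tn_mat[rows, best] / n_neg
    return auc_b, se_b, sp_b


def _percentile(samples, level):
    alpha = 1.0 - level
    with np.errstate(invalid="ignore"):  # inf replicates (degenerate LRs) are fine
        lo, hi = np.quantile(samples, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _interval(samples, level, method="percentile", theta=None):
    """Percentile or basic (reverse-percentile) bootstrap interval.

    The basic interval 2*theta - q reverses the replicate quantiles
    around the point estimate, correcting first-order bias — material
    for the re-maximized Youden index, whose cut-off selection biases
    the replicates upward.
    """
    lo, hi = _percentile(samples, level)
    if method == "percentile":
        return lo, hi
    if method == "basic":
        if theta is None:
            raise ValueError("the basic interval needs the point estimate")
        return 2.0 * theta - hi, 2.0 * theta - lo
    raise ValueError(f"unknown interval method {method!r}")


def bootstrap_youden_ci(scores, labels, orientation: str = HIGHER_IS_POSITIVE,
                        B: int = 2000, seed: Optional[int] = None,
                        level: float = 0.95, refit_cutoff: bool = True,
                        method: str = "basic") -> tuple[float, float]:
    """Bootstrap CI for the (re-maximized) Youden index, percent scale.

    Each of the B stratified resamples re-runs the cut-off search, so the
    interval targets the maximal Youden index.  The default basic
    interval counteracts the upward selection bias of re-maximization
    (plain percentile intervals under-cover by several points here);
    ``method="percentile"`` is available.  Deterministic given seed.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if seed is None:
        raise ValueError("a seed is required for bootstrap reproducibility")
    roc = empirical_roc(scores, labels, orientation)
    cutoff, se, sp = optimal_cutoff(roc)
    rng = np.random.default_rng(seed)
    _, se_b, sp_b = _bootstrap_replicates(
        roc, B, rng, refit_cutoff, None if refit_cutoff else cutoff)
    theta = 100.0 * (se + sp - 1.0)
    return _interval(100.0 * (se_b + sp_b - 1.0), level, method, theta)


@dataclass(frozen=True)
class AucComparison:
    """Paired-bootstrap comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    delta_auc: float
    p_value: float
    boot_sd: float
    degenerate: bool = False


def compare_auc_paired_bootstrap(scores_a, scores_b, labels,
                                 orientations: Sequence[str] = (HIGHER_IS_POSITIVE, HIGHER_IS_POSITIVE),
                                 B: int = 2000, seed: Optional[int] = None) -> AucComparison:
    """Test AUC_a = AUC_b for two markers measured on the same subjects.

    One stratified index resample per replicate drives both markers; the
    observed difference is standardized by the bootstrap SD of the
    differences and referred to the standard normal (two-sided).
    """
    if seed is None:
        raise ValueError("a seed is required for bootstrap reproducibility")
    orient_a, orient_b = orientations
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("paired comparison requires equal-length score and label vectors")

    va, pa, na = _tabulate(scores_a, labels)
    vb, pb, nb = _tabulate(scores_b, labels)
    if pa.sum() == 0 or na.sum() == 0:
        raise ValueError("both a positive and a negative label are required")
    auc_a = float(_auc_from_counts(pa, na, orient_a))
    auc_b = float(_auc_from_counts(pb, nb, orient_b))
    delta = auc_a - auc_b

    # per-subject bin index into each marker's unique-value axis
    bins_a = np.searchsorted(va, scores_a)
    bins_b = np.searchsorted(vb, scores_b)
    pos_a, neg_a = bins_a[labels], bins_a[~labels]
    pos_b, neg_b = bins_b[labels], bins_b[~labels]
    n_pos, n_neg = pos_a.size, neg_a.size

    rng = np.random.default_rng(seed)
    diffs = np.empty(B)
    for r in range(B):
        ip = rng.integers(0, n_pos, n_pos)
        im = rng.integers(0, n_neg, n_neg)
        ra = _auc_from_counts(np.bincount(pos_a[ip], minlength=va.size),
                              np.bincount(neg_a[im], minlength=va.size), orient_a)
        rb = _auc_from_counts(np.bincount(pos_b[ip], minlength=vb.size),
                              np.bincount(neg_b[im], minlength=vb.size), orient_b)
        diffs[r] = ra - rb

    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        if delta == 0.0:
            return AucComparison(auc_a, auc_b, 0.0, 1.0, 0.0)
        return AucComparison(auc_a, auc_b, delta, 0.0, 0.0, degenerate=True)
    z = delta / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(auc_a, auc_b, delta, p, sd)


def evaluate_marker(scores, labels, orientation: str = HIGHER_IS_POSITIVE,
                    B: int = 2000, seed: Optional[int] = None,
                    level: float = 0.95, refit_cutoff: bool = True) -> AccuracyReport:
    """Full accuracy report for one marker against one label set.

    Composes ROC -> AUC -> Youden cut-off -> confusion counts -> accuracy
    measures.  Clopper-Pearson CIs for Se (n = positives), Sp
    (n = negatives), PPV (n = called positive), NPV (n = called
    negative); percentile-bootstrap CIs for the AUC, the Youden index and
    the likelihood ratios.  Pass ``B=0`` to skip the bootstrap.
    """
    roc = empirical_roc(scores, labels, orientation)
    cutoff, _, _ = optimal_cutoff(roc)
    counts = confusion_at(scores, labels, cutoff, orientation)
    report = accuracy_measures(counts, cutoff=cutoff, orientation=orientation)
    report.auc = auc(roc)

    def cp_pct(k, n):
        if n == 0:
            return None
        lo, hi = clopper_pearson(int(k), int(n), level)
        return 100.0 * lo, 100.0 * hi

    report.se_ci = cp_pct(counts.tp, counts.n_pos)
    report.sp_ci = cp_pct(counts.tn, counts.n_neg)
    report.ppv_ci = cp_pct(counts.tp, counts.tp + counts.fp)
    report.npv_ci = cp_pct(counts.tn, counts.tn + counts.fn)

    if B:
        if seed is None:
            raise ValueError("a seed is required for bootstrap reproducibility")
        rng = np.random.default_rng(seed)
        auc_b, se_b, sp_b = _bootstrap_replicates(
            roc, B, rng, refit_cutoff, None if refit_cutoff else cutoff)
        report.auc_ci = _percentile(auc_b, level)
        report.yi_ci = _interval(100.0 * (se_b + sp_b - 1.0), level,
                                 method="basic", theta=report.yi)
        with np.errstate(divide="ignore", invalid="ignore"):
            lrp_b = se_b / (1.0 - sp_b)
            lrn_b = (1.0 - se_b) / sp_b
        report.lrp_ci = _percentile(lrp_b, level)
        report.lrn_ci = _percentile(lrn_b, level)
    return report
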