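"""Statistics layer: group comparisons, ROC, cutoffs, grading, interobserver.

Implements the analysis battery for fractal-dimension grading of prostate
cancer: Kruskal-Wallis and Bonferroni-corrected pairwise Mann-Whitney tests,
linear FD-to-grade correlation, dichotomized ROC with stratified bootstrap
confidence intervals, efficiency-based cutoff selection
(Ef(c) = p*Se(c) + (1-p)*Sp(c)), pooled-grade classification by an FD cutoff
table, Hand-Till multiclass AUC, paired-bootstrap AUC comparison, and
interobserver agreement (Cohen's kappa on banded grades, Bland-Altman on raw
FD).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import cohen_kappa_score, roc_curve

__all__ = ["CutoffTable", "RocResult", "LesionRecord", "group_tests",
           "linear_correlation", "roc_dichotomized", "efficiency_cutoff",
           "classify_grade", "multiclass_auc", "compare_auc", "interobserver",
           "DEFAULT_CUTOFFS"]


@dataclass(frozen=True)
class LesionRecord:
    """One lesion: margin FD statistic, comparator ADC, truth and prediction."""

    lesion_id: str
    fd_margin: float
    adc_q25: float | None = None  # 1e-6 mm^2/s
    isup_group: int | None = None
    predicted_pool: str | None = None
    zone: str = "unknown"

    def __post_init__(self) -> None:
        if not (2.0 <= self.fd_margin <= 3.0):
            raise ValueError("fd_margin must lie in [2, 3]")
        if self.isup_group is not None and self.isup_group not in range(1, 6):
            raise ValueError("isup_group must be in 1..5")
        if self.zone not in ("peripheral", "transitional", "unknown"):
            raise ValueError(f"unknown zone {self.zone!r}")


@dataclass(frozen=True)
class CutoffTable:
    """Three increasing FD thresholds banding [2, 3] into pooled ISUP groups.

    fd < c1 -> group 1; c1 <= fd < c2 -> group 2; c2 <= fd < c3 -> group 3;
    fd >= c3 -> groups 4-5 (closed-left convention: a value exactly on a
    threshold belongs to the higher band).
    """

    thresholds: tuple[float, float, float] = (2.20, 2.31, 2.40)

    def __post_init__(self) -> None:
        c1, c2, c3 = self.thresholds
        if not c1 < c2 < c3:
            raise ValueError("cutoffs must be strictly increasing")

    _LABELS = ("group 1", "group 2", "group 3", "groups 4-5")

    def band(self, fd: float) -> int:
        """Numeric band 1..4 (band 4 pools ISUP groups 4 and 5)."""
        if not (2.0 <= fd <= 3.0):
            raise ValueError(f"fd {fd} outside the admissible range [2, 3]")
        return 1 + int(np.searchsorted(np.asarray(self.thresholds), fd,
                                       side="right"))

    def label(self, fd: float) -> str:
        return self._LABELS[self.band(fd) - 1]


#: Discovery-cohort efficiency cutoffs for 1 vs 2-5, 1-2 vs 3-5, 1-3 vs 4-5.
DEFAULT_CUTOFFS = CutoffTable((2.20, 2.31, 2.40))


def classify_grade(fd: float, table: CutoffTable = DEFAULT_CUTOFFS) -> int:
    """Pooled ISUP grade-group band (1, 2, 3 or 4 = "groups 4-5") for an FD value."""
    return table.band(fd)


@dataclass
class RocResult:
    """Dichotomized ROC summary with bootstrap CI and cutoff operating point."""

    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    tp: int
    n_pos: int
    tn: int
    n_neg: int
    cutoff: float
    split: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.auc <= 1.0
        assert self.ci_low <= self.auc + 1e-12 and self.auc <= self.ci_high + 1e-12
        assert abs(self.sensitivity - self.tp / self.n_pos) < 1e-9
        assert abs(self.specificity - self.tn / self.n_neg) < 1e-9


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([{"lesion_id": r.lesion_id, "fd_margin": r.fd_margin,
                          "adc_q25": r.adc_q25, "isup_group": r.isup_group}
                         for r in records])


def group_tests(fd_by_group: pd.DataFrame, *, fd_col: str = "fd",
                group_col: str = "group") -> dict:
    """Kruskal-Wallis plus Bonferroni-corrected pairwise Mann-Whitney tests.

    Returns a dict with the omnibus H and p, per-group medians and IQRs, and a
    table of pairwise two-sided U tests with Bonferroni-adjusted p values (the
    family is all pairs tested in this call). Groups with fewer than 2
    observations are excluded from pairwise testing with a warning.
    """
    df = fd_by_group
    groups = {g: sub[fd_col].to_numpy(dtype=float)
              for g, sub in df.groupby(group_col, sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    H, p = stats.kruskal(*groups.values())
    summary = {g: {"n": len(v), "median": float(np.median(v)),
                   "iqr": float(np.subtract(*np.percentile(v, [75, 25])))}
               for g, v in groups.items()}
    testable = [g for g, v in groups.items() if len(v) >= 2]
    skipped = sorted(set(groups) - set(testable))
    if skipped:
        warnings.warn(f"groups excluded from pairwise tests (n < 2): {skipped}")
    pairs = list(combinations(testable, 2))
    rows = []
    for a, b in pairs:
        u, praw = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "U": float(u),
                     "p_raw": float(praw),
                     "p_adjusted": float(min(1.0, praw * len(pairs)))})
    return {"kruskal_H": float(H), "kruskal_p": float(p),
            "groups": summary, "pairwise": pd.DataFrame(rows)}


def linear_correlation(fd_by_group: pd.DataFrame, *, fd_col: str = "fd",
                       group_col: str = "group") -> tuple[float, float]:
    """Ordinary least squares of FD on the (numeric) group index: (r^2, p)."""
    x = fd_by_group[group_col].to_numpy(dtype=float)
    y = fd_by_group[fd_col].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct group values")
    if np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
        raise ValueError("degenerate variance")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue)


def _empirical_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(_sk_auc(fpr, tpr))


def roc_dichotomized(records, split: int, *, n_boot: int = 2000,
                     seed: int = 0, score_col: str = "fd_margin") -> RocResult:
    """ROC of FD for a pooled-grade dichotomy (positive: isup_group >= split).

    Higher FD marks the higher-grade pool. AUC is the trapezoidal area under
    the empirical ROC; the 95% CI comes from a stratified percentile bootstrap
    (resampling positives and negatives separately); sensitivity and
    specificity (with counts) are reported at the efficiency cutoff using the
    sample prevalence.
    """
    df = _records_frame(records)
    y = (df["isup_group"].to_numpy() >= split).astype(int)
    x = df[score_col].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both pools must be nonempty for ROC analysis")
    a = _empirical_auc(x, y)
    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    if n_boot > 0:
        boots = np.empty(n_boot)
        for i in range(n_boot):
            idx = np.concatenate([rng.choice(pos, len(pos)),
                                  rng.choice(neg, len(neg))])
            boots[i] = _empirical_auc(x[idx], y[idx])
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:  # point estimate only
        lo = hi = a
    c = efficiency_cutoff(x, y)
    tp = int(np.sum(x[y == 1] >= c))
    tn = int(np.sum(x[y == 0] < c))
    return RocResult(auc=a, ci_low=float(min(lo, a)), ci_high=float(max(hi, a)),
                     sensitivity=tp / len(pos), specificity=tn / len(neg),
                     tp=tp, n_pos=len(pos), tn=tn, n_neg=len(neg),
                     cutoff=float(c), split=f"{'1' if split == 2 else f'1-{split-1}'} vs {split}-5")


def efficiency_cutoff(fd_values, binary_labels, prevalence: float | None = None
                      ) -> float:
    """Cutoff maximizing Ef(c) = p*Se(c) + (1-p)*Sp(c).

    Candidates are midpoints between adjacent distinct sorted scores (a value
    at or above the cutoff is called positive). ``prevalence`` defaults to the
    sample prevalence of the positive pool; ties in Ef break toward the lower
    cutoff.
    """
    x = np.asarray(fd_values, dtype=float)
    y = np.asarray(binary_labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    p = float(np.mean(y)) if prevalence is None else float(prevalence)
    uniq = np.unique(x)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    best_c, best_ef = None, -np.inf
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    for c in cands:
        se = np.sum((x >= c) & (y == 1)) / n_pos
        sp = np.sum((x < c) & (y == 0)) / n_neg
        ef = p * se + (1 - p) * sp
        if ef > best_ef + 1e-12:
            best_ef, best_c = ef, float(c)
    return best_c


def multiclass_auc(records, *, n_boot: int = 2000, seed: int = 0,
                   score_col: str = "fd_margin", method: str = "hand-till"
                   ) -> tuple[float, tuple[float, float]]:
    """Multiclass AUC as the mean of pairwise one-vs-one AUCs (Hand-Till M).

    With a single scalar score, A(i|j) = 1 - A(j|i), so the Hand-Till average
    reduces to the plain mean of pairwise AUCs over unordered class pairs.
    ``method="one-vs-rest"`` averages each class against all others instead.
    The CI is a percentile bootstrap over lesions, seeded. Class pairs where a
    class has fewer than 2 members are excluded with a warning.
    """
    df = _records_frame(records)
    y = df["isup_group"].to_numpy()
    x = df[score_col].to_numpy(dtype=float)

    def _m(xv: np.ndarray, yv: np.ndarray, warn: bool = False) -> float:
        classes, counts = np.unique(yv, return_counts=True)
        ok = classes[counts >= 2]
        if warn and len(ok) < len(classes):
            warnings.warn(f"classes with < 2 members excluded: "
                          f"{sorted(set(classes) - set(ok))}")
        aucs = []
        if method == "hand-till":
            for a, b in combinations(ok, 2):
                sel = (yv == a) | (yv == b)
                aucs.append(_empirical_auc(xv[sel], (yv[sel] == max(a, b)).astype(int)))
        elif method == "one-vs-rest":
            for a in ok:
                hi = (yv >= a)
                if 0 < hi.sum() < len(yv):
                    aucs.append(_empirical_auc(xv, hi.astype(int)))
        else:
            raise ValueError(f"unknown method {method!r}")
        if not aucs:
            raise ValueError("no class pair with >= 2 members per class")
        return float(np.mean(aucs))

    point = _m(x, y, warn=True)
    if n_boot == 0:
        return point, (point, point)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        if len(np.unique(y[idx])) < 2:
            continue
        try:
            boots.append(_m(x[idx], y[idx]))
        except ValueError:
            continue
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, (float(lo), float(hi))


def compare_auc(records, *, score_a: str = "fd_margin", score_b: str = "adc_q25",
                split: int = 2, n_boot: int = 2000, seed: int = 0,
                b_orientation: str = "lower-positive") -> dict:
    """Paired-bootstrap test for a difference in dichotomized AUC of two scores.

    Both scores must be measured on the same lesions; resampling is paired.
    For ADC the orientation is lower-ADC => positive class, so the comparator
    AUC is computed on the negated score. Returns the two AUCs, the observed
    difference and a two-sided bootstrap p value.
    """
    df = _records_frame(records)
    if df[score_a].isna().any() or df[score_b].isna().any():
        raise ValueError("paired comparison requires both scores on every lesion")
    y = (df["isup_group"].to_numpy() >= split).astype(int)
    xa = df[score_a].to_numpy(dtype=float)
    xb = df[score_b].to_numpy(dtype=float)
    if b_orientation == "lower-positive":
        xb = -xb
    auc_a, auc_b = _empirical_auc(xa, y), _empirical_auc(xb, y)
    delta = auc_a - auc_b
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(y), len(y))
        if y[idx].min() == y[idx].max():
            continue
        deltas.append(_empirical_auc(xa[idx], y[idx]) - _empirical_auc(xb[idx], y[idx]))
    deltas = np.asarray(deltas)
    # two-sided p: twice the smaller tail of the bootstrap difference about 0
    p_low = (np.sum(deltas <= 0) + 1) / (len(deltas) + 1)
    p_high = (np.sum(deltas >= 0) + 1) / (len(deltas) + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return {"auc_a": auc_a, "auc_b": auc_b, "delta": delta, "p": float(p)}


def interobserver(fd_reader1, fd_reader2,
                  grade_table: CutoffTable = DEFAULT_CUTOFFS) -> dict:
    """Interobserver agreement: Cohen's kappa on banded grades, Bland-Altman on FD.

    Kappa is computed on the pooled-grade bands each reader's FD maps to via
    ``classify_grade``; bias is mean(reader2 - reader1) and the limits of
    agreement are bias +/- 1.96 * SD of the differences.
    """
    r1 = np.asarray(fd_reader1, dtype=float)
    r2 = np.asarray(fd_reader2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("reader measurement lengths differ")
    b1 = [classify_grade(v, grade_table) for v in r1]
    b2 = [classify_grade(v, grade_table) for v in r2]
    if b1 == b2:
        kappa = 1.0  # identical band assignments (kappa's 0/0 limit)
    else:
        kappa = float(cohen_kappa_score(b1, b2))
    diff = r2 - r1
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    return {"kappa": kappa, "bias": bias,
            "loa": (bias - 1.96 * sd, bias + 1.96 * sd)}
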