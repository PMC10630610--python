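"""Outcome localisation statistics.

The inferential core of the analysis: the resected-versus-spared
distinguishability statistic D_RS (a normalised Mann-Whitney U over
regional abnormality scores), SVM separability of the 2-D abnormality
scatter, the two-cut decision tree over per-patient (D_RS^conn,
D_RS^iEEG) pairs with leave-one-out cross-validation, and the 2x2
contingency machinery (Yates-corrected chi-square, odds ratio with Wald
confidence interval, exact binomial test).

Conventions fixed here for reproducibility:

* D_RS ties get 0.5 credit (standard Mann-Whitney convention).
* D_RS = 0 means the largest abnormality scores are all in resected
  regions; 1 means all in spared regions.
* The SVM is a linear hard-margin classifier (C = 1e6, no feature
  scaling); "separable" means 100% training accuracy.  The probe point
  for the maximal-abnormality call is the componentwise maximum of the
  patient's observed scores.
* Chi-square tests on 2x2 tables use the Yates continuity correction,
  clamped at zero.
* The odds-ratio confidence interval is the Wald (log-scale normal)
  interval; the Haldane-Anscombe +0.5 correction is applied only when a
  zero cell appears.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.optimize import linprog
from sklearn.svm import SVC

__all__ = [
    "TwoByTwoTable",
    "TwoCutTree",
    "PatientOutcomeRecord",
    "TendencyReport",
    "compute_drs",
    "svm_separability",
    "classify_tendency",
    "odds_ratio_ci",
    "yates_chi_square",
    "exact_binomial_p",
    "outcome_auc",
    "fit_two_cut_tree",
    "loocv_tree",
    "rank_regions_for_implantation",
]

SEIZURE_FREE_ILAE_MAX = 2  # ILAE 1-2 = good outcome


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class TwoByTwoTable:
    """2x2 contingency table; rows = exposure, columns = outcome."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class TwoCutTree:
    """Axis-aligned decision tree with exactly one cut per modality.

    The root cut is on ``root_axis`` at ``root_threshold``; the branch
    named by ``split_branch`` ("low" = values < threshold) is refined by a
    second cut on the other modality at ``child_threshold``.  Leaf labels
    are booleans (True = seizure-free).
    """

    root_axis: str  # "conn" | "ieeg"
    root_threshold: float
    child_axis: str
    child_threshold: float
    split_branch: str  # "low" | "high"
    leaf_other: bool  # label of the unsplit root branch
    leaf_low: bool  # label of split-branch side below child threshold
    leaf_high: bool
    training_accuracy: float

    def predict_one(self, conn: float, ieeg: float) -> bool:
        x = {"conn": conn, "ieeg": ieeg}
        side = "low" if x[self.root_axis] < self.root_threshold else "high"
        if side != self.split_branch:
            return self.leaf_other
        return self.leaf_low if x[self.child_axis] < self.child_threshold else self.leaf_high

    def predict(self, points: Sequence[tuple[float, float]]) -> list[bool]:
        return [self.predict_one(c, i) for c, i in points]


@dataclass
class PatientOutcomeRecord:
    """Per-patient summary feeding the cohort-level analyses."""

    patient_id: str
    drs_conn: float | None
    drs_ieeg: float | None
    separable: bool | None
    maximal_resected: str  # "resected" | "spared" | "undefined"
    ilae: int
    extras: dict = field(default_factory=dict)

    @property
    def seizure_free(self) -> bool:
        return self.ilae <= SEIZURE_FREE_ILAE_MAX

    def __post_init__(self) -> None:
        for v, name in ((self.drs_conn, "drs_conn"), (self.drs_ieeg, "drs_ieeg")):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.maximal_resected not in ("resected", "spared", "undefined"):
            raise ValueError(f"bad maximal_resected: {self.maximal_resected}")
        if self.separable and self.maximal_resected == "undefined":
            raise ValueError("separable patients must carry a maximal-abnormality call")


# ---------------------------------------------------------------------------
# D_RS and AUC


def _pairwise_greater_fraction(x: np.ndarray, y: np.ndarray) -> float:
    """Fraction of (xi, yj) pairs with xi > yj; ties count 0.5."""
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def compute_drs(scores: Sequence[float], resected: Sequence[bool]) -> float:
    """Distinguishability of resected vs spared regional abnormality scores.

    Normalised Mann-Whitney U over all (resected, spared) region pairs:
    the fraction of pairs in which the spared region scores *higher*,
    ties credited 0.5.  0 means the largest abnormalities are all
    resected; 1 means they are all spared.  Equals 1 - AUC with resected
    as the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    resected = np.asarray(resected, dtype=bool)
    if scores.shape != resected.shape or scores.ndim != 1:
        raise ValueError("scores and resected flags must be 1-D and aligned")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite abnormality score")
    r, s = scores[resected], scores[~resected]
    if r.size == 0 or s.size == 0:
        raise ValueError("D_RS undefined: need at least one resected and one spared region")
    return _pairwise_greater_fraction(s, r)


def outcome_auc(drs_values: Sequence[float], seizure_free: Sequence[bool]) -> tuple[float, float]:
    """Separation of outcome groups by per-patient D_RS.

    Returns (AUC, two-sided Mann-Whitney p).  AUC > 0.5 means
    seizure-free patients have *lower* D_RS than non-seizure-free
    patients (shares the pairwise 0.5-tie kernel with :func:`compute_drs`).
    """
    drs_values = np.asarray(drs_values, dtype=float)
    seizure_free = np.asarray(seizure_free, dtype=bool)
    sf, nsf = drs_values[seizure_free], drs_values[~seizure_free]
    if sf.size == 0 or nsf.size == 0:
        raise ValueError("AUC undefined: both outcome groups must be non-empty")
    auc = _pairwise_greater_fraction(nsf, sf)
    p = sps.mannwhitneyu(sf, nsf, alternative="two-sided", method="asymptotic").pvalue
    return auc, float(p)


# ---------------------------------------------------------------------------
# SVM separability


def _strictly_separable(pts: np.ndarray, y: np.ndarray) -> bool:
    """Exact linear-separability check via an LP feasibility problem.

    Feasible iff some (w, b) satisfies y_i (w.x_i + b) >= 1 for all i,
    which (by scaling) is equivalent to strict linear separability.
    Screening with the LP keeps the hard-margin SVM fit off the
    overlapping cases it converges slowly on.
    """
    s = np.where(y, 1.0, -1.0)
    # variables (w1, w2, b), unbounded; constraints -s*(x.w + b) <= -1
    a_ub = -s[:, None] * np.column_stack([pts, np.ones(len(s))])
    res = linprog(
        c=np.zeros(3),
        A_ub=a_ub,
        b_ub=-np.ones(len(s)),
        bounds=[(None, None)] * 3,
        method="highs",
    )
    return res.status == 0


def svm_separability(
    points: Sequence[tuple[float, float]], resected: Sequence[bool]
) -> tuple[bool, str]:
    """Can a line split the (ieeg, conn) abnormality scatter into zones?

    Fits a linear maximum-margin SVM to the 2-D per-region points.
    "Separable" requires 100% training accuracy.  If separable, the
    maximal-abnormality probe (componentwise max of the observed scores,
    the top-right of the scatter) is classified; the returned string is
    "resected" or "spared" accordingly, or "undefined" when the classes
    overlap or are too small.
    """
    pts = np.asarray(points, dtype=float)
    y = np.asarray(resected, dtype=bool)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] != y.size:
        raise ValueError("points must be (n, 2) aligned with resected flags")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need >=2 resected and >=2 spared regions with both scores")
    # identical point in both classes can never be split
    dup = {tuple(p) for p in pts[y]} & {tuple(p) for p in pts[~y]}
    if dup:
        return False, "undefined"
    if not _strictly_separable(pts, y):
        return False, "undefined"
    clf = SVC(kernel="linear", C=1e6)
    clf.fit(pts, y)
    if clf.score(pts, y) < 1.0:
        return False, "undefined"
    probe = pts.max(axis=0)
    maximal_resected = bool(clf.predict(probe[None, :])[0])
    return True, "resected" if maximal_resected else "spared"


# ---------------------------------------------------------------------------
# contingency machinery


def yates_chi_square(table: TwoByTwoTable) -> tuple[float, float]:
    """Chi-square test with Yates continuity correction on a 2x2 table.

    chi2 = n * (max(0, |ad - bc| - n/2))^2 / ((a+b)(c+d)(a+c)(b+d)),
    p from chi-square with 1 df.  The correction is clamped at zero.
    """
    a, b, c, d, n = table.a, table.b, table.c, table.d, table.n
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: zero marginal")
    num = max(0.0, abs(a * d - b * c) - n / 2.0)
    chi2 = n * num**2 / math.prod(margins)
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, p


def odds_ratio_ci(
    table: TwoByTwoTable, level: float = 0.95
) -> tuple[float, float, float]:
    """Cross-product odds ratio with a Wald (log-normal) confidence interval.

    A zero cell triggers the Haldane-Anscombe +0.5 correction on all
    cells, which also serves as the fallback for degenerate tables whose
    uncorrected odds ratio would be 0/0 or infinite.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + level / 2.0)
    lo, hi = math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)
    return or_, lo, hi


def exact_binomial_p(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p, doubling the smaller tail (capped at 1)."""
    if not 0 <= k <= n:
        raise ValueError("k outside [0, n]")
    lower = sps.binom.cdf(k, n, p)
    upper = sps.binom.sf(k - 1, n, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass(frozen=True)
class TendencyReport:
    """Cohort-level association of maximal-abnormality resection and outcome."""

    table: TwoByTwoTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    chi2_p: float
    n_separable: int
    n_nonseparable_sf: int
    n_nonseparable_nsf: int
    nonseparable_binomial_p: float | None


def classify_tendency(cohort: Sequence[PatientOutcomeRecord]) -> TendencyReport:
    """Cross-tabulate separable patients (maximal resected x seizure-free).

    Separable patients go into a 2x2 table (rows: maximal abnormality
    resected / spared; columns: seizure-free / not) tested with the
    odds ratio and Yates chi-square.  Non-separable patients are
    summarised with a two-sided exact binomial test of their outcome
    split against 0.5.
    """
    sep = [p for p in cohort if p.separable]
    if not sep:
        raise ValueError("no separable patients to tabulate")
    a = sum(p.maximal_resected == "resected" and p.seizure_free for p in sep)
    b = sum(p.maximal_resected == "resected" and not p.seizure_free for p in sep)
    c = sum(p.maximal_resected == "spared" and p.seizure_free for p in sep)
    d = sum(p.maximal_resected == "spared" and not p.seizure_free for p in sep)
    table = TwoByTwoTable(a, b, c, d)
    or_, lo, hi = odds_ratio_ci(table)
    try:
        chi2, chi2_p = yates_chi_square(table)
    except ValueError:
        chi2, chi2_p = float("nan"), float("nan")
    nonsep = [p for p in cohort if p.separable is False]
    n_sf = sum(p.seizure_free for p in nonsep)
    n_nsf = len(nonsep) - n_sf
    binom_p = exact_binomial_p(n_sf, len(nonsep)) if nonsep else None
    return TendencyReport(
        table=table,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        chi2=chi2,
        chi2_p=chi2_p,
        n_separable=len(sep),
        n_nonseparable_sf=n_sf,
        n_nonseparable_nsf=n_nsf,
        nonseparable_binomial_p=binom_p,
    )


# ---------------------------------------------------------------------------
# two-cut decision tree


def _cut_candidates(values: np.ndarray) -> list[float]:
    u = np.unique(values)
    if u.size < 2:
        return []
    return list((u[:-1] + u[1:]) / 2.0)


def _majority(labels: np.ndarray) -> bool:
    # ties and empty leaves default to seizure-free
    if labels.size == 0:
        return True
    n_true = int(labels.sum())
    return n_true * 2 >= labels.size


def fit_two_cut_tree(
    points: Sequence[tuple[float, float]], outcomes: Sequence[bool]
) -> TwoCutTree:
    """Exhaustive search for the best one-cut-per-modality tree.

    ``points`` are per-patient (drs_conn, drs_ieeg) pairs; ``outcomes``
    are seizure-free flags.  The search enumerates the root axis, root
    threshold (midpoints of sorted unique values), which root branch
    receives the second cut, and the child threshold on the other axis;
    leaves take majority labels (ties -> seizure-free).  Training
    accuracy is maximised; ties are broken by larger worst-case margin
    (min distance of any point to either threshold on its axis), then by
    lexicographic order of the configuration tuple.
    """
    pts = np.asarray(points, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] != y.size:
        raise ValueError("points must be (n, 2) aligned with outcomes")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least two patients per outcome group")
    axes = {"conn": pts[:, 0], "ieeg": pts[:, 1]}
    n = y.size
    best = None  # ((accuracy, margin, neg_lex_key), tree)
    for root_axis, child_axis in (("conn", "ieeg"), ("ieeg", "conn")):
        rv, cv = axes[root_axis], axes[child_axis]
        root_cands = _cut_candidates(rv)
        if not root_cands:
            # degenerate axis: only the other axis offers cuts
            continue
        for rt in root_cands:
            low = rv < rt
            root_margin = float(np.min(np.abs(rv - rt)))
            for split_branch, in_branch in (("low", low), ("high", ~low)):
                other = ~in_branch
                n_other_t = int(y[other].sum())
                n_other = int(other.sum())
                leaf_other = n_other_t * 2 >= n_other
                correct_other = n_other_t if leaf_other else n_other - n_other_t
                child_cands = _cut_candidates(cv[in_branch]) or _cut_candidates(cv)
                if not child_cands:
                    child_cands = [float(np.min(cv)) - 0.5]
                ct = np.asarray(child_cands)  # (m,)
                below = cv[in_branch, None] < ct[None, :]  # (n_in, m)
                y_in = y[in_branch]
                nb = below.sum(axis=0)
                tb = (below & y_in[:, None]).sum(axis=0)
                na = (~below).sum(axis=0)
                ta = (y_in[:, None] & ~below).sum(axis=0)
                leaf_low = tb * 2 >= nb
                leaf_high = ta * 2 >= na
                correct = (
                    correct_other
                    + np.where(leaf_low, tb, nb - tb)
                    + np.where(leaf_high, ta, na - ta)
                )
                acc = correct / n
                child_margin = np.abs(cv[:, None] - ct[None, :]).min(axis=0)
                margin = np.minimum(root_margin, child_margin)
                # best child candidate for this root config: accuracy, then
                # margin, then smaller threshold
                order = np.lexsort((ct, -margin, -acc))
                j = order[0]
                key = (
                    float(acc[j]),
                    float(margin[j]),
                    _neg_lex((root_axis, rt, split_branch, float(ct[j]))),
                )
                if best is None or key > best[0]:
                    tree = TwoCutTree(
                        root_axis=root_axis,
                        root_threshold=float(rt),
                        child_axis=child_axis,
                        child_threshold=float(ct[j]),
                        split_branch=split_branch,
                        leaf_other=bool(leaf_other),
                        leaf_low=bool(leaf_low[j]),
                        leaf_high=bool(leaf_high[j]),
                        training_accuracy=float(acc[j]),
                    )
                    best = (key, tree)
    if best is None:
        raise ValueError("no cut candidates: both axes are degenerate")
    return best[1]


class _neg_lex(tuple):
    """Wrapper making lexicographically *smaller* config tuples win in max()."""

    def __new__(cls, cfg):
        return super().__new__(cls, cfg)

    def __lt__(self, other):  # reversed comparison
        return tuple.__gt__(self, other)

    def __gt__(self, other):
        return tuple.__lt__(self, other)


def loocv_tree(
    points: Sequence[tuple[float, float]], outcomes: Sequence[bool]
) -> tuple[float, float, float]:
    """Leave-one-out cross-validated two-cut tree.

    Refits the tree on n-1 patients and predicts the held-out one.
    Returns (accuracy, sensitivity, specificity) with seizure-free as
    the positive class.  A training fold left with a single outcome
    class predicts that class.
    """
    pts = np.asarray(points, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if y.size < 3:
        raise ValueError("LOOCV needs at least 3 patients")
    preds = np.empty_like(y)
    for i in range(y.size):
        mask = np.ones(y.size, dtype=bool)
        mask[i] = False
        yt = y[mask]
        if yt.all() or not yt.any():
            preds[i] = bool(yt[0])
            continue
        try:
            tree = fit_two_cut_tree(pts[mask], yt)
        except ValueError:
            preds[i] = _majority(yt)
            continue
        preds[i] = tree.predict_one(*pts[i])
    acc = float(np.mean(preds == y))
    tp = int(np.sum(preds & y))
    tn = int(np.sum(~preds & ~y))
    sens = tp / int(y.sum()) if y.sum() else float("nan")
    spec = tn / int((~y).sum()) if (~y).sum() else float("nan")
    return acc, sens, spec


# ---------------------------------------------------------------------------
# implantation planning helper


def rank_regions_for_implantation(
    scores: Mapping[str, float], top_n: int | None = None
) -> list[str]:
    """Regions ordered by descending abnormality score (ties lexicographic).

    A planning aid: regions with the greatest connectivity abnormality
    are candidates for iEEG sampling.  ``top_n`` beyond the available
    count returns everything.
    """
    if not scores:
        raise ValueError("no regional scores to rank")
    ranked = sorted(scores, key=lambda r: (-scores[r], r))
    if top_n is None:
        return ranked
    return ranked[: min(top_n, len(ranked))]
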