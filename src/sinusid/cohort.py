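"""All-pairs score matrix and identity-verification statistics.

Every antemortem image is compared against every postmortem image of a
cohort; the diagonal of the resulting matrix holds the matched
(same-individual) scores and the off-diagonal the mismatched ones. The
two groups are then compared with Welch's t-test, and the identify/reject
decision is characterized by ROC analysis (AUC, Youden-optimal cutoff,
TPR, FPR), overall and within subgroups (sex, AM-PM scan interval split
at 30 days, age split at 60 years).

Conventions: lower score = more similar, so the classification rule is
"identified iff score <= threshold" and ties at the cutoff count positive.
Subgroup mismatched pairs are within-subgroup (both members in the
subgroup). Missing score entries are excluded pairwise, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import InsufficientFeaturesError
from .matching import score_from_descriptors
from .synth import Cohort

logger = logging.getLogger(__name__)

#: every evaluation row carries exactly these fields
REPORT_FIELDS = (
    "sample", "method", "n",
    "matched_min", "matched_max", "matched_mean", "matched_sd",
    "mismatched_min", "mismatched_max", "mismatched_mean", "mismatched_sd",
    "t", "df", "p", "auc", "cutoff", "tpr", "fpr",
)

GROUPINGS = ("all", "sex", "interval_30d", "age_60y")

_MAX_MISSING_FRAC = 0.10


class EvalError(ValueError):
    pass


@dataclass
class ScoreMatrix:
    """n x n grid of AM_i x PM_j similarity scores (NaN = missing)."""

    scores: np.ndarray
    case_ids: list[str]
    method: str
    reasons: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.case_ids)
        if self.scores.shape != (n, n):
            raise EvalError(f"score matrix must be {n}x{n}, got {self.scores.shape}")

    def to_long(self) -> pd.DataFrame:
        """Long-format rows (am_id, pm_id, method, score, reason)."""
        rows = []
        for i, am in enumerate(self.case_ids):
            for j, pm in enumerate(self.case_ids):
                s = self.scores[i, j]
                rows.append({
                    "am_id": am, "pm_id": pm, "method": self.method,
                    "score": s if np.isfinite(s) else np.nan,
                    "reason": self.reasons.get((am, pm), ""),
                })
        return pd.DataFrame(rows)


def score_matrix(cohort: Cohort, method: str, params=None,
                 precomputed: dict[tuple[str, str], float] | None = None) -> ScoreMatrix:
    """Compute all n^2 AM x PM similarity scores of a cohort.

    Features are extracted once per image and reused across pairs.
    Extraction failures are recorded as missing entries with reasons;
    more than 10% missing is a hard error (cohort unusable). Entries in
    ``precomputed`` (e.g. from a resumable CSV cache) are kept as-is.
    """
    from .matching import _extractor

    ids = cohort.case_ids()
    n = len(ids)
    if n < 2:
        raise EvalError("score matrix needs at least 2 cases")
    extract = _extractor(method)

    desc: dict[tuple[str, str], object] = {}
    reasons: dict[tuple[str, str], str] = {}
    for cid in ids:
        for session in ("AM", "PM"):
            try:
                _, d = extract(cohort.image(cid, session), params)
                desc[(cid, session)] = d
            except InsufficientFeaturesError as exc:
                desc[(cid, session)] = None
                reasons_key = f"{session.lower()}:{exc}"
                reasons[(cid, session)] = reasons_key

    scores = np.full((n, n), np.nan)
    pair_reasons: dict[tuple[str, str], str] = {}
    done = precomputed or {}
    for i, am in enumerate(ids):
        for j, pm in enumerate(ids):
            if (am, pm) in done:
                scores[i, j] = done[(am, pm)]
                continue
            da = desc[(am, "AM")]
            dp = desc[(pm, "PM")]
            if da is None or dp is None:
                pair_reasons[(am, pm)] = "insufficient features"
                continue
            scores[i, j] = score_from_descriptors(da, dp).value

    missing = np.isnan(scores).mean()
    if missing > _MAX_MISSING_FRAC:
        raise EvalError(
            f"{missing:.0%} of score-matrix entries are missing (> {_MAX_MISSING_FRAC:.0%}); "
            "cohort unusable"
        )
    return ScoreMatrix(scores=scores, case_ids=ids, method=method, reasons=pair_reasons)


def split_matched_mismatched(matrix: ScoreMatrix,
                             subset: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal (matched) vs off-diagonal (mismatched) scores, restricted
    to pairs whose row AND column case both lie in ``subset``. Missing
    entries are dropped."""
    ids = matrix.case_ids
    if subset is None:
        subset = ids
    if len(subset) == 0:
        raise EvalError("empty case subset")
    idx = [ids.index(c) for c in subset]
    sub = matrix.scores[np.ix_(idx, idx)]
    diag = np.diagonal(sub)
    mask_off = ~np.eye(len(idx), dtype=bool)
    matched = diag[np.isfinite(diag)]
    mismatched = sub[mask_off]
    mismatched = mismatched[np.isfinite(mismatched)]
    if matched.size == 0 and mismatched.size == 0:
        raise EvalError("all entries missing for the requested subset")
    return matched, mismatched


# ---------------------------------------------------------------------------
# statistics


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    n1: int
    mean1: float
    sd1: float
    min1: float
    max1: float
    n2: int
    mean2: float
    sd2: float
    min2: float
    max2: float


def welch_t(x: np.ndarray, y: np.ndarray) -> WelchResult:
    """Welch's two-sample t-test (unequal variances, Welch-Satterthwaite
    fractional degrees of freedom, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise EvalError("Welch test needs at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            # identical-constant groups: no evidence of a difference
            return WelchResult(0.0, float(x.size + y.size - 2), 1.0,
                               x.size, float(x.mean()), 0.0, float(x.min()), float(x.max()),
                               y.size, float(y.mean()), 0.0, float(y.min()), float(y.max()))
        raise EvalError("both groups have zero variance but different means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        n1=int(x.size), mean1=float(x.mean()), sd1=float(x.std(ddof=1)),
        min1=float(x.min()), max1=float(x.max()),
        n2=int(y.size), mean2=float(y.mean()), sd2=float(y.std(ddof=1)),
        min2=float(y.min()), max2=float(y.max()),
    )


@dataclass(frozen=True)
class ROCResult:
    auc: float
    cutoff: float
    tpr: float
    fpr: float
    curve: pd.DataFrame  # columns threshold, tpr, fpr (threshold ascending)


def roc_analysis(matched: np.ndarray, mismatched: np.ndarray) -> ROCResult:
    """ROC analysis with matched (lower-score) as the positive class.

    Classification rule: positive iff score <= threshold. The AUC is the
    Mann-Whitney pair statistic P(matched < mismatched) + 1/2 P(equal);
    the reported cutoff maximizes Youden's J = TPR - FPR (ties resolved to
    the smaller threshold), with TPR/FPR evaluated there.
    """
    m = np.asarray(matched, dtype=float)
    u = np.asarray(mismatched, dtype=float)
    if m.size < 2 or u.size < 2:
        raise EvalError("ROC analysis needs at least 2 scores per class")

    combined = np.concatenate([m, u])
    ranks = stats.rankdata(combined)
    r_m = ranks[: m.size].sum()
    # count of (matched < mismatched) pairs + half the ties
    u_stat = m.size * u.size + m.size * (m.size + 1) / 2.0 - r_m
    auc = float(u_stat / (m.size * u.size))

    thresholds = np.unique(combined)
    m_sorted = np.sort(m)
    u_sorted = np.sort(u)
    tpr = np.searchsorted(m_sorted, thresholds, side="right") / m.size
    fpr = np.searchsorted(u_sorted, thresholds, side="right") / u.size
    j = tpr - fpr
    best = int(np.argmax(j))  # first maximum = smallest threshold
    curve = pd.DataFrame({
        "threshold": np.concatenate([[-np.inf], thresholds]),
        "tpr": np.concatenate([[0.0], tpr]),
        "fpr": np.concatenate([[0.0], fpr]),
    })
    return ROCResult(auc=auc, cutoff=float(thresholds[best]),
                     tpr=float(tpr[best]), fpr=float(fpr[best]), curve=curve)


# ---------------------------------------------------------------------------
# subgroup evaluation


@dataclass
class EvalReport:
    """Rows shaped like the descriptive-statistics and ROC tables: one row
    per (subgroup, method) with fields :data:`REPORT_FIELDS`."""

    rows: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(REPORT_FIELDS))


def _subgroup_subsets(manifest: pd.DataFrame, grouping: str) -> list[tuple[str, list[str]]]:
    ids = manifest["case_id"]
    if grouping == "all":
        return [("All", list(ids))]
    if grouping == "sex":
        return [
            ("Male", list(ids[manifest["sex"] == "M"])),
            ("Female", list(ids[manifest["sex"] == "F"])),
        ]
    if grouping == "interval_30d":
        short = manifest["interval_days"] < 30
        return [
            ("Interval <30 days", list(ids[short])),
            ("Interval >=30 days", list(ids[~short])),
        ]
    if grouping == "age_60y":
        young = manifest["age_years"] < 60
        return [
            ("Age <60 years", list(ids[young])),
            ("Age >=60 years", list(ids[~young])),
        ]
    raise EvalError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")


def evaluate_subset(matrix: ScoreMatrix, subset: list[str], label: str) -> dict:
    matched, mismatched = split_matched_mismatched(matrix, subset)
    if matched.size < 2 or mismatched.size < 2:
        raise EvalError(f"subgroup {label!r} too small for statistics")
    w = welch_t(matched, mismatched)
    r = roc_analysis(matched, mismatched)
    return {
        "sample": label, "method": matrix.method, "n": len(subset),
        "matched_min": w.min1, "matched_max": w.max1,
        "matched_mean": w.mean1, "matched_sd": w.sd1,
        "mismatched_min": w.min2, "mismatched_max": w.max2,
        "mismatched_mean": w.mean2, "mismatched_sd": w.sd2,
        "t": w.t, "df": w.df, "p": w.p,
        "auc": r.auc, "cutoff": r.cutoff, "tpr": r.tpr, "fpr": r.fpr,
    }


def subgroup_eval(manifest: pd.DataFrame, matrix: ScoreMatrix,
                  groupings: tuple[str, ...] = GROUPINGS) -> EvalReport:
    """Per-subgroup matched/mismatched split, Welch test, and ROC
    analysis. Subgroups with fewer than 2 cases are skipped with a
    warning."""
    rows = []
    for grouping in groupings:
        for label, subset in _subgroup_subsets(manifest, grouping):
            if len(subset) < 2:
                logger.warning("skipping subgroup %r: only %d case(s)", label, len(subset))
                continue
            rows.append(evaluate_subset(matrix, subset, label))
    return EvalReport(rows=rows)


def matrix_from_long(scores: pd.DataFrame, method: str) -> ScoreMatrix:
    """Assemble a ScoreMatrix from long-format rows
    (am_id, pm_id, method, score)."""
    required = {"am_id", "pm_id", "method", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise EvalError(f"score table is missing columns: {sorted(missing)}")
    sub = scores[scores["method"] == method]
    if sub.empty:
        raise EvalError(f"no rows for method {method!r} in the score table")
    ids = sorted(set(sub["am_id"]) | set(sub["pm_id"]))
    index = {c: i for i, c in enumerate(ids)}
    mat = np.full((len(ids), len(ids)), np.nan)
    for row in sub.itertuples(index=False):
        mat[index[row.am_id], index[row.pm_id]] = row.score
    return ScoreMatrix(scores=mat, case_ids=ids, method=method)


def tables_from_scores(scores: pd.DataFrame, covariates: pd.DataFrame,
                       groupings: tuple[str, ...] = GROUPINGS) -> EvalReport:
    """Reproduce the evaluation tables directly from a published or cached
    score table, bypassing image processing.

    ``scores`` is long-format (am_id, pm_id, method, score); ``covariates``
    has one row per case (case_id, sex, age_years, interval_days).
    """
    required = {"am_id", "pm_id", "method", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise EvalError(f"score table is missing columns: {sorted(missing)}")
    if "case_id" not in covariates.columns:
        raise EvalError("covariate table needs a case_id column")
    rows = []
    for method in pd.unique(scores["method"]):
        matrix = matrix_from_long(scores, method)
        off = ~np.eye(len(matrix.case_ids), dtype=bool)
        if not np.isfinite(matrix.scores[off]).any():
            raise EvalError(
                f"score table for {method!r} has matched scores only; "
                "mismatched (off-diagonal) pairs are required"
            )
        manifest = covariates[covariates["case_id"].isin(matrix.case_ids)].reset_index(drop=True)
        usable = [g for g in groupings
                  if g == "all" or _grouping_columns(g) <= set(manifest.columns)]
        rows.extend(subgroup_eval(manifest, matrix, tuple(usable)).rows)
    return EvalReport(rows=rows)


def _grouping_columns(grouping: str) -> set[str]:
    return {"sex": {"sex"}, "interval_30d": {"interval_days"},
            "age_60y": {"age_years"}}.get(grouping, set())
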