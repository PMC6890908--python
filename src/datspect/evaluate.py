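"""Statistical evaluation: group tests, ROC/AUC, DeLong comparison, cutoffs.

The ROC machinery is placement-value based so that the nonparametric AUC
equals the Mann-Whitney U statistic divided by n_pos*n_neg (ties counting
one half) and so that paired AUCs can be compared with the DeLong
covariance test.  Optimal cutoffs maximize Youden's J; confusion metrics
are reported as percentages rounded half-up to one decimal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import StandardizedLinearSVM, SplitPlan, stratified_split
from .panel import INDEX_COLUMNS, Q_FEATURES, V_FEATURES

#: direction in which each score indicates the positive (PS) class:
#: "lower" — uptake indices fall with disease; "higher" — shape/asymmetry rise.
DEFAULT_DIRECTIONS = {
    "sbr_q": "lower",
    "pcr_q": "lower",
    "sbr_v": "lower",
    "ai_q": "higher",
    "ai_v": "higher",
    "fd_v": "higher",
    "svm_q": "higher",
    "svm_v": "higher",
}

# --- Mann-Whitney -------------------------------------------------------------


def _enumerate_exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided permutation p of the U statistic by full enumeration."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mu = n_a * (n - n_a) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2.0
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """U statistic for group_a (midrank ties) and a two-sided p value.

    Small tie-free samples (n_a*n_b <= 400) get the exact null distribution;
    ties fall back to the normal approximation with tie correction (an exact
    enumeration is additionally used when the number of group assignments is
    small enough to list).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    ranks = stats.rankdata(pooled)
    u_a = ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0
    small = len(a) * len(b) <= 400
    if small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(u_a), float(res.pvalue)
    if small and has_ties and math.comb(len(pooled), len(a)) <= 200_000:
        return float(u_a), float(_enumerate_exact_p(a, b, u_a))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(u_a), float(res.pvalue)


# --- ROC ----------------------------------------------------------------------


@dataclass
class ROCResult:
    """Ranked-score ROC with placement values for DeLong comparison.

    ``oriented_scores`` are the input scores flipped, if necessary, so that
    larger always indicates the positive class; thresholds/sens/spec refer to
    the rule "oriented score >= threshold => positive".
    """

    auc: float
    n_pos: int
    n_neg: int
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    placements_pos: np.ndarray  # V10: per-positive fraction of negatives below it
    placements_neg: np.ndarray  # V01: per-negative fraction of positives above it
    positive_direction: str
    oriented_scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def roc_auc(scores, labels, positive_direction: str = "higher") -> ROCResult:
    """Nonparametric ROC/AUC with midrank tie handling.

    ``labels`` may be 0/1 or "NPS"/"PS" (PS positive).  ``positive_direction``
    states whether larger raw scores indicate the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        labels = (labels == "PS").astype(int)
    labels = labels.astype(int)
    if positive_direction not in ("higher", "lower"):
        raise ValueError("positive_direction must be 'higher' or 'lower'")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    s = scores if positive_direction == "higher" else -scores

    # placement values via midranks
    ranks_all = stats.rankdata(s)
    ranks_pos = stats.rankdata(s[pos])
    ranks_neg = stats.rankdata(s[neg])
    v10 = (ranks_all[pos] - ranks_pos) / n_neg
    v01 = 1.0 - (ranks_all[neg] - ranks_neg) / n_pos
    auc = float(v10.mean())

    # monotone curve over unique thresholds (descending)
    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    sens = np.array([(s[pos] >= t).mean() for t in thresholds])
    spec = np.array([(s[neg] < t).mean() for t in thresholds])
    return ROCResult(
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        placements_pos=v10,
        placements_neg=v01,
        positive_direction=positive_direction,
        oriented_scores=s,
        labels=labels,
    )


@dataclass(frozen=True)
class DeLongComparison:
    auc_a: float
    auc_b: float
    variance_diff: float
    z: float
    p: float


def delong_compare(roc_a: ROCResult, roc_b: ROCResult) -> DeLongComparison:
    """Paired AUC comparison from placement-value structural components."""
    if roc_a.n_pos != roc_b.n_pos or roc_a.n_neg != roc_b.n_neg:
        raise ValueError("ROC results are not paired (different class sizes)")
    if roc_a.labels is not None and roc_b.labels is not None:
        if not np.array_equal(roc_a.labels, roc_b.labels):
            raise ValueError("ROC results are not paired (labels differ)")
    v10 = np.vstack([roc_a.placements_pos, roc_b.placements_pos])
    v01 = np.vstack([roc_a.placements_neg, roc_b.placements_neg])
    s10 = np.cov(v10, ddof=1)
    s01 = np.cov(v01, ddof=1)
    cov = s10 / roc_a.n_pos + s01 / roc_a.n_neg
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    diff = roc_a.auc - roc_b.auc
    if var_diff <= 0:
        z = 0.0 if abs(diff) < 1e-12 else math.inf * np.sign(diff)
    else:
        z = diff / math.sqrt(var_diff)
    p = 1.0 if not np.isfinite(z) and abs(diff) < 1e-12 else 2.0 * stats.norm.sf(abs(z))
    return DeLongComparison(
        auc_a=roc_a.auc, auc_b=roc_b.auc, variance_diff=var_diff, z=float(z), p=float(p)
    )


def auc_variance(roc: ROCResult) -> float:
    """DeLong variance of a single AUC."""
    return float(
        np.var(roc.placements_pos, ddof=1) / roc.n_pos
        + np.var(roc.placements_neg, ddof=1) / roc.n_neg
    )


# --- cutoff and confusion metrics ---------------------------------------------


def optimal_cutoff(roc: ROCResult) -> float:
    """Threshold (oriented-score scale) maximizing Youden's J.

    Ties resolve toward higher sensitivity; the returned cutoff is the
    midpoint between the adjacent observed scores bracketing the chosen
    operating point (the rule is: oriented score >= cutoff => positive).
    """
    s = roc.oriented_scores
    if s is None:
        raise ValueError("ROC result does not carry scores")
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("degenerate ROC: all scores identical")
    # candidate cutpoints between consecutive observed scores, plus the extremes
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    pos = roc.labels == 1
    best_j, best_sens, best_cut = -np.inf, -np.inf, None
    for c in candidates:
        pred = s >= c
        sens = pred[pos].mean()
        spec = (~pred[~pos]).mean()
        j = sens + spec - 1.0
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and sens > best_sens):
            best_j, best_sens, best_cut = j, sens, c
    return float(best_cut)


def _round_half_up(x: float, decimals: int = 1) -> float:
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts with table-convention percentages (half-up, 1 decimal).

    Ratios with an empty denominator are flagged in ``undefined`` and
    reported as None rather than zero.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float
    undefined: tuple[str, ...]


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer")
    n = tp + fp + fn + tn
    if n == 0:
        raise ValueError("empty confusion matrix")

    def pct(num, den):
        return None if den == 0 else _round_half_up(100.0 * num / den)

    values = {
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
    }
    undefined = tuple(k for k, v in values.items() if v is None)
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=_round_half_up(100.0 * (tp + tn) / n),
        undefined=undefined,
        **values,
    )


def classify_at_cutoff(roc: ROCResult, cutoff: float) -> ConfusionMetrics:
    """Apply 'oriented score >= cutoff => positive' and tabulate."""
    pred = roc.oriented_scores >= cutoff
    pos = roc.labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    return confusion_metrics(tp, fp, fn, tn)


# --- report -------------------------------------------------------------------

PAIRED_COMPARISONS = [("sbr_q", "sbr_v"), ("pcr_q", "fd_v"), ("ai_q", "ai_v")]


@dataclass
class SVMEvaluation:
    """Per-scheme SVM artifacts produced by the pipeline."""

    model: StandardizedLinearSVM
    split: SplitPlan
    test_scores: np.ndarray
    test_labels: np.ndarray


def evaluate_svm_schemes(
    panels_df: pd.DataFrame,
    split_seed: int = 0,
    svm_seed: int = 0,
    test_fraction: float = 0.25,
    c_grid=(0.01, 0.1, 1.0, 10.0, 100.0),
    k_folds: int = 10,
) -> dict[str, SVMEvaluation]:
    """Fit SVM-Q and SVM-V on one shared stratified split of a labeled cohort."""
    labels = panels_df["label"].to_numpy()
    split = stratified_split(
        labels, test_fraction, split_seed, ids=panels_df["subject_id"].to_numpy()
    )
    is_test = panels_df["subject_id"].isin(split.test_ids).to_numpy()
    _, train_counts = np.unique(labels[~is_test], return_counts=True)
    if k_folds > train_counts.min():
        # small cohorts cannot support the requested fold count; shrink rather
        # than refuse so the default configuration still runs end to end
        import warnings

        warnings.warn(
            f"reducing k_folds from {k_folds} to {train_counts.min()} "
            "(smaller training class size)",
            RuntimeWarning,
            stacklevel=2,
        )
        k_folds = int(train_counts.min())
    out = {}
    for scheme, cols in (("q", Q_FEATURES), ("v", V_FEATURES)):
        X = panels_df[cols].to_numpy(dtype=float)
        model = StandardizedLinearSVM(
            c_grid=c_grid, k_folds=k_folds, random_state=svm_seed
        ).fit(X[~is_test], labels[~is_test])
        out[f"svm_{scheme}"] = SVMEvaluation(
            model=model,
            split=split,
            test_scores=model.decision_function(X[is_test]),
            test_labels=(labels[is_test] == "PS").astype(int),
        )
    return out


def build_report(
    panels_df: pd.DataFrame,
    svm_results: dict[str, SVMEvaluation] | None = None,
    directions: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Index-by-index evaluation table plus the paired DeLong comparison block.

    Single-index rows are resubstitution results on the full labeled cohort
    (cutoff chosen and applied on the same subjects); SVM rows are computed on
    the held-out test split carried by ``svm_results``.
    """
    if panels_df["label"].isna().any():
        raise ValueError("report requires labeled panels")
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    labels = (panels_df["label"] == "PS").astype(int).to_numpy()

    rows = []
    rocs: dict[str, ROCResult] = {}
    for name in INDEX_COLUMNS:
        roc = roc_auc(panels_df[name].to_numpy(dtype=float), labels, directions[name])
        rocs[name] = roc
        cut = optimal_cutoff(roc)
        cm = classify_at_cutoff(roc, cut)
        reported_cut = cut if directions[name] == "higher" else -cut
        rows.append(_report_row(name, "resubstitution", roc, reported_cut, cm))

    if svm_results:
        for name, ev in svm_results.items():
            roc = roc_auc(ev.test_scores, ev.test_labels, directions.get(name, "higher"))
            rocs[name] = roc
            cut = optimal_cutoff(roc)
            cm = classify_at_cutoff(roc, cut)
            rows.append(_report_row(name, "test_split", roc, cut, cm))

    comparisons = {}
    for a, b in PAIRED_COMPARISONS:
        comparisons[f"{a}_vs_{b}"] = _comparison_dict(delong_compare(rocs[a], rocs[b]))
    if svm_results and "svm_q" in rocs and "svm_v" in rocs:
        comparisons["svm_q_vs_svm_v"] = _comparison_dict(
            delong_compare(rocs["svm_q"], rocs["svm_v"])
        )
    meta = {
        "comparisons": comparisons,
        "note": "no multiple-testing correction applied; alpha = 0.05, two-sided",
    }
    return pd.DataFrame(rows), meta


def _report_row(name, evaluation, roc, cutoff, cm: ConfusionMetrics):
    return {
        "index": name,
        "evaluation": evaluation,
        "auc": roc.auc,
        "cutoff": cutoff,
        "tp": cm.tp,
        "fp": cm.fp,
        "fn": cm.fn,
        "tn": cm.tn,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "ppv": cm.ppv,
        "npv": cm.npv,
        "accuracy": cm.accuracy,
    }


def _comparison_dict(c: DeLongComparison) -> dict:
    return {"auc_a": c.auc_a, "auc_b": c.auc_b, "z": c.z, "p": c.p}
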