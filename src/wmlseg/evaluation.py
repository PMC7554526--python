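"""Three-level evaluation: pixel metrics, lesion-wise rates, score agreement.

Pixel level: Dice similarity coefficient, precision and recall from
exact voxel-set cardinalities. Lesion level: connected components are
matched by overlap -- a ground-truth lesion counts as detected (TP)
when at least one of its voxels is covered by the prediction; a
predicted component with no ground-truth overlap is a false positive.
The true-negative count needed for a lesion-wise FPR has no natural
voxel-set definition, so it is taken as the correctly rejected
pre-filter candidate components (components that neither overlap the
ground truth nor survive post-processing); because that convention is
a modelling choice, the report also carries the unambiguous lesion
false-discovery proportion fp / (fp + matched predicted components).
Subject level: Spearman rank correlation and the intraclass
correlation coefficient (two-way random effects, absolute agreement,
single rater) between predicted and reference burden scores.

Metrics with an empty denominator (empty masks, no candidates) are
reported as missing (NaN) and excluded from group means -- never
silently coerced to 0 or 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError
from .postprocess import label_components
from .synthetic import severity_stratum

logger = logging.getLogger(__name__)

__all__ = [
    "PixelMetrics",
    "LesionMetrics",
    "AgreementStats",
    "EvaluationReport",
    "pixel_metrics",
    "lesion_metrics",
    "score_agreement",
    "stratify",
    "evaluate_cohort",
]


@dataclass(frozen=True)
class PixelMetrics:
    dsc: float
    precision: float
    recall: float


@dataclass(frozen=True)
class LesionMetrics:
    tp: int
    fn: int
    fp: int
    tn: int
    tpr: float
    fpr: float
    fdp: float  # lesion-wise false-discovery proportion fp / (fp + matched)


@dataclass(frozen=True)
class AgreementStats:
    spearman_r: float
    spearman_p: float
    icc: float
    icc_ci95: tuple[float, float]
    n: int


def _check_aligned(*arrays):
    shapes = {np.shape(a) for a in arrays}
    if len(shapes) > 1:
        raise AlignmentError(f"masks are not aligned: {sorted(map(str, shapes))}")


def pixel_metrics(gt: np.ndarray, pred: np.ndarray) -> PixelMetrics:
    """DSC = 2|G∩P|/(|G|+|P|), recall = |G∩P|/|G|, precision = |G∩P|/|P|."""
    _check_aligned(gt, pred)
    g = np.asarray(gt).astype(bool)
    p = np.asarray(pred).astype(bool)
    ng, np_, inter = int(g.sum()), int(p.sum()), int((g & p).sum())
    if ng == 0:
        logger.warning("empty ground truth: recall (and DSC if prediction empty) undefined")
    if np_ == 0:
        logger.warning("empty prediction: precision undefined")
    dsc = 2 * inter / (ng + np_) if ng + np_ else float("nan")
    recall = inter / ng if ng else float("nan")
    precision = inter / np_ if np_ else float("nan")
    return PixelMetrics(dsc=dsc, precision=precision, recall=recall)


def lesion_metrics(
    gt: np.ndarray,
    pred: np.ndarray,
    candidates: np.ndarray | None = None,
    connectivity: str = "2d8",
    min_overlap: int = 1,
) -> LesionMetrics:
    """Lesion-wise detection counts and rates by component overlap.

    ``candidates`` is the pre-filter candidate mask from
    post-processing; without it, TN (hence FPR) is undefined.
    """
    _check_aligned(gt, pred)
    g = np.asarray(gt).astype(bool)
    p = np.asarray(pred).astype(bool)

    g_lab, n_g = label_components(g, connectivity)
    p_lab, n_p = label_components(p, connectivity)

    tp = fn = 0
    for lab in range(1, n_g + 1):
        if int(p[g_lab == lab].sum()) >= min_overlap:
            tp += 1
        else:
            fn += 1
    fp = matched = 0
    for lab in range(1, n_p + 1):
        if int(g[p_lab == lab].sum()) >= min_overlap:
            matched += 1
        else:
            fp += 1

    tn = 0
    if candidates is not None:
        _check_aligned(gt, candidates)
        c = np.asarray(candidates).astype(bool)
        c_lab, n_c = label_components(c, connectivity)
        for lab in range(1, n_c + 1):
            sel = c_lab == lab
            if int(g[sel].sum()) == 0 and int(p[sel].sum()) == 0:
                tn += 1

    tpr = tp / (tp + fn) if tp + fn else float("nan")
    fpr = fp / (fp + tn) if candidates is not None and fp + tn else float("nan")
    fdp = fp / (fp + matched) if fp + matched else float("nan")
    return LesionMetrics(tp=tp, fn=fn, fp=fp, tn=tn, tpr=tpr, fpr=fpr, fdp=fdp)


def score_agreement(true_scores, predicted_scores) -> AgreementStats:
    """Spearman correlation and ICC(2,1) with its analytic 95% CI."""
    t = np.asarray(true_scores, dtype=float)
    p = np.asarray(predicted_scores, dtype=float)
    if t.shape != p.shape:
        raise ValueError("score lists must have equal length")
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 subjects for agreement statistics")
    if np.ptp(t) == 0 or np.ptp(p) == 0:
        logger.warning("constant score vector: correlation undefined, reported missing")
        return AgreementStats(float("nan"), float("nan"), float("nan"), (float("nan"),) * 2, n)
    sp = stats.spearmanr(t, p)

    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["truth", "model"], n),
            "score": np.concatenate([t, p]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc_tab = pg.intraclass_corr(data=long, targets="subject", raters="rater", ratings="score")
    # two-way random effects, absolute agreement, single rater
    # (labelled ICC2 or ICC(A,1) depending on the pingouin version)
    row = icc_tab[icc_tab["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    ci_col = "CI95%" if "CI95%" in icc_tab.columns else "CI95"
    return AgreementStats(
        spearman_r=float(sp.statistic),
        spearman_p=float(sp.pvalue),
        icc=float(row["ICC"]),
        icc_ci95=(float(row[ci_col][0]), float(row[ci_col][1])),
        n=n,
    )


_METRIC_COLS = ["dsc", "precision", "recall", "tpr", "fpr", "fdp", "wmlv_ml", "score_error"]


def stratify(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of every metric over severity strata and AIL groups.

    Each subject belongs to exactly one severity stratum (by measured
    ground-truth WMLV: mild <= 5 ml < moderate <= 20 ml < severe) and
    one AIL group. Missing metric values are excluded, with the
    effective n reported per cell.
    """
    df = per_subject.copy()
    if "stratum" not in df:
        df["stratum"] = df["true_wmlv_ml"].map(severity_stratum)
    df["ail_group"] = np.where(df["has_ail"], "AILg", "non-AILg")
    groups = [("all", df)]
    groups += [(s, df[df["stratum"] == s]) for s in ("mild", "moderate", "severe")]
    groups += [(a, df[df["ail_group"] == a]) for a in ("AILg", "non-AILg")]
    rows = []
    for name, sub in groups:
        row: dict = {"group": name, "n": len(sub)}
        for col in _METRIC_COLS:
            if col in sub:
                vals = sub[col].astype(float)
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_sd"] = float(vals.std(ddof=1)) if vals.notna().sum() > 1 else float("nan")
                row[f"{col}_n"] = int(vals.notna().sum())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    per_subject: pd.DataFrame
    group_summary: pd.DataFrame
    agreement: AgreementStats | None


def evaluate_cohort(
    test_subjects,
    predictions: dict,
    rating_model=None,
    connectivity: str = "2d8",
) -> EvaluationReport:
    """Assemble the full three-level report for one variant run.

    ``test_subjects`` are PreparedSubject items; ``predictions`` maps
    subject id to the dict produced by run_variant (keys "final",
    "candidate"). When a fitted rating model is given, predicted
    burden scores and their agreement with the true scores are added.
    """
    from .postprocess import compute_wmlv, predict_score

    rows = []
    for s in test_subjects:
        pred = predictions[s.subject_id]
        px = pixel_metrics(s.wml, pred["final"])
        lm = lesion_metrics(s.wml, pred["final"], candidates=pred.get("candidate"), connectivity=connectivity)
        wmlv = compute_wmlv(pred["final"], s.pixel_spacing, s.slice_thickness)
        row = dict(
            id=s.subject_id,
            stratum=s.stratum or severity_stratum(s.true_wmlv),
            has_ail=s.has_ail,
            true_wmlv_ml=s.true_wmlv,
            true_score=s.true_score,
            dsc=px.dsc,
            precision=px.precision,
            recall=px.recall,
            tp=lm.tp,
            fn=lm.fn,
            fp=lm.fp,
            tn=lm.tn,
            tpr=lm.tpr,
            fpr=lm.fpr,
            fdp=lm.fdp,
            wmlv_ml=wmlv,
        )
        if rating_model is not None:
            cont, integer = predict_score(rating_model, wmlv)
            row["score_cont"] = cont
            row["score_int"] = integer
            row["score_error"] = abs(integer - s.true_score)
        rows.append(row)
    per_subject = pd.DataFrame(rows)
    agreement = None
    if rating_model is not None and len(per_subject) >= 3:
        agreement = score_agreement(per_subject["true_score"], per_subject["score_cont"])
    return EvaluationReport(per_subject=per_subject, group_summary=stratify(per_subject), agreement=agreement)
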