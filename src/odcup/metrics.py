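"""Clinical evaluation stack for disc/cup segmentation.

Covers the Dice similarity coefficient (DSC = 2TP/(2TP+FP+FN)), the vertical
cup-to-disc ratio (CDR, ratio of vertical diameters) with its absolute error
δ = |CDR_pred − CDR_gt|, ROC/AUC for CDR-based glaucoma screening, and the
REFUGE-challenge weighted-rank score

    R = 0.35·R_cup + 0.25·R_disc + 0.40·R_δ,

where lower rank is better on every metric (higher DSC, lower δ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label
from scipy.stats import rankdata
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "EvalRecord",
    "dsc",
    "vertical_cdr",
    "cdr_delta",
    "roc_auc",
    "challenge_score",
    "rank_teams",
    "evaluate_pair",
    "SCORE_WEIGHTS",
]

#: weights of (cup rank, disc rank, delta rank) in the challenge score
SCORE_WEIGHTS = (0.35, 0.25, 0.40)


@dataclass
class EvalRecord:
    """Per-image evaluation: Dice per structure, CDRs, δ and pixel counts."""

    dsc_disc: float
    dsc_cup: float
    cdr_pred: float
    cdr_gt: float
    delta: float
    counts_disc: tuple[int, int, int, int]  # tp, fp, fn, tn
    counts_cup: tuple[int, int, int, int]


def _binarize(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    return m if m.dtype == bool else m >= 0.5


def dsc(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity 2TP/(2TP+FP+FN) of one binary mask channel.

    Probabilistic predictions are binarized at 0.5.  Two empty masks count as
    perfect agreement (1.0); this degenerate convention is logged once where
    it fires.
    """
    pred, gt = _binarize(pred), _binarize(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    fn = int(np.sum(~pred & gt))
    if tp + fp + fn == 0:
        logger.debug("dsc: both masks empty; returning 1.0 by convention")
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def _vertical_extent(channel: np.ndarray) -> int:
    """Row extent (in rows) of the largest 8-connected component; 0 if empty."""
    channel = _binarize(channel)
    if not channel.any():
        return 0
    labels, n = cc_label(channel, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())[1:]
    rows = np.nonzero(labels == (1 + int(np.argmax(sizes))))[0]
    return int(rows.max() - rows.min() + 1)


def vertical_cdr(mask: np.ndarray) -> float:
    """Vertical cup-to-disc ratio d(OC)/d(OD) of a (H, W, 2) mask.

    Diameters are vertical extents of the largest connected component of each
    channel, which makes the measure robust to speckle in thresholded
    predictions.
    """
    d_disc = _vertical_extent(mask[..., 0])
    if d_disc == 0:
        raise ValueError("vertical_cdr undefined: disc channel is empty")
    d_cup = _vertical_extent(mask[..., 1])
    if d_cup == 0:
        logger.warning("vertical_cdr: empty cup channel; returning 0.0")
        return 0.0
    return d_cup / d_disc


def cdr_delta(pred: np.ndarray, gt: np.ndarray) -> float:
    """δ = |CDR_pred − CDR_gt|."""
    return abs(vertical_cdr(pred) - vertical_cdr(gt))


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC of a screening score against binary labels.

    Sweeps thresholds over the observed scores; AUC by the trapezoid rule,
    which equals the normalised Mann–Whitney U statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC is undefined with a single class present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return curve, float(_sk_auc(fpr, tpr))


def challenge_score(rank_cup: float, rank_disc: float, rank_delta: float) -> float:
    """Weighted-rank score 0.35·R_cup + 0.25·R_disc + 0.40·R_δ (lower is better)."""
    ranks = (rank_cup, rank_disc, rank_delta)
    if any(r < 1 for r in ranks):
        raise ValueError(f"ranks must be >= 1, got {ranks}")
    w = SCORE_WEIGHTS
    return w[0] * rank_cup + w[1] * rank_disc + w[2] * rank_delta


def rank_teams(table: pd.DataFrame) -> pd.DataFrame:
    """Rank teams on (dsc_cup, dsc_disc, delta) and attach weighted scores.

    ``table`` needs columns ``team``, ``dsc_cup``, ``dsc_disc``, ``delta``.
    Higher DSC ranks better (rank 1), lower δ ranks better; exact ties share
    the average rank.  Teams with missing metrics are dropped with a warning.
    """
    required = {"team", "dsc_cup", "dsc_disc", "delta"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    t = table.copy()
    bad = t[list(required - {"team"})].isna().any(axis=1)
    if bad.any():
        logger.warning("rank_teams: excluding teams with missing metrics: %s",
                       list(t.loc[bad, "team"]))
        t = t[~bad]
    if len(t) < 2:
        raise ValueError("need at least two complete teams to rank")
    t["rank_cup"] = rankdata(-t["dsc_cup"], method="average")
    t["rank_disc"] = rankdata(-t["dsc_disc"], method="average")
    t["rank_delta"] = rankdata(t["delta"], method="average")
    t["score"] = [
        challenge_score(rc, rd, rl)
        for rc, rd, rl in zip(t["rank_cup"], t["rank_disc"], t["rank_delta"])
    ]
    return t.sort_values("score", kind="stable").reset_index(drop=True)


def evaluate_pair(pred: np.ndarray, gt: np.ndarray) -> EvalRecord:
    """Full per-image record comparing a predicted (H, W, 2) mask to truth.

    An empty predicted disc (a degenerate but possible prediction) is scored
    as CDR 0 with a warning; an empty ground-truth disc is an error.
    """

    def counts(p, g):
        p, g = _binarize(p), _binarize(g)
        return (
            int(np.sum(p & g)),
            int(np.sum(p & ~g)),
            int(np.sum(~p & g)),
            int(np.sum(~p & ~g)),
        )

    if _binarize(pred[..., 0]).any():
        cdr_p = vertical_cdr(pred)
    else:
        logger.warning("evaluate_pair: empty predicted disc; scoring CDR as 0")
        cdr_p = 0.0
    cdr_g = vertical_cdr(gt)
    return EvalRecord(
        dsc_disc=dsc(pred[..., 0], gt[..., 0]),
        dsc_cup=dsc(pred[..., 1], gt[..., 1]),
        cdr_pred=cdr_p,
        cdr_gt=cdr_g,
        delta=abs(cdr_p - cdr_g),
        counts_disc=counts(pred[..., 0], gt[..., 0]),
        counts_cup=counts(pred[..., 1], gt[..., 1]),
    )
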