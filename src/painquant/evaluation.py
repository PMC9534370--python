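"""Model assessment: leave-one-recording-out CV, Pearson r, RMSE,
ICC(3,1), a recording-level permutation null, and Bland-Altman agreement.

Leave-one-recording-out (LORO) CV holds out *all* windows of one
recording at a time; z-scoring is refit on each training fold so no test
statistics leak into training.  The permutation test shuffles the
recording-level (start, end) pain-score pairs across recordings — the
recording is the exchangeable unit, and keeping each pair together
preserves within-recording score structure — re-runs the full LORO
pipeline per permutation, and reports an add-one-smoothed p-value on the
Pearson r of the cross-validated predictions:

    p = (1 + #{null r >= observed r}) / (n_perm + 1)

ICC(3,1) is the two-way mixed-model, single-measure, *consistency*
intraclass correlation with windows as targets and {reported, predicted}
as the two fixed raters; it is invariant to a constant shift between the
raters.  Bland-Altman reports bias = mean(predicted - reported) and
limits of agreement bias +/- 1.96 * SD(differences) (sample SD); for
plotting, the x-axis is the reported (reference) score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import config_context

from . import features as feat
from . import modeling
from .modeling import ModelSpec

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    null: np.ndarray


@dataclass
class BlandAltman:
    bias: float
    lower: float
    upper: float
    differences: np.ndarray
    reference: np.ndarray


@dataclass
class EvalReport:
    """Cross-validated performance of one model."""

    r: float
    rmse: float
    icc31: float
    perm_p: float | None
    ba_bias: float
    ba_limits: tuple[float, float]
    n_windows: int
    n_recordings: int
    predictions: pd.DataFrame


# ---------------------------------------------------------------------------
# metrics

def pearson_r(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Product-moment correlation between predicted and reported scores."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if len(p) != len(o) or len(p) < 2:
        raise ValueError("need two equal-length vectors with >= 2 points")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(p, o).statistic)


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if len(p) != len(o) or len(p) == 0:
        raise ValueError("need two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def icc31(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Shrout-Fleiss ICC(3,1): two-way mixed, single measure, consistency.

    Computed from the two-way ANOVA decomposition of the n x 2 table with
    windows as rows and {reported, predicted} as columns:

        ICC = (MS_rows - MS_err) / (MS_rows + (k - 1) * MS_err),  k = 2.
    """
    x = np.column_stack([np.asarray(obs, dtype=float), np.asarray(pred, dtype=float)])
    n, k = x.shape
    if n < 2:
        raise ValueError("need >= 2 paired observations")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        raise ValueError("ICC undefined: no between-window variance")
    return float((ms_rows - ms_err) / denom)


def bland_altman(pred: Sequence[float], obs: Sequence[float]) -> BlandAltman:
    """Agreement between predicted and reported scores.

    ``differences = pred - obs``; limits are bias +/- 1.96 * SD (sample
    SD, ddof=1; zero for n identical differences).
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if len(p) != len(o) or len(p) < 2:
        raise ValueError("need two equal-length vectors with >= 2 points")
    d = p - o
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, lower=bias - 1.96 * sd, upper=bias + 1.96 * sd,
                       differences=d, reference=o)


# ---------------------------------------------------------------------------
# leave-one-recording-out CV

@dataclass
class _Fold:
    recording_id: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    X_train: pd.DataFrame          # z-scored, zero-variance columns dropped
    X_test: pd.DataFrame


def _prepare_folds(df: pd.DataFrame, feature_cols: Sequence[str]) -> list[_Fold]:
    """Per-fold standardized design matrices.

    Normalization depends only on the features, never on labels, so folds
    can be prepared once and reused across label permutations.
    """
    folds = []
    rec_ids = sorted(df["recording_id"].unique())
    if len(rec_ids) < 2:
        raise ValueError("leave-one-recording-out CV needs >= 2 recordings")
    groups = df.groupby("recording_id").indices
    all_idx = np.arange(len(df))
    Xall = df[list(feature_cols)].reset_index(drop=True)
    for rid in rec_ids:
        test_idx = np.asarray(groups[rid])
        train_mask = np.ones(len(df), dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        if len(train_idx) == 0:
            raise ValueError(f"fold {rid}: empty training set")
        Xtr, Xte, _ = feat.fit_apply_zscore(
            Xall.iloc[train_idx], Xall.iloc[test_idx], feature_cols=list(feature_cols)
        )
        folds.append(_Fold(rid, train_idx, test_idx, Xtr, Xte))
    return folds


def _cv_predict(folds: Sequence[_Fold], y: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Fit one model per fold and predict its held-out windows."""
    pred = np.full(int(max(f.test_idx.max() for f in folds)) + 1, np.nan)
    with config_context(assume_finite=True):
        for f in folds:
            model = modeling.fit_model(f.X_train, y[f.train_idx], spec)
            pred[f.test_idx] = modeling.predict(model, f.X_test)
    return pred


def loro_cv(
    df: pd.DataFrame,
    spec: ModelSpec,
    feature_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Leave-one-recording-out cross-validated predictions.

    ``df`` is a feature table (one row per window) carrying the meta
    columns ``recording_id, subject_id, half, label``.  Returns a copy of
    the meta columns plus ``pred`` and ``fold`` (the held-out
    recording_id).  Each window is predicted exactly once, by a model
    that never saw any window from its recording.
    """
    if spec.level == "individual" and df["subject_id"].nunique() > 1:
        raise ValueError("individual-level CV requires a single subject's windows")
    if feature_cols is None:
        feature_cols = [c for c in df.columns
                        if c not in feat.META_COLUMNS + ("start", "end")]
    df = df.reset_index(drop=True)
    folds = _prepare_folds(df, feature_cols)
    y = df["label"].to_numpy(dtype=float)
    pred = _cv_predict(folds, y, spec)
    out = df[list(feat.META_COLUMNS)].copy()
    out["pred"] = pred[: len(df)]
    out["fold"] = out["recording_id"]
    return out


def permutation_test(
    df: pd.DataFrame,
    spec: ModelSpec,
    n_perm: int = 1000,
    seed: int = 0,
    feature_cols: Sequence[str] | None = None,
    scores: Mapping[str, tuple[float, float]] | None = None,
) -> PermutationResult:
    """Permutation null for the LORO-CV Pearson r.

    Recording-level (start, end) score pairs are shuffled across
    recordings (kept as pairs), the full cross-validation is re-run per
    permutation, and the add-one-smoothed p-value is returned.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if feature_cols is None:
        feature_cols = [c for c in df.columns
                        if c not in feat.META_COLUMNS + ("start", "end")]
    df = df.reset_index(drop=True)
    folds = _prepare_folds(df, feature_cols)
    y_obs = df["label"].to_numpy(dtype=float)
    obs = pearson_r(_cv_predict(folds, y_obs, spec)[: len(df)], y_obs)

    rec_ids = sorted(df["recording_id"].unique())
    if scores is None:
        scores = _scores_from_table(df, rec_ids)
    half_is_first = (df["half"] == "first").to_numpy()
    rec_of_window = df["recording_id"].to_numpy()
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        donor = rng.permutation(len(rec_ids))
        pair_of = {rec_ids[i]: scores[rec_ids[donor[i]]] for i in range(len(rec_ids))}
        y_b = np.array([
            pair_of[r][0] if first else pair_of[r][1]
            for r, first in zip(rec_of_window, half_is_first)
        ], dtype=float)
        try:
            null[b] = pearson_r(_cv_predict(folds, y_b, spec)[: len(df)], y_b)
        except ValueError:
            # constant permuted labels or constant predictions: no signal
            null[b] = -np.inf
    p = (1 + int(np.sum(null >= obs))) / (n_perm + 1)
    return PermutationResult(p_value=float(p), observed=obs, null=null)


def _scores_from_table(df: pd.DataFrame, rec_ids: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Recover per-recording (start, end) scores from window labels.

    A half missing from the table (all its windows unstable) falls back to
    the other half's score; the missing half's value is never used for the
    recording itself, only when the pair is donated under permutation.
    """
    out = {}
    for rid, grp in df.groupby("recording_id"):
        first = grp.loc[grp["half"] == "first", "label"]
        second = grp.loc[grp["half"] == "second", "label"]
        s = float(first.iloc[0]) if len(first) else float(second.iloc[0])
        e = float(second.iloc[0]) if len(second) else float(first.iloc[0])
        out[rid] = (s, e)
    return out


def evaluate(
    df: pd.DataFrame,
    spec: ModelSpec,
    *,
    n_perm: int = 0,
    perm_seed: int = 0,
    feature_cols: Sequence[str] | None = None,
    recording_means: bool = False,
) -> EvalReport:
    """LORO-CV a model and compute the full metric panel.

    With ``recording_means=True`` the metrics are computed on per-recording
    mean predicted/reported scores instead of per-window values.
    """
    preds = loro_cv(df, spec, feature_cols=feature_cols)
    if recording_means:
        agg = preds.groupby("recording_id")[["pred", "label"]].mean()
        p, o = agg["pred"].to_numpy(), agg["label"].to_numpy()
    else:
        p, o = preds["pred"].to_numpy(), preds["label"].to_numpy()
    ba = bland_altman(p, o)
    perm_p = None
    if n_perm > 0:
        perm_p = permutation_test(
            df, spec, n_perm=n_perm, seed=perm_seed, feature_cols=feature_cols
        ).p_value
    return EvalReport(
        r=pearson_r(p, o),
        rmse=rmse(p, o),
        icc31=icc31(p, o),
        perm_p=perm_p,
        ba_bias=ba.bias,
        ba_limits=(ba.lower, ba.upper),
        n_windows=len(preds),
        n_recordings=preds["recording_id"].nunique(),
        predictions=preds,
    )
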