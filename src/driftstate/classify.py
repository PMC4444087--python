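"""Training, tuning and cross-validated comparison of state classifiers.

Four methods are compared for separating "at sea" (S) from "on board" (B)
positions: a speed filter (VEL) whose threshold is the maximum at-sea speed
observed in the training data, multiple logistic regression (MLR), a
single-hidden-layer neural network (ANN) and a random forest (RF). The three
statistical methods are tuned caret-style: for each configuration-parameter
grid point, bootstrap resamples of the training set are fitted and scored on
the out-of-bag rows by accuracy and Cohen's Kappa, and the grid point with
the best mean accuracy (Kappa as tie-break) is refitted on the full training
set. Cross-validation splits by *trajectory*, never by position.

Performance is summarized by five indicators: error rate, precision, True
Sea Rate (sensitivity for S), False Sea Rate (share of true B predicted S)
and the segmentation rate (relative excess of predicted state segments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_COLUMNS

METHODS = ("vel", "mlr", "ann", "rf")


@dataclass
class VelModel:
    """Speed filter: speed <= threshold is classified S (inclusive, since the
    threshold is defined as the maximum observed at-sea speed)."""

    threshold: float

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


@dataclass
class TuningGrid:
    """Configuration-parameter grids and bootstrap settings.

    Defaults are scaled for desk runs; ``full_scale`` restores the full-size
    protocol (200 bootstrap iterations).
    """

    mlr_decay: tuple[float, ...] = (0.0, 0.1)
    ann_decay: tuple[float, ...] = (0.1,)
    ann_size: tuple[int, ...] = (5,)
    rf_mtry: tuple[int, ...] = (2, 3, 4)
    n_boot: int = 25
    rf_trees: int = 200
    rf_boot_trees: int = 60  # smaller forest while scoring bootstrap resamples
    ann_max_iter: int = 300

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        for g in (self.mlr_decay, self.ann_decay, self.ann_size, self.rf_mtry):
            if len(g) == 0:
                raise ValueError("tuning grids must be non-empty")

    @classmethod
    def full_scale(cls) -> "TuningGrid":
        return cls(
            mlr_decay=(0.0, 0.01, 0.1),
            ann_decay=(0.01, 0.1, 0.5),
            ann_size=(3, 5, 10),
            rf_mtry=(2, 3, 4, 6),
            n_boot=200,
            rf_trees=500,
            rf_boot_trees=500,
            ann_max_iter=500,
        )

    def points(self, method: str) -> list[dict]:
        if method == "mlr":
            return [{"decay": w} for w in self.mlr_decay]
        if method == "ann":
            return [{"decay": w, "size": s} for w in self.ann_decay for s in self.ann_size]
        if method == "rf":
            return [{"mtry": m} for m in self.rf_mtry]
        raise ValueError(f"no tuning grid for method {method!r}")


@dataclass
class ConfusionCounts:
    ts: int
    tb: int
    fs: int
    fb: int

    @property
    def n(self) -> int:
        return self.ts + self.tb + self.fs + self.fb


@dataclass
class PerformanceIndicators:
    error_rate: float
    precision: float
    tsr: float
    fsr: float
    segmentation_rate: float

    def as_dict(self) -> dict:
        return {
            "error_rate": self.error_rate,
            "precision": self.precision,
            "tsr": self.tsr,
            "fsr": self.fsr,
            "segmentation_rate": self.segmentation_rate,
        }


INDICATORS = ("error_rate", "precision", "tsr", "fsr", "segmentation_rate")


def count_segments(states) -> int:
    """Number of maximal runs of equal state in a sequence over {S, B}."""
    s = np.asarray(list(states))
    if s.size == 0:
        raise ValueError("empty state sequence")
    return int(1 + (s[1:] != s[:-1]).sum())


def confusion_counts(true, pred) -> ConfusionCounts:
    t = np.asarray(list(true))
    p = np.asarray(list(pred))
    if t.shape != p.shape:
        raise ValueError("true and pred must have equal length")
    return ConfusionCounts(
        ts=int(((p == "S") & (t == "S")).sum()),
        tb=int(((p == "B") & (t == "B")).sum()),
        fs=int(((p == "S") & (t == "B")).sum()),
        fb=int(((p == "B") & (t == "S")).sum()),
    )


def compute_indicators(true, pred, track_ids=None) -> PerformanceIndicators:
    """The five performance indicators for one prediction.

    With ``track_ids``, segment counts are summed per track (a track boundary
    is not a state transition). FSR is NaN when no B is observed, precision
    NaN when no S is predicted.
    """
    t = np.asarray(list(true))
    p = np.asarray(list(pred))
    if t.shape != p.shape:
        raise ValueError("true and pred must have equal length")
    if t.size == 0:
        raise ValueError("empty sequences")
    c = confusion_counts(t, p)
    s_obs = c.ts + c.fb
    s_pred = c.ts + c.fs
    b_obs = c.tb + c.fs
    if track_ids is None:
        groups = [np.arange(t.size)]
    else:
        ids = np.asarray(track_ids)
        groups = [np.flatnonzero(ids == u) for u in pd.unique(ids)]
    seg_obs = sum(count_segments(t[g]) for g in groups)
    seg_pred = sum(count_segments(p[g]) for g in groups)
    return PerformanceIndicators(
        error_rate=(c.fb + c.fs) / c.n,
        precision=c.ts / s_pred if s_pred else np.nan,
        tsr=c.ts / s_obs if s_obs else np.nan,
        fsr=c.fs / b_obs if b_obs else np.nan,
        segmentation_rate=(seg_pred - seg_obs) / seg_obs,
    )


def calibrate_vel(speeds, labels) -> VelModel:
    """Threshold = maximum finite speed among at-sea labelled positions."""
    sp = np.asarray(speeds, dtype=float)
    lb = np.asarray(list(labels))
    sel = (lb == "S") & np.isfinite(sp)
    if not sel.any():
        raise ValueError("no at-sea position with finite speed")
    return VelModel(threshold=float(sp[sel].max()))


def vel_classify(speeds, model: VelModel) -> np.ndarray:
    sp = np.asarray(speeds, dtype=float)
    return np.where(sp <= model.threshold, "S", "B")


def _make_estimator(method: str, params: dict, grid: TuningGrid, seed: int):
    if method == "mlr":
        w = params["decay"]
        c = 1e8 if w == 0 else 1.0 / w
        return make_pipeline(
            StandardScaler(), LogisticRegression(C=c, max_iter=1000)
        )
    if method == "ann":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(params["size"],),
                alpha=params["decay"],
                max_iter=grid.ann_max_iter,
                random_state=seed,
            ),
        )
    if method == "rf":
        return RandomForestClassifier(
            n_estimators=grid.rf_trees,
            max_features=params["mtry"],
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown method {method!r}")


def train_classifier(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: TuningGrid | None = None,
    seed: int = 0,
):
    """Bootstrap-tuned fit of one statistical classifier.

    Each grid point is scored by mean out-of-bag accuracy over ``n_boot``
    bootstrap resamples, with mean Kappa breaking ties; the winner is
    refitted on the full training set. Returns (estimator, chosen_params).
    """
    grid = grid or TuningGrid()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    points = grid.points(method)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3001]))
    if len(points) == 1:
        best = points[0]
    else:
        n = len(y)
        scores = []
        for params in points:
            accs, kappas = [], []
            for _ in range(grid.n_boot):
                idx = rng.integers(0, n, size=n)
                oob = np.setdiff1d(np.arange(n), idx)
                if oob.size == 0 or len(np.unique(y[idx])) < 2:
                    continue
                est = _make_estimator(method, params, grid, seed)
                if method == "rf":
                    est.set_params(n_estimators=min(grid.rf_trees, grid.rf_boot_trees))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[idx], y[idx])
                    pred = est.predict(X[oob])
                accs.append((pred == y[oob]).mean())
                kappas.append(cohen_kappa_score(y[oob], pred))
            scores.append((np.mean(accs), np.mean(kappas)))
        best = points[int(np.lexsort((-np.array([k for _, k in scores]),
                                      -np.array([a for a, _ in scores])))[0])]
    est = _make_estimator(method, best, grid, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return est, best


def predict_states(est, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Probability of S thresholded at ``threshold`` (default 0.5)."""
    proba = est.predict_proba(np.asarray(X, dtype=float))
    s_col = list(est.classes_).index("S")
    return np.where(proba[:, s_col] >= threshold, "S", "B")


@dataclass
class CvResult:
    """Per-repeat, per-method indicators plus (optionally) raw predictions."""

    results: pd.DataFrame
    n_repeats: int
    predictions: dict[int, pd.DataFrame] = field(default_factory=dict)
    splits: dict[int, tuple[tuple, tuple]] = field(default_factory=dict)


def cross_validate(
    learning: pd.DataFrame,
    methods=METHODS,
    n_repeats: int = 20,
    split: float = 0.5,
    seed: int = 0,
    grid: TuningGrid | None = None,
    feature_columns=FEATURE_COLUMNS,
    keep_predictions: bool = False,
    rebalance: bool = False,
) -> CvResult:
    """Repeated random trajectory-level split cross-validation.

    ``learning`` carries buoy_id, state and the feature columns. Each repeat
    splits the *trajectories* (not positions) in half, calibrates every
    method on the training half and scores the five indicators on the
    validation half. With ``rebalance`` the majority class of the training
    rows is subsampled to parity before fitting (off by default).
    """
    grid = grid or TuningGrid()
    ids = pd.unique(learning["buoy_id"])
    if len(ids) < 4:
        raise ValueError("need at least 4 trajectories to split")
    rows = []
    predictions: dict[int, pd.DataFrame] = {}
    splits: dict[int, tuple[tuple, tuple]] = {}
    for rep in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 4001, rep]))
        perm = rng.permutation(ids)
        n_train = int(round(split * len(ids)))
        train_ids = set(perm[:n_train])
        splits[rep] = (tuple(sorted(train_ids)), tuple(sorted(set(ids) - train_ids)))
        train = learning.loc[learning["buoy_id"].isin(train_ids)]
        valid = learning.loc[~learning["buoy_id"].isin(train_ids)].sort_values(
            ["buoy_id", "time"], kind="stable"
        )
        fit_rows = train
        if rebalance:
            counts = train["state"].value_counts()
            minority = counts.idxmin()
            keep_n = counts.min()
            parts = []
            for cls, g in train.groupby("state"):
                if cls == minority:
                    parts.append(g)
                else:
                    sel = rng.choice(len(g), size=keep_n, replace=False)
                    parts.append(g.iloc[np.sort(sel)])
            fit_rows = pd.concat(parts)
        Xtr = fit_rows[list(feature_columns)].to_numpy(dtype=float)
        ytr = fit_rows["state"].to_numpy()
        Xva = valid[list(feature_columns)].to_numpy(dtype=float)
        yva = valid["state"].to_numpy()
        tids = valid["buoy_id"].to_numpy()
        pred_frame = valid[["buoy_id", "time"]].copy()
        pred_frame["state_true"] = yva
        for method in methods:
            if method == "vel":
                model = calibrate_vel(train["speed"], train["state"])
                pred = vel_classify(valid["speed"], model)
            else:
                est, _ = train_classifier(method, Xtr, ytr, grid, seed=seed + rep)
                pred = predict_states(est, Xva)
            ind = compute_indicators(yva, pred, tids)
            rows.append({"repeat": rep, "method": method, **ind.as_dict()})
            pred_frame[f"pred_{method}"] = pred
        if keep_predictions:
            predictions[rep] = pred_frame.reset_index(drop=True)
    return CvResult(
        results=pd.DataFrame(rows), n_repeats=n_repeats,
        predictions=predictions, splits=splits,
    )


def compare_methods(cv: CvResult, reference: str = "vel", alpha: float = 0.05) -> pd.DataFrame:
    """Mean indicators and paired two-sided t-test comparison to a reference.

    For every non-reference method and indicator the mean difference to the
    reference over CV repeats, its t-based 95% confidence interval and the
    paired t-test p-value are reported.
    """
    res = cv.results
    wide = {m: g.sort_values("repeat").set_index("repeat") for m, g in res.groupby("method")}
    if reference not in wide:
        raise ValueError(f"reference method {reference!r} not in results")
    rows = []
    for method, g in wide.items():
        for ind in INDICATORS:
            x = g[ind].to_numpy(dtype=float)
            row = {"method": method, "indicator": ind, "mean": np.nanmean(x)}
            if method != reference:
                d = x - wide[reference][ind].to_numpy(dtype=float)
                d = d[np.isfinite(d)]
                if d.size >= 2:
                    m, sd = d.mean(), d.std(ddof=1)
                    if sd == 0:
                        lo = hi = m
                        pval = np.nan if m == 0 else 0.0
                    else:
                        tq = stats.t.ppf(1 - alpha / 2, d.size - 1)
                        lo, hi = m - tq * sd / np.sqrt(d.size), m + tq * sd / np.sqrt(d.size)
                        pval = stats.ttest_rel(
                            x[np.isfinite(x)], wide[reference][ind].to_numpy(dtype=float)[np.isfinite(x)]
                        ).pvalue
                    row.update({"diff_mean": m, "ci_low": lo, "ci_high": hi, "p_value": pval})
            rows.append(row)
    return pd.DataFrame(rows)


def optimize_threshold(probabilities, labels) -> float:
    """Probability cut maximizing sensitivity + specificity for class S.

    Optional alternative to the default 0.5 cut for imbalanced data; scans
    midpoints between consecutive distinct predicted probabilities.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(list(labels))
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    uniq = np.unique(p)
    cands = np.concatenate([[0.0], (uniq[1:] + uniq[:-1]) / 2.0, [1.0]])
    best_t, best_j = 0.5, -np.inf
    n_s = (y == "S").sum()
    n_b = (y == "B").sum()
    for t in cands:
        pred_s = p >= t
        sens = (pred_s & (y == "S")).sum() / n_s
        spec = (~pred_s & (y == "B")).sum() / n_b
        if sens + spec > best_j:
            best_j, best_t = sens + spec, t
    return float(best_t)
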