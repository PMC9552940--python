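"""Random-forest ICP regression and its evaluation machinery.

Fivefold cross-validation (random 80/20 splits stratified so every
subject appears in every train and test block), a 100-tree random forest
with 50% feature sampling and 80% bootstrap subsampling, r2/MSE scoring,
Bland-Altman limits of agreement, split-fraction and impurity feature
importance, a 10,000-draw bootstrap comparison of two models' r2, and the
two ablation experiments (drop MAP; rebalance the low-ICP-heavy label
distribution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .features import FEATURE_NAMES

__all__ = [
    "RFConfig",
    "CVReport",
    "cv_split",
    "train_rf",
    "evaluate",
    "bland_altman",
    "feature_importance",
    "bootstrap_compare",
    "run_cv",
    "ablate_map",
    "balance_dataset",
]


@dataclass
class RFConfig:
    """Forest hyperparameters: 100 trees, 50% features, 80% bootstrap.

    Trees are grown to purity (no depth limit) with the squared-error
    split criterion; feature subsampling is applied at each split, as the
    reference scikit-learn estimator does.
    """

    n_trees: int = 100
    max_features_fraction: float = 0.5
    subsample_fraction: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.max_features_fraction <= 1 or not 0 < self.subsample_fraction <= 1:
            raise ValueError("fractions must be in (0, 1]")
        if self.n_trees < 1:
            raise ValueError("need at least one tree")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CVReport:
    """Per-fold and pooled cross-validation results for one modality."""

    modality: str
    feature_names: list[str]
    fold_r2: list[float]
    fold_mse: list[float]
    predictions: np.ndarray  # pooled out-of-fold ICPest
    labels: np.ndarray  # matching ICPinv
    ba_mean: float
    ba_lo: float
    ba_hi: float
    split_fraction: np.ndarray  # per-feature, fold-averaged
    split_fraction_sd: np.ndarray  # between-tree SD, fold-averaged
    impurity_importance: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def r2_sd(self) -> float:
        return float(np.std(self.fold_r2))

    @property
    def mse_mean(self) -> float:
        return float(np.mean(self.fold_mse))

    @property
    def mse_sd(self) -> float:
        return float(np.std(self.fold_mse))

    def summary(self) -> dict:
        return {
            "modality": self.modality,
            "r2": self.r2_mean,
            "r2_sd": self.r2_sd,
            "mse_mmHg2": self.mse_mean,
            "mse_sd": self.mse_sd,
            "ci95_mmHg": [self.ba_lo, self.ba_hi],
            "mean_diff_mmHg": self.ba_mean,
            "split_fraction": dict(zip(self.feature_names, self.split_fraction.tolist())),
            "split_fraction_sd": dict(
                zip(self.feature_names, self.split_fraction_sd.tolist())
            ),
            "impurity_importance": dict(
                zip(self.feature_names, self.impurity_importance.tolist())
            ),
            **self.meta,
        }


def cv_split(
    subjects: np.ndarray, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition stratified by subject.

    Each subject's rows are shuffled and dealt into ``k`` nearly equal
    chunks (rotated per subject so fold sizes balance), so every subject
    appears in every train and test block whenever it has at least ``k``
    rows.  Returns ``k`` (train_idx, test_idx) pairs; the test blocks are
    disjoint and cover all rows.
    """
    subjects = np.asarray(subjects)
    n = len(subjects)
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} rows for {k}-fold CV")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for s_i, s in enumerate(pd.unique(subjects)):
        idx = np.flatnonzero(subjects == s)
        if len(idx) < k:
            warnings.warn(f"subject {s} has fewer than {k} rows: best-effort split")
        rng.shuffle(idx)
        chunks = np.array_split(idx, k)
        for j, chunk in enumerate(chunks):
            folds[(j + s_i) % k].extend(chunk.tolist())
    out = []
    for j in range(k):
        test = np.sort(np.asarray(folds[j], dtype=np.int64))
        train = np.sort(
            np.asarray([i for jj in range(k) if jj != j for i in folds[jj]], dtype=np.int64)
        )
        out.append((train, test))
    return out


def train_rf(x: np.ndarray, y: np.ndarray, cfg: RFConfig) -> RandomForestRegressor:
    """Fit the forest: trees to purity on bootstrap subsamples."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 10:
        raise ValueError("need at least 10 training rows")
    if np.ptp(y) == 0:
        warnings.warn("constant training label: the model is a constant predictor")
    model = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features_fraction,
        max_samples=cfg.subsample_fraction,
        bootstrap=True,
        criterion="squared_error",
        max_depth=None,
        random_state=cfg.rng_seed,
        n_jobs=1,
    )
    model.fit(x, y)
    return model


def evaluate(
    model: RandomForestRegressor, x: np.ndarray, y: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """(r2, MSE, predictions) on a test set.

    ``r2 = 1 - SSE/SST`` with population variance, so the identity
    ``r2 = 1 - MSE/var(y)`` holds to machine precision.  Zero label
    variance makes r2 undefined (NaN, with a warning).
    """
    y = np.asarray(y, dtype=np.float64)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = model.predict(np.asarray(x, dtype=np.float64))
    mse = float(np.mean((pred - y) ** 2))
    var = float(np.var(y))
    if var == 0:
        warnings.warn("zero label variance: r2 undefined")
        return float("nan"), mse, pred
    return 1.0 - mse / var, mse, pred


def bland_altman(
    preds: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """(mean difference, lower, upper 95% limit of agreement).

    Differences are ICPest - ICPinv; limits are mean +/- 1.96 population
    SD of the differences.
    """
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if len(preds) != len(labels) or len(preds) < 2:
        raise ValueError("need equal-length prediction/label vectors of length >= 2")
    d = preds - labels
    m = float(np.mean(d))
    sd = float(np.std(d))
    return m, m - 1.96 * sd, m + 1.96 * sd


def feature_importance(
    model: RandomForestRegressor,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(split fraction, its between-tree SD, impurity importance).

    The split fraction of a feature is the fraction of internal node
    splits that use it, averaged over trees; both it and the
    impurity-decrease importance sum to 1 over features.
    """
    n_feat = model.n_features_in_
    fracs = np.zeros((len(model.estimators_), n_feat))
    for t_i, tree in enumerate(model.estimators_):
        feats = tree.tree_.feature
        internal = feats[feats >= 0]
        if len(internal):
            fracs[t_i] = np.bincount(internal, minlength=n_feat) / len(internal)
    return fracs.mean(axis=0), fracs.std(axis=0), model.feature_importances_


def _boot_r2(
    preds: np.ndarray, labels: np.ndarray, n_boot: int, frac: float, rng: np.random.Generator
) -> np.ndarray:
    n = len(preds)
    m = int(np.ceil(frac * n))
    idx = rng.integers(0, n, size=(n_boot, m))
    p, l = preds[idx], labels[idx]
    sse = ((p - l) ** 2).mean(axis=1)
    var = l.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - sse / var
    return r2


def bootstrap_compare(
    preds_a: np.ndarray,
    labels_a: np.ndarray,
    preds_b: np.ndarray,
    labels_b: np.ndarray,
    n_boot: int = 10000,
    frac: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Bootstrap comparison of two models' r2 distributions.

    Draws ``frac`` of each test set with replacement ``n_boot`` times,
    computes r2 per draw, and decides significance by whether the
    (alpha, 1 - alpha) percentile interval of the per-draw r2 difference
    excludes zero.  Draws for the two models are independent streams
    paired by draw index.
    """
    rng = np.random.default_rng(seed)
    preds_a, labels_a = np.asarray(preds_a, float), np.asarray(labels_a, float)
    preds_b, labels_b = np.asarray(preds_b, float), np.asarray(labels_b, float)
    if len(preds_a) == 0 or len(preds_b) == 0:
        raise ValueError("empty prediction sets")
    r2a = _boot_r2(preds_a, labels_a, n_boot, frac, rng)
    r2b = _boot_r2(preds_b, labels_b, n_boot, frac, rng)
    ok = np.isfinite(r2a) & np.isfinite(r2b)
    diff = r2a[ok] - r2b[ok]
    lo, hi = np.quantile(diff, [alpha, 1.0 - alpha])
    significant = bool(lo > 0 or hi < 0)
    def summarize(r2):
        r2 = r2[np.isfinite(r2)]
        return {
            "p05": float(np.quantile(r2, 0.05)),
            "mean": float(np.mean(r2)),
            "p95": float(np.quantile(r2, 0.95)),
        }
    return {
        "r2_a": r2a,
        "r2_b": r2b,
        "summary_a": summarize(r2a),
        "summary_b": summarize(r2b),
        "diff_interval": (float(lo), float(hi)),
        "significant": significant,
        "better": "a" if np.mean(diff) > 0 else "b",
    }


def run_cv(
    table: pd.DataFrame,
    modality: str | None = None,
    cfg: RFConfig | None = None,
    k: int = 5,
    seed: int = 0,
    features: list[str] | None = None,
) -> CVReport:
    """Full fivefold CV for one modality; pools out-of-fold predictions."""
    cfg = cfg or RFConfig()
    features = features or FEATURE_NAMES
    df = table if modality is None else table[table["modality"] == modality]
    df = df.reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no rows for modality {modality!r}")
    x = df[features].to_numpy(dtype=np.float64)
    y = df["label_icp"].to_numpy(dtype=np.float64)
    splits = cv_split(df["subject_id"].to_numpy(), k=k, seed=seed)
    pooled_pred = np.full(len(df), np.nan)
    fold_r2, fold_mse = [], []
    sf = np.zeros((k, len(features)))
    sf_sd = np.zeros((k, len(features)))
    imp = np.zeros((k, len(features)))
    for j, (train, test) in enumerate(splits):
        fold_cfg = RFConfig(
            cfg.n_trees, cfg.max_features_fraction, cfg.subsample_fraction,
            rng_seed=cfg.rng_seed + j,
        )
        model = train_rf(x[train], y[train], fold_cfg)
        r2, mse, pred = evaluate(model, x[test], y[test])
        fold_r2.append(r2)
        fold_mse.append(mse)
        pooled_pred[test] = pred
        sf[j], sf_sd[j], imp[j] = feature_importance(model)
    ba_mean, ba_lo, ba_hi = bland_altman(pooled_pred, y)
    return CVReport(
        modality=modality or "all",
        feature_names=list(features),
        fold_r2=fold_r2,
        fold_mse=fold_mse,
        predictions=pooled_pred,
        labels=y,
        ba_mean=ba_mean,
        ba_lo=ba_lo,
        ba_hi=ba_hi,
        split_fraction=sf.mean(axis=0),
        split_fraction_sd=sf_sd.mean(axis=0),
        impurity_importance=imp.mean(axis=0),
        meta={"k": k, "seed": seed, "n_rows": int(len(df))},
    )


def ablate_map(
    table: pd.DataFrame,
    modality: str | None = None,
    cfg: RFConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Rerun the CV with MAP removed from the feature set."""
    features = [f for f in FEATURE_NAMES if f != "MAP"]
    return run_cv(table, modality=modality, cfg=cfg, k=k, seed=seed, features=features)


def balance_dataset(
    table: pd.DataFrame,
    low: float = 5.0,
    high: float = 10.0,
    remove_frac: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Rebalance the label distribution by thinning the low-ICP band.

    Rows with ``low <= label_icp <= high`` are subsampled without
    replacement, keeping ``1 - remove_frac`` of them; all other rows are
    kept.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    in_band = np.flatnonzero(
        (table["label_icp"] >= low) & (table["label_icp"] <= high)
    )
    n_keep = int(round((1.0 - remove_frac) * len(in_band)))
    keep_band = rng.choice(in_band, size=n_keep, replace=False) if len(in_band) else in_band
    out_band = np.setdiff1d(np.arange(len(table)), in_band)
    keep = np.sort(np.concatenate([out_band, keep_band]))
    return table.iloc[keep].reset_index(drop=True)
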