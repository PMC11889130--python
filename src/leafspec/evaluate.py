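"""Splitting, scaling, metrics, and the preprocessing × selector × model
evaluation grid.

The pipeline order for every combination is fixed and leakage-free:

    split -> preprocess (fit on train, apply to both)
          -> Pearson profile + band mask on train
          -> feature extractor fit on train, applied to test
          -> min-max scale features and target (training statistics)
          -> fit model -> predict test -> invert target scaling
          -> metrics in SPAD units

Metrics are the coefficient of determination R^2 (measured-centered
denominator), RMSE, and NRMSE = RMSE / mean(measured).  The grid runner
evaluates all 27 (preprocessing, selector, model) cells on one shared
train/test split so cells are comparable, and never aborts on a failed
cell — failures are recorded with their error message.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SpectraSet, TargetVector, check_aligned
from .models import (
    ForestConfig,
    GABPConfig,
    KernelConfig,
    forest_fit,
    gabp_fit,
    kernel_fit,
)
from .preprocess import msc_fit, msc_transform, snv_transform
from .select import gbt_importance_select, pca_project, pearson_profile, rfe_select, threshold_mask

logger = logging.getLogger(__name__)

PREPROCESSINGS = ("original", "snv", "msc")
SELECTORS = ("gbt", "rfe", "pca")
MODELS = ("gabp", "rfr", "svr")

__all__ = [
    "SplitSpec",
    "Scaler",
    "EvaluationResult",
    "GridReport",
    "PipelineConfigs",
    "PipelineFit",
    "split",
    "fit_scaler",
    "metrics",
    "fit_pipeline",
    "predict_pipeline",
    "run_combination",
    "run_grid",
]


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Hold-out split: seeded uniform shuffle, first floor(f*n) to train."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split(
    spectra: SpectraSet, targets: TargetVector, spec: SplitSpec = SplitSpec()
) -> tuple[tuple[SpectraSet, TargetVector], tuple[SpectraSet, TargetVector]]:
    """Deterministic 7:3-style hold-out split (91 samples -> 63/28)."""
    check_aligned(spectra, targets)
    n = spectra.n_samples
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    perm = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(np.floor(spec.train_fraction * n))
    tr, te = perm[:n_train], perm[n_train:]
    return (spectra.take(tr), targets.take(tr)), (spectra.take(te), targets.take(te))


@dataclasses.dataclass(eq=False)
class Scaler:
    """Min-max scaler for features and target, fitted on training data only.

    Features and target map to [0, 1] over the training range; held-out
    values outside that range pass through un-clipped.  A constant
    training feature maps to 0.5 (flagged with a warning at fit time).
    """

    feat_min: np.ndarray
    feat_max: np.ndarray
    y_min: float
    y_max: float

    @property
    def constant_features(self) -> np.ndarray:
        return self.feat_max == self.feat_min

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = np.where(self.constant_features, 1.0, self.feat_max - self.feat_min)
        out = (X - self.feat_min) / span
        out[:, self.constant_features] = 0.5
        return out

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        if self.y_max == self.y_min:
            return np.full_like(np.asarray(y, dtype=float), 0.5)
        return (np.asarray(y, dtype=float) - self.y_min) / (self.y_max - self.y_min)

    def invert_y(self, y_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(y_scaled, dtype=float) * (self.y_max - self.y_min) + self.y_min


def fit_scaler(X_train: np.ndarray, y_train: np.ndarray) -> Scaler:
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    fmin, fmax = X.min(axis=0), X.max(axis=0)
    if np.any(fmax == fmin):
        warnings.warn(f"{int((fmax == fmin).sum())} constant training features "
                      "map to 0.5", stacklevel=2)
    if y.max() == y.min():
        warnings.warn("constant training target; scaled target is 0.5 everywhere",
                      stacklevel=2)
    return Scaler(feat_min=fmin, feat_max=fmax, y_min=float(y.min()), y_max=float(y.max()))


@dataclasses.dataclass(frozen=True)
class EvaluationResult:
    """Hold-out metrics in SPAD units."""

    r2: float
    rmse: float
    nrmse: float
    n_test: int


def metrics(measured: np.ndarray, predicted: np.ndarray) -> EvaluationResult:
    """R^2, RMSE and NRMSE = RMSE / mean(measured)."""
    y = np.asarray(measured, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if y.size != p.size:
        raise ValueError(f"length mismatch: {y.size} measured vs {p.size} predicted")
    if y.size < 2:
        raise ValueError("need at least 2 values")
    ybar = y.mean()
    if ybar == 0:
        raise ValueError("mean of measured values is zero; NRMSE undefined")
    sse = float(np.sum((y - p) ** 2))
    sst = float(np.sum((y - ybar) ** 2))
    if sst == 0:
        raise ValueError("measured values are constant; R^2 undefined")
    rmse = float(np.sqrt(sse / y.size))
    return EvaluationResult(r2=1.0 - sse / sst, rmse=rmse, nrmse=rmse / ybar,
                            n_test=int(y.size))


@dataclasses.dataclass(frozen=True)
class PipelineConfigs:
    """Every tunable of the pipeline stages in one place."""

    threshold: float = 0.6      # Pearson |r| cut for the band mask
    k: int = 10                 # bands kept by gbt/rfe extractors
    cum_var: float = 0.99       # cumulative explained variance kept by pca
    gabp: GABPConfig = GABPConfig()
    forest: ForestConfig = ForestConfig()
    kernel: KernelConfig = KernelConfig()


@dataclasses.dataclass(eq=False)
class PipelineFit:
    """All state fitted on the training split for one grid cell."""

    preprocessing: str
    selector: str
    model_name: str
    msc_ref: object | None
    profile: object
    mask: object
    features: object
    scaler: Scaler
    model: object


def _preprocess_train(train_s: SpectraSet, method: str):
    """Fit preprocessing on train; return (train transformed, state)."""
    if method == "original":
        return train_s, None
    if method == "snv":
        return snv_transform(train_s), None
    if method == "msc":
        ref = msc_fit(train_s)
        return msc_transform(train_s, ref), ref
    raise ValueError(f"unknown preprocessing {method!r}")


def _preprocess_apply(test_s: SpectraSet, method: str, state) -> SpectraSet:
    if method == "original":
        return test_s
    if method == "snv":
        return snv_transform(test_s)
    if method == "msc":
        return msc_transform(test_s, state)
    raise ValueError(f"unknown preprocessing {method!r}")


def _fit_selector(train_s, train_t, mask, selector, cfg: PipelineConfigs, seed: int):
    if selector == "gbt":
        return gbt_importance_select(train_s, train_t, mask, k=cfg.k, seed=seed)
    if selector == "rfe":
        return rfe_select(train_s, train_t, mask, k=cfg.k, seed=seed)
    if selector == "pca":
        return pca_project(train_s, mask, cum_var=cfg.cum_var)
    raise ValueError(f"unknown selector {selector!r}")


def _fit_model(name: str, X: np.ndarray, y: np.ndarray, cfg: PipelineConfigs, seed: int):
    if name == "gabp":
        return gabp_fit(X, y, dataclasses.replace(cfg.gabp, seed=seed))
    if name == "rfr":
        return forest_fit(X, y, dataclasses.replace(cfg.forest, seed=seed))
    if name == "svr":
        return kernel_fit(X, y, cfg.kernel)
    raise ValueError(f"unknown model {name!r}")


def fit_pipeline(
    train_s: SpectraSet,
    train_t: TargetVector,
    preprocessing: str,
    selector: str,
    model: str,
    configs: PipelineConfigs = PipelineConfigs(),
    selector_seed: int = 0,
    model_seed: int = 0,
) -> PipelineFit:
    """Fit every pipeline stage using the training split only."""
    check_aligned(train_s, train_t)
    prep_s, state = _preprocess_train(train_s, preprocessing)
    profile = pearson_profile(prep_s, train_t)
    mask = threshold_mask(profile, configs.threshold)
    features = _fit_selector(prep_s, train_t, mask, selector, configs, selector_seed)
    logger.debug("cell (%s, %s, %s): %d features, wavelengths %s",
                 preprocessing, selector, model, features.n_features,
                 features.selected_wavelengths)
    scaler = fit_scaler(features.design_matrix, train_t.spad)
    Xs = scaler.transform(features.design_matrix)
    ys = scaler.transform_y(train_t.spad)
    fitted = _fit_model(model, Xs, ys, configs, model_seed)
    return PipelineFit(preprocessing=preprocessing, selector=selector,
                       model_name=model, msc_ref=state, profile=profile,
                       mask=mask, features=features, scaler=scaler, model=fitted)


def predict_pipeline(fit: PipelineFit, test_s: SpectraSet) -> np.ndarray:
    """Push held-out spectra through a fitted pipeline; SPAD predictions."""
    prep = _preprocess_apply(test_s, fit.preprocessing, fit.msc_ref)
    X = fit.scaler.transform(fit.features.transform(prep))
    return fit.scaler.invert_y(fit.model.predict(X))


def _derive_seed(master_seed: int, index: int) -> int:
    # stable per-stage integer seeds below 2**31
    return (int(master_seed) * 1000003 + index * 7919 + 17) % (2**31 - 1)


def run_combination(
    spectra: SpectraSet,
    targets: TargetVector,
    preprocessing: str,
    selector: str,
    model: str,
    split_spec: SplitSpec | None = None,
    configs: PipelineConfigs = PipelineConfigs(),
    master_seed: int = 0,
) -> EvaluationResult:
    """End-to-end evaluation of a single (preprocessing, selector, model) cell."""
    targets = targets.align_to(spectra)
    if split_spec is None:
        split_spec = SplitSpec(seed=master_seed)
    (tr_s, tr_t), (te_s, te_t) = split(spectra, targets, split_spec)
    pi = PREPROCESSINGS.index(preprocessing)
    si = SELECTORS.index(selector)
    idx = pi * 9 + si * 3 + MODELS.index(model)
    try:
        # seed scheme matches run_grid: selector seed per (preprocessing,
        # selector) pair, model seed per cell
        fit = fit_pipeline(tr_s, tr_t, preprocessing, selector, model, configs,
                           selector_seed=_derive_seed(master_seed, 100 + pi * 3 + si),
                           model_seed=_derive_seed(master_seed, 200 + idx))
        pred = predict_pipeline(fit, te_s)
    except Exception as exc:
        raise type(exc)(
            f"[{preprocessing}/{selector}/{model}] {exc}").with_traceback(
                exc.__traceback__) from None
    return metrics(te_t.spad, pred)


@dataclasses.dataclass(eq=False)
class GridReport:
    """27-row report of the full method grid on one shared split."""

    table: pd.DataFrame
    best_cell: tuple[str, str, str] | None
    master_seed: int

    def cell(self, preprocessing: str, selector: str, model: str) -> pd.Series:
        t = self.table
        row = t[(t.preprocessing == preprocessing) & (t.selector == selector)
                & (t.model == model)]
        return row.iloc[0]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False, float_format="%.12g")
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "master_seed": self.master_seed,
            "best_cell": list(self.best_cell) if self.best_cell else None,
            "rows": json.loads(self.table.to_json(orient="records")),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def run_grid(
    spectra: SpectraSet,
    targets: TargetVector,
    master_seed: int = 0,
    split_spec: SplitSpec | None = None,
    configs: PipelineConfigs = PipelineConfigs(),
    out_dir: str | Path | None = None,
) -> GridReport:
    """Evaluate all 27 cells of the method grid on one shared split.

    Preprocessing and feature extraction are computed once per
    (preprocessing, selector) pair and reused by the three models, which
    is both faster and exactly equivalent to running each cell in
    isolation with the same derived seeds.  A failed cell is recorded as
    NaN with its error message; the grid never aborts.
    """
    targets = targets.align_to(spectra)
    if split_spec is None:
        split_spec = SplitSpec(seed=master_seed)
    (tr_s, tr_t), (te_s, te_t) = split(spectra, targets, split_spec)

    rows = []
    for pi, prep in enumerate(PREPROCESSINGS):
        try:
            prep_tr, state = _preprocess_train(tr_s, prep)
            prep_te = _preprocess_apply(te_s, prep, state)
            profile = pearson_profile(prep_tr, tr_t)
            mask = threshold_mask(profile, configs.threshold)
            prep_err = None
        except Exception as exc:
            prep_err = f"{type(exc).__name__}: {exc}"
        for si, selector in enumerate(SELECTORS):
            feats = None
            sel_err = prep_err
            if sel_err is None:
                try:
                    feats = _fit_selector(
                        prep_tr, tr_t, mask, selector, configs,
                        seed=_derive_seed(master_seed, 100 + pi * 3 + si))
                    Xtr = feats.design_matrix
                    Xte = feats.transform(prep_te)
                except Exception as exc:
                    sel_err = f"{type(exc).__name__}: {exc}"
            for mi, model in enumerate(MODELS):
                idx = pi * 9 + si * 3 + mi
                record = {"preprocessing": prep, "selector": selector, "model": model,
                          "r2": np.nan, "nrmse": np.nan,
                          "n_train": tr_s.n_samples, "n_test": te_s.n_samples,
                          "status": "ok"}
                if sel_err is not None:
                    record["status"] = sel_err
                else:
                    try:
                        scaler = fit_scaler(Xtr, tr_t.spad)
                        fitted = _fit_model(model, scaler.transform(Xtr),
                                            scaler.transform_y(tr_t.spad),
                                            configs, _derive_seed(master_seed, 200 + idx))
                        pred = scaler.invert_y(fitted.predict(scaler.transform(Xte)))
                        res = metrics(te_t.spad, pred)
                        record["r2"], record["nrmse"] = res.r2, res.nrmse
                    except Exception as exc:
                        record["status"] = f"{type(exc).__name__}: {exc}"
                rows.append(record)

    table = pd.DataFrame(rows)
    best_cell = None
    if table["r2"].notna().any():
        i = table["r2"].idxmax()
        best_cell = (table.loc[i, "preprocessing"], table.loc[i, "selector"],
                     table.loc[i, "model"])
    report = GridReport(table=table, best_cell=best_cell, master_seed=master_seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "grid_report.csv")
        report.to_json(out_dir / "grid_report.json")
    return report
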