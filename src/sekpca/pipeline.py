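"""End-to-end runners: entropy features -> (none | PCA | KPCA) reduction ->
support-vector classification under stratified cross-validation.

The reduction stage is fitted on each training split only; held-out rows are
projected with the stored training statistics (feature means/SDs for PCA,
Gram centring means for KPCA), so no information from the held-out fold
reaches the fitted model. Reports carry per-fold held-out and training-fold
accuracies, the component counts used, pooled confusion counts and a full
config echo, and are bitwise-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .decomposition import (
    KernelSpec,
    cvc_select,
    kpca_fit,
    kpca_project,
    kpca_scores,
    pca_fit,
    pca_project,
    standardize,
    apply_standardize,
)
from .entropy import EntropyParams, epoch_feature_matrix
from .errors import ConfigurationError
from .features import FeatureMatrix, RawSignals

__all__ = [
    "PipelineConfig",
    "ClassificationReport",
    "make_stratified_folds",
    "run_pipeline",
    "compare_methods",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that defines one classification run.

    ``protocol`` is ``"cv"`` (stratified k-fold, default k=3) or
    ``"holdout"`` (single stratified split with ``train_fraction`` training
    rows). SVM defaults: RBF kernel, unit regularization, inverse-feature-
    count kernel scale.
    """

    estimator: str = "sample"
    reducer: str = "kpca"  # none | pca | kpca
    kernel: KernelSpec = field(default_factory=lambda: KernelSpec("rbf", delta=0.2))
    cvc_threshold: float = 0.90
    protocol: str = "cv"
    cv_folds: int = 3
    train_fraction: float = 0.70
    seed: int = 0
    svc_kernel: str = "rbf"
    svc_c: float = 1.0
    svc_gamma: str | float = "auto"
    standardize_features: bool = False  # z-score before 'none'/'kpca' reduction
    entropy: EntropyParams = field(default_factory=EntropyParams)
    epoch_len: float = 1.0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.reducer not in {"none", "pca", "kpca"}:
            raise ConfigurationError(f"unknown reducer {self.reducer!r}")
        if self.protocol not in {"cv", "holdout"}:
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if not 0 < self.cvc_threshold <= 1:
            raise ConfigurationError("cvc_threshold must be in (0, 1]")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        bits = [self.estimator, self.reducer]
        if self.reducer == "kpca":
            bits.append(self.kernel.family)
        return "_".join(bits)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel"] = self.kernel.to_dict()
        d["entropy"] = asdict(self.entropy)
        return d


@dataclass
class ClassificationReport:
    """Per-fold and aggregate accuracy (in percent) of one pipeline run."""

    protocol: str
    fold_accuracies: list[float]
    train_accuracies: list[float]
    mean_accuracy: float
    n_components: list[int]
    confusion: list[list[int]]  # pooled over held-out folds, rows = true class
    config: dict
    seed: int

    def __post_init__(self) -> None:
        if not all(0.0 <= a <= 100.0 for a in self.fold_accuracies):
            raise ConfigurationError("accuracies must lie in [0, 100]")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        lines = [f"protocol: {self.protocol}", f"seed: {self.seed}"]
        for i, (acc, k) in enumerate(zip(self.fold_accuracies, self.n_components)):
            lines.append(f"fold {i + 1}: acc={acc:.2f}% (k={k})")
        lines.append(f"mean accuracy: {self.mean_accuracy:.2f}%")
        return "\n".join(lines)


def make_stratified_folds(
    labels: Sequence[int], n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified fold assignments (train_idx, test_idx per fold)."""
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(labels.size), labels)]


def _as_features(
    data: FeatureMatrix | RawSignals, config: PipelineConfig
) -> FeatureMatrix:
    if isinstance(data, FeatureMatrix):
        return data
    if isinstance(data, RawSignals):
        if data.epoch_labels is None:
            raise ConfigurationError("raw signals need per-epoch labels")
        params = replace(config.entropy, estimator=config.estimator)
        return epoch_feature_matrix(
            data.values,
            rate=data.rate,
            epoch_len=config.epoch_len,
            params=params,
            labels=data.epoch_labels,
            channel_names=data.channel_names,
        )
    raise ConfigurationError("data must be a FeatureMatrix or RawSignals")


def _reduce_split(
    x_train: np.ndarray,
    x_test: np.ndarray,
    features: FeatureMatrix,
    config: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fit the reduction on the training rows only; project both splits."""
    if config.reducer == "none":
        if config.standardize_features:
            x_train, stats = standardize(x_train)
            x_test = apply_standardize(x_test, stats)
        return x_train, x_test, x_train.shape[1]
    if config.reducer == "pca":
        fit = pca_fit(x_train)
        k = cvc_select(fit.contribution_rates, config.cvc_threshold)
        return pca_project(x_train, fit, k), pca_project(x_test, fit, k), k
    fit = kpca_fit(
        x_train, config.kernel, standardize_input=config.standardize_features
    )
    k = cvc_select(fit.contribution_rates, config.cvc_threshold)
    return kpca_scores(fit, k), kpca_project(x_test, fit, k), k


def _make_svc(config: PipelineConfig) -> SVC:
    return SVC(kernel=config.svc_kernel, C=config.svc_c, gamma=config.svc_gamma)


def run_pipeline(
    data: FeatureMatrix | RawSignals,
    config: PipelineConfig,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ClassificationReport:
    """Run one configuration end to end and report held-out accuracy.

    ``folds`` lets callers impose precomputed fold assignments (used by
    :func:`compare_methods` so every configuration sees identical splits, and
    by leakage canaries that manipulate labels after splitting).
    """
    features = _as_features(data, config)
    labels = features.require_labels()
    classes = np.unique(labels)
    if classes.size < 2:
        raise ConfigurationError("need both classes present to classify")

    if folds is None:
        if config.protocol == "cv":
            folds = make_stratified_folds(labels, config.cv_folds, config.seed)
        else:
            tr, te = train_test_split(
                np.arange(labels.size),
                train_size=config.train_fraction,
                stratify=labels,
                random_state=config.seed,
            )
            folds = [(np.sort(tr), np.sort(te))]

    fold_acc: list[float] = []
    train_acc: list[float] = []
    n_comp: list[int] = []
    pooled = np.zeros((2, 2), dtype=int)
    for tr, te in folds:
        y_tr, y_te = labels[tr], labels[te]
        if np.unique(y_tr).size < 2:
            raise ConfigurationError(
                "a training fold contains one class only; use stratified splitting"
            )
        s_tr, s_te, k = _reduce_split(
            features.values[tr], features.values[te], features, config
        )
        clf = _make_svc(config).fit(s_tr, y_tr)
        pred_te = clf.predict(s_te)
        fold_acc.append(100.0 * float(np.mean(pred_te == y_te)))
        train_acc.append(100.0 * float(np.mean(clf.predict(s_tr) == y_tr)))
        n_comp.append(k)
        pooled += confusion_matrix(y_te, pred_te, labels=[0, 1])

    return ClassificationReport(
        protocol=config.protocol,
        fold_accuracies=fold_acc,
        train_accuracies=train_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        n_components=n_comp,
        confusion=pooled.tolist(),
        config=config.to_dict(),
        seed=config.seed,
    )


def compare_methods(
    data: FeatureMatrix | RawSignals,
    configs: Sequence[PipelineConfig],
) -> tuple[list[ClassificationReport], pd.DataFrame]:
    """Run several configurations on identical fold assignments.

    All configs must agree on protocol, fold count and seed (the folds are
    shared); offenders are listed in the error. Returns the reports plus a
    tidy table (one row per config) ordered as given.
    """
    if len(configs) < 2:
        raise ConfigurationError("compare_methods needs at least 2 configs")
    ref = configs[0]
    bad = [
        c.label
        for c in configs
        if (c.protocol, c.cv_folds, c.seed) != (ref.protocol, ref.cv_folds, ref.seed)
    ]
    if bad:
        raise ConfigurationError(
            f"configs with incompatible fold settings: {bad}"
        )
    needs_raw = {c.label for c in configs if c.estimator != ref.estimator}
    if isinstance(data, FeatureMatrix) and needs_raw:
        raise ConfigurationError(
            "these configs need raw signals to re-extract features with a "
            f"different estimator: {sorted(needs_raw)}"
        )

    # Feature extraction may differ per estimator, but folds must not: they
    # are drawn once from the (shared) label sequence.
    first_features = _as_features(data, ref)
    labels = first_features.require_labels()
    if ref.protocol == "cv":
        folds = make_stratified_folds(labels, ref.cv_folds, ref.seed)
    else:
        tr, te = train_test_split(
            np.arange(labels.size),
            train_size=ref.train_fraction,
            stratify=labels,
            random_state=ref.seed,
        )
        folds = [(np.sort(tr), np.sort(te))]

    reports = []
    rows = []
    cache: dict[str, FeatureMatrix] = {ref.estimator: first_features}
    for cfg in configs:
        if cfg.estimator not in cache:
            cache[cfg.estimator] = _as_features(data, cfg)
        rep = run_pipeline(cache[cfg.estimator], cfg, folds=folds)
        reports.append(rep)
        rows.append(
            {
                "method": cfg.label,
                "estimator": cfg.estimator,
                "reducer": cfg.reducer,
                "kernel": cfg.kernel.family if cfg.reducer == "kpca" else "",
                "cvc": cfg.cvc_threshold,
                "mean_accuracy": rep.mean_accuracy,
                **{
                    f"fold{i + 1}_accuracy": a
                    for i, a in enumerate(rep.fold_accuracies)
                },
            }
        )
    return reports, pd.DataFrame(rows)
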