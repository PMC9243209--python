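"""Classification of ULBPEZ features: SVM on padded token vectors and the
small CNN on feature images, under regrouped DR grading schemes.

Grades 0-4 (none, mild, moderate, severe NPDR, PDR) are rarely balanced in
screening data, so besides the binary normal/abnormal task two regroupings
are supported: the 0/1/5 scheme (moderate-and-worse collapsed into grade
"5") and the 0/M/S scheme of Shaban et al. (mild+moderate -> "M",
severe NPDR + PDR -> "S").  Data is split 70/30 stratified by class, and
the minority grades can be doubled by vertical mirroring before feature
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cnn import CNNArchitecture, SmallCNN, TrainConfig, cnn_output_shapes

__all__ = [
    "SVMConfig",
    "GradeScheme",
    "SCHEMES",
    "SplitSpec",
    "kernel_value",
    "regroup",
    "mirror_augment",
    "stratified_split",
    "train_svm",
    "predict_svm",
    "train_cnn",
    "predict_cnn",
    "CNNArchitecture",
    "TrainConfig",
    "cnn_output_shapes",
]

_KERNELS = ("linear", "rbf", "polynomial", "gaussian")


@dataclass
class SVMConfig:
    """Kernel choice and parameters.

    kernel formulas: linear K = x.y; rbf K = exp(-gamma ||x-y||^2);
    polynomial K = (1 + x.y)^q; gaussian K = exp(-||x-y||^2 / (2 sigma)).
    The gaussian denominator is 2*sigma by definition here (see the methods
    note); set ``gaussian_conventional=True`` for the usual 2*sigma^2.
    """

    kernel: str = "linear"
    gamma: float = 1.0
    sigma: float = 1.0
    degree: int = 2
    C: float = 1.0
    gaussian_conventional: bool = False

    def __post_init__(self) -> None:
        if self.kernel not in _KERNELS:
            raise ValueError(f"kernel must be one of {_KERNELS}")
        if self.kernel == "rbf" and self.gamma <= 0:
            raise ValueError("rbf kernel needs gamma > 0")
        if self.kernel == "gaussian" and self.sigma <= 0:
            raise ValueError("gaussian kernel needs sigma > 0")
        if self.kernel == "polynomial" and self.degree < 2:
            raise ValueError("polynomial kernel needs integer degree >= 2")
        if self.C <= 0:
            raise ValueError("regularisation constant must be > 0")

    @property
    def _gaussian_gamma(self) -> float:
        denom = 2.0 * self.sigma**2 if self.gaussian_conventional else 2.0 * self.sigma
        return 1.0 / denom


def kernel_value(cfg: SVMConfig, x: np.ndarray, y: np.ndarray) -> float:
    """Evaluate the configured kernel on a single vector pair."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("kernel arguments must have equal length")
    if cfg.kernel == "linear":
        return float(x @ y)
    if cfg.kernel == "rbf":
        return float(np.exp(-cfg.gamma * np.sum((x - y) ** 2)))
    if cfg.kernel == "polynomial":
        return float((1.0 + x @ y) ** cfg.degree)
    return float(np.exp(-np.sum((x - y) ** 2) * cfg._gaussian_gamma))


@dataclass(frozen=True)
class GradeScheme:
    """Total mapping from DR grades 0-4 to coarser class labels."""

    name: str
    mapping: dict[int, str]

    def __post_init__(self) -> None:
        if set(self.mapping) != set(range(5)):
            raise ValueError("scheme mapping must cover grades 0..4 exactly")

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for g in range(5):
            if self.mapping[g] not in seen:
                seen.append(self.mapping[g])
        return seen


SCHEMES: dict[str, GradeScheme] = {
    "binary": GradeScheme(
        "binary", {0: "normal", 1: "abnormal", 2: "abnormal", 3: "abnormal", 4: "abnormal"}
    ),
    "ours_015": GradeScheme("ours_015", {0: "0", 1: "1", 2: "5", 3: "5", 4: "5"}),
    "shaban_0MS": GradeScheme("shaban_0MS", {0: "0", 1: "M", 2: "M", 3: "S", 4: "S"}),
    "raw_5class": GradeScheme("raw_5class", {g: str(g) for g in range(5)}),
}


def regroup(labels: Sequence[int], scheme: GradeScheme | str) -> np.ndarray:
    """Map raw DR grades element-wise through a grouping scheme."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    out = []
    for g in labels:
        g = int(g)
        if g not in scheme.mapping:
            raise ValueError(f"unknown DR grade {g}")
        out.append(scheme.mapping[g])
    return np.array(out)


def mirror_augment(
    images: np.ndarray,
    labels: Sequence[int],
    abnormal_only: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Append the vertical mirror (flip about the vertical axis) of images.

    With ``abnormal_only`` set, only grade 1-4 images are mirrored —
    the balancing trick for the sparse abnormal grades; otherwise every
    image is doubled.  Mirroring twice recovers the original image.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    if images.shape[0] == 0:
        raise ValueError("nothing to augment")
    if abnormal_only:
        sel = np.flatnonzero(labels != 0)
    else:
        sel = np.arange(images.shape[0])
    mirrored = images[sel][:, :, ::-1, ...]
    return np.concatenate([images, mirrored]), np.concatenate([labels, labels[sel]])


@dataclass
class SplitSpec:
    """Stratified 70/30 split specification."""

    train_fraction: float = 0.70
    seed: int = 0


def stratified_split(
    features: np.ndarray,
    labels: Sequence,
    spec: Optional[SplitSpec] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic class-stratified partition -> (X_train, X_test, y_train, y_test)."""
    spec = spec or SplitSpec()
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least two members to split")
    return train_test_split(
        np.asarray(features),
        labels,
        train_size=spec.train_fraction,
        stratify=labels,
        random_state=spec.seed,
    )


@dataclass
class FittedSVM:
    scaler: StandardScaler
    model: SVC
    cfg: SVMConfig


def train_svm(features: np.ndarray, labels: Sequence, cfg: Optional[SVMConfig] = None) -> FittedSVM:
    """Fit a one-vs-one SVM on standardised padded token vectors."""
    cfg = cfg or SVMConfig()
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("SVM training needs at least two classes")
    scaler = StandardScaler().fit(features)
    if cfg.kernel == "linear":
        svc = SVC(kernel="linear", C=cfg.C, decision_function_shape="ovo")
    elif cfg.kernel == "rbf":
        svc = SVC(kernel="rbf", gamma=cfg.gamma, C=cfg.C, decision_function_shape="ovo")
    elif cfg.kernel == "polynomial":
        svc = SVC(
            kernel="poly", degree=cfg.degree, gamma=1.0, coef0=1.0, C=cfg.C,
            decision_function_shape="ovo",
        )
    else:  # gaussian, as an rbf with gamma = 1/(2 sigma) (or 1/(2 sigma^2))
        svc = SVC(
            kernel="rbf", gamma=cfg._gaussian_gamma, C=cfg.C,
            decision_function_shape="ovo",
        )
    svc.fit(scaler.transform(features), labels)
    return FittedSVM(scaler=scaler, model=svc, cfg=cfg)


def predict_svm(fitted: FittedSVM, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and decision scores (for ROC analysis)."""
    x = fitted.scaler.transform(np.asarray(features, dtype=np.float64))
    return fitted.model.predict(x), fitted.model.decision_function(x)


def train_cnn(
    images: np.ndarray,
    labels: Sequence,
    arch: Optional[CNNArchitecture] = None,
    train_cfg: Optional[TrainConfig] = None,
) -> SmallCNN:
    """Train the small CNN on square feature images.

    The final fully-connected width is set to the number of distinct
    classes in ``labels`` unless an explicit architecture is supplied.
    """
    labels = np.asarray(labels)
    n_classes = np.unique(labels).size
    if arch is None:
        side = int(np.asarray(images).shape[-1])
        arch = CNNArchitecture(input_side=side, n_classes=n_classes)
    model = SmallCNN(arch, seed=(train_cfg.seed if train_cfg else 0))
    return model.fit(images, labels, train_cfg)


def predict_cnn(model: SmallCNN, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and per-class softmax probabilities."""
    probs = model.predict_proba(images)
    if model.classes_ is None:
        raise RuntimeError("model is not fitted")
    return model.classes_[probs.argmax(axis=1)], probs
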