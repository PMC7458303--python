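"""RBF-kernel SVM classification of antibody immunogenicity.

The predictor combines up to three antibody features — CDR cavity volume
(Å³), CDR-H3 hydrophobic solvent-accessible surface area (Å²), and the
presence/absence of glycine at the CDR-H2 β-turn — in a C-SVC with a radial
basis function kernel.  Two feature variants are supported, matching the two
deployment scenarios:

* ``crystal``: (cavity volume, CDR-H3 hydrophobic area) — used when an
  experimental structure is available.  Cavity volumes computed from homology
  models are unreliable, so this variant is reserved for crystal structures.
* ``modeled``: (CDR-H3 hydrophobic area, Gly presence) — robust to modeling
  error and usable when only a modeled structure exists.

Features are min-max scaled to [-1, 1] on the training set (the svm-scale
default); hyperparameters (C, gamma) are chosen once per training set by an
exhaustive search over libsvm's recommended grid (C = 2^-5, 2^-3, ..., 2^15;
gamma = 2^-15, 2^-13, ..., 2^3 — exponent step 2) maximizing leave-one-out
cross-validation accuracy, with ties broken toward smaller C then smaller
gamma.  The reported leave-one-out
accuracy is the accuracy at the selected grid point, i.e. the grid maximum —
the standard small-sample usage of libsvm's grid-search tool.  The whole
protocol is deterministic: no fold shuffling, no random state.

The quadratic program is solved by a sequential minimal optimization (SMO)
solver with second-order working-set selection — the same algorithm and
stopping rule (eps = 1e-3) used by libsvm's C-SVC — JIT-compiled with numba
so that the nested leave-one-out grid search over a few hundred (C, gamma)
pairs runs in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "FeatureVector",
    "LabeledDataset",
    "TrainedModel",
    "PredictionResult",
    "VARIANT_FEATURES",
    "train_svm",
    "loo_accuracy",
    "predict",
    "read_dataset_csv",
    "write_dataset_csv",
]

# Hyperparameter grid: libsvm's recommended coarse grid (exponent step 2).
C_EXPONENTS = tuple(range(-5, 16, 2))
GAMMA_EXPONENTS = tuple(range(-15, 4, 2))

LABEL_IMMUNOGENIC = "immunogenic"
LABEL_NON_IMMUNOGENIC = "non-immunogenic"

VARIANT_FEATURES: dict[str, tuple[str, ...]] = {
    "crystal": ("cavity_volume", "h3_hydrophobic_area"),
    "modeled": ("h3_hydrophobic_area", "gly_h2_turn_present"),
    "crystal3": ("cavity_volume", "h3_hydrophobic_area", "gly_h2_turn_present"),
}


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """The immunogenicity features of one antibody.

    ``cavity_volume`` may be ``None`` for modeled structures, where the
    built-in or external pocket detector was not run.  ``gly_h2_turn_present``
    is derived from the count and enters the SVM as a binary 0/1 feature; the
    raw count is retained for descriptive statistics.
    """

    antibody_name: str
    h3_hydrophobic_area: float
    gly_h2_turn_count: int
    cavity_volume: float | None = None
    structure_source: str = "crystal"

    def __post_init__(self) -> None:
        if self.h3_hydrophobic_area < 0:
            raise ValueError(f"{self.antibody_name}: negative H3 area")
        if self.cavity_volume is not None and self.cavity_volume < 0:
            raise ValueError(f"{self.antibody_name}: negative cavity volume")
        if self.gly_h2_turn_count < 0:
            raise ValueError(f"{self.antibody_name}: negative Gly count")

    @property
    def gly_h2_turn_present(self) -> int:
        return 1 if self.gly_h2_turn_count > 0 else 0

    def get(self, feature: str) -> float:
        value = getattr(self, feature)
        if value is None:
            raise ValueError(
                f"antibody {self.antibody_name!r} is missing feature {feature!r}"
            )
        return float(value)


@dataclass
class LabeledDataset:
    """Named antibodies with feature vectors and immunogenicity labels."""

    items: list[tuple[FeatureVector, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [fv.antibody_name for fv, _ in self.items]
        if len(set(names)) != len(names):
            raise ValueError("antibody names must be unique")
        for _, label in self.items:
            if label not in (LABEL_IMMUNOGENIC, LABEL_NON_IMMUNOGENIC):
                raise ValueError(f"unknown label {label!r}")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def names(self) -> list[str]:
        return [fv.antibody_name for fv, _ in self.items]

    @property
    def feature_vectors(self) -> list[FeatureVector]:
        return [fv for fv, _ in self.items]

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.items]

    def feature_matrix(self, features: Sequence[str]) -> np.ndarray:
        return np.array(
            [[fv.get(f) for f in features] for fv, _ in self.items], dtype=float
        )

    def label_vector(self) -> np.ndarray:
        """Labels encoded as +1 (immunogenic) / -1 (non-immunogenic)."""
        return np.array(
            [1.0 if lab == LABEL_IMMUNOGENIC else -1.0 for _, lab in self.items]
        )

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.items[i] for i in indices])


@dataclass(frozen=True)
class PredictionResult:
    antibody_name: str
    predicted_label: int  # 1 = immunogenic, 0 = non-immunogenic


# ---------------------------------------------------------------------------
# SMO solver (libsvm C-SVC algorithm, second-order working-set selection)
# ---------------------------------------------------------------------------

_SMO_EPS = 1e-3
_SMO_TAU = 1e-12
_SMO_MAX_ITER = 10_000_000


@njit(cache=True)
def _smo_solve(K, y, C, eps, max_iter):  # pragma: no cover - exercised via wrappers
    """Solve the C-SVC dual on a precomputed kernel matrix.

    min 0.5 a^T Q a - e^T a,  0 <= a_i <= C,  y^T a = 0,  Q_ij = y_i y_j K_ij.
    Returns (alpha, rho); the decision value of a point x is
    sum_i alpha_i y_i K(x_i, x) - rho.
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    grad = -np.ones(n)  # G_i = sum_j Q_ij a_j - 1

    for _ in range(max_iter):
        # first index: most violating in I_up (>= keeps the last maximizer,
        # matching libsvm's scan order)
        gmax = -1e300
        i = -1
        for t in range(n):
            if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
                v = -y[t] * grad[t]
                if v >= gmax:
                    gmax = v
                    i = t
        # second index: best second-order gain in I_low
        gmax2 = -1e300
        j = -1
        obj_min = 1e300
        for t in range(n):
            if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C):
                v = y[t] * grad[t]
                if v > gmax2:
                    gmax2 = v
                grad_diff = gmax + v
                if grad_diff > 0:
                    quad = K[i, i] + K[t, t] - 2.0 * K[i, t]
                    if quad <= 0:
                        quad = _SMO_TAU
                    obj = -(grad_diff * grad_diff) / quad
                    if obj <= obj_min:
                        j = t
                        obj_min = obj
        if gmax + gmax2 < eps or j == -1:
            break

        old_ai = alpha[i]
        old_aj = alpha[j]
        if y[i] != y[j]:
            quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
            if quad <= 0:
                quad = _SMO_TAU
            delta = (-grad[i] - grad[j]) / quad
            diff = alpha[i] - alpha[j]
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = diff
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
            if diff > 0:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = C - diff
            else:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = C + diff
        else:
            quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
            if quad <= 0:
                quad = _SMO_TAU
            delta = (grad[i] - grad[j]) / quad
            ssum = alpha[i] + alpha[j]
            alpha[i] -= delta
            alpha[j] += delta
            if ssum > C:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = ssum - C
            else:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = ssum
            if ssum > C:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = ssum - C
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = ssum

        dai = alpha[i] - old_ai
        daj = alpha[j] - old_aj
        for t in range(n):
            grad[t] += y[i] * y[t] * K[i, t] * dai + y[j] * y[t] * K[j, t] * daj

    # rho per libsvm: average of y_i G_i over free SVs, else midpoint of bounds
    ub = 1e300
    lb = -1e300
    nfree = 0
    sum_free = 0.0
    for t in range(n):
        yg = y[t] * grad[t]
        if alpha[t] >= C:
            if y[t] < 0:
                if yg < ub:
                    ub = yg
            else:
                if yg > lb:
                    lb = yg
        elif alpha[t] <= 0:
            if y[t] > 0:
                if yg < ub:
                    ub = yg
            else:
                if yg > lb:
                    lb = yg
        else:
            nfree += 1
            sum_free += yg
    rho = sum_free / nfree if nfree > 0 else (ub + lb) / 2.0
    return alpha, rho


@njit(cache=True)
def _decision_values(K_test, alpha, y, rho):  # pragma: no cover
    """Decision values for test points; K_test has shape (n_test, n_train)."""
    n_test, n_train = K_test.shape
    out = np.empty(n_test)
    for t in range(n_test):
        s = 0.0
        for i in range(n_train):
            s += alpha[i] * y[i] * K_test[t, i]
        out[t] = s - rho
    return out


@njit(cache=True)
def _loo_correct(K, y, C, eps, max_iter):  # pragma: no cover
    """Number of correctly predicted samples under leave-one-out at fixed
    (kernel, C).  Degenerate single-class training folds predict that class."""
    n = K.shape[0]
    correct = 0
    idx = np.empty(n - 1, dtype=np.int64)
    for k in range(n):
        m = 0
        for t in range(n):
            if t != k:
                idx[m] = t
                m += 1
        Ksub = np.empty((n - 1, n - 1))
        ysub = np.empty(n - 1)
        for a in range(n - 1):
            ysub[a] = y[idx[a]]
            for b in range(n - 1):
                Ksub[a, b] = K[idx[a], idx[b]]
        npos = 0
        for a in range(n - 1):
            if ysub[a] > 0:
                npos += 1
        if npos == 0 or npos == n - 1:
            pred = 1.0 if npos > 0 else -1.0
        else:
            alpha, rho = _smo_solve(Ksub, ysub, C, eps, max_iter)
            s = -rho
            for a in range(n - 1):
                s += alpha[a] * ysub[a] * K[k, idx[a]]
            pred = 1.0 if s > 0 else -1.0
        if pred == y[k]:
            correct += 1
    return correct


# ---------------------------------------------------------------------------
# Scaling, kernels, grid search
# ---------------------------------------------------------------------------

def _fit_scaling(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0.0] = 1.0  # constant column scales to -1
    return lo, span


def _apply_scaling(X: np.ndarray, lo: np.ndarray, span: np.ndarray) -> np.ndarray:
    """Min-max scale to [-1, 1] with frozen training lo/span (svm-scale default)."""
    return 2.0 * (X - lo) / span - 1.0


def _rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    sq = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


def _grid_select(Xs: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pick (C, gamma) maximizing leave-one-out accuracy on (Xs, y).

    Iterates C ascending then gamma ascending with a strict improvement rule,
    so ties resolve to the smallest C, then the smallest gamma.  Returns the
    selected (C, gamma) and the number of correct leave-one-out predictions
    at that grid point.
    """
    best = (-1, 2.0 ** C_EXPONENTS[0], 2.0 ** GAMMA_EXPONENTS[0])
    kernels = [
        (2.0 ** ge, _rbf_kernel(Xs, Xs, 2.0 ** ge)) for ge in GAMMA_EXPONENTS
    ]
    for ce in C_EXPONENTS:
        C = 2.0 ** ce
        for gamma, K in kernels:
            correct = _loo_correct(K, y, C, _SMO_EPS, _SMO_MAX_ITER)
            if correct > best[0]:
                best = (correct, C, gamma)
    return best[1], best[2], best[0]


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A trained RBF-SVM with its frozen feature scaling.

    Prediction encodes immunogenic as 1 and non-immunogenic as 0.
    """

    features: tuple[str, ...]
    C: float
    gamma: float
    scale_min: np.ndarray
    scale_span: np.ndarray
    X_train: np.ndarray  # scaled
    y_train: np.ndarray  # +1 / -1
    alpha: np.ndarray
    rho: float
    inner_loo_correct: int = 0

    def decision_values(self, X_raw: np.ndarray) -> np.ndarray:
        Xs = _apply_scaling(np.asarray(X_raw, dtype=float), self.scale_min,
                            self.scale_span)
        K = _rbf_kernel(Xs, self.X_train, self.gamma)
        return _decision_values(K, self.alpha, self.y_train, self.rho)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel": "rbf",
                "features": list(self.features),
                "C": self.C,
                "gamma": self.gamma,
                "scale_min": self.scale_min.tolist(),
                "scale_span": self.scale_span.tolist(),
                "X_train": self.X_train.tolist(),
                "y_train": self.y_train.tolist(),
                "alpha": self.alpha.tolist(),
                "rho": self.rho,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        if d.get("kernel") != "rbf":
            raise ValueError("unsupported kernel in model file")
        return cls(
            features=tuple(d["features"]),
            C=float(d["C"]),
            gamma=float(d["gamma"]),
            scale_min=np.asarray(d["scale_min"], dtype=float),
            scale_span=np.asarray(d["scale_span"], dtype=float),
            X_train=np.asarray(d["X_train"], dtype=float),
            y_train=np.asarray(d["y_train"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
            rho=float(d["rho"]),
        )


def _resolve_features(variant: str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(variant, str):
        try:
            return VARIANT_FEATURES[variant]
        except KeyError:
            raise ValueError(
                f"unknown variant {variant!r}; expected one of "
                f"{sorted(VARIANT_FEATURES)} or an explicit feature tuple"
            ) from None
    return tuple(variant)


def _check_dataset(dataset: LabeledDataset) -> None:
    if len(dataset) < 6:
        raise ValueError(f"need at least 6 labeled antibodies, got {len(dataset)}")
    labels = set(dataset.labels)
    if len(labels) < 2:
        raise ValueError("dataset contains a single class; both labels required")


def train_svm(
    dataset: LabeledDataset, variant: str | Sequence[str] = "modeled"
) -> TrainedModel:
    """Train an RBF-SVM on a labeled dataset with grid-searched (C, gamma)."""
    features = _resolve_features(variant)
    _check_dataset(dataset)
    X = dataset.feature_matrix(features)
    y = dataset.label_vector()
    lo, span = _fit_scaling(X)
    Xs = _apply_scaling(X, lo, span)
    C, gamma, correct = _grid_select(Xs, y)
    K = _rbf_kernel(Xs, Xs, gamma)
    alpha, rho = _smo_solve(K, y, C, _SMO_EPS, _SMO_MAX_ITER)
    return TrainedModel(
        features=features, C=C, gamma=gamma, scale_min=lo, scale_span=span,
        X_train=Xs, y_train=y, alpha=alpha, rho=rho, inner_loo_correct=correct,
    )


def predict(
    model: TrainedModel, feature_vectors: Sequence[FeatureVector]
) -> list[PredictionResult]:
    """Predict 1 (immunogenic) / 0 (non-immunogenic) for each antibody."""
    X = np.array(
        [[fv.get(f) for f in model.features] for fv in feature_vectors],
        dtype=float,
    )
    dec = model.decision_values(X)
    return [
        PredictionResult(fv.antibody_name, int(d > 0))
        for fv, d in zip(feature_vectors, dec)
    ]


def prediction_accuracy(
    predictions: Sequence[PredictionResult], labels: Sequence[str]
) -> float:
    """Percentage of predictions agreeing with reference labels."""
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    truth = [1 if lab == LABEL_IMMUNOGENIC else 0 for lab in labels]
    n_ok = sum(p.predicted_label == t for p, t in zip(predictions, truth))
    return 100.0 * n_ok / len(labels)


def loo_accuracy(
    dataset: LabeledDataset, variant: str | Sequence[str] = "modeled"
) -> float:
    """Leave-one-out accuracy (%) at grid-selected hyperparameters.

    (C, gamma) are chosen by the grid search maximizing leave-one-out
    accuracy over the whole dataset, and the accuracy at that grid point is
    returned; each held-out antibody is predicted by an SVM retrained on the
    remaining n-1 with those fixed hyperparameters.  Because the selection
    criterion and the reported metric coincide, this equals the grid maximum
    and carries the optimistic bias inherent to that protocol.
    """
    features = _resolve_features(variant)
    _check_dataset(dataset)
    X = dataset.feature_matrix(features)
    y = dataset.label_vector()
    lo, span = _fit_scaling(X)
    Xs = _apply_scaling(X, lo, span)
    _, _, correct = _grid_select(Xs, y)
    return 100.0 * correct / len(dataset)


# ---------------------------------------------------------------------------
# Dataset CSV I/O  (dialect: antibody,cavity_volume,h3_hydrophobic_area,
#                   gly_count,label,source)
# ---------------------------------------------------------------------------

def read_dataset_csv(text: str) -> LabeledDataset:
    import csv
    import io

    reader = csv.DictReader(io.StringIO(text))
    required = {"antibody", "h3_hydrophobic_area", "gly_count", "label"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValueError(
            f"dataset CSV must have columns {sorted(required)} "
            f"(plus optional cavity_volume, source)"
        )
    items: list[tuple[FeatureVector, str]] = []
    for row in reader:
        cavity = row.get("cavity_volume", "")
        cavity_val = float(cavity) if cavity not in ("", None) else None
        fv = FeatureVector(
            antibody_name=row["antibody"],
            h3_hydrophobic_area=float(row["h3_hydrophobic_area"]),
            gly_h2_turn_count=int(row["gly_count"]),
            cavity_volume=cavity_val,
            structure_source=row.get("source", "crystal") or "crystal",
        )
        items.append((fv, row["label"].strip()))
    if not items:
        raise ValueError("dataset CSV has no rows")
    return LabeledDataset(items)


def write_dataset_csv(dataset: LabeledDataset) -> str:
    lines = ["antibody,cavity_volume,h3_hydrophobic_area,gly_count,label,source"]
    for fv, label in dataset.items:
        cav = "" if fv.cavity_volume is None else repr(fv.cavity_volume)
        lines.append(
            f"{fv.antibody_name},{cav},{fv.h3_hydrophobic_area!r},"
            f"{fv.gly_h2_turn_count},{label},{fv.structure_source}"
        )
    return "\n".join(lines) + "\n"
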