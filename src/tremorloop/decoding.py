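"""Decoder training, block-wise cross-validation and model selection.

One binary classifier is trained per (task, stimulation-state) cell —
movement/posture × stim on/off — because stimulation changes both the
neural signal and the artifact content, giving four models per subject.
Seven algorithms are supported (SVM, logistic regression, LDA, naive
Bayes, decision tree, k-NN, and a two-layer random-projection extreme
learning machine); the best cross-validated AUC per cell is retrained on
all of that cell's data.

Cross-validation folds split by protocol block (contiguous frames), never
by frame: neighbouring frames share most of their 500 ms analysis window,
so frame-wise folds would leak.  A support-vector regressor maps the same
features to continuous tremor intensity (log 3–7 Hz accelerometer power).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier

from .core import TremorLoopError
from .features import FeatureMatrix, Normalizer, fit_normalizer
from .labeling import LabelSeries, TremorTarget

ALGORITHMS = ("svm", "lr", "lda", "nb", "dt", "knn", "helm")
_TIE_ORDER = {a: i for i, a in enumerate(ALGORITHMS)}


class _ELM:
    """Two-layer random-projection extreme learning machine.

    Hidden layers are fixed random tanh projections (seeded); only the
    linear readout is fit, by ridge regression to the 0/1 targets.
    """

    def __init__(self, hidden=(64, 64), ridge=1e-2, seed=0):
        self.hidden = hidden
        self.ridge = ridge
        self.seed = seed

    def _project(self, X):
        h = X
        for W, b in self.layers_:
            h = np.tanh(h @ W + b)
        return h

    def fit(self, X, y):
        rng = np.random.default_rng(self.seed)
        self.layers_ = []
        d = X.shape[1]
        for width in self.hidden:
            W = rng.standard_normal((d, width)) / np.sqrt(d)
            b = rng.uniform(-1, 1, width)
            self.layers_.append((W, b))
            d = width
        H = self._project(X)
        H1 = np.column_stack([H, np.ones(len(H))])
        A = H1.T @ H1 + self.ridge * np.eye(H1.shape[1])
        self.w_ = np.linalg.solve(A, H1.T @ (2.0 * y - 1.0))
        return self

    def decision_function(self, X):
        H = self._project(X)
        return np.column_stack([H, np.ones(len(H))]) @ self.w_


def make_estimator(algorithm: str, seed: int = 0, svm_kernel: str = "linear"):
    if algorithm == "svm":
        return SVC(kernel=svm_kernel, C=1.0, random_state=seed)
    if algorithm == "lr":
        return LogisticRegression(C=1.0, max_iter=2000)
    if algorithm == "lda":
        return LinearDiscriminantAnalysis()
    if algorithm == "nb":
        return GaussianNB()
    if algorithm == "dt":
        return DecisionTreeClassifier(random_state=seed, min_samples_leaf=5)
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if algorithm == "helm":
        return _ELM(seed=seed)
    raise TremorLoopError(f"unknown algorithm {algorithm!r}", code="unknown-algorithm")


def _score01(estimator, X: np.ndarray) -> np.ndarray:
    """Probability-like score in [0, 1] regardless of estimator API."""
    if hasattr(estimator, "predict_proba"):
        return estimator.predict_proba(X)[:, 1]
    return expit(estimator.decision_function(X))


@dataclass
class DecoderModel:
    """One trained classifier for a (task, stimulation-state) cell."""

    task: str
    stim_state: str  # "on" | "off"
    algorithm: str
    estimator: object
    normalizer: Normalizer
    feature_names: list[str]
    decision_threshold: float = 0.5
    seed: int = 0

    def predict_score(self, values: np.ndarray) -> np.ndarray:
        values = np.atleast_2d(values)
        return _score01(self.estimator, self.normalizer.apply(values))

    def predict_label(self, values: np.ndarray) -> np.ndarray:
        return (self.predict_score(values) >= self.decision_threshold).astype(int)


def _training_mask(features: FeatureMatrix, stim_on: np.ndarray, stim_state: str) -> np.ndarray:
    stim_on = np.asarray(stim_on, bool)
    want_on = stim_state == "on"
    return features.valid() & (stim_on == want_on)


def train_decoder(
    features: FeatureMatrix,
    labels: LabelSeries,
    task: str,
    stim_state: str,
    algorithm: str = "svm",
    stim_on: np.ndarray | None = None,
    seed: int = 0,
    svm_kernel: str = "linear",
) -> DecoderModel:
    """Train one cell's classifier on stim-state-matched, non-warm-up frames.

    The stim-state firewall is structural: frames whose stimulation state
    does not match ``stim_state`` never enter normalization or fitting.
    """
    if stim_on is None:
        stim_on = np.zeros(features.n_frames, bool)
    if len(labels) != features.n_frames or len(stim_on) != features.n_frames:
        raise TremorLoopError("labels/stim mask must match frame count", code="grid-mismatch")
    mask = _training_mask(features, stim_on, stim_state)
    y = labels.labels[mask]
    if len(np.unique(y)) < 2:
        raise TremorLoopError("training labels are single-class", code="degenerate-labels")
    norm = fit_normalizer(features, mask)
    X = norm.apply(features.values[mask])
    est = make_estimator(algorithm, seed=seed, svm_kernel=svm_kernel)
    est.fit(X, y)
    return DecoderModel(task, stim_state, algorithm, est, norm, list(features.names), seed=seed)


@dataclass
class CrossValReport:
    """Pooled out-of-fold ROC and AUC for one algorithm on one cell."""

    algorithm: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_folds: int
    class_balance: float  # fraction of positive frames
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def auc_trapezoid(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and the trapezoidal integral of the ROC curve."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def _fold_assignment(block_ids: np.ndarray, k: int) -> np.ndarray:
    """Fold index per frame: contiguous blocks grouped into k folds."""
    blocks = pd.unique(block_ids[block_ids >= 0])
    if len(blocks) < k:
        raise TremorLoopError(f"{len(blocks)} blocks < k={k}", code="too-few-blocks")
    groups = np.array_split(blocks, k)
    fold_of_block = {b: i for i, grp in enumerate(groups) for b in grp}
    return np.array([fold_of_block.get(b, -1) for b in block_ids])


def blocks_from_protocol(protocol, n_frames: int) -> np.ndarray:
    """Protocol block index per frame (frames beyond the protocol get -1)."""
    ids = np.full(n_frames, -1, dtype=np.int64)
    t0 = 0.0
    for i, (_, dur) in enumerate(protocol.blocks):
        k0 = int(np.ceil(t0 / 0.1 - 1e-9))
        k1 = int(np.ceil((t0 + dur) / 0.1 - 1e-9))
        ids[k0 : min(k1, n_frames)] = i
        t0 += dur
    return ids


def cross_validate(
    features: FeatureMatrix,
    labels: LabelSeries,
    block_ids: np.ndarray,
    stim_on: np.ndarray | None = None,
    stim_state: str = "off",
    algorithm: str = "svm",
    k: int = 5,
    seed: int = 0,
) -> CrossValReport:
    """Block-wise k-fold CV; pools out-of-fold scores into one ROC/AUC."""
    if stim_on is None:
        stim_on = np.zeros(features.n_frames, bool)
    mask = _training_mask(features, stim_on, stim_state)
    folds = _fold_assignment(np.where(mask, block_ids, -1), k)
    scores = np.full(features.n_frames, np.nan)
    for f in range(k):
        tr = mask & (folds >= 0) & (folds != f)
        te = mask & (folds == f)
        if not np.any(te):
            continue
        y_tr = labels.labels[tr]
        if len(np.unique(y_tr)) < 2:
            raise TremorLoopError("fold training labels single-class", code="degenerate-labels")
        norm = fit_normalizer(features, tr)
        est = make_estimator(algorithm, seed=seed)
        est.fit(norm.apply(features.values[tr]), y_tr)
        scores[te] = _score01(est, norm.apply(features.values[te]))
    pooled = ~np.isnan(scores)
    y = labels.labels[pooled]
    s = scores[pooled]
    if len(np.unique(y)) < 2:
        raise TremorLoopError("pooled labels single-class", code="degenerate-labels")
    fpr, tpr, auc = auc_trapezoid(s, y)
    return CrossValReport(algorithm, fpr, tpr, auc, k, float(np.mean(y)), s, y)


def compare_algorithms(
    features: FeatureMatrix,
    labels: LabelSeries,
    block_ids: np.ndarray,
    stim_on: np.ndarray | None = None,
    stim_state: str = "off",
    algorithms=ALGORITHMS,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC per algorithm on identical folds; best flagged (fixed tie order)."""
    if len(algorithms) < 1:
        raise TremorLoopError("need at least one algorithm", code="unknown-algorithm")
    rows = []
    reports = {}
    for alg in algorithms:
        try:
            rep = cross_validate(
                features, labels, block_ids, stim_on, stim_state, alg, k, seed
            )
            reports[alg] = rep
            rows.append({"algorithm": alg, "auc": rep.auc})
        except TremorLoopError as err:
            import warnings

            warnings.warn(f"{alg}: {err}", stacklevel=2)
            rows.append({"algorithm": alg, "auc": np.nan})
    df = pd.DataFrame(rows)
    order = df["algorithm"].map(_TIE_ORDER)
    ranked = df.assign(_o=order).sort_values(["auc", "_o"], ascending=[False, True])
    best = ranked.iloc[0]["algorithm"] if np.isfinite(ranked.iloc[0]["auc"]) else None
    df["best"] = df["algorithm"] == best
    df.attrs["reports"] = reports
    return df


class ModelBundle(dict):
    """The four per-subject models keyed by (task, stim_state)."""

    def model(self, task: str, stim_state: str) -> DecoderModel:
        key = (task, stim_state)
        if key not in self:
            raise TremorLoopError(f"missing model for {key}", code="incomplete-grid")
        return self[key]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "models": dict(self)}, fh)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with open(path, "rb") as fh:
            doc = pickle.load(fh)
        return cls(doc["models"])


def select_models(cells: dict, algorithms=ALGORITHMS, k: int = 5, seed: int = 0) -> tuple[ModelBundle, pd.DataFrame]:
    """Pick the best algorithm per cell by CV and retrain it on all data.

    ``cells`` maps ``(task, stim_state)`` to a dict with keys ``features``,
    ``labels``, ``block_ids``, ``stim_on``.  All four cells must be present
    and trainable.
    """
    bundle = ModelBundle()
    rows = []
    for task in ("movement", "posture"):
        for stim_state in ("on", "off"):
            key = (task, stim_state)
            if key not in cells:
                raise TremorLoopError(f"missing cell {key}", code="incomplete-grid")
            c = cells[key]
            try:
                table = compare_algorithms(
                    c["features"], c["labels"], c["block_ids"], c.get("stim_on"),
                    stim_state, algorithms, k, seed,
                )
            except TremorLoopError as err:
                raise TremorLoopError(f"cell {key}: {err}", code="incomplete-grid") from err
            if not table["best"].any():
                raise TremorLoopError(f"cell {key} has no usable algorithm", code="incomplete-grid")
            best = table.loc[table["best"], "algorithm"].iloc[0]
            model = train_decoder(
                c["features"], c["labels"], task, stim_state, best, c.get("stim_on"), seed
            )
            bundle[key] = model
            for _, r in table.iterrows():
                rows.append(
                    {"task": task, "stim_state": stim_state, **r[["algorithm", "auc", "best"]]}
                )
    return bundle, pd.DataFrame(rows)


# ------------------------------------------------------------------ intensity


@dataclass
class IntensityModel:
    """SVR mapping LFP features to tremor-band accelerometer power."""

    estimator: object
    normalizer: Normalizer
    log_epsilon: float = 1e-12

    def predict(self, values: np.ndarray) -> np.ndarray:
        values = np.atleast_2d(values)
        log_pred = self.estimator.predict(self.normalizer.apply(values))
        return np.clip(np.exp(log_pred) - self.log_epsilon, 0.0, None)


def fit_intensity(
    features: FeatureMatrix,
    target: TremorTarget,
    stim_on: np.ndarray | None = None,
    kernel: str = "rbf",
    C: float = 10.0,
    epsilon: float = 0.01,
) -> IntensityModel:
    """Fit the tremor-intensity SVR on stimulation-off frames only."""
    if stim_on is None:
        stim_on = np.zeros(features.n_frames, bool)
    mask = features.valid() & ~np.asarray(stim_on, bool)
    y = np.asarray(target.power)[mask]
    if np.ptp(y) <= 0:
        raise TremorLoopError("tremor target is constant", code="degenerate-target")
    norm = fit_normalizer(features, mask)
    eps = 1e-12
    est = SVR(kernel=kernel, C=C, epsilon=epsilon)
    est.fit(norm.apply(features.values[mask]), np.log(y + eps))
    return IntensityModel(est, norm, eps)


def predict_intensity(model: IntensityModel, features: FeatureMatrix) -> np.ndarray:
    """Predicted tremor power per frame (NaN on warm-up frames)."""
    out = np.full(features.n_frames, np.nan)
    v = features.valid()
    out[v] = model.predict(features.values[v])
    return out


def crossval_intensity(
    features: FeatureMatrix,
    target: TremorTarget,
    block_ids: np.ndarray,
    stim_on: np.ndarray | None = None,
    k: int = 5,
    kernel: str = "rbf",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Held-out-block predictions; returns (pearson r, predicted, actual)."""
    from scipy.stats import pearsonr

    if stim_on is None:
        stim_on = np.zeros(features.n_frames, bool)
    mask = features.valid() & ~np.asarray(stim_on, bool)
    folds = _fold_assignment(np.where(mask, block_ids, -1), k)
    pred = np.full(features.n_frames, np.nan)
    for f in range(k):
        tr = mask & (folds >= 0) & (folds != f)
        te = mask & (folds == f)
        if not np.any(te) or not np.any(tr):
            continue
        sub = FeatureMatrix(features.values, features.names, ~tr)
        model = fit_intensity(sub, target, stim_on=np.zeros(features.n_frames, bool))
        pred[te] = model.predict(features.values[te])
    sel = ~np.isnan(pred)
    r = float(pearsonr(pred[sel], np.asarray(target.power)[sel]).statistic)
    return r, pred[sel], np.asarray(target.power)[sel]


def block_permutation_pvalue(
    pred: np.ndarray, actual: np.ndarray, block_ids: np.ndarray, n_perm: int = 200, seed: int = 0
) -> float:
    """One-sided p for r > 0 by permuting whole blocks of the target."""
    from scipy.stats import pearsonr

    rng = np.random.default_rng(seed)
    r_obs = pearsonr(pred, actual).statistic
    blocks = pd.unique(block_ids)
    segments = [np.flatnonzero(block_ids == b) for b in blocks]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(segments))
        shuffled = np.concatenate([actual[segments[j]] for j in perm])
        if pearsonr(pred[: len(shuffled)], shuffled).statistic >= r_obs:
            count += 1
    return (count + 1) / (n_perm + 1)
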