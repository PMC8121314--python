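"""Classifier configurations: GA-selected RBF-SVM, image-embedding
pathway, and the fused random forest.

Every trained model emits a confidence score CS in [0, 1]; CS -> 1 means
confidently symmetric, CS -> 0 confidently asymmetric.  Classification
uses threshold 0.5 with asymmetry as the positive class; a score of
exactly 0.5 is called symmetric (tie to the negative class).

All fitting (feature standardization, feature selection, embedding
training, PCA) happens strictly on training data; the fitted state is
carried inside :class:`TrainedClassifier` / the extractor objects so
held-out rows are transformed with training statistics only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize, rotate
from sklearn.calibration import CalibratedClassifierCV
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: Encoded classes: the classifier scores "symmetric" probability.
POSITIVE_CLASS = "asymmetric"  # positive for AUC/recall/precision

_SVM_C_GRID = (0.1, 1.0, 10.0, 100.0)
_SVM_GAMMA_GRID = (0.001, 0.01, 0.1, 1.0)


def encode_labels(labels: Sequence[str]) -> np.ndarray:
    """symmetric -> 1, asymmetric -> 0 (CS is P(symmetric))."""
    arr = np.asarray(labels)
    bad = set(arr) - {"symmetric", "asymmetric"}
    if bad:
        raise ValueError(f"unknown label(s): {sorted(bad)}")
    return (arr == "symmetric").astype(int)


@dataclass
class TrainedClassifier:
    """A fitted scorer over (selected) feature columns."""

    kind: str  # "svm_rbf" | "random_forest"
    estimator: object
    scaler: Optional[StandardScaler]
    feature_mask: np.ndarray  # boolean over input columns

    def predict_cs(self, X: np.ndarray) -> np.ndarray:
        """Confidence scores in [0, 1] (1 = confidently symmetric)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.feature_mask.size:
            raise ValueError(
                f"expected {self.feature_mask.size} columns, got {X.shape}"
            )
        Xm = X[:, self.feature_mask]
        if self.scaler is not None:
            Xm = self.scaler.transform(Xm)
        proba = self.estimator.predict_proba(Xm)
        cs = proba[:, list(self.estimator.classes_).index(1)]
        return np.clip(cs, 0.0, 1.0)

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        """Threshold-0.5 labels; CS == 0.5 exactly -> symmetric."""
        cs = self.predict_cs(X)
        return np.where(cs < 0.5, "asymmetric", "symmetric")


def train_svm(
    X: np.ndarray,
    y: Sequence[str] | np.ndarray,
    selected_mask: Optional[np.ndarray] = None,
    hyper: dict | str = "search",
    seed: int = 0,
) -> TrainedClassifier:
    """Fit an RBF-kernel SVM on z-scored (masked) features.

    ``hyper`` is either ``"search"`` (small C/gamma grid by internal
    stratified 5-fold accuracy) or a dict with fixed ``C``/``gamma``.
    Probability scores come from Platt scaling fitted on training folds.
    """
    X = np.asarray(X, dtype=float)
    yb = y if isinstance(y, np.ndarray) and y.dtype.kind == "i" else encode_labels(y)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    if len(np.unique(yb)) < 2:
        raise ValueError("need both classes in y")
    if np.bincount(yb).min() < 2:
        raise ValueError("need >= 2 samples per class")
    mask = (
        np.ones(X.shape[1], bool)
        if selected_mask is None
        else np.asarray(selected_mask, bool)
    )
    if mask.sum() == 0:
        raise ValueError("feature mask selects no features")
    scaler = StandardScaler().fit(X[:, mask])
    Xs = scaler.transform(X[:, mask])
    n_splits = min(5, int(np.bincount(yb).min()))
    if hyper == "search":
        grid = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(_SVM_C_GRID), "gamma": list(_SVM_GAMMA_GRID)},
            scoring="accuracy",
            cv=StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed),
        )
        grid.fit(Xs, yb)
        svc = SVC(kernel="rbf", **grid.best_params_)
    else:
        svc = SVC(kernel="rbf", C=hyper.get("C", 1.0), gamma=hyper.get("gamma", "scale"))
    # Platt scaling fitted on internal training folds
    est = CalibratedClassifierCV(
        svc, method="sigmoid", ensemble=False,
        cv=StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=seed),
    ).fit(Xs, yb)
    return TrainedClassifier("svm_rbf", est, scaler, mask)


# ---------------------------------------------------------------------------
# Genetic-algorithm feature selection (wrapper around the RBF-SVM)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GAConfig:
    """Evolution settings for binary feature-mask search."""

    population_size: int = 20
    crossover_prob: float = 0.7
    mutation_prob: float = 0.2  # per-individual mutation event probability
    tournament_size: int = 2
    max_generations: int = 1000
    patience: int = 100  # improvement-free generations before early stop
    per_gene_flip_prob: Optional[float] = None  # default 1/n_features
    mutation_semantics: str = "per_individual"  # or "per_gene"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.population_size % 2:
            raise ValueError("population size must be even")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class GAResult:
    selected_mask: np.ndarray
    fitness_history: list[float]  # best-so-far per generation
    n_selected: int
    best_fitness: float


def _mask_fitness(mask, X, y, seed, cv_folds=5, hyper=None):
    """Mean accuracy of an RBF-SVM under internal stratified CV."""
    hyper = hyper or {"C": 1.0, "gamma": "scale"}
    from sklearn.pipeline import make_pipeline

    n_splits = min(cv_folds, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("too few samples per class for internal CV")
    pipe = make_pipeline(
        StandardScaler(),
        SVC(kernel="rbf", C=hyper["C"], gamma=hyper["gamma"], random_state=seed),
    )
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return float(np.mean(cross_val_score(pipe, X[:, mask], y, cv=cv, scoring="accuracy")))


def gafs_select(
    X: np.ndarray,
    y: Sequence[str] | np.ndarray,
    ga: GAConfig = GAConfig(),
    svm_hyper: Optional[dict] = None,
    cv_folds: int = 5,
) -> GAResult:
    """Evolve a binary feature-inclusion mask for the RBF-SVM.

    Tournament selection, one-point crossover, bit-flip mutation;
    fitness is internal stratified CV accuracy on the provided
    (training) data only.  Elitism keeps the best individual each
    generation, so best-so-far fitness is nondecreasing.
    """
    X = np.asarray(X, dtype=float)
    yb = y if isinstance(y, np.ndarray) and y.dtype.kind == "i" else encode_labels(y)
    rng = np.random.default_rng(ga.rng_seed)
    n_feat = X.shape[1]
    flip_p = ga.per_gene_flip_prob or 1.0 / n_feat

    def repair(mask):
        if not mask.any():
            mask[rng.integers(n_feat)] = True
        return mask

    cache: dict[bytes, float] = {}

    def fitness(mask):
        key = mask.tobytes()
        if key not in cache:
            cache[key] = _mask_fitness(mask, X, yb, ga.rng_seed, cv_folds, svm_hyper)
        return cache[key]

    pop = [repair(rng.random(n_feat) < 0.5) for _ in range(ga.population_size)]
    fits = [fitness(m) for m in pop]
    best_idx = int(np.argmax(fits))
    best_mask, best_fit = pop[best_idx].copy(), fits[best_idx]
    history = [best_fit]
    stall = 0

    for _ in range(ga.max_generations):
        # tournament selection
        parents = []
        for _ in range(ga.population_size):
            contenders = rng.integers(0, ga.population_size, ga.tournament_size)
            parents.append(pop[max(contenders, key=lambda i: fits[i])].copy())
        # one-point crossover on consecutive pairs
        children = []
        for a, b in zip(parents[::2], parents[1::2]):
            if n_feat > 1 and rng.random() < ga.crossover_prob:
                cut = int(rng.integers(1, n_feat))
                a2 = np.concatenate([a[:cut], b[cut:]])
                b2 = np.concatenate([b[:cut], a[cut:]])
                children += [a2, b2]
            else:
                children += [a, b]
        # mutation
        for m in children:
            if ga.mutation_semantics == "per_gene":
                flips = rng.random(n_feat) < ga.mutation_prob
                m ^= flips
            elif rng.random() < ga.mutation_prob:
                flips = rng.random(n_feat) < flip_p
                m ^= flips
            repair(m)
        # elitism: keep the incumbent best
        children[0] = best_mask.copy()
        pop = children
        fits = [fitness(m) for m in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = fits[gen_best]
            best_mask = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1
        history.append(best_fit)
        if stall >= ga.patience:
            break
    return GAResult(best_mask, history, int(best_mask.sum()), best_fit)


# ---------------------------------------------------------------------------
# Embedding extractors (the image pathway)
# ---------------------------------------------------------------------------


class PixelPCAExtractor:
    """Embedding = PCA of downsampled pixel intensities.

    A deliberately simple, deterministic image pathway: images are
    resized to ``input_size`` and the top principal components of the
    flattened training pixels form the embedding basis.
    """

    def __init__(self, n_components: int = 100, input_size: int = 32):
        self.n_components = n_components
        self.input_size = input_size
        self._pca: Optional[PCA] = None

    def _flatten(self, images: Sequence[np.ndarray]) -> np.ndarray:
        rows = [
            resize(
                np.asarray(im, float), (self.input_size, self.input_size),
                anti_aliasing=True,
            ).ravel()
            for im in images
        ]
        return np.asarray(rows)

    def fit(self, images: Sequence[np.ndarray], y=None) -> "PixelPCAExtractor":
        F = self._flatten(images)
        k = min(self.n_components, F.shape[0] - 1, F.shape[1])
        self._pca = PCA(n_components=k, random_state=0).fit(F)
        return self

    def transform(self, images: Sequence[np.ndarray]) -> np.ndarray:
        if self._pca is None:
            raise RuntimeError("extractor not fitted")
        return self._pca.transform(self._flatten(images))


class CNNEmbeddingExtractor:
    """Compact convolutional feature extractor trained from scratch.

    Architecture: conv(8 @ 5x5, stride 2) -> ReLU -> maxpool(2) ->
    conv(16 @ 3x3, stride 2) -> ReLU; the flattened second feature map is
    the embedding.  A global-average-pool + logistic head is attached
    during training with SGD (lr 1e-4, momentum 0.9), batch size 32,
    binary cross-entropy, and flip/rotation augmentation; the head is
    discarded at extraction time.
    """

    def __init__(
        self,
        input_size: int = 128,
        epochs: int = 30,
        batch_size: int = 32,
        lr: float = 1e-4,
        momentum: float = 0.9,
        augment: bool = True,
        seed: int = 0,
    ):
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.momentum = momentum
        self.augment = augment
        self.seed = seed
        self._params: Optional[dict] = None

    # -- plumbing -----------------------------------------------------------

    def _prep(self, images: Sequence[np.ndarray]) -> np.ndarray:
        out = [
            resize(np.asarray(im, float) / 255.0, (self.input_size, self.input_size),
                   anti_aliasing=True)
            for im in images
        ]
        return np.asarray(out)

    @staticmethod
    def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int]:
        n, h, w = x.shape
        out = (h - k) // stride + 1
        s0, s1, s2 = x.strides
        windows = np.lib.stride_tricks.as_strided(
            x,
            shape=(n, out, out, k, k),
            strides=(s0, s1 * stride, s2 * stride, s1, s2),
        )
        return windows.reshape(n, out * out, k * k), out

    @staticmethod
    def _conv_forward(x, W, b, stride):
        # x: (n, c, h, w); W: (k*k*c, f)
        n, c, h, w = x.shape
        k = int(np.sqrt(W.shape[0] // c))
        cols = []
        for ch in range(c):
            col, out = CNNEmbeddingExtractor._im2col(x[:, ch], k, stride)
            cols.append(col)
        cols = np.concatenate(cols, axis=2)  # (n, out*out, k*k*c)
        y = cols @ W + b  # (n, out*out, f)
        return y.transpose(0, 2, 1).reshape(n, W.shape[1], out, out), cols, out

    def _init_params(self, rng) -> dict:
        w1 = rng.normal(0, np.sqrt(2.0 / 25), (25, 8))
        w2 = rng.normal(0, np.sqrt(2.0 / (9 * 8)), (9 * 8, 16))
        return {
            "W1": w1, "b1": np.zeros(8),
            "W2": w2, "b2": np.zeros(16),
            "w": rng.normal(0, 0.1, 16), "b": 0.0,
        }

    def _forward(self, x, p):
        h1, cols1, o1 = self._conv_forward(x[:, None], p["W1"], p["b1"], 2)
        r1 = np.maximum(h1, 0)
        n, f, oh, ow = r1.shape
        ph, pw = oh // 2, ow // 2
        pooled_view = r1[:, :, : ph * 2, : pw * 2].reshape(n, f, ph, 2, pw, 2)
        pooled = pooled_view.max(axis=(3, 5))
        h2, cols2, o2 = self._conv_forward(pooled, p["W2"], p["b2"], 2)
        r2 = np.maximum(h2, 0)
        return {
            "cols1": cols1, "h1": h1, "r1": r1, "pooled": pooled,
            "cols2": cols2, "h2": h2, "r2": r2, "o1": o1, "o2": o2,
        }

    def _augment_batch(self, xb, rng):
        out = np.empty_like(xb)
        for i, im in enumerate(xb):
            if rng.random() < 0.5:
                im = im[:, ::-1]
            if rng.random() < 0.5:
                im = im[::-1, :]
            angle = rng.uniform(-15, 15)
            im = rotate(im, angle, mode="edge")
            out[i] = im
        return out

    def fit(self, images: Sequence[np.ndarray], y: np.ndarray) -> "CNNEmbeddingExtractor":
        rng = np.random.default_rng(self.seed)
        X = self._prep(images)
        yb = np.asarray(y, float)
        p = self._init_params(rng)
        vel = {k: np.zeros_like(np.asarray(v, float)) for k, v in p.items()}
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X[idx]
                if self.augment:
                    xb = self._augment_batch(xb, rng)
                grads = self._grads(xb, yb[idx], p)
                for k in p:
                    vel[k] = self.momentum * vel[k] - self.lr * grads[k]
                    p[k] = p[k] + vel[k]
        self._params = p
        return self

    def _grads(self, xb, yb, p):
        st = self._forward(xb, p)
        n, f2, oh2, ow2 = st["r2"].shape
        gap = st["r2"].mean(axis=(2, 3))
        logits = gap @ p["w"] + p["b"]
        prob = 1.0 / (1.0 + np.exp(-logits))
        dlogit = (prob - yb) / n
        g = {}
        g["w"] = gap.T @ dlogit
        g["b"] = dlogit.sum()
        dgap = np.outer(dlogit, p["w"])
        dr2 = (dgap / (oh2 * ow2))[:, :, None, None] * np.ones_like(st["r2"])
        dh2 = dr2 * (st["h2"] > 0)
        dh2_flat = dh2.reshape(n, f2, -1).transpose(0, 2, 1)  # (n, o2*o2, f2)
        g["W2"] = np.einsum("npk,npf->kf", st["cols2"], dh2_flat)
        g["b2"] = dh2_flat.sum(axis=(0, 1))
        # grads wrt pooled input of conv2
        dcols2 = dh2_flat @ p["W2"].T  # (n, o2*o2, 9*8)
        npool, c1, hp, wp = st["pooled"].shape
        dpooled = np.zeros_like(st["pooled"])
        o2 = st["o2"]
        k2 = 3
        dcols2 = dcols2.reshape(n, o2, o2, c1, k2 * k2)  # channel-major concat
        # cols were concatenated per channel: (k*k) blocks per channel
        for ch in range(c1):
            block = dcols2[:, :, :, ch, :].reshape(n, o2, o2, k2, k2)
            for ki in range(k2):
                for kj in range(k2):
                    rows = np.arange(o2) * 2 + ki
                    colsj = np.arange(o2) * 2 + kj
                    np.add.at(
                        dpooled,
                        (slice(None), ch, rows[:, None], colsj[None, :]),
                        block[:, :, :, ki, kj],
                    )
        # unpool (max positions)
        nb, f1, oh1, ow1 = st["r1"].shape
        ph, pw = oh1 // 2, ow1 // 2
        window = st["r1"][:, :, : ph * 2, : pw * 2].reshape(nb, f1, ph, 2, pw, 2)
        maxval = window.max(axis=(3, 5), keepdims=True)
        ismax = window == maxval
        counts = ismax.sum(axis=(3, 5), keepdims=True)
        dwin = ismax * (dpooled[:, :, :, None, :, None] / counts)
        dr1 = np.zeros_like(st["r1"])
        dr1[:, :, : ph * 2, : pw * 2] = dwin.reshape(nb, f1, ph * 2, pw * 2)
        dh1 = dr1 * (st["h1"] > 0)
        dh1_flat = dh1.reshape(nb, f1, -1).transpose(0, 2, 1)
        g["W1"] = np.einsum("npk,npf->kf", st["cols1"], dh1_flat)
        g["b1"] = dh1_flat.sum(axis=(0, 1))
        return g

    def transform(self, images: Sequence[np.ndarray]) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("extractor not fitted")
        X = self._prep(images)
        st = self._forward(X, self._params)
        n = X.shape[0]
        return st["r2"].reshape(n, -1)


def extract_embeddings(images: Sequence[np.ndarray], extractor) -> np.ndarray:
    """Apply a fitted extractor; rows must share one fixed length."""
    E = np.asarray(extractor.transform(images), dtype=float)
    if E.ndim != 2:
        raise ValueError("extractor must return a 2-D matrix")
    return E


def reduce_pca(
    E_train: np.ndarray, k: int = 100, E_test: Optional[np.ndarray] = None
) -> tuple[np.ndarray, Optional[np.ndarray], PCA]:
    """Centered PCA fitted on training rows; k' = min(k, n-1, d)."""
    E_train = np.asarray(E_train, float)
    n, d = E_train.shape
    if n < 2:
        raise ValueError("need at least 2 training rows for PCA")
    k_eff = min(k, n - 1, d)
    if k_eff < k:
        logger.warning("PCA components reduced from %d to %d (rank bound)", k, k_eff)
    pca = PCA(n_components=k_eff, random_state=0).fit(E_train)
    Rt = pca.transform(E_train)
    Re = pca.transform(np.asarray(E_test, float)) if E_test is not None else None
    return Rt, Re, pca


def train_random_forest(
    X28: np.ndarray,
    Epca: np.ndarray,
    y: Sequence[str] | np.ndarray,
    n_trees: int = 100_000,
    seed: int = 0,
) -> TrainedClassifier:
    """Random forest on the fused [28 handcrafted | PCA-embedding] matrix.

    CS = fraction of trees voting symmetric.  The default tree count
    matches the reference configuration; pass a smaller ``n_trees``
    (e.g. 500) for desk-scale runs.
    """
    X28 = np.asarray(X28, float)
    Epca = np.asarray(Epca, float)
    if X28.shape[0] != Epca.shape[0]:
        raise ValueError(
            f"row mismatch: {X28.shape[0]} feature rows vs {Epca.shape[0]} embeddings"
        )
    yb = y if isinstance(y, np.ndarray) and y.dtype.kind == "i" else encode_labels(y)
    X = np.hstack([X28, Epca])
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, yb)
    mask = np.ones(X.shape[1], bool)
    return TrainedClassifier("random_forest", rf, None, mask)


def predict_cs(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict_cs(X)
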