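"""High-level workflows tying extraction, models and evaluation together.

These are the units the CLI and the reproduction script call: batch
feature extraction over a manifest or in-memory samples, and per-fold
model specifications (GA-SVM, fused random forest, label-shuffled null)
for :func:`choroviz.evaluation.run_model_comparison`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .core_io import DatasetManifest, read_image
from .features import FEATURE_COLUMNS, compute_features
from .models import (
    GAConfig,
    TrainedClassifier,
    encode_labels,
    extract_embeddings,
    gafs_select,
    reduce_pca,
    train_random_forest,
    train_svm,
)
from .synth import SynthSample


def extract_feature_table(
    manifest: DatasetManifest,
    image_dir: str | Path,
    cfg: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Compute the 28 features for every manifest record."""
    image_dir = Path(image_dir)
    rows = []
    for rec in manifest:
        img = read_image(
            image_dir / rec.image_path, rec.laterality, cfg.scale_mm_per_px, rec.eye_id
        )
        f = compute_features(img, cfg)
        rows.append({"eye_id": rec.eye_id, **f, "label": rec.label})
    return pd.DataFrame(rows)


def feature_table_from_samples(
    samples: Sequence[SynthSample], cfg: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """Feature table for in-memory synthetic samples."""
    rows = []
    for s in samples:
        use_cfg = cfg or PipelineConfig(scale_mm_per_px=s.image.scale_mm_per_px)
        f = compute_features(s.image, use_cfg)
        rows.append({"eye_id": s.image.eye_id, **f, "label": s.label})
    return pd.DataFrame(rows)


def split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(FEATURE_COLUMNS)].to_numpy(float)
    y = table["label"].to_numpy()
    return X, y


# ---------------------------------------------------------------------------
# Per-fold model specifications for run_model_comparison
# ---------------------------------------------------------------------------


@dataclass
class _FittedTabular:
    model: TrainedClassifier

    def score_cs(self, X, images, idx):
        return self.model.predict_cs(np.asarray(X, float)[idx])


@dataclass
class SVMModelSpec:
    """RBF-SVM on the 28 features, optionally GA-feature-selected per fold."""

    name: str = "svm"
    use_gafs: bool = True
    ga: GAConfig = field(default_factory=GAConfig)
    hyper: dict | str = "search"

    def fit_fold(self, X, images, y, train_idx, seed):
        Xt = np.asarray(X, float)[train_idx]
        yt = np.asarray(y)[train_idx]
        mask = None
        if self.use_gafs:
            ga = GAConfig(
                **{**self.ga.__dict__, "rng_seed": (self.ga.rng_seed + seed) % 2**31}
            )
            mask = gafs_select(Xt, yt, ga).selected_mask
        model = train_svm(Xt, yt, selected_mask=mask, hyper=self.hyper, seed=seed)
        return _FittedTabular(model)


@dataclass
class _FittedFusion:
    extractor: object
    pca: object
    model: TrainedClassifier

    def score_cs(self, X, images, idx):
        E = extract_embeddings([images[i] for i in idx], self.extractor)
        Ep = self.pca.transform(E)
        fused = np.hstack([np.asarray(X, float)[idx], Ep])
        return self.model.predict_cs(fused)


@dataclass
class RandomForestFusionSpec:
    """Random forest on [28 features | PCA-reduced image embeddings].

    The embedding extractor and the PCA basis are fitted inside each
    training fold only.
    """

    extractor_factory: Callable[[int], object]
    name: str = "random_forest"
    n_trees: int = 500
    pca_k: int = 100

    def fit_fold(self, X, images, y, train_idx, seed):
        if images is None:
            raise ValueError("fusion model requires images")
        Xt = np.asarray(X, float)[train_idx]
        yt = np.asarray(y)[train_idx]
        extractor = self.extractor_factory(seed)
        extractor.fit([images[i] for i in train_idx], encode_labels(yt))
        Et = extract_embeddings([images[i] for i in train_idx], extractor)
        Rt, _, pca = reduce_pca(Et, k=self.pca_k)
        model = train_random_forest(Xt, Rt, yt, n_trees=self.n_trees, seed=seed)
        return _FittedFusion(extractor, pca, model)


# ---------------------------------------------------------------------------
# Standing synthetic benchmark
# ---------------------------------------------------------------------------


def reference_benchmark(
    n: int = 200,
    alpha_symmetric: float = 0.1,
    alpha_asymmetric: float = 0.9,
    seed: int = 7,
    k: int = 10,
    n_trees: int = 500,
    image_size: int = 256,
    ga: Optional[GAConfig] = None,
    include_shuffled: bool = True,
):
    """The repository's standing end-to-end benchmark.

    Generates a balanced phantom cohort (mild vs strong hemifield
    asymmetry), extracts the 28 features, and runs the shared-fold
    cross-validated comparison: GA-selected RBF-SVM, fused random forest
    (pixel-PCA embedding pathway), and a label-shuffled null.  Returns
    (summary, feature_table).
    """
    from .evaluation import run_model_comparison
    from .models import PixelPCAExtractor
    from .synth import SynthConfig, generate_samples

    samples = generate_samples(
        n,
        SynthConfig(image_size=image_size, alpha=alpha_symmetric),
        SynthConfig(image_size=image_size, alpha=alpha_asymmetric),
        seed=seed,
    )
    table = feature_table_from_samples(samples)
    X, y = split_xy(table)
    images = [s.image.pixels for s in samples]
    # desk-scale GA: small evolution budget, reference operator settings
    ga = ga or GAConfig(max_generations=10, patience=5, rng_seed=seed)
    specs = [
        SVMModelSpec(name="svm", use_gafs=True, ga=ga),
        RandomForestFusionSpec(
            extractor_factory=lambda s: PixelPCAExtractor(n_components=100),
            name="random_forest",
            n_trees=n_trees,
        ),
    ]
    if include_shuffled:
        specs.append(
            ShuffledLabelSpec(
                base=SVMModelSpec(name="base", use_gafs=False, hyper={"C": 1.0}),
                name="shuffled",
                seed=seed,
            )
        )
    summary = run_model_comparison(X, y, specs, images=images, k=k, seed=seed)
    return summary, table


def gafs_recovery_rate(
    n_runs: int = 10,
    n: int = 200,
    seed: int = 0,
    ga: Optional[GAConfig] = None,
) -> float:
    """Fraction of seeded GA runs that keep both informative features.

    Simulation: the class depends only on two feature columns; the other
    26 are pure noise.  Each run draws fresh data and evolves a mask.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for run in range(n_runs):
        X = rng.normal(0.0, 1.0, (n, 28))
        y = np.where(X[:, 1] + X[:, 2] > 0, "symmetric", "asymmetric")
        cfg = ga or GAConfig(max_generations=12, patience=6)
        cfg = GAConfig(**{**cfg.__dict__, "rng_seed": (seed * 1009 + run) % 2**31})
        res = gafs_select(X, y, cfg)
        hits += bool(res.selected_mask[1] and res.selected_mask[2])
    return hits / n_runs


@dataclass
class ShuffledLabelSpec:
    """Null model: the base spec trained on permuted training labels."""

    base: object
    name: str = "shuffled"
    seed: int = 0

    def fit_fold(self, X, images, y, train_idx, seed):
        rng = np.random.default_rng(self.seed + seed)
        y_perm = np.asarray(y).copy()
        y_perm[train_idx] = rng.permutation(y_perm[train_idx])
        return self.base.fit_fold(X, images, y_perm, train_idx, seed)
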