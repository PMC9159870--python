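"""End-to-end pipeline: denoise, extract the 14-feature vector, classify.

The classifier consumes, per image, six multiscale LBP descriptors (histogram
energy and entropy at (D, r) in {(8,1), (16,2), (24,3)}) and eight Laws'
texture-energy descriptors — 14 features total — computed on the
wavelet-denoised image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import laws, lbp, logistic, synth, wavelet

__all__ = ["PipelineConfig", "extract_features", "extract_feature_table", "run_benchmark"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full pipeline, serializable for the CLI and config files."""

    wavelet: str = "haar"
    denoise_levels: int = 1
    denoise_rule: str = "universal"
    lbp_scales: tuple[tuple[int, float], ...] = lbp.DEFAULT_SCALES
    laws_epsilon: float = laws.DEFAULT_EPSILON
    ridge_lambda: float = 1e-6
    cv_folds: int = 5
    seed: int = 7
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.denoise_levels not in (0, 1, 2, 3):
            raise ValueError("denoise_levels must be 0 (off), 1, 2 or 3")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be nonnegative")
        object.__setattr__(
            self,
            "lbp_scales",
            tuple((int(D), float(r)) for D, r in self.lbp_scales),
        )

    def to_dict(self) -> dict:
        return {
            "wavelet": self.wavelet,
            "denoise_levels": self.denoise_levels,
            "denoise_rule": self.denoise_rule,
            "lbp_scales": [list(s) for s in self.lbp_scales],
            "laws_epsilon": self.laws_epsilon,
            "ridge_lambda": self.ridge_lambda,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "lbp_scales" in d:
            d["lbp_scales"] = tuple(tuple(s) for s in d["lbp_scales"])
        return cls(**d)


def extract_features(image, config: PipelineConfig = PipelineConfig()) -> dict[str, float]:
    """Denoise one image and compute its 14 named texture features."""
    arr = np.asarray(image, dtype=float)
    if config.denoise_levels > 0:
        arr = wavelet.denoise(
            arr,
            wavelet=config.wavelet,
            levels=config.denoise_levels,
            threshold_rule=config.denoise_rule,
        )
    feats = lbp.lbp_features(arr, scales=config.lbp_scales)
    feats.update(laws.laws_features(arr, epsilon=config.laws_epsilon))
    return feats


def extract_feature_table(
    images, labels=None, config: PipelineConfig = PipelineConfig(), filenames=None
) -> pd.DataFrame:
    """Feature rows for a batch of images; optional label/filename columns."""
    rows = [extract_features(img, config) for img in images]
    df = pd.DataFrame(rows)
    if labels is not None:
        labels = np.asarray(labels, dtype=int)
        if labels.size != len(df):
            raise ValueError("labels length does not match image count")
        df["label"] = labels
    if filenames is not None:
        df.insert(0, "filename", list(filenames))
    return df


@dataclass
class BenchmarkResult:
    feature_table: pd.DataFrame
    cv: logistic.CVResult
    config: PipelineConfig
    synthetic_config: synth.SyntheticConfig

    def report(self) -> dict:
        m = self.cv.pooled_metrics
        c = self.cv.pooled_counts
        return {
            "n_images": int(len(self.feature_table)),
            "pooled_counts": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn},
            "accuracy": m.accuracy,
            "precision": m.precision,
            "recall": m.recall,
            "f1": m.f1,
            "fold_accuracies": [fm.accuracy for fm in self.cv.fold_metrics],
            "config": self.config.to_dict(),
        }


def run_benchmark(
    synthetic_config: synth.SyntheticConfig | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> BenchmarkResult:
    """Simulate the two-class dataset, extract features, cross-validate.

    Defaults are the package benchmark: 100 images per class at 128x128,
    stratified 5-fold CV.
    """
    if synthetic_config is None:
        synthetic_config = synth.SyntheticConfig(seed=config.seed)
    data = synth.generate_dataset(synthetic_config)
    table = extract_feature_table(data.images, data.labels, config)
    feature_names = [c for c in table.columns if c != "label"]
    cv = logistic.cross_validate(
        table[feature_names].to_numpy(),
        table["label"].to_numpy(),
        feature_names,
        k_folds=config.cv_folds,
        seed=config.seed,
        ridge_lambda=config.ridge_lambda,
        threshold=config.threshold,
    )
    return BenchmarkResult(table, cv, config, synthetic_config)
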