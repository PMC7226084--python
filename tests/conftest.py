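import numpy as np
import pandas as pd
import pytest

from hfopipe.io import FEATURE_COLUMNS
from hfopipe.synth import GeneratorConfig, generate_recording


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A short two-channel recording for fast integration tests."""
    return GeneratorConfig(duration=60.0, n_channels=2, seed=13)


@pytest.fixture(scope="session")
def small_recording(small_config):
    return generate_recording(small_config)


def make_feature_frame(X: np.ndarray, labels) -> pd.DataFrame:
    """Wrap a feature matrix (first columns of the 12-feature schema, rest
    zero-padded) and labels into a minimal valid segment table."""
    X = np.asarray(X, dtype=float)
    full = np.zeros((len(X), len(FEATURE_COLUMNS)))
    full[:, :X.shape[1]] = X
    df = pd.DataFrame(full, columns=FEATURE_COLUMNS)
    df.insert(0, "subject", "s01")
    df.insert(1, "channel", "ch01")
    df.insert(2, "start_s", np.arange(len(X)) * 0.01)
    df.insert(3, "end_s", np.arange(1, len(X) + 1) * 0.01)
    df.insert(4, "window_ms", 10)
    df["label"] = list(labels)
    return df


def gaussian_clouds(rng: np.random.Generator, centers: dict[str, np.ndarray],
                    n_per_class: dict[str, int], scale: float = 1.0,
                    n_features: int = 12) -> pd.DataFrame:
    """Isotropic Gaussian class clouds as a segment table.

    Class means are tiled across all feature columns so separation survives
    the per-feature standardization inside the classifier pipelines.
    """
    X, labels = [], []
    for cls, mu in centers.items():
        mu = np.atleast_1d(mu)
        mu_full = np.tile(mu, int(np.ceil(n_features / len(mu))))[:n_features]
        X.append(rng.normal(mu_full, scale, size=(n_per_class[cls], n_features)))
        labels += [cls] * n_per_class[cls]
    return make_feature_frame(np.vstack(X), labels)
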