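import numpy as np
import pytest

from bfmorph import discrim, features, synth


@pytest.fixture(scope="session")
def feature_config():
    return features.FeatureConfig()


@pytest.fixture(scope="session")
def single_cell_pair():
    """One deterministic synthetic cell with clean clump contrast."""
    params = synth.GenotypeParams(
        "FIX", clump_rate=3.0, clump_darkness=60.0, background_noise_sd=2.0
    )
    return synth.generate_cell_image(params, clone=0, seed=7), params


@pytest.fixture(scope="session")
def toy_logistic_data():
    """Small well-conditioned two-class problem (no separation)."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((80, 4))
    eta = 0.8 * X[:, 0] - 0.6 * X[:, 2] + 0.25
    y = (rng.random(80) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


def scaled_cv_config(seed: int, **kw) -> discrim.CVConfig:
    """Nested-CV settings at the scaled-down problem size used in tests."""
    defaults = dict(n_lambda=50, lambda_decades=3.0, seed=seed)
    defaults.update(kw)
    return discrim.CVConfig(**defaults)


def model_level_xy(spec: synth.EffectSpec, n_per_class: int, seed: int):
    df = synth.generate_feature_table(spec, n_per_class, seed=seed)
    cols = synth.feature_columns(spec.n_features)
    return df[cols].to_numpy(), (df.genotype != "WT").astype(int).to_numpy()
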