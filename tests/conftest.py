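import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import smilespline as sp
from smilespline.model import ModelSpec, MixedSSANOVA, estimate_random_intercept

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def small_config(n_part=150, **kw):
    nf = round(n_part * 510 / 802)
    return sp.StudyConfig(n_participants=n_part, n_female=nf,
                          n_male=n_part - nf, **kw)


@pytest.fixture(scope="session")
def small_data():
    """A modest synthetic study shared across read-only tests."""
    cfg = small_config()
    truth = sp.default_truth(cfg)
    return sp.generate_ratings(cfg, truth, seed=11), truth, cfg


@pytest.fixture(scope="session")
def sym_fit(small_data):
    """Full (model 1) fit of the Effective response on the shared study."""
    data, truth, cfg = small_data
    sym = data[data.stimulus_kind == "symmetric"].reset_index(drop=True)
    spec = sp.enumerate_smile_models("effective")[0]
    th, s2 = estimate_random_intercept(sym, spec)
    return MixedSSANOVA(sym, spec).fit(theta2=th, sigma2=s2)


@pytest.fixture(scope="session")
def asym_fit(small_data):
    """Delay-asymmetry fit of the Pleasant response on the shared study."""
    from smilespline.pipeline import asymmetric_subset
    data, truth, cfg = small_data
    sub = asymmetric_subset(data)
    spec = ModelSpec("pleasant", "asymmetric")
    th, s2 = estimate_random_intercept(sub, spec)
    return MixedSSANOVA(sub, spec).fit(theta2=th, sigma2=s2)


def single_term_model(n=50, seed=42, noise=0.3):
    """Tiny one-covariate dataset for spline-solver oracle checks."""
    rng = np.random.default_rng(seed)
    age = rng.integers(18, 83, n)
    y = np.sin(2 * np.pi * (age - 18) / 64) + noise * rng.normal(size=n)
    df = pd.DataFrame({
        "participant_id": [f"P{i // 2}" for i in range(n)],
        "age": age, "gender": "F", "drinks": 0, "effective": y,
    })
    return MixedSSANOVA(df, ModelSpec("effective"), terms=("age",))
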