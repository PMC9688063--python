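import numpy as np
import pytest

import eegms


@pytest.fixture(scope="session")
def montage():
    return eegms.standard_1020()


@pytest.fixture(scope="session")
def templates(montage):
    return eegms.make_templates(montage)


@pytest.fixture(scope="session")
def small_cohort():
    """2+2 subjects, 20 s each — enough for structural checks."""
    cfg = eegms.GeneratorConfig(n_per_group=2, duration=20.0, seed=42)
    return cfg, eegms.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    """Feature table from the small cohort, using ground-truth templates."""
    cfg, cohort = small_cohort
    ess = [eegms.preprocess(rec, reject=False) for rec, _ in cohort]
    ts = eegms.TemplateSet(
        maps=cohort[0][1].templates, labels=("A", "B", "C", "D")
    )
    table, flags = eegms.extract_feature_table(ess, ts)
    return table, flags


def two_gaussian_table(n_per_class=100, d=6, sep=3.0, seed=0):
    """Well-separated two-class feature table for classifier tests."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, d))
    b = rng.normal(sep, 1.0, size=(n_per_class, d))
    x = np.vstack([a, b])
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(d)])
    df["group"] = ["HC"] * n_per_class + ["SZ"] * n_per_class
    df["subject_id"] = [f"{g}{i % 4}" for i, g in enumerate(df["group"])]
    return df
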