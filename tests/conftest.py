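"""Shared fixtures: simulated datasets and fitted posteriors.

Expensive objects (genome-scale normalization fixtures, variational
fits) are session-scoped so each is computed once per run.
"""

import numpy as np
import pandas as pd
import pytest

import tfactivity as tfa
from tfactivity.inference import TFActivityModel


@pytest.fixture(scope="session")
def design():
    return tfa.ExperimentDesign()


@pytest.fixture(scope="session")
def recovery_dataset():
    """Reference parameter-recovery fixture: 10 TFs x 200 genes."""
    return tfa.simulate_dataset(n_tfs=10, n_genes=200, amplitude=2.0,
                                frac_responsive=0.5, noise_sd=0.2, seed=1)


@pytest.fixture(scope="session")
def recovery_fit(recovery_dataset):
    ds = recovery_dataset
    return TFActivityModel(ds.expression, ds.network).fit()


@pytest.fixture(scope="session")
def null_dataset():
    """All TF activities identically zero: pure noise."""
    return tfa.simulate_dataset(n_tfs=10, n_genes=200, frac_responsive=0.0,
                                noise_sd=0.2, seed=2)


@pytest.fixture(scope="session")
def null_fit(null_dataset):
    ds = null_dataset
    return TFActivityModel(ds.expression, ds.network).fit()


#: Generator settings for the genome-scale normalization fixture. LOWESS
#: absorbs the local mean of true signal, so its accuracy depends on the
#: feature count per array; the fixture mirrors an E. coli-scale array.
BANANA_KW = dict(n_genes=4000, n_tfs=40, frac_responsive=0.15,
                 amplitude=1.5, noise_sd=0.2)


def decile_mean_residual(tab: pd.DataFrame, expr) -> float:
    """Max over arrays and intensity deciles of |mean(M - true x)|."""
    truth_long = expr.to_long().rename(
        columns={"M": "x", "gene": "feature_id", "replicate": "replicate_id"})
    df = tab.merge(truth_long,
                   on=["feature_id", "replicate_id", "time_min", "condition"])
    worst = 0.0
    for _, sub in df.groupby(["replicate_id", "time_min"]):
        dec = pd.qcut(sub["A"], 10, labels=False, duplicates="drop")
        worst = max(worst,
                    float((sub["M"] - sub["x"]).groupby(dec).mean().abs().max()))
    return worst


@pytest.fixture(scope="session")
def banana_biased():
    """Bias-amplitude-1 dataset with its raw and normalized MA tables."""
    ds = tfa.simulate_dataset(bias_amplitude=1.0, seed=11, **BANANA_KW)
    pairs = tfa.compute_ratios(ds.array_table)
    norm = tfa.lowess_normalize(pairs)
    return ds, pairs, norm


@pytest.fixture(scope="session")
def banana_clean():
    """Bias-free counterpart of the normalization fixture."""
    ds = tfa.simulate_dataset(bias_amplitude=0.0, seed=11, **BANANA_KW)
    pairs = tfa.compute_ratios(ds.array_table)
    norm = tfa.lowess_normalize(pairs)
    return ds, pairs, norm


def make_posterior(mean, sd, tf_ids=None, times=None, condition="A"):
    """Posterior container from bare profile arrays (test helper)."""
    mean = np.atleast_2d(np.asarray(mean, dtype=float))
    sd = np.atleast_2d(np.asarray(sd, dtype=float))
    n_tf, n_t = mean.shape
    return tfa.TFActivityResults(
        tf_ids=tf_ids or [f"TF{i + 1:02d}" for i in range(n_tf)],
        time_points_min=list(times) if times is not None
        else [0, 10, 20, 40, 60, 120][:n_t],
        activity_mean=mean,
        activity_sd=sd,
        condition=condition,
    )
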