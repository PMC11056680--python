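import numpy as np
import pandas as pd
import pytest

from screensim import GeneratorParams, generate_corpus, default_arms, simulate_arms


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(weekly_me_results=500, weekly_mag_custom=300, seed=1)


@pytest.fixture(scope="session")
def small_corpus(small_params):
    return generate_corpus(small_params)


@pytest.fixture(scope="session")
def arms():
    return default_arms()


@pytest.fixture(scope="session")
def small_simulation(small_params, arms):
    """Corpus, calibrated gate, all eight arm outcomes, and gold standard."""
    corpus, gate, outcomes, gold = simulate_arms(small_params, arms)
    return corpus, gate, outcomes, gold


def toy_records(rows):
    """Build a record DataFrame from (record_id, dup_of, eligible, score0) tuples."""
    df = pd.DataFrame(rows, columns=["record_id", "dup_of", "eligible", "score0"])
    df["dup_of"] = df["dup_of"].astype("Int64")
    df["in_me"] = True
    df["in_mag"] = True
    df["in_mag_custom_stratum"] = False
    df["language_english"] = True
    df["week"] = 1
    return df
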