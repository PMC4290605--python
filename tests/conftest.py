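import numpy as np
import pytest

from sumosite import feature_encoding as fe
from sumosite import synthetic_data as sd


@pytest.fixture(scope="session")
def small_dataset():
    """A small generated dataset shared by model-level tests."""
    spec = sd.SyntheticSpec(n_sites=400, n_proteins=40, seed=7)
    dataset = sd.generate(spec)
    df = fe.encode_dataset(dataset.windows(), dataset.proteins, dataset.annotations)
    X = fe.feature_matrix(df)
    y = (df["label"] == "positive").astype(int).to_numpy()
    Xs = fe.apply_scaler(fe.fit_scaler(X), X)
    return dataset, df, Xs, y


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWYX"), size=length))
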