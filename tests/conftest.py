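import numpy as np
import pytest

from gsmm_lpca import differentialize, fit_lpca
from gsmm_lpca.synthgen import SynthSpec, generate_matrix


def random_binary(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    """Random 0/1 matrix guaranteed to have no constant column."""
    while True:
        x = (rng.random((n, r)) < 0.5).astype(np.int8)
        colsum = x.sum(axis=0)
        if ((colsum > 0) & (colsum < n)).all():
            return x


@pytest.fixture(scope="session")
def canonical():
    """Canonical planted-cluster fixture with a fitted rank-2 model."""
    spec = SynthSpec(seed=11)
    raw, smap, truth = generate_matrix(spec)
    matrix, _ = differentialize(raw)
    model = fit_lpca(matrix, k=2, m=4.0)
    return {"matrix": matrix, "smap": smap, "truth": truth, "model": model}
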