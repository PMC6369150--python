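import numpy as np
import pytest

from adsleep.config import RunConfig
from adsleep.pipeline import run_all
from adsleep.recording import Epoch, Recording


def as_epoch(rec: Recording) -> Epoch:
    return Epoch(rec.samples, rec.fs_hz, list(rec.labels))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full end-to-end run of the default longitudinal study."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig()
    report = run_all(cfg, outdir)
    return cfg, report, outdir


def white_noise_epochs(n_epochs: int, n: int = 2000, fs: float = 100.0, seed: int = 0,
                       labels=("C3",)) -> list[Epoch]:
    """Unit-variance white Gaussian noise epochs."""
    g = np.random.default_rng(seed)
    return [
        Epoch(g.standard_normal((len(labels), n)), fs, list(labels))
        for _ in range(n_epochs)
    ]
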