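import numpy as np
import pytest

from nirsalt import PreprocessConfig, preprocess, synth


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced two-cohort synthetic dataset (fast enough for unit tests)."""
    cfg = synth.SpectralForwardConfig(seed=11)
    return synth.generate_dataset([synth.g1_default(60), synth.g2_default(25)], cfg)


@pytest.fixture(scope="session")
def preprocessed(small_dataset):
    """Averaged + first-derivative spectra aligned per cohort."""
    avg = preprocess.apply_pipeline(small_dataset.spectra, PreprocessConfig())
    idx = {s: i for i, s in enumerate(avg.sample_ids)}

    def cohort_xy(name):
        ref = small_dataset.reference.subset(name)
        X = avg.absorbance[[idx[s] for s in ref.sample_ids]]
        return X, ref

    return cohort_xy


def random_spectra_like(rng, n_rows, grid):
    """Smooth-ish random rows on a given grid (for I/O round trips)."""
    base = rng.normal(size=(n_rows, grid.size))
    return np.cumsum(base, axis=1) * 0.01
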