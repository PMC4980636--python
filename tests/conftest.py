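import numpy as np
import pytest

from m1apred.classifier import SVMConfig
from m1apred.sequence_io import SequenceRecord
from m1apred.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture
def small_svm_config():
    """A compact grid so grid search stays cheap in unit tests."""
    return SVMConfig(
        C_grid=(0.5, 2.0, 8.0),
        gamma_grid=(2.0**-7, 2.0**-5, 2.0**-3),
        inner_cv_folds=3,
        seed=7,
    )


@pytest.fixture
def strong_signal_dataset():
    """Near-separable synthetic windows (deterministic 6-position signal)."""
    return generate_dataset(
        SyntheticSpec(n_pos=60, n_neg=60, signal_strength=1.0, seed=11, tag="strong")
    )


@pytest.fixture
def null_dataset():
    """Positives and negatives exchangeable (no signal)."""
    return generate_dataset(
        SyntheticSpec(n_pos=60, n_neg=60, signal_strength=0.0, seed=13, tag="null")
    )


def random_records(n, length, seed, prefix="r"):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    return [
        SequenceRecord(f"{prefix}{i}", "".join(rng.choice(bases, size=length)))
        for i in range(n)
    ]


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(text, name="input.fa"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
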