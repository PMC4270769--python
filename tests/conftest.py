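import numpy as np
import pytest

from emochoice.choice_model import ChoiceDesign
from emochoice.synthetic_data import SynthConfig, generate_panel, generate_paired_panels


@pytest.fixture(scope="session")
def small_panel():
    """25-subject non-verbal-instrument panel; fast enough for per-test reuse."""
    panel, truth = generate_panel(SynthConfig(seed=42, n_subjects=25))
    return panel, truth


@pytest.fixture(scope="session")
def paired_panels():
    """Full-size paired panels (123 subjects, 12- and 39-item instruments)."""
    return generate_paired_panels(SynthConfig(seed=7))


def simulate_design(rng, n, J=7, beta=(0.8, -0.5), asc=None):
    """Draw a choice design with known slopes; the workhorse oracle generator."""
    beta = np.asarray(beta, dtype=float)
    X = rng.normal(size=(n, J, len(beta)))
    U = X @ beta
    if asc is not None:
        U = U + np.asarray(asc)[None, :]
    P = np.exp(U - U.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    chosen = (P.cumsum(axis=1) > rng.random((n, 1))).argmax(axis=1)
    alts = [chr(65 + j) for j in range(J)]
    names = [f"x{k}" for k in range(len(beta))]
    return ChoiceDesign(X, chosen, alts, names)
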