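import numpy as np
import pytest

from baconscope import phmm, synth


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic synthetic dataset shared across read-only tests."""
    cfg = synth.SynthConfig(seed=11)
    contigs, truth = synth.simulate_dataset(cfg)
    return cfg, contigs, truth


@pytest.fixture(scope="session")
def seed_profile():
    """Ancestral domain, a seed alignment of diverged copies, and its profile."""
    cfg = synth.SynthConfig(seed=5)
    rng = np.random.default_rng(5)
    ancestor, rows = synth.make_seed_alignment(cfg, rng)
    return cfg, ancestor, rows, phmm.build_profile(rows)
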