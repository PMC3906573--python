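"""Shared fixtures: one gradient scheme and a few phantoms per session.

Phantom generation dominates suite runtime, so everything reusable is
session-scoped.  Fixtures return immutable-by-convention objects; tests
that exclude volumes must operate on ``scan.copy()``.
"""

import numpy as np
import pytest

from dwiqc import bias, directional, phantom
from dwiqc.io import Protocol


@pytest.fixture(scope="session")
def scheme42():
    return bias.scheme_electrostatic(42, seed=12345)


@pytest.fixture(scope="session")
def scheme6():
    return bias.scheme_uniform6()


@pytest.fixture(scope="session")
def protocol():
    return Protocol()


@pytest.fixture(scope="session")
def clean_phantom(scheme42):
    """A noisy clean phantom (scan, manifest); copy before mutating."""
    return phantom.make_phantom(scheme=scheme42, seed=0)


@pytest.fixture(scope="session")
def noise_free_phantom(scheme42):
    return phantom.make_phantom(scheme=scheme42, snr=None, seed=0)


@pytest.fixture(scope="session")
def cohort(scheme42):
    """30 clean + 20 severe directional-bias phantoms (shared by the
    directional acceptance runs)."""
    return phantom.make_cohort(30, 20, seed=1, scheme=scheme42)


@pytest.fixture(scope="session")
def trained_stats(cohort, protocol):
    """Entropy statistics trained on the first 10 clean cohort phantoms."""
    clean, _ = cohort
    entropies = [directional.scan_entropy(scan, protocol)
                 for scan, _ in clean[:10]]
    return directional.train_stats(entropies)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
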