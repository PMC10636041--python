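import numpy as np
import pytest

from plexquant import (NoiseModel, make_panel, make_plate_plan,
                       simulate_counts)


@pytest.fixture(scope="session")
def small_panel():
    return make_panel(5, seed=11, barcode_length=12, min_distance=5)


@pytest.fixture(scope="session")
def small_plate(small_panel):
    return make_plate_plan(small_panel, seed=12, n_wells=24)


@pytest.fixture(scope="session")
def small_counts(small_panel, small_plate):
    return simulate_counts(small_panel, small_plate,
                           noise=NoiseModel(nb_dispersion=20.0), seed=13)


def levenshtein(a: str, b: str) -> int:
    """Plain unweighted edit distance, independent of the package and edlib."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j - 1] + (ca != cb), prev[j] + 1,
                           cur[j - 1] + 1))
        prev = cur
    return prev[-1]
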