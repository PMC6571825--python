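import numpy as np
import pandas as pd
import pytest

from wheyscreen.synthetic import (NoiseSpec, default_axis, default_library,
                                  generate_dataset, standard_design)

CLASS_ORDER = ["W", "WC", "WG", "WT", "WCG", "WCT", "WTG"]

# Benchmark confusion table of a published 7-class SIMCA whey-adulteration
# screen (500-1100 cm^-1 region): rows = true class, columns = assigned class
# in CLASS_ORDER plus a trailing no-class column.
SIMCA_BENCH_TRAIN = np.array([
    [7, 0, 0, 0, 0, 0, 0, 0],
    [0, 20, 0, 0, 0, 0, 0, 0],
    [0, 0, 20, 0, 0, 0, 0, 0],
    [0, 0, 0, 20, 0, 0, 0, 0],
    [0, 0, 0, 0, 19, 1, 0, 0],
    [0, 0, 0, 0, 0, 20, 0, 0],
    [0, 0, 0, 2, 0, 0, 18, 0],
])
SIMCA_BENCH_TEST = np.array([
    [3, 1, 0, 0, 0, 0, 0, 0],
    [0, 10, 0, 0, 0, 0, 0, 0],
    [1, 0, 9, 0, 0, 0, 0, 0],
    [0, 0, 0, 10, 0, 0, 0, 0],
    [0, 0, 0, 0, 10, 0, 0, 0],
    [0, 0, 0, 0, 0, 10, 0, 0],
    [0, 0, 0, 0, 0, 0, 10, 0],
])

# Published per-class statistics for the same screen (percent, one decimal),
# as (training, test) pairs in CLASS_ORDER.
SIMCA_BENCH_STATS = {
    "sensitivity": [(100.0, 75.0), (100.0, 100.0), (100.0, 90.0),
                    (100.0, 100.0), (95.0, 100.0), (100.0, 100.0),
                    (90.0, 100.0)],
    "specificity": [(100.0, 98.3), (100.0, 98.1), (100.0, 100.0),
                    (98.1, 100.0), (100.0, 100.0), (99.1, 100.0),
                    (100.0, 100.0)],
    "precision": [(100.0, 75.0), (100.0, 90.9), (100.0, 100.0),
                  (90.9, 100.0), (100.0, 100.0), (95.2, 100.0),
                  (100.0, 100.0)],
    "youden": [(100.0, 73.3), (100.0, 98.1), (100.0, 90.0),
               (98.1, 100.0), (95.0, 100.0), (99.1, 100.0),
               (90.0, 100.0)],
}


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def quiet_noise():
    """All artefacts off: pure linear mixtures."""
    return NoiseSpec().silent()


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset shared across tests (seed 7)."""
    design, sset = generate_dataset(standard_design(), seed=7)
    return design, sset


def bench_confusion(which: str):
    """Benchmark counts as a ConfusionMatrix."""
    from wheyscreen.evaluate import ConfusionMatrix
    counts = SIMCA_BENCH_TRAIN if which == "training" else SIMCA_BENCH_TEST
    return ConfusionMatrix(classes=CLASS_ORDER, counts=counts,
                           set_label=which)


@pytest.fixture(scope="session")
def bench_train():
    return bench_confusion("training")


@pytest.fixture(scope="session")
def bench_test():
    return bench_confusion("test")
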