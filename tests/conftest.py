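import pytest
from random import Random

from tablescout.model import Cell, TableGrid
from tablescout.synth import SyntheticSpec, generate_corpus


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def small_corpus():
    """A 30-article synthetic corpus with ground truth (fixed seed)."""
    return generate_corpus(n_articles=30, seed=101)


@pytest.fixture()
def baseline_grid():
    """Hand-built 1x1 baseline table: elements on rows, arms on columns."""
    cells = [
        Cell("Characteristic", 0, 0),
        Cell("Placebo (n=25)", 0, 1), Cell("HFNC (n=40)", 0, 2),
        Cell("Age, y, mean ± SD", 1, 0),
        Cell("53.2 ± 9.1", 1, 1), Cell("51.8 ± 8.7", 1, 2),
        Cell("Mortality, n (%)", 2, 0),
        Cell("2 (8.0)", 2, 1), Cell("3 (7.5)", 2, 2),
        Cell("Smoking status, n (%)", 3, 0), Cell("", 3, 1), Cell("", 3, 2),
        Cell("  Never", 4, 0), Cell("10 (40.0)", 4, 1), Cell("18 (45.0)", 4, 2),
        Cell("  Current", 5, 0), Cell("15 (60.0)", 5, 1), Cell("22 (55.0)", 5, 2),
        Cell("Sex M/F", 6, 0), Cell("11/14", 6, 1), Cell("21/19", 6, 2),
    ]
    return TableGrid(cells, 7, 3, 1, 1,
                     caption="Baseline characteristics of the study arms.")


@pytest.fixture()
def rng():
    return Random(12345)
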