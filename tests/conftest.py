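import itertools

import numpy as np
import pandas as pd
import pytest

from fitmeta.comparisons import canonical_comparisons
from fitmeta.regulation import RegulationMatrix


def matrix_from_calls(calls: pd.DataFrame, tissue: str = "roots") -> RegulationMatrix:
    """Wrap a gene x legend-number call frame (columns 1..7 or a subset)
    into a RegulationMatrix over the canonical comparisons."""
    specs = [s for s in canonical_comparisons(tissue) if s.number in set(calls.columns)]
    frame = calls.copy()
    frame.columns = [s.comparison_id for s in specs]
    frame = frame.astype(np.int8)
    measured = pd.DataFrame(True, index=frame.index, columns=frame.columns)
    return RegulationMatrix(specs, frame, measured)


def full_pattern_matrix(patterns: list[tuple[int, ...]], numbers: tuple[int, ...],
                        tissue: str = "roots") -> RegulationMatrix:
    """One gene per pattern; calls for ``numbers`` set from the pattern,
    every other canonical comparison zero."""
    genes = [f"G{i:05d}" for i in range(len(patterns))]
    calls = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"),
                         columns=list(range(1, 8)), dtype=int)
    for gene, pattern in zip(genes, patterns):
        for number, value in zip(numbers, pattern):
            calls.loc[gene, number] = value
    return matrix_from_calls(calls, tissue)


@pytest.fixture(scope="session")
def all_ternary_quads() -> list[tuple[int, ...]]:
    return list(itertools.product((-1, 0, 1), repeat=4))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
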