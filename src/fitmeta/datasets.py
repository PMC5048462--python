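"""Bundled reference data.

``load_marker_compendium`` returns the published ternary regulation calls
for the 25 most stably iron-deficiency-regulated Arabidopsis genes across
14 transcriptomic analyses (11 studies; analyses "7" and "10" are
induced-only sources and are therefore excluded from the denominator for
down-regulated genes). Useful as a smoke-test input and as the reference
for marker ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .virtual import StudyMatrix, StudyMeta, VirtConfig

__all__ = [
    "MARKER_STUDY_IDS",
    "MARKER_GENES_UP",
    "MARKER_GENES_DOWN",
    "load_marker_compendium",
    "marker_compendium_config",
    "PUBLISHED_VIRT",
]

MARKER_STUDY_IDS = [
    "1", "2", "3", "4", "5", "6a", "6b", "6c", "7", "8", "9a", "9b", "10", "11",
]
_INDUCED_ONLY = {"7", "10"}
_DOWN_ELIGIBLE = [s for s in MARKER_STUDY_IDS if s not in _INDUCED_ONLY]

# gene -> calls over the 14 analyses, in MARKER_STUDY_IDS order
MARKER_GENES_UP: dict[str, list[int]] = {
    "AT3G07720": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "AT3G58810": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "AT4G19690": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0],
    "AT3G12900": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0],
    "AT3G61930": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0],
    "AT1G09560": [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0],
    "AT3G06890": [1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 0],
    "AT3G46900": [1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0],
    "AT3G50740": [1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 1, 1, 1, 1],
    "AT3G56980": [1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 0, 1],
    "AT1G56160": [1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0],
    "AT3G58060": [1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 0],
}

# down-regulated genes: calls given over the 12 down-eligible analyses
# (induced-only sources never report these genes and carry 0)
_MARKER_DOWN_12: dict[str, list[int]] = {
    "AT5G01600": [-1, 0, -1, -1, -1, -1, -1, -1, -1, -1, -1, 0],
    "AT4G04770": [-1, 0, -1, -1, -1, -1, -1, -1, 0, -1, -1, 0],
    "AT2G36885": [-1, 0, 0, 0, -1, -1, -1, -1, -1, -1, -1, 0],
    "AT1G31330": [-1, 0, -1, -1, 0, -1, -1, 0, 0, -1, -1, 0],
    "AT1G68650": [-1, 0, 0, 0, -1, -1, -1, -1, -1, 0, -1, 0],
    "AT2G37130": [-1, 0, -1, -1, 0, -1, -1, 0, 0, -1, -1, 0],
    "AT2G40300": [-1, 0, 0, -1, -1, -1, -1, -1, -1, 0, 0, 0],
    "AT3G09220": [-1, -1, 0, 0, -1, -1, -1, 0, 0, -1, -1, 0],
    "AT4G08390": [-1, 0, -1, -1, 0, -1, -1, 0, 0, -1, -1, 0],
    "AT5G59400": [-1, 0, -1, -1, -1, -1, -1, -1, 0, 0, 0, 0],
    "AT1G58290": [0, 0, 0, 0, -1, -1, -1, -1, 0, -1, -1, 0],
    "AT4G25100": [-1, -1, 0, -1, -1, 0, 0, -1, 0, 0, 0, -1],
    "AT5G64100": [0, -1, 0, -1, 0, -1, -1, 0, 0, -1, -1, 0],
}


def _expand_down(calls12: list[int]) -> list[int]:
    full = dict(zip(_DOWN_ELIGIBLE, calls12))
    return [full.get(s, 0) for s in MARKER_STUDY_IDS]


MARKER_GENES_DOWN: dict[str, list[int]] = {
    gene: _expand_down(calls) for gene, calls in _MARKER_DOWN_12.items()
}

#: published 2-decimal VIRT values for the marker genes
PUBLISHED_VIRT: dict[str, float] = {
    "AT3G07720": 1.00, "AT3G58810": 1.00,
    "AT4G19690": 0.93, "AT3G12900": 0.93, "AT3G61930": 0.93,
    "AT1G09560": 0.86, "AT3G06890": 0.86, "AT3G46900": 0.86,
    "AT3G50740": 0.86, "AT3G56980": 0.86, "AT1G56160": 0.86, "AT3G58060": 0.86,
    "AT5G01600": -0.83, "AT4G04770": -0.75, "AT2G36885": -0.67,
    "AT1G31330": -0.58, "AT1G68650": -0.58, "AT2G37130": -0.58,
    "AT2G40300": -0.58, "AT3G09220": -0.58, "AT4G08390": -0.58,
    "AT5G59400": -0.58, "AT1G58290": -0.50, "AT4G25100": -0.50,
    "AT5G64100": -0.50,
}


def load_marker_compendium() -> StudyMatrix:
    """The 25-gene x 14-analysis ternary marker reference matrix."""
    rows = {**MARKER_GENES_UP, **MARKER_GENES_DOWN}
    values = pd.DataFrame.from_dict(
        rows, orient="index", columns=MARKER_STUDY_IDS, dtype=np.int8
    )
    values.index.name = "gene_id"
    studies = [
        StudyMeta(study_id=s, label=f"analysis {s}", induced_only=s in _INDUCED_ONLY)
        for s in MARKER_STUDY_IDS
    ]
    return StudyMatrix(studies, values)


def marker_compendium_config() -> VirtConfig:
    """Thresholds used for the published compendium (N=14 up, N=12 down)."""
    return VirtConfig(sum_min=2, rat_min=0.5, virt_min=0.25, n_total_up=14, n_total_down=12)
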