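"""Synthetic inputs with planted structure for end-to-end testing.

Two generators:

* :func:`generate_comparisons` — per-comparison log2FC/p tables for the
  seven canonical contrasts in roots and seedlings, with genes planted in
  classes that realize the defining sign patterns of the filter cascades
  (robustly FIT-induced/-repressed, tissue-specific variants, an
  iron-regulated-but-FIT-independent distractor, and unregulated genes).

* :func:`generate_study_matrix` — a gene x study ternary matrix with
  planted up/down genes whose per-study reporting probability
  ("consistency") and spurious-call rate ("background") are configurable,
  including induced-only studies that never report down-regulation.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparisons import canonical_comparisons
from .regulation import ComparisonTable
from .virtual import StudyMatrix, StudyMeta

__all__ = [
    "GENE_CLASSES",
    "SyntheticConfig",
    "StudySimConfig",
    "generate_comparisons",
    "generate_study_matrix",
]

GENE_CLASSES = (
    "robust_fit_induced",
    "robust_fit_repressed",
    "seedling_only_induced",
    "root_only_induced",
    "seedling_only_repressed",
    "root_only_repressed",
    "fe_regulated_fit_independent",
    "unregulated",
)

_DEFAULT_PROPORTIONS = {
    "robust_fit_induced": 0.05,
    "robust_fit_repressed": 0.05,
    "seedling_only_induced": 0.05,
    "root_only_induced": 0.05,
    "seedling_only_repressed": 0.05,
    "root_only_repressed": 0.05,
    "fe_regulated_fit_independent": 0.15,
    "unregulated": 0.55,
}

# planted ternary pattern per tissue over legend numbers 1..7 (absent -> 0).
# Robust classes carry their pattern in both tissues with contrast 7 left at
# 0 so they also survive the tissue cascades (and are then subtracted), as
# observed empirically. The FIT-independent distractor violates exactly the
# fourth criterion of each cascade (contrast 1 up, contrast 7 up).
_PATTERNS: dict[str, dict[str, dict[int, int]]] = {
    "robust_fit_induced": {
        "roots": {6: 1, 2: -1, 5: 1},
        "seedlings": {6: 1, 2: -1, 5: 1},
    },
    "robust_fit_repressed": {
        "roots": {6: -1, 2: 1, 5: -1},
        "seedlings": {6: -1, 2: 1, 5: -1},
    },
    "seedling_only_induced": {
        "roots": {6: 1},
        "seedlings": {6: 1, 2: -1, 5: 1},
    },
    "root_only_induced": {
        "roots": {6: 1, 2: -1, 5: 1},
        "seedlings": {6: 1},
    },
    "seedling_only_repressed": {
        "roots": {6: -1},
        "seedlings": {6: -1, 2: 1, 5: -1},
    },
    "root_only_repressed": {
        "roots": {6: -1, 2: 1, 5: -1},
        "seedlings": {6: -1},
    },
    "fe_regulated_fit_independent": {
        "roots": {6: 1, 2: -1, 5: 1, 1: 1, 7: 1},
        "seedlings": {6: 1, 2: -1, 5: 1, 1: 1, 7: 1},
    },
    "unregulated": {"roots": {}, "seedlings": {}},
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 1000
    class_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    effect_log2fc: float = 2.0
    noise_sd: float = 0.0
    p_signal: tuple[float, float] = (0.0, 0.05)  # uniform (low, high] for planted calls
    p_null: tuple[float, float] = (0.05, 1.0)  # uniform (low, high] for null cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene class(es): {', '.join(sorted(unknown))}")
        props = [self.class_proportions.get(c, 0.0) for c in GENE_CLASSES]
        if any(p < 0 for p in props):
            raise ValueError("class proportions must be >= 0")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {sum(props)}")
        if self.effect_log2fc <= np.log2(1.5):
            raise ValueError("effect_log2fc must exceed log2(1.5) for recoverability")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _class_counts(config: SyntheticConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_genes over the classes."""
    props = {c: config.class_proportions.get(c, 0.0) for c in GENE_CLASSES}
    raw = {c: config.n_genes * p for c, p in props.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    remainder = config.n_genes - sum(counts.values())
    by_frac = sorted(GENE_CLASSES, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in by_frac[:remainder]:
        counts[c] += 1
    return counts


def _gene_ids(n: int) -> list[str]:
    # synthetic AGI-like tokens (chromosome "S") that cannot collide with real loci
    return [f"ATSG{i:05d}" for i in range(1, n + 1)]


def generate_comparisons(
    config: SyntheticConfig,
) -> tuple[list[ComparisonTable], list[ComparisonTable], pd.Series]:
    """Seven tables per tissue plus the gene -> class truth labels.

    Planted calls translate into log2fc = call * effect + noise with a
    significant p-value; null cells get near-zero log2fc and an
    insignificant p-value, so at ``noise_sd=0`` the planted patterns are
    recovered exactly by thresholding.
    """
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config)
    genes = _gene_ids(config.n_genes)
    labels: list[str] = []
    for cls in GENE_CLASSES:
        labels.extend([cls] * counts[cls])
    truth = pd.Series(labels, index=pd.Index(genes, name="gene_id"), name="gene_class")

    p_sig_low, p_sig_high = config.p_signal
    p_null_low, p_null_high = config.p_null

    outputs: dict[str, list[ComparisonTable]] = {}
    for tissue in ("roots", "seedlings"):
        tables = []
        for spec in canonical_comparisons(tissue):
            calls = np.array(
                [_PATTERNS[cls][tissue].get(spec.number, 0) for cls in labels],
                dtype=float,
            )
            log2fc = calls * config.effect_log2fc + rng.normal(
                0.0, config.noise_sd, size=len(genes)
            )
            planted = calls != 0
            p = np.where(
                planted,
                rng.uniform(p_sig_low, p_sig_high, size=len(genes)),
                rng.uniform(p_null_low, p_null_high, size=len(genes)),
            )
            # keep planted p strictly significant and null p strictly not
            p = np.where(planted, np.maximum(p, 1e-12), np.maximum(p, np.nextafter(p_null_low, 1)))
            tables.append(
                ComparisonTable(
                    spec,
                    pd.DataFrame({"gene_id": genes, "log2fc": log2fc, "p_value": p}),
                )
            )
        outputs[tissue] = tables
    return outputs["roots"], outputs["seedlings"], truth


@dataclass(frozen=True)
class StudySimConfig:
    n_genes: int = 500
    n_studies: int = 14
    n_induced_only: int = 2
    consistency: float = 0.9
    background_rate: float = 0.0
    prop_up: float = 0.2
    prop_down: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_induced_only <= self.n_studies):
            raise ValueError("n_induced_only must be between 0 and n_studies")
        for name in ("consistency", "background_rate", "prop_up", "prop_down"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.prop_up + self.prop_down > 1:
            raise ValueError("prop_up + prop_down must not exceed 1")


def generate_study_matrix(config: StudySimConfig) -> tuple[StudyMatrix, pd.Series]:
    """Ternary study matrix plus gene -> {'up','down','none'} truth labels.

    True-up genes emit +1 with probability ``consistency`` in every study;
    true-down genes emit -1 in every non-induced-only study (induced-only
    columns are forced to 0 for them). Remaining zero cells flip to a
    spurious call with probability ``background_rate``; spurious calls in
    induced-only studies are always +1.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_up = int(round(config.prop_up * config.n_genes))
    n_down = int(round(config.prop_down * config.n_genes))
    labels = ["up"] * n_up + ["down"] * n_down + ["none"] * (config.n_genes - n_up - n_down)
    truth = pd.Series(labels, index=pd.Index(genes, name="gene_id"), name="direction")

    induced_only = np.zeros(config.n_studies, dtype=bool)
    induced_only[config.n_studies - config.n_induced_only :] = True
    studies = [
        StudyMeta(
            study_id=f"S{i + 1:02d}",
            label=f"synthetic analysis {i + 1}",
            induced_only=bool(flag),
        )
        for i, flag in enumerate(induced_only)
    ]

    values = np.zeros((config.n_genes, config.n_studies), dtype=np.int8)
    is_up = np.array([lbl == "up" for lbl in labels])
    is_down = np.array([lbl == "down" for lbl in labels])

    emit = rng.random(values.shape) < config.consistency
    values[is_up] = np.where(emit[is_up], 1, 0)
    down_emit = emit & ~induced_only[None, :]
    values[is_down] = np.where(down_emit[is_down], -1, 0)

    background = (values == 0) & (rng.random(values.shape) < config.background_rate)
    signs = np.where(rng.random(values.shape) < 0.5, 1, -1).astype(np.int8)
    signs[:, induced_only] = 1  # induced-only sources never report down
    values[background] = signs[background]

    frame = pd.DataFrame(
        values, index=pd.Index(genes, name="gene_id"), columns=[s.study_id for s in studies]
    )
    return StudyMatrix(studies, frame), truth
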