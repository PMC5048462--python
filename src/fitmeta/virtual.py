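"""Cross-study vote-counting meta-analysis of ternary regulation calls.

Each gene carries one call per study/analysis: +1 (up under iron
deficiency), -1 (down) or 0 (insignificant, below threshold, or not
reported). Per gene:

* ``ABS``  — number of nonzero calls (occurrence count),
* ``SUM``  — signed sum of the calls,
* ``RAT``  — ``|SUM| / ABS``, the uniformity of direction,
* ``VIRT`` — ``(SUM / N) * RAT``, the virtual expected expression change,
  where N counts the analyses eligible for the gene's direction: all of
  them for up-regulation, but excluding "induced-only" analyses (sources
  that report only up-regulated genes) for down-regulation.

A gene is retained when ``|SUM| >= sum_min``, ``RAT >= rat_min`` and
``|VIRT| >= virt_min`` (defaults 2 / 0.5 / 0.25, all inclusive). |VIRT|
roughly approximates the probability of observing the gene regulated in
its majority direction, and ranks the retained genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .comparisons import normalize_agi

__all__ = [
    "StudyMeta",
    "StudyMatrix",
    "VirtConfig",
    "VirtRecord",
    "compute_virt",
    "build_virtual_dataset",
    "virt_records",
    "records_to_frame",
    "summarize_dataset",
    "rank_markers",
    "round_half_away",
]


@dataclass(frozen=True)
class StudyMeta:
    """One source analysis in the compendium."""

    study_id: str
    label: str = ""
    induced_only: bool = False  # source reports only up-regulated genes
    tissue: str = "mixed"  # roots | seedlings | mixed

    def __post_init__(self) -> None:
        if self.tissue not in ("roots", "seedlings", "mixed"):
            raise ValueError(f"tissue must be roots/seedlings/mixed, got {self.tissue!r}")


@dataclass
class StudyMatrix:
    """Gene x study ternary call matrix with per-study metadata."""

    studies: list[StudyMeta]
    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate study_id")
        if list(self.values.columns) != ids:
            raise ValueError("value columns must match study ids in order")
        self.values.index = pd.Index(
            [normalize_agi(g) for g in self.values.index], name="gene_id"
        )
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicate gene row(s): {', '.join(sorted(set(dup))[:5])}")
        arr = self.values.to_numpy()
        if not np.isin(arr, (-1, 0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (-1, 0, 1)))[0]
            raise ValueError(
                f"call outside {{-1,0,1}} at gene {self.values.index[bad[0]]!r}, "
                f"study {ids[bad[1]]!r}"
            )
        for meta in self.studies:
            if meta.induced_only:
                col = self.values[meta.study_id]
                offending = col.index[col == -1]
                if len(offending):
                    raise ValueError(
                        f"induced-only study {meta.study_id!r} carries a -1 call "
                        f"for gene {offending[0]!r}"
                    )
        self.values = self.values.astype(np.int8)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_induced_only(self) -> int:
        return sum(s.induced_only for s in self.studies)

    def default_config(self, **overrides) -> "VirtConfig":
        """Thresholds with denominators derived from this study set."""
        params = dict(
            n_total_up=len(self.studies),
            n_total_down=len(self.studies) - self.n_induced_only,
        )
        params.update(overrides)
        return VirtConfig(**params)


@dataclass(frozen=True)
class VirtConfig:
    """Thresholds and direction-dependent denominators.

    Defaults (14 total analyses, 12 down-eligible) match a compendium of
    14 analyses of which 2 are induced-only.
    """

    sum_min: int = 2
    rat_min: float = 0.5
    virt_min: float = 0.25
    n_total_up: int = 14
    n_total_down: int = 12

    def __post_init__(self) -> None:
        if self.sum_min < 1:
            raise ValueError("sum_min must be >= 1")
        if not (0 < self.rat_min <= 1):
            raise ValueError("rat_min must be in (0, 1]")
        if not (0 < self.virt_min <= 1):
            raise ValueError("virt_min must be in (0, 1]")
        if self.n_total_down > self.n_total_up:
            raise ValueError("n_total_down cannot exceed n_total_up")
        if min(self.n_total_up, self.n_total_down) < 1:
            raise ValueError("denominators must be positive")


@dataclass(frozen=True)
class VirtRecord:
    gene_id: str
    abs_occ: int
    sum_reg: int
    rat: float
    virt: float
    passes: bool
    direction: str  # up | down | none

    @property
    def virt_rounded(self) -> float:
        """VIRT rounded half-away-from-zero to two decimals (report scale)."""
        return round_half_away(self.virt, 2)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.005 -> 0.01, -0.005 -> -0.01)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def compute_virt(
    row: Sequence[int] | pd.Series,
    studies: Sequence[StudyMeta],
    config: VirtConfig,
    gene_id: str = "",
) -> VirtRecord:
    """Score one gene's calls across the study set.

    Calls from induced-only studies contribute as given (they are never -1);
    the direction-dependent denominator is taken from ``config``.
    """
    calls = np.asarray(row, dtype=int)
    if calls.shape != (len(studies),):
        raise ValueError(f"expected {len(studies)} calls, got {calls.shape}")
    if not np.isin(calls, (-1, 0, 1)).all():
        raise ValueError(f"calls outside {{-1,0,1}} for gene {gene_id!r}")
    for meta, call in zip(studies, calls):
        if meta.induced_only and call == -1:
            raise ValueError(
                f"induced-only study {meta.study_id!r} carries -1 for gene {gene_id!r}"
            )

    abs_occ = int(np.count_nonzero(calls))
    sum_reg = int(calls.sum())
    if abs_occ == 0:
        return VirtRecord(gene_id, 0, 0, 0.0, 0.0, False, "none")
    rat = abs(sum_reg) / abs_occ
    if sum_reg > 0:
        n_total = config.n_total_up
    elif sum_reg < 0:
        n_total = config.n_total_down
    else:
        # SUM = 0: no majority direction; VIRT is 0 regardless of denominator
        n_total = config.n_total_up
    virt = (sum_reg / n_total) * rat
    passes = (
        abs(sum_reg) >= config.sum_min
        and rat >= config.rat_min
        and abs(virt) >= config.virt_min
    )
    direction = "none"
    if passes:
        direction = "up" if sum_reg > 0 else "down"
    return VirtRecord(gene_id, abs_occ, sum_reg, rat, virt, passes, direction)


def virt_records(matrix: StudyMatrix, config: Optional[VirtConfig] = None) -> list[VirtRecord]:
    """A record for every gene in the matrix (passing or not)."""
    cfg = config if config is not None else matrix.default_config()
    return [
        compute_virt(matrix.values.loc[gene].to_numpy(), matrix.studies, cfg, gene_id=gene)
        for gene in matrix.genes
    ]


def _rank_key(record: VirtRecord) -> tuple:
    # |VIRT| descending, then ABS descending, then AGI ascending
    return (-abs(record.virt), -record.abs_occ, record.gene_id)


def build_virtual_dataset(
    matrix: StudyMatrix, config: Optional[VirtConfig] = None
) -> list[VirtRecord]:
    """Retained (passing) records, ranked by |VIRT| with deterministic ties.

    Ties are broken by occurrence count (descending) then gene identifier
    (ascending), so output order is stable and reproducible.
    """
    records = virt_records(matrix, config)
    return sorted((r for r in records if r.passes), key=_rank_key)


def records_to_frame(records: Iterable[VirtRecord]) -> pd.DataFrame:
    """Tabular view with report-scale (2-decimal) VIRT alongside raw values."""
    rows = [
        {
            "gene_id": r.gene_id,
            "ABS": r.abs_occ,
            "SUM": r.sum_reg,
            "RAT": r.rat,
            "VIRT": r.virt,
            "VIRT_2dp": r.virt_rounded,
            "passes": r.passes,
            "direction": r.direction,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "ABS", "SUM", "RAT", "VIRT", "VIRT_2dp", "passes", "direction"],
    )


def summarize_dataset(
    records: Iterable[VirtRecord],
    reference_genes: Optional[set[str]] = None,
) -> dict:
    """Counts and mean |VIRT| over passing records.

    When ``reference_genes`` is given, also reports the fraction of passing
    genes found in that reference set (coverage).
    """
    passing = [r for r in records if r.passes]
    summary: dict = {
        "n_pass": len(passing),
        "n_up": sum(r.direction == "up" for r in passing),
        "n_down": sum(r.direction == "down" for r in passing),
        "mean_abs_virt": (
            float(np.mean([abs(r.virt) for r in passing])) if passing else None
        ),
    }
    if reference_genes is not None and passing:
        ref = {normalize_agi(g) for g in reference_genes}
        covered = sum(r.gene_id in ref for r in passing)
        summary["reference_coverage"] = covered / len(passing)
    return summary


def rank_markers(records: Iterable[VirtRecord], direction: str, k: int) -> list[VirtRecord]:
    """Top-k passing records of one direction by |VIRT| (stable tie-break)."""
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    eligible = sorted(
        (r for r in records if r.passes and r.direction == direction), key=_rank_key
    )
    return eligible[:k]
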