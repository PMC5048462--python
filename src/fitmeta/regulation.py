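"""Ternary regulation calls from differential-expression tables.

A gene is called up-regulated (+1) in a comparison when its p-value is at or
below the significance threshold and its log2 fold change is at or above
log2 of the fold-change threshold; down-regulated (-1) symmetrically; and 0
otherwise. Calls are assembled into a gene x comparison matrix together with
a "measured" mask so that "not regulated" stays distinguishable from "not on
the platform".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparisons import ComparisonSpec, normalize_agi

__all__ = [
    "CallConfig",
    "ComparisonTable",
    "RegulationMatrix",
    "call_regulation",
    "assemble_matrix",
    "regulated_set",
    "venn_partition",
]


@dataclass(frozen=True)
class CallConfig:
    """Significance thresholds for ternary calls.

    ``fc_threshold`` is on the linear scale (default 1.5) and applied to
    log2 fold changes as ``|log2fc| >= log2(fc_threshold)``; both thresholds
    are inclusive.
    """

    fc_threshold: float = 1.5
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError(f"fc_threshold must be > 1, got {self.fc_threshold}")
        if not (0 < self.p_threshold < 1):
            raise ValueError(f"p_threshold must be in (0,1), got {self.p_threshold}")

    @property
    def log2fc_threshold(self) -> float:
        return math.log2(self.fc_threshold)


@dataclass
class ComparisonTable:
    """Per-gene log2 fold change and p-value for one comparison."""

    comparison: ComparisonSpec
    data: pd.DataFrame = field(repr=False)  # columns: gene_id, log2fc, p_value

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = ["gene_id", "log2fc", "p_value"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"comparison table missing column(s): {', '.join(missing)}")
        df["gene_id"] = df["gene_id"].map(normalize_agi)
        df["log2fc"] = pd.to_numeric(df["log2fc"])
        df["p_value"] = pd.to_numeric(df["p_value"])
        bad = df.loc[~np.isfinite(df["log2fc"]), "gene_id"]
        if len(bad):
            raise ValueError(f"non-finite log2fc for gene(s): {', '.join(bad.head(5))}")
        bad = df.loc[(df["p_value"] < 0) | (df["p_value"] > 1) | df["p_value"].isna(), "gene_id"]
        if len(bad):
            raise ValueError(f"p_value outside [0,1] for gene(s): {', '.join(bad.head(5))}")
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene_id(s): {', '.join(sorted(set(dup))[:5])}")
        self.data = df[required].reset_index(drop=True)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.data["gene_id"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RegulationMatrix:
    """Gene x comparison ternary calls plus a measured-gene mask.

    ``calls`` holds values in {-1, 0, +1}; ``measured`` is boolean with the
    same shape. Unmeasured cells are always 0.
    """

    comparisons: list[ComparisonSpec]
    calls: pd.DataFrame = field(repr=False)
    measured: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ids = [c.comparison_id for c in self.comparisons]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate comparison_id in matrix")
        if list(self.calls.columns) != ids or list(self.measured.columns) != ids:
            raise ValueError("calls/measured columns must match comparison ids in order")
        if not self.calls.index.equals(self.measured.index):
            raise ValueError("calls and measured must share the same gene index")
        if self.calls.index.has_duplicates:
            raise ValueError("duplicate gene rows")
        vals = self.calls.to_numpy()
        if not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("calls must be in {-1, 0, 1}")
        if (vals[~self.measured.to_numpy()] != 0).any():
            raise ValueError("unmeasured cells must carry call 0")

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def comparison_ids(self) -> list[str]:
        return [c.comparison_id for c in self.comparisons]

    def column(self, comparison_id: str) -> pd.Series:
        if comparison_id not in self.calls.columns:
            raise KeyError(f"unknown comparison_id {comparison_id!r}")
        return self.calls[comparison_id]

    def column_by_number(self, number: int) -> pd.Series:
        """Call column for a canonical legend number."""
        for spec in self.comparisons:
            if spec.number == number:
                return self.calls[spec.comparison_id]
        raise KeyError(f"no comparison with legend number {number}")

    def negated(self) -> "RegulationMatrix":
        """Matrix with every call sign-flipped (mask unchanged)."""
        return RegulationMatrix(self.comparisons, -self.calls, self.measured.copy())


def call_regulation(table: ComparisonTable, config: CallConfig = CallConfig()) -> pd.Series:
    """Ternary call per gene for a single comparison table.

    Returns an int8 Series indexed by gene_id with values in {-1, 0, +1}.
    """
    lfc = table.data["log2fc"].to_numpy()
    p = table.data["p_value"].to_numpy()
    thr = config.log2fc_threshold
    sig = p <= config.p_threshold
    calls = np.where(sig & (lfc >= thr), 1, np.where(sig & (lfc <= -thr), -1, 0))
    return pd.Series(calls.astype(np.int8), index=table.genes, name=table.comparison.comparison_id)


def assemble_matrix(
    tables: list[ComparisonTable],
    config: CallConfig = CallConfig(),
    gene_universe: list[str] | None = None,
) -> RegulationMatrix:
    """Stack per-comparison calls into a RegulationMatrix.

    The gene universe is the union of the tables' genes unless supplied.
    Genes absent from a table are measured=False (call 0) in that column.
    """
    if not tables:
        raise ValueError("at least one comparison table required")
    ids = [t.comparison.comparison_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate comparison_id among tables: {ids}")

    if gene_universe is None:
        genes = sorted(set(itertools.chain.from_iterable(t.genes for t in tables)))
    else:
        genes = [normalize_agi(g) for g in gene_universe]
        if len(set(genes)) != len(genes):
            raise ValueError("gene_universe contains duplicates")
    index = pd.Index(genes, name="gene_id")

    calls = pd.DataFrame(0, index=index, columns=ids, dtype=np.int8)
    measured = pd.DataFrame(False, index=index, columns=ids, dtype=bool)
    for table in tables:
        col = call_regulation(table, config)
        present = col.index.intersection(index)
        cid = table.comparison.comparison_id
        calls.loc[present, cid] = col.loc[present].astype(np.int8)
        measured.loc[present, cid] = True
    return RegulationMatrix([t.comparison for t in tables], calls, measured)


def regulated_set(
    matrix: RegulationMatrix,
    comparisons: list[str] | None = None,
    direction: str = "any",
) -> set[str]:
    """Genes whose call matches ``direction`` in at least one listed comparison.

    ``direction`` is 'up' (+1), 'down' (-1) or 'any' (nonzero).
    """
    if direction not in ("up", "down", "any"):
        raise ValueError(f"direction must be up/down/any, got {direction!r}")
    cols = matrix.comparison_ids if comparisons is None else list(comparisons)
    unknown = [c for c in cols if c not in matrix.calls.columns]
    if unknown:
        raise KeyError(f"unknown comparison_id(s): {', '.join(unknown)}")
    sub = matrix.calls[cols]
    if direction == "up":
        hit = (sub == 1).any(axis=1)
    elif direction == "down":
        hit = (sub == -1).any(axis=1)
    else:
        hit = (sub != 0).any(axis=1)
    return set(matrix.genes[hit])


def venn_partition(sets: dict[str, set[str]]) -> dict[frozenset, int]:
    """Counts over all non-empty membership regions of 2-4 named sets.

    Keys are frozensets of set names: the region of elements belonging to
    exactly those sets and no others. Counts sum to the size of the union.
    """
    if not (2 <= len(sets) <= 4):
        raise ValueError(f"venn_partition supports 2-4 sets, got {len(sets)}")
    names = list(sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            regions[frozenset(combo)] = 0
    for element in set().union(*sets.values()):
        membership = frozenset(n for n in names if element in sets[n])
        regions[membership] += 1
    return regions
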