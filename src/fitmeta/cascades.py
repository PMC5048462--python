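"""Four-step sign-pattern cascades for FIT dependence.

Two families of cascades, built from the canonical legend numbers:

* robust cascades (both tissues, comparisons 6, 2, 5, 1):
  a robustly FIT-induced gene is up in WT -Fe vs +Fe, down in fit -Fe vs
  WT -Fe, up in HA-FIT -Fe vs +Fe, and NOT up in fit +Fe vs WT +Fe — in
  roots AND seedlings. The repressed cascade is the sign mirror.

* tissue cascades (one tissue, comparisons 6, 2, 5, 7): the first two and
  last two conditions are evaluated as two combined steps; the fourth
  condition uses the fit intra-line contrast (7) instead of contrast 1.
  The robust set is subtracted from the survivors to leave the exclusively
  tissue-specific genes.

"Not up" means call != +1 (down-regulated or below threshold), and "not
down" means call != -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .regulation import RegulationMatrix, regulated_set

__all__ = [
    "Requirement",
    "CascadeSpec",
    "CascadeResult",
    "ROBUST_INDUCED",
    "ROBUST_REPRESSED",
    "TISSUE_INDUCED",
    "TISSUE_REPRESSED",
    "filter_robust_induced",
    "filter_robust_repressed",
    "filter_tissue_induced",
    "filter_tissue_repressed",
    "cascade_report",
]

# requirement token -> predicate on a ternary call Series
_PREDICATES = {
    "up": lambda s: s == 1,
    "down": lambda s: s == -1,
    "not_up": lambda s: s != 1,
    "not_down": lambda s: s != -1,
}

Requirement = tuple[int, str]  # (legend number, requirement token)


@dataclass(frozen=True)
class CascadeSpec:
    """An ordered list of filter steps, each a conjunction of requirements."""

    name: str
    steps: tuple[tuple[Requirement, ...], ...]
    tissues: str  # 'both' or 'single'

    def __post_init__(self) -> None:
        if self.tissues not in ("both", "single"):
            raise ValueError("tissues must be 'both' or 'single'")
        for step in self.steps:
            for _, token in step:
                if token not in _PREDICATES:
                    raise ValueError(f"unknown requirement {token!r}")


ROBUST_INDUCED = CascadeSpec(
    "robust_induced",
    (((6, "up"),), ((2, "down"),), ((5, "up"),), ((1, "not_up"),)),
    tissues="both",
)
ROBUST_REPRESSED = CascadeSpec(
    "robust_repressed",
    (((6, "down"),), ((2, "up"),), ((5, "down"),), ((1, "not_down"),)),
    tissues="both",
)
# steps 1+2 and 3+4 are evaluated pairwise, as in the single-tissue analysis
TISSUE_INDUCED = CascadeSpec(
    "tissue_induced",
    (((6, "up"), (2, "down")), ((5, "up"), (7, "not_up"))),
    tissues="single",
)
TISSUE_REPRESSED = CascadeSpec(
    "tissue_repressed",
    (((6, "down"), (2, "up")), ((5, "down"), (7, "not_down"))),
    tissues="single",
)


@dataclass
class CascadeResult:
    spec: CascadeSpec
    input_universe: set[str]
    per_step_survivors: list[set[str]] = field(repr=False)
    final_set: set[str] = field(default_factory=set)
    subtracted: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        prev = self.input_universe
        for step in self.per_step_survivors:
            if not step <= prev:
                raise ValueError("cascade survivors are not nested")
            prev = step


def _passes(matrices: list[RegulationMatrix], step: tuple[Requirement, ...], genes: set[str]) -> set[str]:
    """Genes in ``genes`` satisfying every requirement in every matrix."""
    keep = set(genes)
    for matrix in matrices:
        mask = pd.Series(True, index=matrix.genes)
        for number, token in step:
            mask &= _PREDICATES[token](matrix.column_by_number(number))
        keep &= set(matrix.genes[mask])
    return keep


def _run_cascade(
    spec: CascadeSpec,
    matrices: list[RegulationMatrix],
    universe: set[str],
    robust_set: set[str] | None = None,
) -> CascadeResult:
    survivors: list[set[str]] = []
    current = set(universe)
    for step in spec.steps:
        current = _passes(matrices, step, current)
        survivors.append(set(current))
    subtracted: set[str] = set()
    final = set(current)
    if robust_set is not None:
        subtracted = final & robust_set
        final -= subtracted
    return CascadeResult(spec, set(universe), survivors, final, subtracted)


def _check_canonical(matrix: RegulationMatrix, numbers: tuple[int, ...]) -> None:
    for n in numbers:
        matrix.column_by_number(n)  # raises KeyError when absent


def _both_tissue_universe(roots: RegulationMatrix, seedlings: RegulationMatrix) -> set[str]:
    return regulated_set(roots) & regulated_set(seedlings)


def filter_robust_induced(
    roots: RegulationMatrix,
    seedlings: RegulationMatrix,
    universe: set[str] | None = None,
) -> CascadeResult:
    """Genes passing the induced cascade in both tissues.

    ``universe`` defaults to the genes regulated in at least one comparison
    in roots AND in at least one comparison in seedlings.
    """
    for m in (roots, seedlings):
        _check_canonical(m, (6, 2, 5, 1))
    if universe is None:
        universe = _both_tissue_universe(roots, seedlings)
    return _run_cascade(ROBUST_INDUCED, [roots, seedlings], universe)


def filter_robust_repressed(
    roots: RegulationMatrix,
    seedlings: RegulationMatrix,
    universe: set[str] | None = None,
) -> CascadeResult:
    """Sign mirror of :func:`filter_robust_induced`."""
    for m in (roots, seedlings):
        _check_canonical(m, (6, 2, 5, 1))
    if universe is None:
        universe = _both_tissue_universe(roots, seedlings)
    return _run_cascade(ROBUST_REPRESSED, [roots, seedlings], universe)


def filter_tissue_induced(
    matrix: RegulationMatrix,
    tissue_universe: set[str] | None = None,
    robust_set: set[str] | None = None,
) -> CascadeResult:
    """FIT-induced genes in a single tissue, with the robust set subtracted."""
    _check_canonical(matrix, (6, 2, 5, 7))
    if tissue_universe is None:
        tissue_universe = regulated_set(matrix)
    robust = set(robust_set or ())
    stray = robust - set(matrix.genes)
    if stray:
        import logging

        logging.getLogger(__name__).warning(
            "%d robust-set gene(s) absent from the matrix universe", len(stray)
        )
    return _run_cascade(TISSUE_INDUCED, [matrix], tissue_universe, robust)


def filter_tissue_repressed(
    matrix: RegulationMatrix,
    tissue_universe: set[str] | None = None,
    robust_set: set[str] | None = None,
) -> CascadeResult:
    """Sign mirror of :func:`filter_tissue_induced`."""
    _check_canonical(matrix, (6, 2, 5, 7))
    if tissue_universe is None:
        tissue_universe = regulated_set(matrix)
    robust = set(robust_set or ())
    stray = robust - set(matrix.genes)
    if stray:
        import logging

        logging.getLogger(__name__).warning(
            "%d robust-set gene(s) absent from the matrix universe", len(stray)
        )
    return _run_cascade(TISSUE_REPRESSED, [matrix], tissue_universe, robust)


def cascade_report(result: CascadeResult) -> dict:
    """Survivor counts, per-step attrition and per-gene dropout step.

    ``dropout`` maps every excluded universe gene to the 1-based step at
    which it dropped out; surviving genes are absent from the mapping.
    """
    counts = [len(s) for s in result.per_step_survivors]
    sizes = [len(result.input_universe)] + counts
    attrition = [sizes[i] - sizes[i + 1] for i in range(len(counts))]
    dropout: dict[str, int] = {}
    prev = result.input_universe
    for i, survivors in enumerate(result.per_step_survivors, start=1):
        for gene in prev - survivors:
            dropout[gene] = i
        prev = survivors
    table = pd.DataFrame(
        {
            "step": list(range(1, len(counts) + 1)),
            "survivors": counts,
            "attrition": attrition,
        }
    )
    return {
        "cascade": result.spec.name,
        "input_size": len(result.input_universe),
        "survivor_counts": counts,
        "attrition": attrition,
        "subtracted": sorted(result.subtracted),
        "final_set": sorted(result.final_set),
        "dropout_step": dropout,
        "table": table,
    }
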