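"""Comparison design: lines, iron conditions and the canonical contrast set.

The experimental design crosses three Arabidopsis lines (wild type, the
``fit`` knock-out, and the HA-FIT over-expressor) with two iron conditions
(+Fe, -Fe) in two tissues (six-week-old roots, six-day-old seedlings).
Seven pairwise contrasts per tissue are canonical and carry stable legend
numbers used throughout the filtering cascades:

    1  fit +Fe   vs WT +Fe
    2  fit -Fe   vs WT -Fe
    3  HAFIT +Fe vs WT +Fe
    4  HAFIT -Fe vs WT -Fe
    5  HAFIT -Fe vs HAFIT +Fe
    6  WT -Fe    vs WT +Fe
    7  fit -Fe   vs fit +Fe

Contrasts between conditions within one line are "intra-line"; contrasts
between lines at a fixed iron status are "inter-line".
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

LINES = ("WT", "fit", "HAFIT")
IRON = ("+Fe", "-Fe")
TISSUES = ("roots", "seedlings")

#: legend number -> ((numerator line, numerator iron), (denominator line, denominator iron))
CANONICAL_CONTRASTS: dict[int, tuple[tuple[str, str], tuple[str, str]]] = {
    1: (("fit", "+Fe"), ("WT", "+Fe")),
    2: (("fit", "-Fe"), ("WT", "-Fe")),
    3: (("HAFIT", "+Fe"), ("WT", "+Fe")),
    4: (("HAFIT", "-Fe"), ("WT", "-Fe")),
    5: (("HAFIT", "-Fe"), ("HAFIT", "+Fe")),
    6: (("WT", "-Fe"), ("WT", "+Fe")),
    7: (("fit", "-Fe"), ("fit", "+Fe")),
}

_AGI_VERSION = re.compile(r"\.\d+$")


def normalize_agi(gene_id: str) -> str:
    """Uppercase a locus identifier and strip a trailing version suffix.

    >>> normalize_agi("at4g19690.1")
    'AT4G19690'
    """
    return _AGI_VERSION.sub("", str(gene_id).strip()).upper()


@dataclass(frozen=True)
class ComparisonSpec:
    """One named pairwise contrast (one tissue, one line/condition pair)."""

    comparison_id: str
    tissue: str
    numerator: tuple[str, str]  # (line, iron)
    denominator: tuple[str, str]
    number: Optional[int] = None  # canonical legend number, if any

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        for line, iron in (self.numerator, self.denominator):
            if line not in LINES:
                raise ValueError(f"unknown line {line!r}; expected one of {LINES}")
            if iron not in IRON:
                raise ValueError(f"unknown iron status {iron!r}; expected one of {IRON}")
        if self.numerator == self.denominator:
            raise ValueError(f"{self.comparison_id}: numerator equals denominator")
        # exactly one of line / iron may differ
        if (self.numerator[0] != self.denominator[0]) and (self.numerator[1] != self.denominator[1]):
            raise ValueError(
                f"{self.comparison_id}: contrast changes both line and iron status"
            )

    @property
    def comparison_class(self) -> str:
        """'intra_line' (iron contrast within a line) or 'inter_line'."""
        if self.numerator[0] == self.denominator[0]:
            return "intra_line"
        return "inter_line"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        n, d = self.numerator, self.denominator
        return f"{self.comparison_id}[{n[0]} {n[1]} vs {d[0]} {d[1]}, {self.tissue}]"


def canonical_comparisons(tissue: str, prefix: str | None = None) -> list[ComparisonSpec]:
    """The seven canonical contrasts for one tissue, in legend order.

    ``comparison_id`` defaults to ``<initial><number>`` (e.g. ``r6``, ``s2``).
    """
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}")
    pfx = prefix if prefix is not None else tissue[0]
    return [
        ComparisonSpec(
            comparison_id=f"{pfx}{number}",
            tissue=tissue,
            numerator=num,
            denominator=den,
            number=number,
        )
        for number, (num, den) in CANONICAL_CONTRASTS.items()
    ]


def by_number(comparisons: list[ComparisonSpec]) -> dict[int, ComparisonSpec]:
    """Index comparisons by legend number; numbers must be unique."""
    out: dict[int, ComparisonSpec] = {}
    for spec in comparisons:
        if spec.number is None:
            continue
        if spec.number in out:
            raise ValueError(f"duplicate legend number {spec.number}")
        out[spec.number] = spec
    return out
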