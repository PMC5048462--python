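"""Readers and writers for the tabular interchange formats.

One dialect everywhere: tab-separated, UTF-8, header row, '.' decimal.
Every writer's output is readable by its paired reader with value
equality. Validation errors name the offending column, gene and/or line
number (1-based, counting the header as line 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .comparisons import CANONICAL_CONTRASTS, ComparisonSpec
from .regulation import ComparisonTable, RegulationMatrix
from .virtual import StudyMatrix, StudyMeta, VirtRecord, records_to_frame

__all__ = [
    "FormatError",
    "read_comparison_manifest",
    "write_comparison_manifest",
    "read_comparison_table",
    "write_comparison_table",
    "read_regulation_matrix",
    "write_regulation_matrix",
    "read_study_matrix",
    "write_study_matrix",
    "read_profile_matrix",
    "write_profile_matrix",
    "read_marker_list",
    "write_virt_records",
    "write_json",
]

_FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    """Malformed input file."""


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kwargs)


def _require_columns(df: pd.DataFrame, required: list[str], path: Path | str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, column: str, path: Path | str) -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & (df[column] != "")
    bad |= df[column] == ""
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise FormatError(
            f"{path}: unparseable value {df.loc[bad.idxmax(), column]!r} "
            f"in column {column!r} at line {line}"
        )
    return converted


# -- comparison manifests and tables -----------------------------------------

_MANIFEST_COLUMNS = [
    "comparison_id",
    "tissue",
    "numerator_line",
    "numerator_iron",
    "denominator_line",
    "denominator_iron",
]


def _infer_number(numerator: tuple[str, str], denominator: tuple[str, str]) -> int | None:
    for number, (num, den) in CANONICAL_CONTRASTS.items():
        if (num, den) == (numerator, denominator):
            return number
    return None


def read_comparison_manifest(path: str | Path) -> dict[str, ComparisonSpec]:
    """comparison_id -> ComparisonSpec; canonical legend numbers inferred."""
    df = _read_tsv(path)
    _require_columns(df, _MANIFEST_COLUMNS, path)
    specs: dict[str, ComparisonSpec] = {}
    for _, row in df.iterrows():
        cid = row["comparison_id"]
        if cid in specs:
            raise FormatError(f"{path}: duplicate comparison_id {cid!r}")
        numerator = (row["numerator_line"], row["numerator_iron"])
        denominator = (row["denominator_line"], row["denominator_iron"])
        specs[cid] = ComparisonSpec(
            comparison_id=cid,
            tissue=row["tissue"],
            numerator=numerator,
            denominator=denominator,
            number=_infer_number(numerator, denominator),
        )
    return specs


def write_comparison_manifest(specs: list[ComparisonSpec], path: str | Path) -> None:
    rows = [
        {
            "comparison_id": s.comparison_id,
            "tissue": s.tissue,
            "numerator_line": s.numerator[0],
            "numerator_iron": s.numerator[1],
            "denominator_line": s.denominator[0],
            "denominator_iron": s.denominator[1],
        }
        for s in specs
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_comparison_table(path: str | Path, spec: ComparisonSpec) -> ComparisonTable:
    df = _read_tsv(path)
    _require_columns(df, ["gene_id", "log2fc", "p_value"], path)
    data = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "log2fc": _numeric(df, "log2fc", path),
            "p_value": _numeric(df, "p_value", path),
        }
    )
    try:
        return ComparisonTable(spec, data)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_comparison_table(table: ComparisonTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


# -- regulation matrices -----------------------------------------------------

def write_regulation_matrix(
    matrix: RegulationMatrix, calls_path: str | Path, mask_path: str | Path | None = None
) -> None:
    """Calls as a gene x comparison TSV; mask (0/1) to a parallel file."""
    matrix.calls.to_csv(calls_path, sep="\t")
    if mask_path is not None:
        matrix.measured.astype(int).to_csv(mask_path, sep="\t")


def read_regulation_matrix(
    calls_path: str | Path,
    manifest: dict[str, ComparisonSpec],
    mask_path: str | Path | None = None,
) -> RegulationMatrix:
    calls = _read_tsv(calls_path, index_col=0)
    unknown = [c for c in calls.columns if c not in manifest]
    if unknown:
        raise FormatError(f"{calls_path}: comparison(s) not in manifest: {', '.join(unknown)}")
    for column in calls.columns:
        _numeric(calls, column, calls_path)
    calls = calls.astype(int)
    bad = ~calls.isin((-1, 0, 1))
    if bad.to_numpy().any():
        gene = calls.index[bad.any(axis=1)][0]
        col = calls.columns[bad.loc[gene].to_numpy().argmax()]
        raise FormatError(
            f"{calls_path}: call outside {{-1,0,1}} at gene {gene!r}, comparison {col!r}"
        )
    if mask_path is not None:
        mask = _read_tsv(mask_path, index_col=0)
        for column in mask.columns:
            _numeric(mask, column, mask_path)
        measured = mask.astype(int).astype(bool)
        measured = measured.reindex(index=calls.index, columns=calls.columns)
        if measured.isna().to_numpy().any():
            raise FormatError(f"{mask_path}: mask does not cover the calls matrix")
    else:
        measured = pd.DataFrame(True, index=calls.index, columns=calls.columns)
    calls.index = calls.index.astype(str)
    measured.index = measured.index.astype(str)
    specs = [manifest[c] for c in calls.columns]
    try:
        return RegulationMatrix(specs, calls.astype(np.int8), measured)
    except ValueError as exc:
        raise FormatError(f"{calls_path}: {exc}") from exc


# -- study matrices ----------------------------------------------------------

_STUDY_COLUMNS = ["study_id", "label", "induced_only", "tissue"]
_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no", ""}


def read_study_manifest(path: str | Path) -> list[StudyMeta]:
    df = _read_tsv(path)
    _require_columns(df, _STUDY_COLUMNS, path)
    studies = []
    for _, row in df.iterrows():
        flag = row["induced_only"].strip().lower()
        if flag in _TRUTHY:
            induced_only = True
        elif flag in _FALSY:
            induced_only = False
        else:
            raise FormatError(
                f"{path}: induced_only must be boolean-like, "
                f"got {row['induced_only']!r} for study {row['study_id']!r}"
            )
        studies.append(
            StudyMeta(
                study_id=row["study_id"],
                label=row["label"],
                induced_only=induced_only,
                tissue=row["tissue"] or "mixed",
            )
        )
    return studies


def write_study_manifest(studies: list[StudyMeta], path: str | Path) -> None:
    rows = [
        {
            "study_id": s.study_id,
            "label": s.label,
            "induced_only": int(s.induced_only),
            "tissue": s.tissue,
        }
        for s in studies
    ]
    pd.DataFrame(rows, columns=_STUDY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_study_matrix(matrix_path: str | Path, manifest_path: str | Path) -> StudyMatrix:
    """Ternary matrix TSV + study manifest TSV -> validated StudyMatrix.

    A -1 call in an induced-only study's column is rejected with the study
    and gene named; any cell outside {-1,0,1} is rejected with coordinates.
    """
    studies = read_study_manifest(manifest_path)
    df = _read_tsv(matrix_path, index_col=0)
    known = {s.study_id for s in studies}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise FormatError(
            f"{matrix_path}: study column(s) not in manifest: {', '.join(unknown)}"
        )
    for column in df.columns:
        _numeric(df, column, matrix_path)
    values = df.astype(int)
    bad = ~values.isin((-1, 0, 1))
    if bad.to_numpy().any():
        gene = values.index[bad.any(axis=1)][0]
        col = values.columns[bad.loc[gene].to_numpy().argmax()]
        raise FormatError(
            f"{matrix_path}: call {values.loc[gene, col]} outside {{-1,0,1}} "
            f"at gene {gene!r}, study {col!r}"
        )
    ordered = [s for s in studies if s.study_id in set(values.columns)]
    values = values[[s.study_id for s in ordered]]
    values.index = values.index.astype(str)
    try:
        return StudyMatrix(ordered, values.astype(np.int8))
    except ValueError as exc:
        raise FormatError(f"{matrix_path}: {exc}") from exc


def write_study_matrix(
    matrix: StudyMatrix, matrix_path: str | Path, manifest_path: str | Path | None = None
) -> None:
    matrix.values.to_csv(matrix_path, sep="\t")
    if manifest_path is not None:
        write_study_manifest(matrix.studies, manifest_path)


# -- profiles, markers, results ----------------------------------------------

def read_profile_matrix(path: str | Path):
    """Gene x comparison log2fc TSV; empty cells are missing values."""
    from .clustering import ProfileMatrix

    df = _read_tsv(path, index_col=0)
    values = df.replace("", np.nan)
    for column in values.columns:
        converted = pd.to_numeric(values[column], errors="coerce")
        bad = converted.isna() & values[column].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(
                f"{path}: unparseable log2fc in column {column!r} at line {line}"
            )
        values[column] = converted
    values.index = values.index.astype(str)
    return ProfileMatrix(values)


def write_profile_matrix(matrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


def read_marker_list(path: str | Path) -> list[str]:
    """One AGI code per line; blank lines and '#' comments ignored."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    markers = []
    for raw in path.read_text().splitlines():
        token = raw.strip()
        if token and not token.startswith("#"):
            markers.append(token)
    return markers


def write_virt_records(records: list[VirtRecord], path: str | Path) -> None:
    frame = records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
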