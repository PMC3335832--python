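"""Readers and writers for the formats the pipeline touches.

* GEO-Series-Matrix-style TSV: "!"-prefixed metadata lines carrying sample
  annotations, then a rectangular probe x sample data block between
  ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers.
  Group labels are extracted from characteristics lines with configurable
  regular expressions, since the field dialects vary across submitters.
* GMT gene-set collections (name, description, symbols, tab-separated).
* Plain TSV clinical tables and detection-p-value tables.

Parsers report 1-based line numbers on error; writers emit full-precision
values and stable row order so outputs diff cleanly.
"""

from __future__ import annotations

import re
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .gse import GeneSet, GeneSetCollection

TABLE_BEGIN = "!series_matrix_table_begin"
TABLE_END = "!series_matrix_table_end"

#: default regexes applied to !Sample_characteristics values
DEFAULT_CHARACTERISTIC_PATTERNS = {
    "group": r"group:\s*(.+)",
    "sex": r"sex:\s*(.+)",
    "subject_id": r"subject(?:_id)?:\s*(.+)",
}

_MISSING_TOKENS = {"", "na", "nan", "null"}


def _quote(x: str) -> str:
    return '"' + str(x) + '"'


def write_series_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write expression values and sample annotations as a Series-Matrix TSV."""
    samples = list(matrix.samples)
    ann = matrix.sample_annotations
    with open(path, "w") as fh:
        fh.write("!Series_title\t" + _quote("edsig synthetic cohort") + "\n")
        fh.write("!Series_scale\t" + _quote(matrix.scale) + "\n")
        fh.write("!Sample_title\t" + "\t".join(_quote(s) for s in samples) + "\n")
        for key in ("group", "sex", "subject_id"):
            if key in ann.columns and ann[key].notna().any():
                fh.write(
                    "!Sample_characteristics_ch1\t"
                    + "\t".join(_quote(f"{key}: {ann.loc[s, key]}") for s in samples)
                    + "\n"
                )
        fh.write(TABLE_BEGIN + "\n")
        fh.write("\t".join([_quote("ID_REF"), *(_quote(s) for s in samples)]) + "\n")
        arr = matrix.values.to_numpy(float)
        for probe, row in zip(matrix.probes, arr):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write("\t".join([_quote(probe), *cells]) + "\n")
        fh.write(TABLE_END + "\n")


def write_detection(matrix: ExpressionMatrix, path) -> None:
    """Parallel detection-p TSV: header ID_REF + sample ids, full precision."""
    with open(path, "w") as fh:
        fh.write("\t".join(["ID_REF", *matrix.samples]) + "\n")
        arr = matrix.detection_p.to_numpy(float)
        for probe, row in zip(matrix.probes, arr):
            fh.write("\t".join([probe, *(repr(float(v)) for v in row)]) + "\n")


def write_probe_annotations(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("probe\tgene\n")
        for probe, sym in matrix.probe_annotations.items():
            fh.write(f"{probe}\t{'' if pd.isna(sym) else sym}\n")


class SeriesMatrixParseError(ValueError):
    """Parse failure, annotated with the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _strip_quotes(cell: str) -> str:
    cell = cell.strip()
    if len(cell) >= 2 and cell[0] == '"' and cell[-1] == '"':
        return cell[1:-1]
    return cell


def read_series_matrix(
    path,
    detection_path=None,
    probe_annotation_path=None,
    characteristic_patterns: Mapping[str, str] | None = None,
    scale: str = "intensity",
) -> ExpressionMatrix:
    """Parse a Series-Matrix-style TSV into an :class:`ExpressionMatrix`.

    Sample annotations come from ``!Sample_characteristics`` lines matched
    against ``characteristic_patterns`` (annotation name -> regex with one
    capture group). Missing data cells are loaded as NaN. Files written by
    :func:`write_series_matrix` round-trip exactly, including the scale
    flag carried on the ``!Series_scale`` line.
    """
    patterns = {k: re.compile(v, re.IGNORECASE) for k, v in (characteristic_patterns or DEFAULT_CHARACTERISTIC_PATTERNS).items()}
    metadata: list[list[str]] = []
    samples: list[str] | None = None
    probes: list[str] = []
    seen_probes: set[str] = set()
    data: list[np.ndarray] = []
    in_table = False
    table_done = False
    file_scale: str | None = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(TABLE_END):
                if not in_table:
                    raise SeriesMatrixParseError("table end marker before begin marker", lineno)
                in_table = False
                table_done = True
                continue
            if line.startswith(TABLE_BEGIN):
                if table_done:
                    raise SeriesMatrixParseError("second data block", lineno)
                in_table = True
                continue
            if not in_table:
                if line.startswith("!"):
                    cells = [_strip_quotes(c) for c in line.split("\t")]
                    if cells[0] == "!Series_scale" and len(cells) > 1:
                        file_scale = cells[1]
                    metadata.append(cells)
                continue
            cells = [_strip_quotes(c) for c in line.split("\t")]
            if samples is None:
                samples = cells[1:]
                continue
            if len(cells) != len(samples) + 1:
                raise SeriesMatrixParseError(
                    f"ragged row: {len(cells)} fields, expected {len(samples) + 1}", lineno
                )
            probe = cells[0]
            if probe in seen_probes:
                raise SeriesMatrixParseError(f"duplicate probe id {probe!r}", lineno)
            seen_probes.add(probe)
            try:
                row = np.array(
                    [np.nan if c.lower() in _MISSING_TOKENS else float(c) for c in cells[1:]]
                )
            except ValueError as exc:
                raise SeriesMatrixParseError(str(exc), lineno) from None
            probes.append(probe)
            data.append(row)

    if samples is None or not probes:
        raise SeriesMatrixParseError("no data block found", 1)

    values = pd.DataFrame(np.vstack(data), index=pd.Index(probes, name="probe"), columns=pd.Index(samples, name="sample"))

    # sample annotations from characteristics metadata
    ann = pd.DataFrame(index=values.columns)
    for cells in metadata:
        if not cells[0].lower().startswith("!sample_characteristics"):
            continue
        payload = cells[1:]
        if len(payload) != len(samples):
            continue
        for name, pat in patterns.items():
            matches = [pat.search(v) for v in payload]
            if all(m is not None for m in matches):
                ann[name] = [m.group(1).strip() for m in matches]

    detection = _read_plain_table(detection_path, values) if detection_path else pd.DataFrame(
        0.0, index=values.index, columns=values.columns
    )

    if probe_annotation_path:
        pa = pd.read_csv(probe_annotation_path, sep="\t", index_col=0, dtype=str)
        symbols = pa.iloc[:, 0].replace("", np.nan).reindex(values.index)
    else:
        symbols = pd.Series(np.nan, index=values.index, dtype=object)

    return ExpressionMatrix(
        values=values,
        detection_p=detection,
        probe_annotations=symbols,
        sample_annotations=ann,
        scale=file_scale or scale,
    )


def _read_plain_table(path, reference: pd.DataFrame) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table = table.reindex(index=reference.index, columns=reference.columns)
    if table.isna().any().any():
        raise ValueError(f"{path}: table does not cover all probes/samples of the expression matrix")
    return table


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: one set per line, name TAB description TAB symbols."""
    collection = GeneSetCollection(source=source or str(path))
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT line needs >= 3 tab-separated fields")
            name, description = cells[0], cells[1]
            symbols = [c.strip() for c in cells[2:]]
            if any(not s for s in symbols):
                import warnings

                warnings.warn(f"{path}: line {lineno}: empty symbol field dropped", stacklevel=2)
                symbols = [s for s in symbols if s]
            if name in collection:
                raise ValueError(f"{path}: line {lineno}: duplicate gene-set name {name!r}")
            collection.add(GeneSet(name=name, description=description, genes=tuple(symbols)))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# clinical tables


def write_clinical(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "subject"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_clinical(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="subject", na_values=["NA"])
    return table
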