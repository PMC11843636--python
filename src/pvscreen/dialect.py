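"""Reading and writing the FAERS quarterly ASCII dialect.

FAERS quarterly extracts ship one table per file as dollar-sign-delimited
ASCII: the first line is a ``$``-separated header, every following line is
one record, and there is no quoting or escape mechanism.  Because the
dialect has no escaping, a field value may never contain the delimiter;
writers reject such values instead of silently corrupting the table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger("pvscreen")

DELIMITER = "$"
ENCODING = "ascii"

#: Columns consumed by the analysis, per table.  Real FAERS tables carry
#: more columns; extras are tolerated on read and ignored downstream.
TABLE_COLUMNS: dict[str, list[str]] = {
    "DEMO": ["primaryid", "caseid", "caseversion", "fda_dt", "age",
             "age_cod", "sex", "occr_country"],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname",
             "indi_pt"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
}

TABLE_NAMES = tuple(TABLE_COLUMNS)


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    """Serialize ``frame`` to ``path`` in the dollar-delimited dialect.

    All cells are written as text.  Raises ``ValueError`` if any cell or
    column name contains the delimiter (the dialect cannot represent it).
    """
    path = Path(path)
    cells = frame.astype(str)
    if any(DELIMITER in c for c in map(str, frame.columns)):
        raise ValueError("column name contains the field delimiter '$'")
    if cells.apply(lambda col: col.str.contains(DELIMITER, regex=False)).any().any():
        raise ValueError(
            f"a field value contains the delimiter {DELIMITER!r}; "
            "the FAERS dialect has no escaping, value rejected"
        )
    with open(path, "w", encoding=ENCODING, newline="\n") as fh:
        fh.write(DELIMITER.join(map(str, frame.columns)) + "\n")
        for row in cells.itertuples(index=False):
            fh.write(DELIMITER.join(row) + "\n")
    return path


def read_table(path: str | Path, required: list[str] | None = None
               ) -> tuple[pd.DataFrame, int]:
    """Parse one dollar-delimited table.

    Returns ``(frame, n_malformed)`` where ``n_malformed`` counts data
    lines whose field count does not match the header; such lines are
    logged and excluded, never silently dropped.  All values are returned
    as strings; type coercion is the caller's concern.

    Raises ``ValueError`` when a column in ``required`` is absent.
    """
    path = Path(path)
    with open(path, encoding=ENCODING) as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file, no header")
        header = header_line.rstrip("\n").split(DELIMITER)
        rows: list[list[str]] = []
        n_malformed = 0
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split(DELIMITER)
            if len(fields) != len(header):
                n_malformed += 1
                logger.warning("%s:%d: expected %d fields, got %d — line skipped",
                               path, lineno, len(header), len(fields))
                continue
            rows.append(fields)
    frame = pd.DataFrame(rows, columns=header, dtype=str)
    if required:
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    return frame, n_malformed
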