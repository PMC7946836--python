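"""Reading and writing clonotype tables.

Two dialects are supported:

* **AIRR Rearrangement TSV** — tab-separated with a header row following the
  AIRR Community column names. ``junction_aa`` is mandatory;
  ``duplicate_count`` is the abundance (rows where it is missing or zero
  default to 1); ``junction`` (nucleotide), ``v_call`` and ``j_call`` are
  carried through when present.

* **Decombinator-style CSV** — comma-separated lines of five classifier
  fields (V index, J index, V deletions, J deletions, insert string), then an
  integer abundance, then the CDR3 amino-acid string.  The classifier V/J
  indices are stored verbatim as ``v_call``/``j_call``.

Rows sharing a clonotype key are merged with counts summed — upstream error
correction has already collapsed sequencing errors, so duplicate rows are the
same clonotype reported twice.  Sample metadata (patient, chain, timepoint)
is never inferred from file content: it comes from explicit arguments or from
a cohort manifest.
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd

from .errors import EmptyRepertoireError, FormatError, ManifestError
from .repertoire import Clone, Repertoire, merge_clones

AIRR_COLUMNS = ("sequence_id", "junction_aa", "junction", "v_call", "j_call", "duplicate_count")

MANIFEST_COLUMNS = ("sample_id", "patient_id", "chain", "timepoint", "path")

DIALECTS = ("airr", "decombinator")


def _clean(value) -> Optional[str]:
    """Normalize a table cell to a non-empty string or None."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def read_airr(
    path,
    *,
    sample_id: Optional[str] = None,
    patient_id: str = "",
    chain: str = "alpha",
    timepoint: str = "other",
) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a :class:`Repertoire`.

    Rows with identical clonotype keys are merged (counts summed); a missing
    or zero ``duplicate_count`` defaults to 1 per row before merging.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyRepertoireError(f"{path}: file has no header or content")
    if "junction_aa" not in table.columns:
        raise FormatError(f"{path}: missing mandatory column 'junction_aa'")
    if len(table) == 0:
        raise EmptyRepertoireError(f"{path}: no data rows")

    clones = []
    for row in table.itertuples(index=False):
        cdr3_aa = _clean(getattr(row, "junction_aa", None))
        if cdr3_aa is None:
            raise FormatError(f"{path}: empty junction_aa value")
        raw_count = _clean(getattr(row, "duplicate_count", None))
        if raw_count is None:
            count = 1
        else:
            try:
                count = int(float(raw_count))
            except ValueError:
                raise FormatError(f"{path}: non-numeric duplicate_count {raw_count!r}")
            if count <= 0:
                count = 1
        clones.append(
            Clone(
                cdr3_aa=cdr3_aa,
                count=count,
                cdr3_nt=_clean(getattr(row, "junction", None)),
                v_call=_clean(getattr(row, "v_call", None)),
                j_call=_clean(getattr(row, "j_call", None)),
            )
        )

    mode = "nt" if all(c.cdr3_nt is not None for c in clones) else "aa"
    return Repertoire(
        sample_id=sample_id or os.path.splitext(os.path.basename(str(path)))[0],
        clones=merge_clones(clones, mode),
        patient_id=patient_id,
        chain=chain,
        timepoint=timepoint,
    )


def write_airr(rep: Repertoire, path) -> None:
    """Write a repertoire as AIRR Rearrangement TSV (one row per clone)."""
    rows = [
        {
            "sequence_id": f"{rep.sample_id}_{i}",
            "junction_aa": c.cdr3_aa,
            "junction": c.cdr3_nt or "",
            "v_call": c.v_call or "",
            "j_call": c.j_call or "",
            "duplicate_count": c.count,
        }
        for i, c in enumerate(rep.clones)
    ]
    table = pd.DataFrame(rows, columns=list(AIRR_COLUMNS))
    table.to_csv(path, sep="\t", index=False)


def read_decombinator(
    path,
    *,
    sample_id: Optional[str] = None,
    patient_id: str = "",
    chain: str = "alpha",
    timepoint: str = "other",
) -> Repertoire:
    """Read a Decombinator-style frequency CSV into a :class:`Repertoire`.

    Expected line layout: ``v_index, j_index, v_deletions, j_deletions,
    insert, count, cdr3_aa``.  Only the classifier V/J indices, the abundance
    and the CDR3 amino-acid string are retained.
    """
    clones = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            if len(fields) < 7:
                raise FormatError(
                    f"{path}: line {lineno}: expected 7 comma-separated fields, got {len(fields)}"
                )
            raw_count = fields[5]
            try:
                count = int(raw_count)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: abundance field {raw_count!r} is not an integer"
                )
            clones.append(
                Clone(
                    cdr3_aa=fields[6],
                    count=count,
                    v_call=fields[0],
                    j_call=fields[1],
                )
            )
    if not clones:
        raise EmptyRepertoireError(f"{path}: no data lines")
    return Repertoire(
        sample_id=sample_id or os.path.splitext(os.path.basename(str(path)))[0],
        clones=merge_clones(clones, "aa"),
        patient_id=patient_id,
        chain=chain,
        timepoint=timepoint,
    )


def read_repertoire(path, dialect: str = "airr", **metadata) -> Repertoire:
    """Dispatch on dialect name ('airr' or 'decombinator')."""
    if dialect == "airr":
        return read_airr(path, **metadata)
    if dialect == "decombinator":
        return read_decombinator(path, **metadata)
    raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest (TSV: sample_id, patient_id, chain, timepoint, path)."""
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ManifestError(f"{path}: empty manifest")
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestError(f"{path}: manifest missing columns {missing}")
    if len(table) == 0:
        raise ManifestError(f"{path}: manifest has no samples")
    return table
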