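"""Reading and writing variant-evidence tables, FASTA, and reports.

Variant tables are delimited text (tab-separated by default, comma
accepted) with a header row; ``.`` marks a missing value and evidence-code
lists are semicolon-joined.  Required columns: ``variant_id`` plus at
least one of ``mave_code`` / ``functional_class``.  Recognised optional
columns: ``gene``, ``prior``, ``baseline_codes``, ``is_vus``,
``single_substitution``.  Anything else is preserved in each record's
``annotations``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .scoring import InfoResult, VariantEvidenceRecord

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "read_protein_fasta",
    "write_report_json",
    "write_per_variant_tsv",
    "VariantTableError",
]

logger = logging.getLogger(__name__)

MISSING = "."
_KNOWN_COLUMNS = {
    "variant_id",
    "gene",
    "prior",
    "baseline_codes",
    "mave_code",
    "functional_class",
    "is_vus",
    "single_substitution",
}
_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


class VariantTableError(ValueError):
    """Malformed variant table (missing columns or bad row values)."""


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or (
        isinstance(value, str) and value.strip() in ("", MISSING)
    )


def _parse_bool(value, column: str, line: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise VariantTableError(
        f"line {line}: column {column!r} has non-boolean value {value!r}"
    )


def read_variant_table(path) -> list[VariantEvidenceRecord]:
    """Read a TSV/CSV variant-evidence table into validated records.

    Row-level failures are reported with 1-based file line numbers
    (header = line 1).  The delimiter is sniffed from the header line.
    """
    path = Path(path)
    with open(path) as handle:
        header = handle.readline()
    if not header.strip():
        raise VariantTableError(f"{path}: empty file")
    sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    columns = list(frame.columns)
    if "variant_id" not in columns:
        raise VariantTableError(f"{path}: missing required column 'variant_id'")
    if "mave_code" not in columns and "functional_class" not in columns:
        raise VariantTableError(
            f"{path}: need at least one of 'mave_code' / 'functional_class'"
        )
    extra = [c for c in columns if c not in _KNOWN_COLUMNS]

    records: list[VariantEvidenceRecord] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            records.append(_row_to_record(row, columns, extra, line))
        except (VariantTableError, ValueError) as exc:
            errors.append(str(exc))
    if errors:
        raise VariantTableError(
            f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors)
        )
    logger.info("read %d variant records from %s", len(records), path)
    return records


def _row_to_record(row, columns, extra, line) -> VariantEvidenceRecord:
    get = lambda col: row[col] if col in columns else None
    variant_id = str(get("variant_id")).strip()
    if not variant_id or variant_id == MISSING:
        raise VariantTableError(f"line {line}: empty variant_id")

    prior = 0.1
    if not _is_missing(get("prior")):
        try:
            prior = float(get("prior"))
        except ValueError:
            raise VariantTableError(
                f"line {line}: malformed prior {get('prior')!r}"
            ) from None
        if not 0.0 <= prior <= 1.0:
            raise VariantTableError(
                f"line {line}: prior {prior} outside [0, 1]"
            )

    baseline: tuple[str, ...] = ()
    if not _is_missing(get("baseline_codes")):
        baseline = tuple(
            c.strip() for c in str(get("baseline_codes")).split(";") if c.strip()
        )

    mave_code = None if _is_missing(get("mave_code")) else str(get("mave_code")).strip()
    fclass = (
        None
        if _is_missing(get("functional_class"))
        else str(get("functional_class")).strip()
    )
    if mave_code is None and fclass is None:
        raise VariantTableError(
            f"line {line}: neither mave_code nor functional_class given"
        )

    is_vus = None
    if not _is_missing(get("is_vus")):
        is_vus = _parse_bool(get("is_vus"), "is_vus", line)
    single = True
    if not _is_missing(get("single_substitution")):
        single = _parse_bool(get("single_substitution"), "single_substitution", line)

    annotations = {c: row[c] for c in extra if not _is_missing(row[c])}
    try:
        return VariantEvidenceRecord(
            variant_id=variant_id,
            gene="" if _is_missing(get("gene")) else str(get("gene")).strip(),
            prior=prior,
            baseline_codes=baseline,
            mave_code=mave_code,
            functional_class=fclass,
            is_vus=is_vus,
            single_substitution=single,
            annotations=annotations,
        )
    except ValueError as exc:
        raise VariantTableError(f"line {line}: {exc}") from None


def write_variant_table(records: Sequence[VariantEvidenceRecord], path) -> None:
    """Write records as the canonical tab-separated table (``.`` = missing)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "variant_id": rec.variant_id,
                "gene": rec.gene or MISSING,
                "prior": repr(rec.prior),
                "baseline_codes": ";".join(rec.baseline_codes) or MISSING,
                "mave_code": rec.mave_code if rec.mave_code is not None else MISSING,
                "functional_class": rec.functional_class
                if rec.functional_class is not None
                else MISSING,
                "is_vus": MISSING if rec.is_vus is None else str(rec.is_vus).lower(),
                "single_substitution": str(rec.single_substitution).lower(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_protein_fasta(path) -> list[tuple[str, str]]:
    """Read a protein FASTA into ``(id, sequence)`` pairs in file order.

    Sequences are uppercased with whitespace stripped.  Validation of the
    amino-acid alphabet is deferred to the gene-information layer, which
    owns the cleaning policy.
    """
    path = Path(path)
    records = [
        (rec.id, str(rec.seq).upper().strip()) for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_report_json(report, path_or_handle=None) -> str:
    """Serialise any object exposing ``to_dict`` (or a dict) to JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path_or_handle is None:
        return text
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text + "\n")
    else:
        Path(path_or_handle).write_text(text + "\n")
    return text


def write_per_variant_tsv(results: Sequence[InfoResult], path) -> None:
    """Write per-variant information results as a TSV table."""
    frame = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "posterior_before": [r.posterior_before for r in results],
            "posterior_after": [r.posterior_after for r in results],
            "info_before": [r.info_before for r in results],
            "info_after": [r.info_after for r in results],
            "delta_bits": [r.delta_bits for r in results],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
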