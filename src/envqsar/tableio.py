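"""CSV table plumbing: compound tables, reference datasets, run manifests.

Tables are RFC-4180 CSV with a header row, UTF-8, one compound per row:
``id, name, family, smiles`` then descriptor columns by their recognised
names. Numeric round-trips are lossless (shortest-repr float formatting).
Typographic minus signs and dashes that leak in from documents are
normalised to ASCII hyphen-minus on read.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

from .core import (
    CompoundRecord,
    DescriptorVector,
    EnvQsarError,
    RECOGNIZED_DESCRIPTORS,
    ReferenceDataset,
)

__all__ = [
    "read_table",
    "write_table",
    "read_reference_csv",
    "write_reference_csv",
    "write_manifest",
]

_META_COLS = ("id", "name", "family", "smiles")
# U+2212 minus, U+2013 en-dash, U+2014 em-dash → ASCII hyphen-minus
_DASH_TABLE = str.maketrans({"−": "-", "–": "-", "—": "-"})


def _parse_number(raw: str, row: int, column: str) -> float:
    text = raw.translate(_DASH_TABLE).strip()
    try:
        return float(text)
    except ValueError:
        raise EnvQsarError(
            f"malformed number {raw!r} in column {column!r}, row {row}"
        ) from None


def _format(value) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_table(path: str | Path, extra_columns: Sequence[str] = ()) -> list[CompoundRecord]:
    """Read a compound table CSV into records.

    Unknown descriptor columns raise a warning but are carried in the
    descriptor map as opaque extras; empty cells mean "descriptor absent".
    ``extra_columns`` names columns to ignore entirely (e.g. response/split
    columns handled elsewhere).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    records: list[CompoundRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise EnvQsarError(f"{path}: missing header row with an 'id' column")
        skip = set(_META_COLS) | set(extra_columns)
        unknown = [
            c
            for c in reader.fieldnames
            if c not in skip and c not in RECOGNIZED_DESCRIPTORS
        ]
        if unknown:
            warnings.warn(
                f"{path.name}: unrecognized descriptor column(s) carried as-is: "
                f"{unknown}",
                stacklevel=2,
            )
        for rownum, row in enumerate(reader, start=2):
            desc = DescriptorVector()
            for col, raw in row.items():
                if col in skip or raw is None or raw.strip() == "":
                    continue
                desc[col] = _parse_number(raw, rownum, col)
            records.append(
                CompoundRecord(
                    id=row["id"],
                    name=row.get("name", "") or "",
                    family=row.get("family", "") or "other",
                    smiles=row.get("smiles") or None,
                    descriptors=desc,
                )
            )
    return records


def write_table(
    records: Iterable[CompoundRecord],
    path: str | Path,
    extra: dict[str, dict[str, object]] | None = None,
) -> None:
    """Write records to CSV; ``extra`` maps column name → {id: value} for
    appended columns (predictions, classes, splits...)."""
    records = list(records)
    extra = extra or {}
    desc_cols = sorted({name for r in records for name in r.descriptors})
    fieldnames = list(_META_COLS) + desc_cols + list(extra)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(fieldnames)
        for r in records:
            row = [r.id, r.name, r.family, r.smiles or ""]
            row += [
                _format(r.descriptors[c]) if c in r.descriptors else ""
                for c in desc_cols
            ]
            row += [
                _format(extra[col][r.id]) if r.id in extra[col] else ""
                for col in extra
            ]
            writer.writerow(row)


def write_reference_csv(dataset: ReferenceDataset, path: str | Path) -> None:
    """Serialise a reference dataset (descriptors + response + split)."""
    write_table(
        dataset.compounds,
        path,
        extra={"response": dict(dataset.response), "split": dict(dataset.split)},
    )


def read_reference_csv(path: str | Path, property: str) -> ReferenceDataset:
    """Read a reference dataset CSV written by :func:`write_reference_csv`."""
    path = Path(path)
    records = read_table(path, extra_columns=("response", "split"))
    response: dict[str, float] = {}
    split: dict[str, str] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for rownum, row in enumerate(csv.DictReader(fh), start=2):
            if "response" not in row or "split" not in row:
                raise EnvQsarError(f"{path}: needs 'response' and 'split' columns")
            response[row["id"]] = _parse_number(row["response"], rownum, "response")
            split[row["id"]] = row["split"].strip()
    return ReferenceDataset(
        compounds=records, response=response, split=split, property=property
    )


def read_columns(path: str | Path, columns: Sequence[str]) -> dict[str, dict[str, float]]:
    """Read selected numeric columns keyed by compound id (absent cells skipped)."""
    out: dict[str, dict[str, float]] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for rownum, row in enumerate(csv.DictReader(fh), start=2):
            for col in columns:
                raw = row.get(col)
                if raw is not None and raw.strip() != "":
                    out.setdefault(col, {})[row["id"]] = _parse_number(raw, rownum, col)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    command: str,
    config: dict,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write a run manifest (command, config incl. seeds, input hashes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str), encoding="utf-8")
    return path
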