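"""Read, write and validate the three input tables (CSV or JSON Lines).

Timestamps are ISO-8601 at minute resolution ("YYYY-MM-DDTHH:MM"): the
platform exposes minute-level repost times and the speed metric needs a
declared resolution. Rows violating a type invariant are rejected with a
row-level diagnostic and counted, never silently dropped:
``accepted + rejected == input rows`` always holds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ValidationError

from .models import Dataset, Post, RepostRecord, User

log = logging.getLogger(__name__)

TIMESTAMP_FMT = "%Y-%m-%dT%H:%M"

TABLES = {
    "posts": (Post, "post_id"),
    "users": (User, "user_id"),
    "reposts": (RepostRecord, "repost_id"),
}

_REQUIRED = {
    "posts": ("post_id", "author_id", "timestamp"),
    "users": ("user_id",),
    "reposts": ("repost_id", "root_post_id", "reposter_id", "timestamp"),
}

_OPTIONAL_STR = {"topic", "sentiment", "parent_repost_id"}


class SchemaError(ValueError):
    """A table is structurally unusable: missing column or duplicate id."""


@dataclass
class RowDiagnostic:
    table: str
    row: int
    message: str


@dataclass
class ReadReport:
    """Accounting of row acceptance per table."""

    accepted: dict[str, int] = field(default_factory=dict)
    rejected: list[RowDiagnostic] = field(default_factory=list)

    def rejected_count(self, table: str | None = None) -> int:
        return sum(1 for d in self.rejected if table is None or d.table == table)


def _fmt_ts(value) -> str:
    return pd.Timestamp(value).strftime(TIMESTAMP_FMT)


def _record_to_row(rec: BaseModel) -> dict:
    row = rec.model_dump()
    if "timestamp" in row:
        row["timestamp"] = _fmt_ts(row["timestamp"])
    for k, v in row.items():
        if v is None:
            row[k] = ""
        elif isinstance(v, bool):
            row[k] = "true" if v else "false"
    return row


_FREE_TEXT = {"text", "chain_text"}


def _clean_raw(raw: dict) -> dict:
    """Map empty/None optional cells to absent fields before validation.

    Free-text fields pass through verbatim (chain texts may carry
    significant leading/trailing whitespace); all other fields are
    stripped before type coercion.
    """
    out = {}
    for k, v in raw.items():
        if v is None:
            continue
        if isinstance(v, float) and pd.isna(v):
            continue
        if isinstance(v, str) and k not in _FREE_TEXT:
            v = v.strip()
            if v == "":
                continue
            if k == "verified":
                v = v.lower() in ("true", "1", "yes")
        out[k] = v
    return out


def _load_rows(path: Path, fmt: str) -> list[dict]:
    if fmt == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        return rows
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame.to_dict(orient="records")


def _columns_of(rows: list[dict], path: Path, fmt: str) -> set[str]:
    if fmt == "csv":
        header = pd.read_csv(path, dtype=str, nrows=0)
        return set(header.columns)
    cols: set[str] = set()
    for r in rows:
        cols |= set(r)
    return cols


def read_table(
    path: str | Path, table: str, fmt: str = "csv", report: ReadReport | None = None
) -> list[BaseModel]:
    """Read and validate one table; invalid rows are rejected with diagnostics."""
    model, key = TABLES[table]
    path = Path(path)
    rows = _load_rows(path, fmt)
    if rows or fmt == "csv":
        cols = _columns_of(rows, path, fmt)
        missing = [c for c in _REQUIRED[table] if c not in cols]
        if missing:
            raise SchemaError(f"{table}: missing required column(s) {missing}")
    report = report if report is not None else ReadReport()
    records: list[BaseModel] = []
    seen_ids: set[str] = set()
    for i, raw in enumerate(rows):
        try:
            rec = model.model_validate(_clean_raw(raw))
        except ValidationError as exc:
            first = exc.errors()[0]
            loc = ".".join(str(p) for p in first["loc"]) or table
            report.rejected.append(
                RowDiagnostic(table, i, f"{loc}: {first['msg']}")
            )
            continue
        rid = getattr(rec, key)
        if rid in seen_ids:
            raise SchemaError(f"{table}: duplicate {key} {rid!r} at row {i}")
        seen_ids.add(rid)
        records.append(rec)
    report.accepted[table] = len(records)
    if report.rejected_count(table):
        log.warning(
            "%s: rejected %d of %d rows", table, report.rejected_count(table), len(rows)
        )
    return records


def read_dataset(
    posts_path: str | Path,
    users_path: str | Path,
    reposts_path: str | Path,
    fmt: str = "csv",
) -> tuple[Dataset, ReadReport]:
    """Read the three tables into a validated :class:`Dataset`.

    Reposts whose ``root_post_id`` matches no post are rejected (the tree
    they belong to cannot be built); author/reposter ids with no user row
    are flagged in ``Dataset.missing_users``, mirroring blocked accounts.
    """
    report = ReadReport()
    posts = read_table(posts_path, "posts", fmt, report)
    users = read_table(users_path, "users", fmt, report)
    reposts = read_table(reposts_path, "reposts", fmt, report)

    post_ids = {p.post_id for p in posts}
    kept = []
    for j, r in enumerate(reposts):
        if r.root_post_id not in post_ids:
            report.rejected.append(
                RowDiagnostic(
                    "reposts", j, f"root_post_id: unknown post {r.root_post_id!r}"
                )
            )
        else:
            kept.append(r)
    report.accepted["reposts"] = len(kept)

    ds = Dataset(posts=posts, users=users, reposts=kept)
    ds.flag_missing_users()
    if ds.missing_users:
        log.info("flagged %d missing user references", len(ds.missing_users))
    return ds, report


def write_dataset(d: Dataset, out_dir: str | Path, fmt: str = "csv") -> dict[str, Path]:
    """Write the three tables; read(write(d)) is the identity on all fields."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collections = {"posts": d.posts, "users": d.users, "reposts": d.reposts}
    manifest: dict[str, Path] = {}
    for table, records in collections.items():
        model, _ = TABLES[table]
        path = out_dir / f"{table}.{fmt}"
        rows = [_record_to_row(r) for r in records]
        if fmt == "jsonl":
            with open(path, "w", encoding="utf-8") as fh:
                for row in rows:
                    fh.write(json.dumps(row, ensure_ascii=False) + "\n")
        else:
            cols = list(model.model_fields)
            pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        manifest[table] = path
    return manifest
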