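"""Relational catalog for fused multi-study brain-MRI collections.

The catalog is a single-file SQLite store holding ten entity tables
(source dataset, condition, source-condition map, subject, visit, scanner,
image, preprocess task, file type, preprocess file) plus two auxiliary
tables (per-visit clinical scores, QC results).  Foreign-key enforcement
is always on; every insert goes through :func:`record_entity`, which
pre-resolves foreign keys so violations are reported by name.

The store is addressed by URI (a plain path, ``sqlite:///path`` or
``:memory:``) so a server-based engine could be swapped in behind the
same surface.
"""

from __future__ import annotations

import csv
import os
import sqlite3
from contextlib import contextmanager
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

__all__ = [
    "CatalogError",
    "IntegrityError",
    "DuplicateError",
    "UnknownFilterError",
    "SourceDatasetRecord",
    "ConditionRecord",
    "SourceConditionMap",
    "SubjectRecord",
    "VisitRecord",
    "ScannerRecord",
    "ImageRecord",
    "PreprocessTaskRecord",
    "FileTypeRecord",
    "PreprocessFileRecord",
    "CatalogHandle",
    "init_catalog",
    "open_catalog",
    "record_entity",
    "query_images",
    "summarize_catalog",
]


class CatalogError(RuntimeError):
    """Base class for catalog failures."""


class IntegrityError(CatalogError):
    """A foreign key does not resolve."""


class DuplicateError(CatalogError):
    """A uniqueness constraint would be violated."""


class UnknownFilterError(CatalogError):
    """query_images received a filter key outside the allowed set."""


# ---------------------------------------------------------------------------
# Entity records


@dataclass
class SourceDatasetRecord:
    name: str
    id: int | None = None


@dataclass
class ConditionRecord:
    name: str
    id: int | None = None


@dataclass
class SourceConditionMap:
    source_dataset_id: int
    source_label: str
    condition_id: int
    id: int | None = None


@dataclass
class SubjectRecord:
    source_dataset_id: int
    source_subject_code: str
    sex: str | None = None
    handedness: str | None = None
    age_at_baseline: float | None = None
    education_years: float | None = None
    baseline_condition_id: int | None = None
    id: int | None = None


@dataclass
class VisitRecord:
    subject_id: int
    source_dataset_id: int
    days_since_baseline: int
    condition_id: int | None = None
    bmi: float | None = None
    is_synthesized: bool = False
    clinical_scores: dict[str, float] = field(default_factory=dict)
    id: int | None = None


@dataclass
class ScannerRecord:
    source_dataset_id: int
    brand: str
    model: str
    field_strength: float
    id: int | None = None


@dataclass
class ImageRecord:
    visit_id: int
    subject_id: int
    scanner_id: int
    source_dataset_id: int
    file_path: str
    days_since_baseline: int
    modality: str = "T1w"
    preprocessing_status: str = "none"
    file_size: int | None = None
    metadata_path: str | None = None
    id: int | None = None


@dataclass
class PreprocessTaskRecord:
    description: str
    id: int | None = None


@dataclass
class FileTypeRecord:
    name: str
    id: int | None = None


@dataclass
class PreprocessFileRecord:
    image_id: int
    task_id: int
    file_type_id: int
    path: str
    id: int | None = None


# table name, unique tuple, and foreign keys (column -> referenced table)
_ENTITY_META: dict[type, dict[str, Any]] = {
    SourceDatasetRecord: {
        "table": "source_dataset",
        "unique": ("name",),
        "fks": {},
    },
    ConditionRecord: {
        "table": "condition",
        "unique": ("name",),
        "fks": {},
    },
    SourceConditionMap: {
        "table": "source_condition_map",
        "unique": ("source_dataset_id", "source_label"),
        "fks": {"source_dataset_id": "source_dataset", "condition_id": "condition"},
    },
    SubjectRecord: {
        "table": "subject",
        "unique": ("source_dataset_id", "source_subject_code"),
        "fks": {
            "source_dataset_id": "source_dataset",
            "baseline_condition_id": "condition",
        },
    },
    VisitRecord: {
        "table": "visit",
        "unique": ("subject_id", "days_since_baseline"),
        "fks": {
            "subject_id": "subject",
            "source_dataset_id": "source_dataset",
            "condition_id": "condition",
        },
        "skip": ("clinical_scores",),
    },
    ScannerRecord: {
        "table": "scanner",
        "unique": ("source_dataset_id", "brand", "model", "field_strength"),
        "fks": {"source_dataset_id": "source_dataset"},
    },
    ImageRecord: {
        "table": "image",
        "unique": (),
        "fks": {
            "visit_id": "visit",
            "subject_id": "subject",
            "scanner_id": "scanner",
            "source_dataset_id": "source_dataset",
        },
    },
    PreprocessTaskRecord: {
        "table": "preprocess_task",
        "unique": ("description",),
        "fks": {},
    },
    FileTypeRecord: {
        "table": "file_type",
        "unique": ("name",),
        "fks": {},
    },
    PreprocessFileRecord: {
        "table": "preprocess_file",
        "unique": ("image_id", "task_id", "file_type_id"),
        "fks": {
            "image_id": "image",
            "task_id": "preprocess_task",
            "file_type_id": "file_type",
        },
    },
}

ENTITY_TABLES = tuple(meta["table"] for meta in _ENTITY_META.values())

_SCHEMA = """
CREATE TABLE source_dataset (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE CHECK (length(name) > 0)
);
CREATE TABLE condition (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE CHECK (length(name) > 0)
);
CREATE TABLE source_condition_map (
    id INTEGER PRIMARY KEY,
    source_dataset_id INTEGER NOT NULL REFERENCES source_dataset(id),
    source_label TEXT NOT NULL,
    condition_id INTEGER NOT NULL REFERENCES condition(id),
    UNIQUE (source_dataset_id, source_label)
);
CREATE TABLE subject (
    id INTEGER PRIMARY KEY,
    source_dataset_id INTEGER NOT NULL REFERENCES source_dataset(id),
    source_subject_code TEXT NOT NULL,
    sex TEXT,
    handedness TEXT,
    age_at_baseline REAL CHECK (age_at_baseline IS NULL
                                OR (age_at_baseline >= 0 AND age_at_baseline <= 130)),
    education_years REAL CHECK (education_years IS NULL OR education_years >= 0),
    baseline_condition_id INTEGER REFERENCES condition(id),
    UNIQUE (source_dataset_id, source_subject_code)
);
CREATE TABLE visit (
    id INTEGER PRIMARY KEY,
    subject_id INTEGER NOT NULL REFERENCES subject(id),
    source_dataset_id INTEGER NOT NULL REFERENCES source_dataset(id),
    days_since_baseline INTEGER NOT NULL CHECK (days_since_baseline >= 0),
    condition_id INTEGER REFERENCES condition(id),
    bmi REAL,
    is_synthesized INTEGER NOT NULL DEFAULT 0,
    UNIQUE (subject_id, days_since_baseline)
);
CREATE TABLE visit_score (
    id INTEGER PRIMARY KEY,
    visit_id INTEGER NOT NULL REFERENCES visit(id),
    score_name TEXT NOT NULL,
    value REAL,
    UNIQUE (visit_id, score_name)
);
CREATE TABLE scanner (
    id INTEGER PRIMARY KEY,
    source_dataset_id INTEGER NOT NULL REFERENCES source_dataset(id),
    brand TEXT NOT NULL,
    model TEXT NOT NULL,
    field_strength REAL NOT NULL CHECK (field_strength > 0),
    UNIQUE (source_dataset_id, brand, model, field_strength)
);
CREATE TABLE image (
    id INTEGER PRIMARY KEY,
    visit_id INTEGER NOT NULL REFERENCES visit(id),
    subject_id INTEGER NOT NULL REFERENCES subject(id),
    scanner_id INTEGER NOT NULL REFERENCES scanner(id),
    source_dataset_id INTEGER NOT NULL REFERENCES source_dataset(id),
    modality TEXT NOT NULL DEFAULT 'T1w',
    preprocessing_status TEXT NOT NULL DEFAULT 'none'
        CHECK (preprocessing_status IN ('none', 'affine', 'nonlinear')),
    file_path TEXT NOT NULL,
    file_size INTEGER,
    days_since_baseline INTEGER NOT NULL CHECK (days_since_baseline >= 0),
    metadata_path TEXT
);
CREATE TABLE preprocess_task (
    id INTEGER PRIMARY KEY,
    description TEXT NOT NULL UNIQUE
);
CREATE TABLE file_type (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE preprocess_file (
    id INTEGER PRIMARY KEY,
    image_id INTEGER NOT NULL REFERENCES image(id),
    task_id INTEGER NOT NULL REFERENCES preprocess_task(id),
    file_type_id INTEGER NOT NULL REFERENCES file_type(id),
    path TEXT NOT NULL,
    UNIQUE (image_id, task_id, file_type_id)
);
CREATE TABLE qc_result (
    id INTEGER PRIMARY KEY,
    image_id INTEGER NOT NULL REFERENCES image(id),
    task_id INTEGER NOT NULL REFERENCES preprocess_task(id),
    r REAL,
    threshold REAL NOT NULL,
    passed INTEGER NOT NULL,
    n_voxels INTEGER,
    UNIQUE (image_id, task_id)
);
"""

PREPROCESS_TASKS = ("affine", "nonlinear")
FILE_TYPES = (
    "registered_image",
    "brain_mask",
    "affine_matrix",
    "nonlinear_warp",
    "bias_field",
)


def _resolve_uri(store_uri: str | os.PathLike) -> str:
    uri = str(store_uri)
    if uri.startswith("sqlite:///"):
        uri = uri[len("sqlite:///") :]
    return uri


class CatalogHandle:
    """Open connection to a catalog store.

    Use :func:`init_catalog` to create a new store and
    :func:`open_catalog` to connect to an existing one.
    """

    def __init__(self, store_uri: str | os.PathLike, _create: bool = False):
        self.store_uri = str(store_uri)
        path = _resolve_uri(store_uri)
        if not _create and path != ":memory:" and not Path(path).exists():
            raise CatalogError(f"catalog store not found: {path}")
        self._conn = sqlite3.connect(path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.row_factory = sqlite3.Row
        self.opened = True
        self._autocommit = True

    # -- lifecycle ----------------------------------------------------------

    def close(self) -> None:
        self._conn.close()
        self.opened = False

    def __enter__(self) -> "CatalogHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def connection(self) -> sqlite3.Connection:
        return self._conn

    @contextmanager
    def transaction(self):
        """All-or-nothing write scope: commit on exit, roll back on error."""
        prior = self._autocommit
        self._autocommit = False
        try:
            yield self
            self._conn.commit()
        except BaseException:
            self._conn.rollback()
            raise
        finally:
            self._autocommit = prior

    # -- generic row access -------------------------------------------------

    def tables(self) -> list[str]:
        rows = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
        ).fetchall()
        return [r["name"] for r in rows]

    def fetch(self, table: str, key: int) -> dict[str, Any] | None:
        if table not in self.tables():
            raise CatalogError(f"no such table: {table}")
        row = self._conn.execute(f"SELECT * FROM {table} WHERE id=?", (key,)).fetchone()
        return dict(row) if row else None

    def count(self, table: str) -> int:
        return self._conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    def lookup_id(self, table: str, **where: Any) -> int | None:
        keys = sorted(where)
        clause = " AND ".join(f"{k}=?" for k in keys)
        row = self._conn.execute(
            f"SELECT id FROM {table} WHERE {clause}", [where[k] for k in keys]
        ).fetchone()
        return row["id"] if row else None

    # -- writes -------------------------------------------------------------

    def record(self, rec: Any) -> int:
        """Insert one entity record; returns the assigned key."""
        meta = _ENTITY_META.get(type(rec))
        if meta is None:
            raise CatalogError(f"not an entity record: {type(rec).__name__}")
        table = meta["table"]
        skip = set(meta.get("skip", ())) | {"id"}
        cur = self._conn.cursor()
        # resolve foreign keys up-front so errors name the missing entity
        for col, ref in meta["fks"].items():
            val = getattr(rec, col)
            if val is None:
                continue
            hit = cur.execute(f"SELECT 1 FROM {ref} WHERE id=?", (val,)).fetchone()
            if hit is None:
                raise IntegrityError(
                    f"{table}.{col}={val} does not resolve: no {ref} with that id"
                )
        cols = [f.name for f in dc_fields(rec) if f.name not in skip]
        vals = []
        for c in cols:
            v = getattr(rec, c)
            if isinstance(v, bool):
                v = int(v)
            vals.append(v)
        try:
            cur.execute(
                f"INSERT INTO {table} ({', '.join(cols)}) "
                f"VALUES ({', '.join('?' * len(cols))})",
                vals,
            )
        except sqlite3.IntegrityError as e:
            msg = str(e)
            if "UNIQUE" in msg:
                uniq = meta["unique"]
                tup = tuple(getattr(rec, c) for c in uniq) if uniq else ()
                raise DuplicateError(f"duplicate {table} row for {uniq}={tup}") from e
            raise IntegrityError(f"integrity violation inserting into {table}: {msg}") from e
        key = cur.lastrowid
        if isinstance(rec, VisitRecord):
            for name, value in rec.clinical_scores.items():
                cur.execute(
                    "INSERT INTO visit_score (visit_id, score_name, value) VALUES (?,?,?)",
                    (key, name, float(value)),
                )
        if self._autocommit:
            self._conn.commit()
        rec.id = key
        return key

    def delete_study(self, study_name: str) -> None:
        """Remove a source dataset and every row that references it."""
        sid = self.lookup_id("source_dataset", name=study_name)
        if sid is None:
            raise CatalogError(f"no such study: {study_name}")
        cur = self._conn.cursor()
        cur.execute(
            "DELETE FROM qc_result WHERE image_id IN "
            "(SELECT id FROM image WHERE source_dataset_id=?)",
            (sid,),
        )
        cur.execute(
            "DELETE FROM preprocess_file WHERE image_id IN "
            "(SELECT id FROM image WHERE source_dataset_id=?)",
            (sid,),
        )
        cur.execute("DELETE FROM image WHERE source_dataset_id=?", (sid,))
        cur.execute(
            "DELETE FROM visit_score WHERE visit_id IN "
            "(SELECT id FROM visit WHERE source_dataset_id=?)",
            (sid,),
        )
        cur.execute("DELETE FROM visit WHERE source_dataset_id=?", (sid,))
        cur.execute("DELETE FROM subject WHERE source_dataset_id=?", (sid,))
        cur.execute("DELETE FROM scanner WHERE source_dataset_id=?", (sid,))
        cur.execute("DELETE FROM source_condition_map WHERE source_dataset_id=?", (sid,))
        cur.execute("DELETE FROM source_dataset WHERE id=?", (sid,))
        self._conn.commit()

    # -- queries ------------------------------------------------------------

    QUERY_FILTER_KEYS = (
        "source_dataset",
        "condition",
        "sex",
        "age_min",
        "age_max",
        "scanner_brand",
        "scanner_model",
        "field_strength",
        "modality",
        "preprocessing_status",
        "qc_min_r",
    )

    def query_images(self, filters: Mapping[str, Any] | None = None) -> list[dict[str, Any]]:
        """Joined image rows (image ⨝ visit ⨝ subject ⨝ scanner ⨝ study).

        ``filters`` maps keys from :attr:`QUERY_FILTER_KEYS` to values; an
        empty or absent map returns every image, ordered by image id.
        """
        filters = dict(filters or {})
        unknown = set(filters) - set(self.QUERY_FILTER_KEYS)
        if unknown:
            raise UnknownFilterError(
                f"unknown filter key(s) {sorted(unknown)}; "
                f"valid keys: {list(self.QUERY_FILTER_KEYS)}"
            )
        sql = """
            SELECT i.id AS image_id, i.file_path, i.modality,
                   i.preprocessing_status, i.days_since_baseline AS image_day,
                   v.id AS visit_id, v.days_since_baseline AS visit_day,
                   v.is_synthesized, v.bmi,
                   c.name AS condition,
                   s.id AS subject_id, s.source_subject_code, s.sex, s.handedness,
                   s.age_at_baseline, s.education_years,
                   sc.brand AS scanner_brand, sc.model AS scanner_model,
                   sc.field_strength,
                   sd.name AS source_dataset,
                   q.r AS qc_r
            FROM image i
            JOIN visit v ON v.id = i.visit_id
            JOIN subject s ON s.id = i.subject_id
            JOIN scanner sc ON sc.id = i.scanner_id
            JOIN source_dataset sd ON sd.id = i.source_dataset_id
            LEFT JOIN condition c ON c.id = v.condition_id
            LEFT JOIN qc_result q ON q.image_id = i.id
        """
        clauses, params = [], []
        mapping = {
            "source_dataset": "sd.name = ?",
            "condition": "c.name = ?",
            "sex": "s.sex = ?",
            "age_min": "s.age_at_baseline >= ?",
            "age_max": "s.age_at_baseline <= ?",
            "scanner_brand": "sc.brand = ?",
            "scanner_model": "sc.model = ?",
            "field_strength": "sc.field_strength = ?",
            "modality": "i.modality = ?",
            "preprocessing_status": "i.preprocessing_status = ?",
            "qc_min_r": "q.r >= ?",
        }
        for key, val in filters.items():
            clauses.append(mapping[key])
            params.append(val)
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY i.id"
        return [dict(r) for r in self._conn.execute(sql, params).fetchall()]

    def summarize(self) -> list[dict[str, Any]]:
        """Per-study (subjects with ≥1 image, images) plus a Total row."""
        rows = self._conn.execute(
            """
            SELECT sd.name AS study,
                   COUNT(DISTINCT i.subject_id) AS subjects,
                   COUNT(i.id) AS images
            FROM source_dataset sd
            LEFT JOIN image i ON i.source_dataset_id = sd.id
            GROUP BY sd.id ORDER BY sd.name
            """
        ).fetchall()
        out = [dict(r) for r in rows]
        total_s = sum(r["subjects"] for r in out)
        total_i = sum(r["images"] for r in out)
        out.append({"study": "Total", "subjects": total_s, "images": total_i})
        return out

    def summarize_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["study", "subjects", "images"])
            for row in self.summarize():
                w.writerow([row["study"], row["subjects"], row["images"]])

    # -- integrity ----------------------------------------------------------

    def check_referential_closure(self) -> list[str]:
        """Full-scan FK audit; returns a list of violations (empty = clean)."""
        problems = []
        for meta in _ENTITY_META.values():
            table = meta["table"]
            for col, ref in meta["fks"].items():
                rows = self._conn.execute(
                    f"SELECT t.id FROM {table} t "
                    f"LEFT JOIN {ref} r ON r.id = t.{col} "
                    f"WHERE t.{col} IS NOT NULL AND r.id IS NULL"
                ).fetchall()
                for r in rows:
                    problems.append(f"{table}.id={r['id']}: dangling {col} -> {ref}")
        return problems

    def audit_files(self) -> list[str]:
        """Check every file path referenced by the catalog exists on disk."""
        missing = []
        for row in self._conn.execute("SELECT id, file_path FROM image"):
            if not Path(row["file_path"]).exists():
                missing.append(f"image.id={row['id']}: {row['file_path']}")
        for row in self._conn.execute("SELECT id, path FROM preprocess_file"):
            if not Path(row["path"]).exists():
                missing.append(f"preprocess_file.id={row['id']}: {row['path']}")
        return missing


def init_catalog(store_uri: str | os.PathLike) -> CatalogHandle:
    """Create a new catalog store with the full schema and seed rows.

    Refuses to touch an existing non-empty store: there is no silent
    migration path.
    """
    path = _resolve_uri(store_uri)
    if path != ":memory:":
        p = Path(path)
        if p.exists() and p.stat().st_size > 0:
            raise CatalogError(
                f"refusing to initialize: store already exists and is non-empty: {p}"
            )
        p.parent.mkdir(parents=True, exist_ok=True)
    cat = CatalogHandle(store_uri, _create=True)
    cat.connection.executescript(_SCHEMA)
    for desc in PREPROCESS_TASKS:
        cat.connection.execute(
            "INSERT INTO preprocess_task (description) VALUES (?)", (desc,)
        )
    for name in FILE_TYPES:
        cat.connection.execute("INSERT INTO file_type (name) VALUES (?)", (name,))
    cat.connection.commit()
    if path != ":memory:":
        Path(path).with_suffix(".schema.sql").write_text(_SCHEMA)
    return cat


def open_catalog(store_uri: str | os.PathLike) -> CatalogHandle:
    """Connect to an existing catalog store."""
    cat = CatalogHandle(store_uri)
    have = set(cat.tables())
    missing = set(ENTITY_TABLES) - have
    if missing:
        cat.close()
        raise CatalogError(f"store is missing entity tables: {sorted(missing)}")
    return cat


# thin module-level wrappers -------------------------------------------------


def record_entity(catalog: CatalogHandle, record: Any) -> int:
    return catalog.record(record)


def query_images(
    catalog: CatalogHandle, filters: Mapping[str, Any] | None = None
) -> list[dict[str, Any]]:
    return catalog.query_images(filters)


def summarize_catalog(catalog: CatalogHandle) -> list[dict[str, Any]]:
    return catalog.summarize()
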