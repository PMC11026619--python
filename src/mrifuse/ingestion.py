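"""Study ingestion: pluggable adapters plus the harmonization core.

Each source study is read by a :class:`StudyAdapter` that knows the
study's own file dialect and yields rows in a canonical key-value form;
the core then runs the three load phases strictly in order — subjects,
visits, images — matching every image to its closest *past* clinical
visit within a configurable gap (60 days by default), synthesizing visits
where the source has no visit structure, mapping study-specific condition
labels through the catalog's master list, and converting education
qualification codes to years.  Ingestion of a study is all-or-nothing.

Matching never looks forward in time: an image is never attached to a
visit that happened after it was acquired, so no information from future
clinical assessments can leak into prognostic models built on the
catalog.
"""

from __future__ import annotations

import bisect
import csv
import json
import os
from abc import ABC, abstractmethod
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Iterator, Sequence

from .catalog import (
    CatalogError,
    CatalogHandle,
    ConditionRecord,
    ImageRecord,
    ScannerRecord,
    SourceConditionMap,
    SourceDatasetRecord,
    SubjectRecord,
    VisitRecord,
)

__all__ = [
    "MatchRule",
    "MatchError",
    "IngestOrderError",
    "IngestError",
    "MappingError",
    "EducationMapping",
    "IngestReport",
    "StudyAdapter",
    "LongitudinalCSVAdapter",
    "CrossSectionalCSVAdapter",
    "StudyIngest",
    "ingest_study",
    "match_image_to_visit",
    "synthesize_visit",
    "map_condition",
    "education_to_years",
    "make_adapter",
]


class IngestError(CatalogError):
    pass


class IngestOrderError(IngestError):
    """Load phases were driven out of their mandatory order."""


class MatchError(ValueError):
    pass


class MappingError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Image-to-visit matching


@dataclass(frozen=True)
class MatchRule:
    """Closest-past visit matching with a maximum gap (days)."""

    max_gap_days: int = 60

    def __post_init__(self) -> None:
        if self.max_gap_days <= 0:
            raise ValueError("max_gap_days must be positive")


def match_image_to_visit(
    image_day: int, visit_days: Sequence[int], rule: MatchRule | None = None
) -> int | None:
    """Index of the closest past visit within the gap, else ``None``.

    ``visit_days`` must be strictly ascending.  A visit on the image's own
    day counts as past (gap 0); future visits are never matched.
    """
    rule = rule or MatchRule()
    days = list(visit_days)
    if any(b <= a for a, b in zip(days, days[1:])):
        raise MatchError("visit_days must be sorted ascending and distinct")
    pos = bisect.bisect_right(days, image_day) - 1
    if pos < 0:
        return None
    if image_day - days[pos] > rule.max_gap_days:
        return None
    return pos


def synthesize_visit(
    image_day: int,
    subject_id: int,
    source_dataset_id: int = 0,
    condition_id: int | None = None,
) -> VisitRecord:
    """A stand-in visit for an image with no clinical visit to attach to."""
    return VisitRecord(
        subject_id=subject_id,
        source_dataset_id=source_dataset_id,
        days_since_baseline=int(image_day),
        condition_id=condition_id,
        is_synthesized=True,
    )


# ---------------------------------------------------------------------------
# Vocabulary mappings


def map_condition(catalog: CatalogHandle, source_dataset_id: int, source_label: str) -> int:
    """Master-list condition key for a study's own diagnosis label."""
    row = catalog.connection.execute(
        "SELECT condition_id FROM source_condition_map "
        "WHERE source_dataset_id=? AND source_label=?",
        (source_dataset_id, source_label),
    ).fetchone()
    if row is None:
        name = catalog.connection.execute(
            "SELECT name FROM source_dataset WHERE id=?", (source_dataset_id,)
        ).fetchone()
        study = name["name"] if name else source_dataset_id
        raise MappingError(
            f"condition label {source_label!r} of study {study!r} is not in the "
            "source-condition map"
        )
    return row["condition_id"]


@dataclass
class EducationMapping:
    """Qualification code -> years of education (None = unknown)."""

    table: dict[str, float | None]

    @classmethod
    def from_csv(cls, path: str | Path) -> "EducationMapping":
        table: dict[str, float | None] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                val = row["years"].strip()
                table[row["code"]] = float(val) if val not in ("", "NA", "unknown") else None
        return cls(table)


def education_to_years(code: str, mapping: EducationMapping) -> float | None:
    if code not in mapping.table:
        raise MappingError(
            f"education code {code!r} not in mapping; known codes: "
            f"{sorted(mapping.table)}"
        )
    return mapping.table[code]


# ---------------------------------------------------------------------------
# Adapter contract


class StudyAdapter(ABC):
    """Reads one study's files and yields canonical key-value rows.

    Canonical keys: subjects — ``code, sex, handedness, age_at_baseline,
    education_code | education_years, condition``; visits —
    ``subject_code, day, condition, bmi, scores``; images —
    ``subject_code, day, path, modality, scanner{brand,model,
    field_strength}, condition, metadata_path``.  Days are integer offsets
    in the study's own origin; the core rebases them per subject so the
    earliest visit is day 0.  Calendar parsing, when a study uses dates,
    belongs inside the adapter.
    """

    study_name: str
    kind: str  # "longitudinal" | "cross_sectional"

    @abstractmethod
    def iter_subjects(self) -> Iterator[dict[str, Any]]: ...

    @abstractmethod
    def iter_visits(self) -> Iterator[dict[str, Any]]: ...

    @abstractmethod
    def iter_images(self) -> Iterator[dict[str, Any]]: ...

    @abstractmethod
    def condition_map(self) -> dict[str, str]:
        """source label -> master condition name."""

    def education_mapping(self) -> EducationMapping | None:
        return None

    @property
    def condition_vocabulary(self) -> list[str]:
        return sorted(self.condition_map())


class LongitudinalCSVAdapter(StudyAdapter):
    """Adapter for the longitudinal dialect: ``subjects.csv`` +
    ``visits.csv`` + per-image JSON sidecars under ``images/``."""

    kind = "longitudinal"

    def __init__(self, root: str | Path, study_name: str = "synthA"):
        self.root = Path(root)
        self.study_name = study_name

    def iter_subjects(self) -> Iterator[dict[str, Any]]:
        with open(self.root / "subjects.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                yield {
                    "code": row["participant"],
                    "sex": row["gender"] or None,
                    "handedness": row["hand_pref"] or None,
                    "age_at_baseline": float(row["age_at_entry"]) if row["age_at_entry"] else None,
                    "education_code": row["education_level"] or None,
                }

    def iter_visits(self) -> Iterator[dict[str, Any]]:
        with open(self.root / "visits.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                yield {
                    "subject_code": row["participant"],
                    "day": int(row["days_from_entry"]),
                    "condition": row["dx_code"] or None,
                    "bmi": float(row["bmi"]) if row["bmi"] else None,
                    "scores": {"cognitive_score": float(row["cognitive_score"])}
                    if row.get("cognitive_score")
                    else {},
                }

    def iter_images(self) -> Iterator[dict[str, Any]]:
        for sidecar in sorted((self.root / "images").glob("*.json")):
            meta = json.loads(sidecar.read_text())
            yield {
                "subject_code": meta["participant"],
                "day": int(meta["acq_day"]),
                "path": str(self.root / "images" / meta["image"]),
                "modality": meta.get("modality", "T1w"),
                "scanner": {
                    "brand": meta["scanner_brand"],
                    "model": meta["scanner_model"],
                    "field_strength": float(meta["field_T"]),
                },
                "metadata_path": str(sidecar),
            }

    def condition_map(self) -> dict[str, str]:
        return _read_condition_map(self.root / "condition_map.csv")

    def education_mapping(self) -> EducationMapping | None:
        path = self.root / "education_map.csv"
        return EducationMapping.from_csv(path) if path.exists() else None


class CrossSectionalCSVAdapter(StudyAdapter):
    """Adapter for the cross-sectional dialect: one ``participants.csv``
    row per subject, no visit structure, education already in years."""

    kind = "cross_sectional"

    def __init__(self, root: str | Path, study_name: str = "synthB"):
        self.root = Path(root)
        self.study_name = study_name

    def _rows(self) -> list[dict[str, str]]:
        with open(self.root / "participants.csv", newline="") as fh:
            return list(csv.DictReader(fh))

    def iter_subjects(self) -> Iterator[dict[str, Any]]:
        for row in self._rows():
            yield {
                "code": row["subj_id"],
                "sex": row["sex"] or None,
                "handedness": row["handedness"] or None,
                "age_at_baseline": float(row["age"]) if row["age"] else None,
                "education_years": float(row["educ_years"]) if row["educ_years"] else None,
                "condition": row["diagnosis"] or None,
            }

    def iter_visits(self) -> Iterator[dict[str, Any]]:
        return iter(())

    def iter_images(self) -> Iterator[dict[str, Any]]:
        for row in self._rows():
            yield {
                "subject_code": row["subj_id"],
                "day": 0,
                "path": str(self.root / row["scan_file"]),
                "modality": "T1w",
                "scanner": {
                    "brand": row["scanner"],
                    "model": row["model"],
                    "field_strength": float(row["tesla"]),
                },
                "condition": row["diagnosis"] or None,
                "metadata_path": None,
            }

    def condition_map(self) -> dict[str, str]:
        return _read_condition_map(self.root / "condition_map.csv")


def _read_condition_map(path: Path) -> dict[str, str]:
    with open(path, newline="") as fh:
        return {r["source_label"]: r["master_condition"] for r in csv.DictReader(fh)}


_ADAPTERS = {
    "longitudinal-csv": LongitudinalCSVAdapter,
    "cross-sectional-csv": CrossSectionalCSVAdapter,
}


def make_adapter(name: str, root: str | Path, study_name: str) -> StudyAdapter:
    if name not in _ADAPTERS:
        raise IngestError(f"unknown adapter {name!r}; available: {sorted(_ADAPTERS)}")
    return _ADAPTERS[name](root, study_name=study_name)


# ---------------------------------------------------------------------------
# Ingestion driver


@dataclass
class IngestReport:
    study_name: str
    n_subjects: int = 0
    n_visits: int = 0
    n_images: int = 0
    n_images_unmatched: int = 0      # images skipped for lack of a qualifying visit
    n_visits_synthesized: int = 0
    n_subjects_without_images: int = 0
    errors: list[tuple[str, str]] = dc_field(default_factory=list)


class StudyIngest:
    """Drives the three load phases of one study, strictly in order.

    ``unmatched_policy`` decides what happens to a longitudinal image with
    no qualifying past visit: ``"synthesize"`` (default) attaches it to a
    freshly synthesized, flagged visit carrying no clinical data;
    ``"skip"`` leaves it out and records it in the report.
    """

    _PHASES = ("subjects", "visits", "images")

    def __init__(
        self,
        catalog: CatalogHandle,
        adapter: StudyAdapter,
        rule: MatchRule | None = None,
        unmatched_policy: str = "synthesize",
    ):
        if unmatched_policy not in ("synthesize", "skip"):
            raise ValueError("unmatched_policy must be 'synthesize' or 'skip'")
        if catalog.lookup_id("source_dataset", name=adapter.study_name) is not None:
            raise IngestError(f"study {adapter.study_name!r} already ingested")
        self.catalog = catalog
        self.adapter = adapter
        self.rule = rule or MatchRule()
        self.unmatched_policy = unmatched_policy
        self.report = IngestReport(adapter.study_name)
        self._done: set[str] = set()
        self._subject_ids: dict[str, int] = {}
        self._staged_visits: dict[str, list[dict[str, Any]]] = {}
        self._sdid: int | None = None

    def _require(self, phase: str) -> None:
        i = self._PHASES.index(phase)
        if phase in self._done:
            raise IngestOrderError(f"phase {phase!r} already executed")
        missing = [p for p in self._PHASES[:i] if p not in self._done]
        if missing:
            raise IngestOrderError(
                f"cannot run phase {phase!r} before {missing}; phases must run "
                "in order subjects -> visits -> images"
            )

    # -- phase 1 ------------------------------------------------------------

    def load_subjects(self) -> None:
        self._require("subjects")
        cat = self.catalog
        self._sdid = cat.record(SourceDatasetRecord(name=self.adapter.study_name))
        # master condition list: ensure a healthy/control entry plus every
        # master label this study maps to
        cond_ids: dict[str, int] = {}
        for master in sorted(set(self.adapter.condition_map().values()) | {"healthy"}):
            cid = cat.lookup_id("condition", name=master)
            cond_ids[master] = cid if cid is not None else cat.record(ConditionRecord(name=master))
        for src_label, master in sorted(self.adapter.condition_map().items()):
            cat.record(
                SourceConditionMap(
                    source_dataset_id=self._sdid,
                    source_label=src_label,
                    condition_id=cond_ids[master],
                )
            )
        edu = self.adapter.education_mapping()
        for row in self.adapter.iter_subjects():
            code = row["code"]
            if code in self._subject_ids:
                self.report.errors.append((f"subject {code}", "duplicate subject code"))
                continue
            years = row.get("education_years")
            if years is None and row.get("education_code") is not None:
                if edu is None:
                    self.report.errors.append(
                        (f"subject {code}", "education code given but no mapping declared")
                    )
                else:
                    try:
                        years = education_to_years(row["education_code"], edu)
                    except MappingError as e:
                        self.report.errors.append((f"subject {code}", str(e)))
            cond_id = None
            if row.get("condition"):
                try:
                    cond_id = map_condition(cat, self._sdid, row["condition"])
                except MappingError as e:
                    self.report.errors.append((f"subject {code}", str(e)))
            sid = cat.record(
                SubjectRecord(
                    source_dataset_id=self._sdid,
                    source_subject_code=code,
                    sex=row.get("sex"),
                    handedness=row.get("handedness"),
                    age_at_baseline=row.get("age_at_baseline"),
                    education_years=years,
                    baseline_condition_id=cond_id,
                )
            )
            self._subject_ids[code] = sid
            self.report.n_subjects += 1
        self._done.add("subjects")

    # -- phase 2 ------------------------------------------------------------

    def load_visits(self) -> None:
        self._require("visits")
        for row in self.adapter.iter_visits():
            code = row["subject_code"]
            if code not in self._subject_ids:
                self.report.errors.append(
                    (f"visit {code}@{row.get('day')}", "visit for unknown subject; skipped")
                )
                continue
            staged = self._staged_visits.setdefault(code, [])
            clash = next((v for v in staged if v["day"] == row["day"]), None)
            if clash is not None:
                # same-day duplicate: merge, earlier row wins on conflicts
                for k in ("condition", "bmi"):
                    if clash.get(k) is None:
                        clash[k] = row.get(k)
                clash.setdefault("scores", {}).update(
                    {k: v for k, v in (row.get("scores") or {}).items()
                     if k not in clash["scores"]}
                )
                continue
            staged.append(
                {
                    "day": int(row["day"]),
                    "condition": row.get("condition"),
                    "bmi": row.get("bmi"),
                    "scores": dict(row.get("scores") or {}),
                    "synthesized": False,
                }
            )
        self._done.add("visits")

    # -- phase 3 ------------------------------------------------------------

    def load_images(self) -> None:
        self._require("images")
        cat = self.catalog
        images: dict[str, list[dict[str, Any]]] = {}
        for row in self.adapter.iter_images():
            code = row["subject_code"]
            if code not in self._subject_ids:
                self.report.errors.append(
                    (f"image {row.get('path')}", "image for unknown subject; skipped")
                )
                continue
            images.setdefault(code, []).append(row)

        for code, sid in self._subject_ids.items():
            visits = sorted(self._staged_visits.get(code, []), key=lambda v: v["day"])
            keep: list[dict[str, Any]] = []
            for img in sorted(images.get(code, []), key=lambda r: (r["day"], r["path"])):
                day = int(img["day"])
                vdays = [v["day"] for v in visits]
                pos = match_image_to_visit(day, vdays, self.rule)
                if pos is None:
                    if self.unmatched_policy == "skip" and self.adapter.kind == "longitudinal":
                        self.report.n_images_unmatched += 1
                        continue
                    cond = img.get("condition")
                    visits.append(
                        {"day": day, "condition": cond, "bmi": None, "scores": {},
                         "synthesized": True}
                    )
                    visits.sort(key=lambda v: v["day"])
                    pos = next(i for i, v in enumerate(visits) if v["day"] == day)
                img["_visit_day"] = visits[pos]["day"]
                keep.append(img)

            if not visits and not keep:
                continue
            baseline = min(v["day"] for v in visits) if visits else 0
            visit_ids: dict[int, int] = {}
            for v in visits:
                cond_id = None
                if v.get("condition"):
                    try:
                        cond_id = map_condition(cat, self._sdid, v["condition"])
                    except MappingError as e:
                        self.report.errors.append((f"visit {code}@{v['day']}", str(e)))
                vid = cat.record(
                    VisitRecord(
                        subject_id=sid,
                        source_dataset_id=self._sdid,
                        days_since_baseline=v["day"] - baseline,
                        condition_id=cond_id,
                        bmi=v.get("bmi"),
                        is_synthesized=bool(v["synthesized"]),
                        clinical_scores=v.get("scores") or {},
                    )
                )
                visit_ids[v["day"]] = vid
                self.report.n_visits += 1
                if v["synthesized"]:
                    self.report.n_visits_synthesized += 1

            for img in keep:
                sc = img.get("scanner") or {}
                try:
                    scanner_id = self._scanner_id(sc)
                except (KeyError, ValueError) as e:
                    self.report.errors.append((f"image {img['path']}", f"bad scanner: {e}"))
                    continue
                size = None
                if os.path.exists(img["path"]):
                    size = os.path.getsize(img["path"])
                cat.record(
                    ImageRecord(
                        visit_id=visit_ids[img["_visit_day"]],
                        subject_id=sid,
                        scanner_id=scanner_id,
                        source_dataset_id=self._sdid,
                        file_path=img["path"],
                        days_since_baseline=int(img["day"]) - baseline,
                        modality=img.get("modality", "T1w"),
                        file_size=size,
                        metadata_path=img.get("metadata_path"),
                    )
                )
                self.report.n_images += 1

        with_images = {
            r["subject_id"]
            for r in cat.connection.execute(
                "SELECT DISTINCT subject_id FROM image WHERE source_dataset_id=?",
                (self._sdid,),
            )
        }
        self.report.n_subjects_without_images = self.report.n_subjects - len(with_images)
        self._done.add("images")

    def _scanner_id(self, sc: dict[str, Any]) -> int:
        key = dict(
            source_dataset_id=self._sdid,
            brand=sc["brand"],
            model=sc["model"],
            field_strength=float(sc["field_strength"]),
        )
        existing = self.catalog.lookup_id("scanner", **key)
        if existing is not None:
            return existing
        return self.catalog.record(ScannerRecord(**key))

    def run(self) -> IngestReport:
        with self.catalog.transaction():
            self.load_subjects()
            self.load_visits()
            self.load_images()
        return self.report


def ingest_study(
    catalog: CatalogHandle,
    adapter: StudyAdapter,
    rule: MatchRule | None = None,
    unmatched_policy: str = "synthesize",
) -> IngestReport:
    """Ingest one study end to end (all phases, all-or-nothing)."""
    return StudyIngest(catalog, adapter, rule, unmatched_policy).run()
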