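"""Ingestion harmonization: matching rule, visit synthesis, vocabulary
mappings, phase ordering, and end-to-end study loads."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrifuse.catalog import init_catalog
from mrifuse.ingestion import (
    CrossSectionalCSVAdapter,
    EducationMapping,
    IngestError,
    IngestOrderError,
    LongitudinalCSVAdapter,
    MappingError,
    MatchError,
    MatchRule,
    StudyIngest,
    education_to_years,
    ingest_study,
    map_condition,
    match_image_to_visit,
    synthesize_visit,
)


# ---------------------------------------------------------------------------
# match_image_to_visit


def _brute_force_match(image_day, visit_days, max_gap):
    best = None
    for i, d in enumerate(visit_days):
        if d <= image_day and image_day - d <= max_gap:
            if best is None or d > visit_days[best]:
                best = i
    return best


@pytest.mark.parametrize(
    "image_day,visit_days,expect",
    [
        (100, [50, 90, 130], 1),   # closest past within 60; future 130 excluded
        (100, [10, 130], None),    # nearest past gap 90 > 60
        (100, [100, 160], 0),      # same-day visit counts, gap 0
        (5, [10], None),           # only future visits
        (70, [0, 10], 1),          # gap exactly 60: inclusive boundary
        (71, [0, 10], None),       # both past but beyond the gap
    ],
)
def test_match_forced_examples(image_day, visit_days, expect):
    assert match_image_to_visit(image_day, visit_days, MatchRule(60)) == expect


@settings(max_examples=300, derandomize=True)
@given(
    image_day=st.integers(0, 1000),
    visit_days=st.lists(st.integers(0, 1000), min_size=0, max_size=8, unique=True),
    max_gap=st.integers(1, 120),
)
def test_match_equals_brute_force_oracle(image_day, visit_days, max_gap):
    days = sorted(visit_days)
    got = match_image_to_visit(image_day, days, MatchRule(max_gap))
    assert got == _brute_force_match(image_day, days, max_gap)
    if got is not None:
        assert 0 <= image_day - days[got] <= max_gap  # never from the future


def test_match_rejects_unsorted_or_duplicate_days():
    with pytest.raises(MatchError):
        match_image_to_visit(10, [5, 3], MatchRule())
    with pytest.raises(MatchError):
        match_image_to_visit(10, [3, 3], MatchRule())


def test_match_rule_requires_positive_gap():
    with pytest.raises(ValueError):
        MatchRule(0)


# ---------------------------------------------------------------------------
# synthesize_visit / mappings


def test_synthesize_visit_flags_and_day():
    v = synthesize_visit(120, subject_id=7)
    assert v.is_synthesized and v.days_since_baseline == 120 and v.subject_id == 7


def test_synthesized_visits_participate_in_matching():
    # a synthesized visit behaves like a real one for later images
    days = sorted([0, 400])  # 400 synthesized for an imaging-only time point
    assert match_image_to_visit(430, days, MatchRule(60)) == 1


def test_map_condition_and_many_to_one(cat):
    from mrifuse.catalog import (ConditionRecord, SourceConditionMap,
                                 SourceDatasetRecord)
    a = cat.record(SourceDatasetRecord(name="synthA"))
    b = cat.record(SourceDatasetRecord(name="synthB"))
    healthy = cat.record(ConditionRecord(name="healthy"))
    pd = cat.record(ConditionRecord(name="parkinson"))
    cat.record(SourceConditionMap(source_dataset_id=a, source_label="CTRL",
                                  condition_id=healthy))
    cat.record(SourceConditionMap(source_dataset_id=b, source_label="HC",
                                  condition_id=healthy))
    cat.record(SourceConditionMap(source_dataset_id=a, source_label="PD",
                                  condition_id=pd))
    assert map_condition(cat, a, "PD") == pd
    assert map_condition(cat, a, "CTRL") == map_condition(cat, b, "HC") == healthy
    with pytest.raises(MappingError, match="XYZ"):
        map_condition(cat, a, "XYZ")


def test_education_mapping_lookup_and_unknown_code():
    mapping = EducationMapping({"none": 0.0, "degree_university": 16.0,
                                "prefer_not_to_say": None})
    assert education_to_years("degree_university", mapping) == 16.0
    assert education_to_years("none", mapping) == 0.0
    assert education_to_years("prefer_not_to_say", mapping) is None
    with pytest.raises(MappingError, match="degree_university"):
        education_to_years("absent", mapping)


# ---------------------------------------------------------------------------
# end-to-end study ingestion


def test_ingest_longitudinal_counts_match_generator(cat, longitudinal_study):
    path, truth = longitudinal_study
    adapter = LongitudinalCSVAdapter(path, study_name="synthA")
    report = ingest_study(cat, adapter, MatchRule(60), unmatched_policy="skip")
    spec = truth.spec
    assert report.n_subjects == spec.n_subjects
    assert report.n_visits == spec.n_subjects * spec.visits_per_subject
    expected_unmatched = truth.expected_unmatched(60)
    assert report.n_images_unmatched == expected_unmatched
    assert report.n_images == truth.n_images - expected_unmatched
    assert report.n_visits_synthesized == 0
    assert cat.check_referential_closure() == []


def test_ingest_longitudinal_synthesize_policy_keeps_every_image(cat, longitudinal_study):
    path, truth = longitudinal_study
    report = ingest_study(cat, LongitudinalCSVAdapter(path, "synthA"),
                          MatchRule(60), unmatched_policy="synthesize")
    assert report.n_images == truth.n_images
    assert report.n_images_unmatched == 0
    assert report.n_visits_synthesized == truth.expected_unmatched(60)
    # synthesized visits carry no clinical payload
    rows = cat.connection.execute(
        "SELECT condition_id, bmi FROM visit WHERE is_synthesized=1").fetchall()
    assert all(r["condition_id"] is None and r["bmi"] is None for r in rows)


def test_ingest_cross_sectional_synthesizes_one_visit_per_image(cat, cross_sectional_study):
    path, truth = cross_sectional_study
    report = ingest_study(cat, CrossSectionalCSVAdapter(path, "synthB"))
    n = truth.spec.n_subjects
    assert (report.n_subjects, report.n_images) == (n, n)
    assert report.n_visits == report.n_visits_synthesized == n
    # diagnosis carried from the participant row onto the synthesized visit
    got = dict(cat.connection.execute(
        """SELECT s.source_subject_code, c.name FROM visit v
           JOIN subject s ON s.id=v.subject_id
           LEFT JOIN condition c ON c.id=v.condition_id"""))
    master = truth.spec.condition_master
    for subj in truth.subjects:
        assert got[subj["code"]] == master[subj["condition"]]


def test_reingesting_same_study_errors_and_leaves_catalog_unchanged(cat, cross_sectional_study):
    path, _ = cross_sectional_study
    ingest_study(cat, CrossSectionalCSVAdapter(path, "synthB"))
    before = cat.summarize()
    with pytest.raises(IngestError, match="already ingested"):
        ingest_study(cat, CrossSectionalCSVAdapter(path, "synthB"))
    assert cat.summarize() == before


def test_ingest_delete_ingest_is_idempotent(cat, longitudinal_study):
    path, _ = longitudinal_study
    ingest_study(cat, LongitudinalCSVAdapter(path, "synthA"))
    first = cat.summarize()
    cat.delete_study("synthA")
    assert cat.summarize()[-1] == {"study": "Total", "subjects": 0, "images": 0}
    ingest_study(cat, LongitudinalCSVAdapter(path, "synthA"))
    assert cat.summarize() == first


def test_phase_order_is_enforced(cat, longitudinal_study):
    path, _ = longitudinal_study
    ingest = StudyIngest(cat, LongitudinalCSVAdapter(path, "synthA"))
    with pytest.raises(IngestOrderError, match="subjects"):
        ingest.load_images()
    with pytest.raises(IngestOrderError):
        ingest.load_visits()
    ingest.load_subjects()
    with pytest.raises(IngestOrderError, match="already"):
        ingest.load_subjects()
    ingest.load_visits()
    ingest.load_images()


def test_report_counts_equal_catalog_deltas(cat, longitudinal_study):
    path, _ = longitudinal_study
    before = {t: cat.count(t) for t in ("subject", "visit", "image")}
    report = ingest_study(cat, LongitudinalCSVAdapter(path, "synthA"))
    assert cat.count("subject") - before["subject"] == report.n_subjects
    assert cat.count("visit") - before["visit"] == report.n_visits
    assert cat.count("image") - before["image"] == report.n_images


def test_image_visit_gap_invariant(cat, longitudinal_study):
    path, _ = longitudinal_study
    ingest_study(cat, LongitudinalCSVAdapter(path, "synthA"), MatchRule(60))
    rows = cat.connection.execute(
        """SELECT i.days_since_baseline AS iday, v.days_since_baseline AS vday,
                  v.is_synthesized AS synth
           FROM image i JOIN visit v ON v.id=i.visit_id"""
    ).fetchall()
    assert rows
    for r in rows:
        gap = r["iday"] - r["vday"]
        assert 0 <= gap <= 60
        if r["synth"]:
            assert gap == 0
    # every subject's first visit sits at day 0
    firsts = cat.connection.execute(
        "SELECT MIN(days_since_baseline) AS d FROM visit GROUP BY subject_id"
    ).fetchall()
    assert all(r["d"] == 0 for r in firsts)


def test_image_for_unknown_subject_recorded_and_skipped(cat, cross_sectional_study, tmp_path):
    path, _ = cross_sectional_study
    # append a participants row referencing a subject that never appears in
    # iter_subjects (simulate by a custom adapter wrapper)
    adapter = CrossSectionalCSVAdapter(path, "synthB")

    class Broken(CrossSectionalCSVAdapter):
        def iter_images(self):
            yield from super().iter_images()
            yield {"subject_code": "ghost", "day": 0, "path": "/nope.nii.gz",
                   "modality": "T1w",
                   "scanner": {"brand": "X", "model": "Y", "field_strength": 3.0},
                   "metadata_path": None}

    report = ingest_study(cat, Broken(path, "synthB"))
    assert any("unknown subject" in msg for _, msg in report.errors)
    assert report.n_images == len(list(adapter.iter_images()))


def test_failed_ingest_rolls_back(cat, longitudinal_study):
    path, _ = longitudinal_study

    class Exploding(LongitudinalCSVAdapter):
        def iter_images(self):
            raise RuntimeError("boom")

    with pytest.raises(RuntimeError):
        ingest_study(cat, Exploding(path, "synthA"))
    assert cat.count("subject") == 0
    assert cat.count("source_dataset") == 0
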