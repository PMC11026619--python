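"""Shared helpers for the test suite."""

import numpy as np

from mrifuse.catalog import (
    ConditionRecord,
    ImageRecord,
    ScannerRecord,
    SourceDatasetRecord,
    SubjectRecord,
    VisitRecord,
)


def dice(a, b):
    a, b = np.asarray(a) > 0, np.asarray(b) > 0
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def register_one_image(cat, path, study="pipe", code="s1"):
    """Minimal catalog scaffolding so one image file can be preprocessed."""
    sd = cat.lookup_id("source_dataset", name=study)
    if sd is None:
        sd = cat.record(SourceDatasetRecord(name=study))
    cond = cat.lookup_id("condition", name="healthy")
    if cond is None:
        cond = cat.record(ConditionRecord(name="healthy"))
    sid = cat.lookup_id("subject", source_dataset_id=sd, source_subject_code=code)
    if sid is None:
        sid = cat.record(SubjectRecord(source_dataset_id=sd, source_subject_code=code,
                                       baseline_condition_id=cond))
    vid = cat.lookup_id("visit", subject_id=sid, days_since_baseline=0)
    if vid is None:
        vid = cat.record(VisitRecord(subject_id=sid, source_dataset_id=sd,
                                     days_since_baseline=0))
    scan = cat.lookup_id("scanner", source_dataset_id=sd, brand="S", model="P",
                         field_strength=3.0)
    if scan is None:
        scan = cat.record(ScannerRecord(source_dataset_id=sd, brand="S", model="P",
                                        field_strength=3.0))
    return cat.record(ImageRecord(visit_id=vid, subject_id=sid, scanner_id=scan,
                                  source_dataset_id=sd, file_path=str(path),
                                  days_since_baseline=0))
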