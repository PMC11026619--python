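"""Registration quality control by template correlation.

A registered image that truly landed on the template should correlate
strongly, voxel for voxel, with the template's intensities inside the
brain mask; a failed registration (or a badly truncated brain) will not.
The gate is the masked voxel-wise Pearson correlation coefficient with a
pass threshold of 0.4 — a deliberately cheap integrity check, not a full
QA suite.  Failures stay in the catalog, flagged; exclusion happens at
query time via the ``qc_min_r`` filter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .catalog import CatalogHandle
from .preprocess import Volume

__all__ = ["QCResult", "template_correlation", "qc_filter", "DEFAULT_QC_THRESHOLD"]

DEFAULT_QC_THRESHOLD = 0.4


@dataclass
class QCResult:
    image_id: int
    r: float | None
    threshold: float
    passed: bool
    n_voxels: int


def template_correlation(
    registered: Volume, template: Volume, template_mask: Volume
) -> float:
    """Pearson correlation of intensities inside the template brain mask.

    Both images must live on the template grid and be non-constant within
    the mask.
    """
    if tuple(registered.shape) != tuple(template.shape):
        raise ValueError("registered image is not on the template grid")
    sel = np.asarray(template_mask.data) > 0
    if not sel.any():
        raise ValueError("template mask is empty")
    a = np.asarray(registered.data, dtype=float)[sel]
    b = np.asarray(template.data, dtype=float)[sel]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: image constant within mask")
    return float(np.corrcoef(a, b)[0, 1])


def qc_filter(
    catalog: CatalogHandle,
    template: Volume,
    template_mask: Volume,
    threshold: float = DEFAULT_QC_THRESHOLD,
    stage: str = "affine",
) -> list[QCResult]:
    """Score every image preprocessed at ``stage`` against the template.

    Computes the masked correlation of each registered image, persists the
    results (keyed by image and preprocess task, so re-runs overwrite),
    and returns them all with pass/fail at the threshold.  A missing or
    unreadable registered file is recorded as a failure with unknown r.
    """
    task_id = catalog.lookup_id("preprocess_task", description=stage)
    if task_id is None:
        raise ValueError(f"unknown preprocess stage {stage!r}")
    ft_id = catalog.lookup_id("file_type", name="registered_image")
    rows = catalog.connection.execute(
        """
        SELECT i.id AS image_id, pf.path
        FROM image i
        JOIN preprocess_file pf
          ON pf.image_id = i.id AND pf.task_id = ? AND pf.file_type_id = ?
        WHERE i.preprocessing_status != 'none'
        ORDER BY i.id
        """,
        (task_id, ft_id),
    ).fetchall()

    n_mask = int((np.asarray(template_mask.data) > 0).sum())
    results: list[QCResult] = []
    for row in rows:
        r: float | None
        try:
            reg = Volume.from_nifti(row["path"])
            r = template_correlation(reg, template, template_mask)
        except (OSError, ValueError):
            r = None
        passed = r is not None and r >= threshold
        results.append(QCResult(row["image_id"], r, threshold, passed, n_mask))

    conn = catalog.connection
    with catalog.transaction():
        for res in results:
            conn.execute(
                "INSERT INTO qc_result (image_id, task_id, r, threshold, passed, n_voxels) "
                "VALUES (?,?,?,?,?,?) "
                "ON CONFLICT(image_id, task_id) DO UPDATE SET "
                "r=excluded.r, threshold=excluded.threshold, "
                "passed=excluded.passed, n_voxels=excluded.n_voxels",
                (res.image_id, task_id, res.r, res.threshold, int(res.passed), res.n_voxels),
            )
    return results


def export_qc_csv(results: list[QCResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "r", "passed"])
        for res in results:
            w.writerow([res.image_id, "" if res.r is None else f"{res.r:.6f}", int(res.passed)])
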