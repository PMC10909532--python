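"""Reading and writing multi-scorer hypnogram matrices.

Dialect: one UTF-8 CSV per subject.  The header names the columns; column 1
is the 0-based epoch index and every remaining column is one scorer.  Cell
values are stage labels (case-insensitive): W, N1, N2, N3, R, plus U
(unscored) and A (invalid).  Empty cells — typically leading/trailing
epochs a scorer never reached — are read as unscored.

A sidecar JSON next to the CSV (same name, ``.json``) carries the metadata
a flat matrix cannot: subject id, epoch length, start clock time, centre
ids and, for merged-category sets, the stage alphabet.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import HypnogramSet, SubjectCovariates
from .stages import STAGE_LABELS, UNSCORED, label_to_code


class HypnogramParseError(ValueError):
    """Malformed hypnogram CSV (ragged rows, no scorer columns, bad labels)."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_hypnogram_set(path: str | Path) -> HypnogramSet:
    """Read one subject's scorer-by-epoch stage matrix from CSV.

    Raises
    ------
    HypnogramParseError
        On ragged rows (named by line number), zero scorer columns, or
        labels outside the stage alphabet (offending cells listed).
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise HypnogramParseError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    if len(header) < 2:
        raise HypnogramParseError(f"{path}: no scorer columns in header")
    scorer_ids = header[1:]
    n_cols = len(header)

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
    stage_labels = tuple(meta.get("stage_labels", STAGE_LABELS))
    label_map = {lab.upper(): code for code, lab in enumerate(stage_labels)}
    label_map.setdefault("U", UNSCORED)
    label_map.setdefault("A", UNSCORED + 1)  # INVALID

    codes = np.empty((len(rows) - 1, len(scorer_ids)), dtype=np.int16)
    bad_cells: list[str] = []
    for r, row in enumerate(rows[1:], start=2):  # 1-based file line numbers
        if len(row) != n_cols:
            raise HypnogramParseError(
                f"{path}: line {r} has {len(row)} cells, expected {n_cols}"
            )
        for c, cell in enumerate(row[1:]):
            label = cell.strip().upper()
            if label == "":
                codes[r - 2, c] = UNSCORED
                continue
            try:
                codes[r - 2, c] = label_map[label]
            except KeyError:
                bad_cells.append(f"line {r}, column {scorer_ids[c]}: {cell!r}")
    if bad_cells:
        raise HypnogramParseError(
            f"{path}: unknown stage labels at " + "; ".join(bad_cells)
        )
    if codes.shape[0] < 1:
        raise HypnogramParseError(f"{path}: no epoch rows")

    start_clock = None
    if meta.get("start_clock"):
        start_clock = _dt.time.fromisoformat(meta["start_clock"])
    return HypnogramSet(
        subject_id=meta.get("subject_id", path.stem),
        stages=codes.T,
        epoch_seconds=float(meta.get("epoch_seconds", 30.0)),
        start_clock=start_clock,
        scorer_ids=scorer_ids,
        centre_ids=meta.get("centre_ids"),
        stage_labels=stage_labels,
    )


def write_hypnogram_set(hset: HypnogramSet, path: str | Path) -> Path:
    """Write a HypnogramSet to CSV plus its metadata sidecar.

    Round-trip safe: ``read_hypnogram_set(write_hypnogram_set(h, p)) == h``.
    """
    if not isinstance(hset, HypnogramSet):
        raise TypeError("expected a HypnogramSet")
    path = Path(path)

    def cell(code: int) -> str:
        if code == UNSCORED:
            return "U"
        if code == UNSCORED + 1:
            return "A"
        return hset.stage_labels[code]

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", *hset.scorer_ids])
        for i in range(hset.n_epochs):
            writer.writerow([i, *(cell(int(c)) for c in hset.stages[:, i])])

    meta = {
        "subject_id": hset.subject_id,
        "epoch_seconds": hset.epoch_seconds,
        "start_clock": hset.start_clock.isoformat() if hset.start_clock else None,
        "centre_ids": hset.centre_ids,
        "stage_labels": list(hset.stage_labels),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return path


def read_covariates(path: str | Path) -> dict[str, SubjectCovariates]:
    """Read a subject-covariate table (columns subject_id, ahi, ari[, odi])."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "ahi", "ari"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate file missing columns: {sorted(missing)}")
    out: dict[str, SubjectCovariates] = {}
    for rec in df.to_dict("records"):
        odi = rec.get("odi")
        out[rec["subject_id"]] = SubjectCovariates(
            subject_id=rec["subject_id"],
            ahi=float(rec["ahi"]),
            ari=float(rec["ari"]),
            odi=None if odi is None or pd.isna(odi) else float(odi),
        )
    return out


def write_covariates(covs: dict[str, SubjectCovariates], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {"subject_id": c.subject_id, "ahi": c.ahi, "ari": c.ari, "odi": c.odi}
            for c in covs.values()
        ]
    ).to_csv(path, index=False)
    return path
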