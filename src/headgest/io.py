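"""Recording CSV readers/writers, dataset layout, and model serialization.

Recording dialects
------------------
* quaternion: columns ``timestamp_ms, x, y, z, w`` (vector part first,
  scalar last — note that w-first dialects exist elsewhere).
* euler: columns ``timestamp_ms, yaw_deg, pitch_deg, roll_deg``, converted
  to quaternions on load using the intrinsic yaw(y)–pitch(x)–roll(z)
  convention that matches the generator's direction model.

Dataset layout: ``<root>/<subject>/<class>/<name>.csv``.

Timestamps are milliseconds since recording start and must be strictly
increasing; quaternion rows are normalized on load (a warning with the
off-norm row count is logged if any row deviates from unit norm beyond
write precision).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import quaternion as hq
from .dba import GestureTemplate, TemplateClassifier
from .ensemble import BaggedModel
from .sequences import OrientationSequence

logger = logging.getLogger("headgest")

__all__ = [
    "read_recording",
    "write_recording",
    "load_dataset",
    "write_dataset",
    "save_model",
    "load_model",
]

_QUAT_COLS = ["timestamp_ms", "x", "y", "z", "w"]
_EULER_COLS = ["timestamp_ms", "yaw_deg", "pitch_deg", "roll_deg"]


def read_recording(
    path: str | Path,
    dialect: str = "quaternion",
    subject: str | None = None,
    label: str | None = None,
) -> OrientationSequence:
    """Load one recording CSV, validating and normalizing on the way in."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = _QUAT_COLS if dialect == "quaternion" else _EULER_COLS
    if dialect not in ("quaternion", "euler"):
        raise ValueError(f"unknown dialect {dialect!r}")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")

    ts = df["timestamp_ms"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(ts) <= 0)
    if len(bad):
        raise ValueError(
            f"{path}: timestamps not strictly increasing at row {int(bad[0]) + 1}"
        )

    if dialect == "euler":
        quats = Rotation.from_euler(
            "YXZ",
            np.column_stack(
                [df["yaw_deg"], -df["pitch_deg"].to_numpy(), df["roll_deg"]]
            ),
            degrees=True,
        ).as_quat()  # xyzw
    else:
        quats = df[["x", "y", "z", "w"]].to_numpy(dtype=float)
        norms = hq.qnorm(quats)
        zero = np.flatnonzero(norms == 0)
        if len(zero):
            raise ValueError(f"{path}: zero-norm quaternion at row {int(zero[0])}")
        off = np.flatnonzero(np.abs(norms - 1.0) > 1e-6)
        if len(off):
            logger.warning(
                "%s: %d row(s) deviate from unit norm; normalizing",
                path,
                len(off),
            )
        quats = quats / norms[:, np.newaxis]

    return OrientationSequence(
        quaternions=quats, timestamps_ms=ts, subject=subject, label=label
    )


def write_recording(seq: OrientationSequence, path: str | Path) -> None:
    """Write a recording in the quaternion CSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ts = (
        seq.timestamps_ms
        if seq.timestamps_ms is not None
        else np.arange(len(seq), dtype=float)
    )
    pd.DataFrame(
        {
            "timestamp_ms": ts,
            "x": seq.quaternions[:, 0],
            "y": seq.quaternions[:, 1],
            "z": seq.quaternions[:, 2],
            "w": seq.quaternions[:, 3],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def load_dataset(root: str | Path, dialect: str = "quaternion") -> list[OrientationSequence]:
    """Load ``<root>/<subject>/<class>/*.csv`` into a labeled dataset.

    Files are walked in lexicographic order for cross-platform determinism;
    stray non-CSV files are skipped with a warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"dataset root {root} is not a directory")
    dataset: list[OrientationSequence] = []
    counts: dict[tuple[str, str], int] = {}
    for subject_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for class_dir in sorted(p for p in subject_dir.iterdir() if p.is_dir()):
            for f in sorted(class_dir.iterdir()):
                if f.suffix.lower() != ".csv":
                    logger.warning("skipping non-CSV file %s", f)
                    continue
                dataset.append(
                    read_recording(
                        f, dialect, subject=subject_dir.name, label=class_dir.name
                    )
                )
                counts[(subject_dir.name, class_dir.name)] = (
                    counts.get((subject_dir.name, class_dir.name), 0) + 1
                )
    if not dataset:
        raise ValueError(f"no recordings found under {root}")
    for (subj, lbl), n in sorted(counts.items()):
        logger.info("loaded %s/%s: %d recordings", subj, lbl, n)
    return dataset


def write_dataset(dataset: list[OrientationSequence], root: str | Path) -> None:
    """Write a dataset in the ``<root>/<subject>/<class>/`` layout."""
    root = Path(root)
    counters: dict[tuple[str, str], int] = {}
    for rec in dataset:
        if rec.subject is None or rec.label is None:
            raise ValueError("every recording needs subject and label to be filed")
        key = (rec.subject, rec.label)
        counters[key] = counters.get(key, 0) + 1
        write_recording(
            rec, root / rec.subject / rec.label / f"rec{counters[key]:03d}.csv"
        )


def _template_to_dict(t: GestureTemplate) -> dict:
    return {
        "label": t.label,
        "quat_template": t.quat_template.tolist(),
        "objective_trace": list(t.objective_trace),
    }


def _template_from_dict(d: dict) -> GestureTemplate:
    quat = np.asarray(d["quat_template"], dtype=float)
    return GestureTemplate(
        label=d["label"],
        quat_template=quat,
        spatial_template=hq.to_spatial(quat),
        objective_trace=list(d["objective_trace"]),
    )


def save_model(model, path: str | Path) -> None:
    """Serialize a template or bagged model to JSON (spatial templates are
    recomputed on load)."""
    if isinstance(model, TemplateClassifier):
        payload = {
            "kind": "dtw",
            "templates": [_template_to_dict(t) for t in model.templates],
        }
    elif isinstance(model, BaggedModel):
        payload = {
            "kind": "dtwb",
            "members": {
                subj: [_template_to_dict(t) for t in ts]
                for subj, ts in model.members.items()
            },
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    """Inverse of :func:`save_model`; returns the appropriate model type."""
    payload = json.loads(Path(path).read_text())
    kind = payload.get("kind")
    if kind == "dtw":
        return TemplateClassifier(
            templates=[_template_from_dict(d) for d in payload["templates"]]
        )
    if kind == "dtwb":
        return BaggedModel(
            members={
                subj: [_template_from_dict(d) for d in ts]
                for subj, ts in payload["members"].items()
            }
        )
    raise ValueError(f"unknown model kind {kind!r} in {path}")
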