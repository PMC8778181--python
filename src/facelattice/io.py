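"""Readers and writers for every artifact format.

Frame-log CSV dialect: header ``timestamp,animation,sound,leds,speaking,
x0,y0,...,x67,y67`` (optionally a trailing ``state`` column); animation in
{None, Disappointed, Default, Stand}; binary modalities in {no, yes}; empty
landmark cells mean the face was not detected in that frame.  Labeled
training CSV: ``label,x0,y0,...,x67,y67``.  Metric parameters travel as the
flat 126-gene JSON chromosome so GA results round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .face_tree import N_LANDMARKS, LandmarkSet, TrivialTree, build_face_tree
from .ga_metric_opt import decode, encode
from .lattice_metric import MetricParams
from .pose_prototypes import PrototypeSet
from .session_analysis import (
    ANIMATION_VALUES,
    BINARY_VALUES,
    Attempt,
    Frame,
)

LANDMARK_COLUMNS = [f"{ax}{i}" for i in range(N_LANDMARKS) for ax in ("x", "y")]
ACTION_COLUMNS = ["animation", "sound", "leds", "speaking"]
FRAME_COLUMNS = ["timestamp"] + ACTION_COLUMNS + LANDMARK_COLUMNS


def _check_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")


def read_frames_csv(path, attempt_id: str | None = None) -> Attempt:
    """Read one attempt from a frame-log CSV."""
    path = Path(path)
    # keep_default_na=False: the literal action value "None" must survive
    df = pd.read_csv(
        path, dtype={c: str for c in ["timestamp"] + ACTION_COLUMNS}, keep_default_na=False
    )
    _check_columns(df, FRAME_COLUMNS, path)
    has_state = "state" in df.columns
    lm = df[LANDMARK_COLUMNS].replace("", np.nan).to_numpy(dtype=float)
    frames = []
    for i, row in enumerate(df.itertuples(index=False)):
        anim = row.animation
        if anim not in ANIMATION_VALUES:
            raise InputError(f"{path} row {i}: bad animation value {anim!r}")
        for col in ("sound", "leds", "speaking"):
            if getattr(row, col) not in BINARY_VALUES:
                raise InputError(f"{path} row {i}: bad {col} value {getattr(row, col)!r}")
        coords = lm[i]
        if np.all(np.isfinite(coords)):
            landmarks = coords.reshape(N_LANDMARKS, 2)
        elif np.all(~np.isfinite(coords)):
            landmarks = None
        else:
            raise InputError(f"{path} row {i}: partially blank landmark cells")
        state = None
        if has_state:
            raw = getattr(row, "state")
            if raw not in (None, "") and not (isinstance(raw, float) and np.isnan(raw)):
                state = int(float(raw))
        frames.append(
            Frame(
                timestamp=row.timestamp,
                animation=anim,
                sound=row.sound,
                leds=row.leds,
                speaking=row.speaking,
                landmarks=landmarks,
                state=state,
            )
        )
    return Attempt(attempt_id=attempt_id or path.stem, frames=frames)


def write_frames_csv(attempt: Attempt, path, include_state: bool = False) -> None:
    """Write an attempt in the frame-log CSV dialect (byte-stable)."""
    rows = []
    for f in attempt.frames:
        row = {
            "timestamp": str(f.timestamp),
            "animation": f.animation,
            "sound": f.sound,
            "leds": f.leds,
            "speaking": f.speaking,
        }
        if f.landmarks is None:
            row.update({c: "" for c in LANDMARK_COLUMNS})
        else:
            flat = np.asarray(f.landmarks, dtype=float).reshape(-1)
            row.update({c: repr(float(v)) for c, v in zip(LANDMARK_COLUMNS, flat)})
        if include_state:
            row["state"] = "" if f.state is None else str(f.state)
        rows.append(row)
    cols = FRAME_COLUMNS + (["state"] if include_state else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_labeled_landmarks_csv(path) -> tuple[list[TrivialTree], list[str]]:
    """Read labeled training landmarks and convert them to labeled trees."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, ["label"] + LANDMARK_COLUMNS, path)
    lm = df[LANDMARK_COLUMNS].to_numpy(dtype=float)
    trees, labels = [], []
    for i in range(len(df)):
        lab = str(df["label"].iloc[i])
        trees.append(build_face_tree(LandmarkSet(lm[i].reshape(N_LANDMARKS, 2)), provenance=lab))
        labels.append(lab)
    return trees, labels


def write_labeled_landmarks_csv(landmark_sets, labels, path) -> None:
    rows = []
    for lms, lab in zip(landmark_sets, labels):
        pts = lms.points if isinstance(lms, LandmarkSet) else np.asarray(lms, dtype=float)
        row = {"label": lab}
        row.update({c: repr(float(v)) for c, v in zip(LANDMARK_COLUMNS, pts.reshape(-1))})
        rows.append(row)
    pd.DataFrame(rows, columns=["label"] + LANDMARK_COLUMNS).to_csv(path, index=False)


def write_params_json(params: MetricParams, path, extra: dict | None = None) -> None:
    """Serialize metric parameters as the flat 126-gene chromosome."""
    obj = {"genes": encode(params).tolist()}
    if extra:
        obj.update(extra)
    Path(path).write_text(json.dumps(obj, indent=1))


def read_params_json(path) -> MetricParams:
    obj = json.loads(Path(path).read_text())
    return decode(np.asarray(obj["genes"], dtype=float))


def write_prototypes_json(protos: PrototypeSet, path, extra: dict | None = None) -> None:
    obj = {"prototypes": protos.to_list()}
    if extra:
        obj.update(extra)
    Path(path).write_text(json.dumps(obj, indent=1))


def read_prototypes_json(path) -> PrototypeSet:
    obj = json.loads(Path(path).read_text())
    return PrototypeSet.from_list(obj["prototypes"])


def write_tree_json(tree: TrivialTree, path) -> None:
    Path(path).write_text(json.dumps(tree.to_dict(), indent=1))


def read_tree_json(path) -> TrivialTree:
    return TrivialTree.from_dict(json.loads(Path(path).read_text()))
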