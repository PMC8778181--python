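"""Synthetic landmark and session generators with known ground truth.

Pose data are produced by rigidly rotating a fixed, anatomically plausible
3D 68-point face template by per-pose yaw/pitch presets, projecting
orthographically to the image plane and adding Gaussian landmark jitter.
The four noise presets mimic a 2x2 camera-distance x lighting design as
increasing jitter scales (fractions of the inter-ocular distance):
40cm/normal 0.5%, 1m/normal 1%, 40cm/dim 2%, 1m/dim 3% — ordered by
difficulty, not calibrated to any particular camera.

Session logs are produced by a Markov chain over the nine states whose
transition probabilities shift toward state 0 (Front) for a fixed number of
frames after every robot-action outset; the boost strength is the known
ground truth the analysis tools should recover.  Frames are emitted at
3 Hz in the package's frame-log CSV dialect, with a configurable fraction
of frames blanked (face not detected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .face_tree import (
    LEFT_EYE,
    RIGHT_EYE,
    N_LANDMARKS,
    LandmarkSet,
    build_face_tree,
)
from .pose_prototypes import SUBCLASS_LABELS
from .session_analysis import (
    ANIMATION_VALUES,
    MODALITIES,
    Attempt,
    Frame,
)

# ---------------------------------------------------------------------------
# canonical 3D face template
# ---------------------------------------------------------------------------


def _ellipse(cx, cy, rx, ry, angles, z):
    pts = np.stack(
        [cx + rx * np.cos(angles), cy + ry * np.sin(angles), np.full(len(angles), z)], axis=1
    )
    return pts


def face_template_3d() -> np.ndarray:
    """Fixed (68, 3) template; x right, y up, z toward the camera.

    Units are arbitrary (inter-ocular distance is 1.3); anatomy follows the
    standard 68-point convention.
    """
    pts = np.zeros((N_LANDMARKS, 3))
    # jaw 0-16: left temple around the chin to the right temple
    t = np.linspace(0.0, np.pi, 17)
    pts[0:17, 0] = -1.5 * np.cos(t)
    pts[0:17, 1] = 0.5 - 2.6 * np.sin(t) ** 1.5
    pts[0:17, 2] = -0.45 * np.sin(t)
    # brows 17-21 (left) and 22-26 (right), slightly arched
    bx = np.linspace(-1.15, -0.35, 5)
    arch = 0.12 * np.sin(np.linspace(0.3, np.pi - 0.3, 5))
    pts[17:22] = np.stack([bx, 0.95 + arch, np.full(5, 0.15)], axis=1)
    pts[22:27] = np.stack([-bx[::-1], 0.95 + arch[::-1], np.full(5, 0.15)], axis=1)
    # nose bridge 27-30: top of nose down to the tip, protruding forward
    pts[27:31] = np.stack(
        [np.zeros(4), np.linspace(0.75, 0.05, 4), np.linspace(0.25, 0.65, 4)], axis=1
    )
    # lower nose 31-35: the nostril line
    pts[31:36] = np.stack(
        [
            np.linspace(-0.28, 0.28, 5),
            np.array([-0.18, -0.22, -0.24, -0.22, -0.18]),
            np.full(5, 0.45),
        ],
        axis=1,
    )
    # eyes 36-41 (left) and 42-47 (right): 6-point contours
    ang6 = np.pi - np.array([0.0, np.pi / 3, 2 * np.pi / 3, np.pi, 4 * np.pi / 3, 5 * np.pi / 3])
    pts[36:42] = _ellipse(-0.65, 0.70, 0.22, 0.10, ang6, 0.10)
    pts[42:48] = _ellipse(0.65, 0.70, 0.22, 0.10, ang6, 0.10)
    # outer mouth 48-59: 12 points counter-clockwise from the left corner
    ang12 = np.pi - np.linspace(0.0, 2 * np.pi, 12, endpoint=False)
    pts[48:60] = _ellipse(0.0, -0.95, 0.55, 0.28, ang12, 0.30)
    # inner mouth 60-67
    ang8 = np.pi - np.linspace(0.0, 2 * np.pi, 8, endpoint=False)
    pts[60:68] = _ellipse(0.0, -0.95, 0.35, 0.12, ang8, 0.30)
    return pts


#: yaw/pitch presets in degrees, sign-symmetric left/right and up/down
POSE_PRESETS: dict[str, tuple[float, float]] = {
    "FrontLeft": (-12.0, 0.0),
    "FrontProper": (0.0, 0.0),
    "FrontRight": (12.0, 0.0),
    "UpperLeft": (-35.0, 25.0),
    "Up": (0.0, 25.0),
    "UpperRight": (35.0, 25.0),
    "Right": (35.0, 0.0),
    "LowerRight": (35.0, -25.0),
    "Down": (0.0, -25.0),
    "LowerLeft": (-35.0, -25.0),
    "Left": (-35.0, 0.0),
}

#: jitter scale as a fraction of the inter-ocular distance
NOISE_PRESETS: dict[str, float] = {
    "none": 0.0,
    "40cm_normal": 0.005,
    "1m_normal": 0.01,
    "40cm_dim": 0.02,
    "1m_dim": 0.03,
}

#: reported state -> generating head-pose preset
STATE_TO_POSE = (
    "FrontProper",
    "UpperLeft",
    "Up",
    "UpperRight",
    "Right",
    "LowerRight",
    "Down",
    "LowerLeft",
    "Left",
)


def _rotation(yaw_deg: float, pitch_deg: float, roll_deg: float = 0.0) -> np.ndarray:
    y, p, r = np.radians([yaw_deg, pitch_deg, roll_deg])
    ry = np.array([[np.cos(y), 0, np.sin(y)], [0, 1, 0], [-np.sin(y), 0, np.cos(y)]])
    rx = np.array([[1, 0, 0], [0, np.cos(p), -np.sin(p)], [0, np.sin(p), np.cos(p)]])
    rz = np.array([[np.cos(r), -np.sin(r), 0], [np.sin(r), np.cos(r), 0], [0, 0, 1]])
    return rz @ ry @ rx


def _project(pts3d: np.ndarray, scale: float, center: np.ndarray) -> np.ndarray:
    """Orthographic projection to pixel coordinates (image y axis down)."""
    out = np.empty((pts3d.shape[0], 2))
    out[:, 0] = center[0] + scale * pts3d[:, 0]
    out[:, 1] = center[1] - scale * pts3d[:, 1]
    return out


def generate_pose_landmarks(
    pose: str,
    n: int,
    noise: str = "40cm_normal",
    seed: int = 0,
    scale: float = 60.0,
    center=(320.0, 240.0),
) -> list[LandmarkSet]:
    """Generate n landmark sets for one head-pose sub-class.

    With a nonzero noise preset each sample additionally gets a small
    random pose perturbation (sigma = 100 x jitter fraction, in degrees)
    and a random scale/translation, none of which affect the normalized
    tree; with ``noise="none"`` all n samples are identical.
    """
    if pose not in POSE_PRESETS:
        raise InputError(f"unknown pose preset: {pose!r}")
    if noise not in NOISE_PRESETS:
        raise InputError(f"unknown noise preset: {noise!r}")
    if n < 1:
        raise InputError("n must be >= 1")
    sigma_frac = NOISE_PRESETS[noise]
    template = face_template_3d()
    iod = float(np.linalg.norm(template[LEFT_EYE].mean(0) - template[RIGHT_EYE].mean(0)))
    yaw, pitch = POSE_PRESETS[pose]
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    out = []
    for _ in range(n):
        if sigma_frac > 0:
            dyaw, dpitch, droll = rng.normal(0.0, 100.0 * sigma_frac, size=3)
            s = scale * rng.uniform(0.9, 1.1)
            c = center + rng.uniform(-30.0, 30.0, size=2)
        else:
            dyaw = dpitch = droll = 0.0
            s, c = scale, center
        rot = (template @ _rotation(yaw + dyaw, pitch + dpitch, droll).T)
        pix = _project(rot, s, c)
        if sigma_frac > 0:
            pix = pix + rng.normal(0.0, sigma_frac * iod * s, size=pix.shape)
        out.append(LandmarkSet(pix))
    return out


def generate_pose_dataset(
    n_per_class: int, noise: str = "40cm_normal", seed: int = 0
) -> tuple[list[LandmarkSet], list[str]]:
    """Landmark sets for all 11 sub-classes with their labels."""
    sets: list[LandmarkSet] = []
    labels: list[str] = []
    for i, lab in enumerate(SUBCLASS_LABELS):
        sets.extend(generate_pose_landmarks(lab, n_per_class, noise, seed=seed + i))
        labels.extend([lab] * n_per_class)
    return sets, labels


def pose_trees(n_per_class: int, noise: str = "40cm_normal", seed: int = 0):
    """Convenience: the same dataset already converted to labeled trees."""
    sets, labels = generate_pose_dataset(n_per_class, noise, seed)
    trees = [build_face_tree(s, provenance=lab) for s, lab in zip(sets, labels)]
    return trees, labels


# ---------------------------------------------------------------------------
# session-log generation
# ---------------------------------------------------------------------------


@dataclass
class SessionScript:
    """Schedule and state-dynamics model for one synthetic attempt.

    The child-state Markov chain is sticky (``stay_prob`` on the diagonal,
    the remainder uniform).  For ``boost_frames`` frames after every robot
    action outset the transition row is mixed with a point mass on state 0
    with weight ``boost`` — the causal link the analysis tools measure;
    ``boost = 0`` is the null model.
    """

    n_frames: int = 600
    seed: int = 0
    stay_prob: float = 0.80
    boost: float = 0.6
    boost_frames: int = 6  # 2 s at 3 Hz
    event_rate: float = 0.02  # per-frame outset probability while inactive
    mean_duration: float = 9.0  # frames an action stays active
    blank_fraction: float = 0.15
    noise: str = "40cm_normal"
    start_state: int = 0

    def base_matrix(self) -> np.ndarray:
        m = np.full((9, 9), (1.0 - self.stay_prob) / 8.0)
        np.fill_diagonal(m, self.stay_prob)
        return m

    def boosted_matrix(self) -> np.ndarray:
        m = (1.0 - self.boost) * self.base_matrix()
        m[:, 0] += self.boost
        return m


def generate_conditional_frames(
    state_probs, n_active: int, modality: str = "Sound", seed: int = 0
) -> list[Frame]:
    """Frames whose states are drawn i.i.d. from a known conditional
    distribution while ``modality`` is active — the direct ground truth for
    histogram-recovery checks."""
    p = np.asarray(state_probs, dtype=float)
    if p.shape != (9,) or not np.isclose(p.sum(), 1.0):
        raise InputError("state_probs must be 9 probabilities summing to 1")
    if modality not in MODALITIES:
        raise InputError(f"unknown modality: {modality!r}")
    rng = np.random.default_rng(seed)
    states = rng.choice(9, size=n_active, p=p)
    t0 = pd.Timestamp("2021-01-01 10:00:00")
    frames = []
    for t, s in enumerate(states):
        f = Frame(timestamp=t0 + pd.Timedelta(seconds=t / 3.0), landmarks=np.zeros((68, 2)))
        if modality == "Animation":
            f.animation = "Default"
        else:
            setattr(f, modality.lower(), "yes")
        f.state = int(s)
        frames.append(f)
    return frames


@dataclass
class SessionResult:
    """A generated attempt plus its ground truth."""

    attempt: Attempt
    true_states: np.ndarray  # per frame, including blanked ones
    metadata: dict


def generate_session(script: SessionScript, attempt_id: str = "synthetic-attempt") -> SessionResult:
    """Emit one attempt of 3 Hz frames with known state dynamics."""
    rng = np.random.default_rng(script.seed)
    n = script.n_frames
    base = script.base_matrix()
    boosted = script.boosted_matrix()

    # robot-action schedules, one independent on/off chain per modality
    active = {m: np.zeros(n, dtype=bool) for m in MODALITIES}
    anim_value = np.array(["None"] * n, dtype=object)
    p_off = 1.0 / script.mean_duration
    for m in MODALITIES:
        on = False
        current = "None"
        for t in range(n):
            if not on and rng.random() < script.event_rate:
                on = True
                if m == "Animation":
                    current = str(rng.choice(ANIMATION_VALUES[1:]))
            elif on and rng.random() < p_off:
                on = False
                current = "None"
            active[m][t] = on
            if m == "Animation":
                anim_value[t] = current if on else "None"

    # any-modality outsets drive the state boost
    outset = np.zeros(n, dtype=bool)
    for m in MODALITIES:
        a = active[m]
        outset[1:] |= a[1:] & ~a[:-1]
        outset[0] |= a[0]

    states = np.empty(n, dtype=int)
    states[0] = script.start_state
    since_event = np.inf
    for t in range(1, n):
        since_event = 0 if outset[t - 1] else since_event + 1
        row = boosted[states[t - 1]] if since_event < script.boost_frames else base[states[t - 1]]
        states[t] = rng.choice(9, p=row)

    blank = rng.random(n) < script.blank_fraction
    t0 = pd.Timestamp("2021-01-01 10:00:00")
    frames = []
    for t in range(n):
        if blank[t]:
            lms = None
        else:
            lms = generate_pose_landmarks(
                STATE_TO_POSE[states[t]],
                1,
                script.noise,
                seed=int(rng.integers(0, 2**31 - 1)),
            )[0].points
        frames.append(
            Frame(
                timestamp=t0 + pd.Timedelta(seconds=t / 3.0),
                animation=str(anim_value[t]),
                sound="yes" if active["Sound"][t] else "no",
                leds="yes" if active["LEDs"][t] else "no",
                speaking="yes" if active["Speaking"][t] else "no",
                landmarks=lms,
            )
        )
    attempt = Attempt(attempt_id=attempt_id, frames=frames)
    meta = {
        "seed": script.seed,
        "boost": script.boost,
        "boost_frames": script.boost_frames,
        "stay_prob": script.stay_prob,
        "blank_fraction": script.blank_fraction,
        "noise": script.noise,
        "n_frames": n,
    }
    return SessionResult(attempt=attempt, true_states=states, metadata=meta)
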