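"""Synthetic multi-sensor daily-life recordings with ground-truth labels.

The generator emulates the statistical structure a gait/posture classifier
exploits in hemiparetic wearers: posture-dependent gravity orientation per
sensor, cadence-locked gait oscillation (fundamental plus one harmonic)
with attenuated amplitudes on the paretic side, barometric ramps during
stair bouts (quantized to the altimeter's 10-cm resolution), and smooth
orientation interpolation across labeled transition segments.

Sitting and standing differ only in orientation and micro-movement, and
per-bout orientation jitter is largest at the wrists — reproducing the
hardest real-world confusion (wrist-only posture discrimination) while
keeping chest and ankle cues informative.

The default cohort's activity schedule is calibrated so each session's
class-time shares match the study-scale distribution (lying 4.8 %,
sitting 20.2 %, standing 32.8 %, walking 19.5 %, stairs 6.5 %, the rest
transitions) to well within one percentage point.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np

from .recordings import (DEFAULT_SAMPLE_RATE_HZ, BARO_RESOLUTION_M,
                         LOCATIONS, LabelTrack, RecordingSession, SensorStream)

GRAVITY = 9.81

#: Valid adjacency between activity classes (undirected).
_ADJACENT = {frozenset(p) for p in
             [("lying", "sitting"), ("sitting", "standing"),
              ("standing", "walking"), ("standing", "stairs")]}

_TRANSITION_OF = {
    frozenset(("lying", "sitting")): "trans_lying_sit",
    frozenset(("sitting", "standing")): "trans_sit_stand",
    frozenset(("standing", "walking")): "trans_stand_walk",
    frozenset(("standing", "stairs")): "trans_stand_walk",
}

#: Mean transition durations (s), matching the study-scale bout statistics.
TRANSITION_MEANS_S = {"trans_lying_sit": 4.0, "trans_sit_stand": 2.7,
                      "trans_stand_walk": 4.7}

#: Class shares of total recording time (%), study-scale distribution.
ACTIVITY_SHARES_PCT = {"lying": 4.8, "sitting": 20.2, "standing": 32.8,
                       "walking": 19.5, "stairs": 6.5}

#: Base gravity direction per location and posture (unit vectors).
_BASE_ORIENTATIONS = {
    "chest": {"lying": (0.97, 0.0, 0.24), "sitting": (0.35, 0.0, 0.94),
              "standing": (0.0, 0.0, 1.0)},
    "wrist": {"lying": (0.50, 0.85, 0.20), "sitting": (0.45, 0.08, 0.89),
              "standing": (0.15, 0.10, 0.98)},
    "ankle": {"lying": (0.95, 0.10, 0.30), "sitting": (0.25, 0.0, 0.97),
              "standing": (0.0, 0.0, 1.0)},
}

#: Per-bout orientation jitter SD (degrees). Wrist orientation wanders
#: strongly within a posture (gesturing, desk work, eating), which is what
#: makes wrist-only posture discrimination hard in practice.
_ORIENTATION_JITTER_DEG = {"chest": 3.0, "wrist": 25.0, "ankle": 4.0}

DEFAULT_SEED = 20220926


@dataclasses.dataclass
class SubjectProfile:
    """Parameters shaping one synthetic subject's signals.

    cadence_hz is the stride (full gait cycle) rate; arm_swing_amp is the
    wrist gyro amplitude in deg/s; affected_attenuation in [0, 1]
    multiplies all limb amplitudes on the affected side (1 = symmetric).
    """

    subject_id: str
    affected_side: str
    cadence_hz: float = 0.8
    walk_speed_mps: float = 0.8
    arm_swing_amp: float = 25.0
    affected_attenuation: float = 0.5
    stair_rise_m: float = 0.17
    step_time_stairs_s: float = 1.0
    step_over_step: bool = True
    noise_sd: dict = dataclasses.field(
        default_factory=lambda: {"accel": 0.15, "gyro": 1.5, "baro": 0.03})
    posture_orientations: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.affected_attenuation <= 1.0:
            raise ValueError("affected_attenuation must lie in [0, 1]")
        if self.cadence_hz <= 0 or self.arm_swing_amp < 0:
            raise ValueError("rates and amplitudes must be non-negative")

    def orientation(self, location: str, posture: str) -> np.ndarray:
        group = location.split("_")[0]
        table = self.posture_orientations or _BASE_ORIENTATIONS
        key = posture if posture in ("lying", "sitting") else "standing"
        v = np.asarray(table[group][key], dtype=float)
        return v / np.linalg.norm(v)


@dataclasses.dataclass
class ActivityScript:
    """Ordered activity bouts (class, duration s); transitions are implicit."""

    bouts: list

    def __post_init__(self) -> None:
        if not self.bouts:
            raise ValueError("script must contain at least one bout")
        for cls, dur in self.bouts:
            if cls not in ACTIVITY_SHARES_PCT:
                raise ValueError(f"unknown activity class {cls!r}")
            if dur <= 0:
                raise ValueError("bout durations must be positive")
        for (a, _), (b, _) in zip(self.bouts, self.bouts[1:]):
            if frozenset((a, b)) not in _ADJACENT:
                raise ValueError(f"invalid adjacency {a} -> {b}")

    def class_seconds(self) -> dict:
        totals: dict = {}
        for cls, dur in self.bouts:
            totals[cls] = totals.get(cls, 0.0) + dur
        return totals


def _jitter_direction(v: np.ndarray, sd_deg: float, rng: np.random.Generator
                      ) -> np.ndarray:
    """Randomly tilt a unit vector by ~sd_deg degrees."""
    perturb = rng.normal(0.0, np.tan(np.radians(sd_deg)), size=3)
    perturb -= perturb @ v * v  # tangent component only
    out = v + perturb
    return out / np.linalg.norm(out)


def _segment_plan(script: ActivityScript, fs: float, rng: np.random.Generator):
    """Expand a script into (label, n_samples, bout_index) segments.

    Transition segments take their class's mean duration jittered by +-5 %.
    ``bout_index`` points into script.bouts for activity segments and is
    (i, i+1) for the transition between bouts i and i+1.
    """
    segments = []
    for i, (cls, dur) in enumerate(script.bouts):
        if i > 0:
            prev = script.bouts[i - 1][0]
            tlabel = _TRANSITION_OF[frozenset((prev, cls))]
            tdur = TRANSITION_MEANS_S[tlabel] * (1 + rng.uniform(-0.05, 0.05))
            segments.append((tlabel, max(1, int(round(tdur * fs))), (i - 1, i)))
        segments.append((cls, max(1, int(round(dur * fs))), i))
    return segments


def generate_session(profile: SubjectProfile, script: ActivityScript,
                     seed: int, fs: float = DEFAULT_SAMPLE_RATE_HZ,
                     clinical: dict | None = None) -> RecordingSession:
    """Synthesize one subject's five-sensor 50 Hz recording session.

    The emitted label track is exact ground truth; identical inputs and
    seed give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    segments = _segment_plan(script, fs, rng)
    n_total = sum(n for _, n, _ in segments)
    labels = np.empty(n_total, dtype=object)
    seg_bounds = []
    pos = 0
    for label, n, ref in segments:
        labels[pos:pos + n] = label
        seg_bounds.append((label, pos, pos + n, ref))
        pos += n

    # --- shared barometric altitude (stairs ramps, alternating direction)
    baro_base = np.empty(n_total)
    level = 0.0
    stairs_dir = 1.0
    for label, a, b, ref in seg_bounds:
        n = b - a
        if label == "stairs":
            n_steps = max(1, int((n / fs) / profile.step_time_stairs_s))
            rise = stairs_dir * profile.stair_rise_m * n_steps
            baro_base[a:b] = level + np.linspace(0.0, rise, n, endpoint=False)
            level += rise
            stairs_dir = -stairs_dir
        else:
            baro_base[a:b] = level

    # --- per-bout jittered gravity orientations, per location
    session_streams = {}
    for loc in LOCATIONS:
        group = loc.split("_")[0]
        jitter_sd = _ORIENTATION_JITTER_DEG[group]
        bout_orient = {}
        for i, (cls, _) in enumerate(script.bouts):
            base = profile.orientation(loc, cls)
            bout_orient[i] = _jitter_direction(base, jitter_sd, rng)

        grav = np.empty((n_total, 3))
        for label, a, b, ref in seg_bounds:
            if isinstance(ref, tuple):  # transition: interpolate neighbors
                v0, v1 = bout_orient[ref[0]], bout_orient[ref[1]]
                w = np.linspace(0.0, 1.0, b - a)[:, None]
                v = (1 - w) * v0 + w * v1
                grav[a:b] = v / np.linalg.norm(v, axis=1, keepdims=True)
            else:
                grav[a:b] = bout_orient[ref]

        accel = GRAVITY * grav + rng.normal(0.0, profile.noise_sd["accel"],
                                            (n_total, 3))
        gyro = rng.normal(0.0, profile.noise_sd["gyro"], (n_total, 3))

        side = loc.split("_")[-1]
        atten = (profile.affected_attenuation
                 if side == profile.affected_side else 1.0)

        for label, a, b, ref in seg_bounds:
            n = b - a
            t = np.arange(n) / fs
            if label in ("walking", "stairs"):
                f = profile.cadence_hz
                if label == "stairs":
                    f = 1.0 / max(profile.step_time_stairs_s, 1e-6)
                    if not profile.step_over_step:
                        f *= 0.7  # step-by-step: slower, pausing pattern
                phi = rng.uniform(0, 2 * np.pi)
                fund = np.sin(2 * np.pi * f * t + phi)
                harm = np.sin(4 * np.pi * f * t + phi + rng.uniform(0, np.pi))
                if group == "ankle":
                    amp_a = (3.0 if label == "walking" else 2.5) * atten
                    accel[a:b, 0] += amp_a * fund
                    accel[a:b, 2] += 0.6 * amp_a * harm
                    gyro[a:b, 1] += 60.0 * atten * fund
                    gyro[a:b, 0] += 20.0 * atten * harm
                elif group == "wrist":
                    amp_w = profile.arm_swing_amp * atten
                    gyro[a:b, 1] += amp_w * fund
                    accel[a:b, 0] += 0.8 * atten * fund
                else:  # chest: vertical bounce at step frequency
                    accel[a:b, 2] += 0.6 * harm
                    gyro[a:b, 0] += 8.0 * fund
            elif label == "standing" and group in ("chest", "ankle"):
                # postural sway is a trunk/lower-limb cue, absent at wrists
                accel[a:b, 0] += 0.12 * np.sin(2 * np.pi * 0.4 * t
                                               + rng.uniform(0, 2 * np.pi))
            elif isinstance(ref, tuple):  # transition movement burst
                bump = np.sin(np.pi * np.arange(n) / max(n - 1, 1)) ** 2
                gyro[a:b, 0] += 30.0 * bump
                accel[a:b, 1] += 0.5 * bump

        baro = baro_base + rng.normal(0.0, profile.noise_sd["baro"], n_total)
        baro = np.round(baro / BARO_RESOLUTION_M) * BARO_RESOLUTION_M
        session_streams[loc] = SensorStream(location=loc, accel=accel,
                                            gyro=gyro, baro_alt=baro,
                                            sample_rate_hz=fs)

    return RecordingSession(
        subject_id=profile.subject_id,
        affected_side=profile.affected_side,
        streams=session_streams,
        label_track=LabelTrack(labels=labels, sample_rate_hz=fs),
        clinical=clinical)


# ---------------------------------------------------------------------------
# Default cohort (study-scale class-time calibration)

#: One ~9-minute schedule block; tiled and scaled to the session length.
#: Chain respects the adjacency graph; bout counts were chosen so the
#: implied transition-time split is close to the study-scale one.
_TEMPLATE = ["sitting", "lying", "sitting", "standing", "walking", "standing",
             "sitting", "standing", "stairs", "standing", "walking", "standing",
             "sitting", "standing", "walking", "standing", "stairs", "standing",
             "sitting", "standing", "walking", "standing"]
_TEMPLATE_SECONDS = 540.0


def build_script(minutes: float, rng: np.random.Generator) -> ActivityScript:
    """Activity schedule whose class-time shares match the calibration.

    Transition time is fixed by the chain's adjacency counts times the
    mean transition durations; the remaining time is split across activity
    classes proportionally to their target shares, with +-15 % per-bout
    jitter that is renormalized within each class, so class totals are
    exact in seconds.
    """
    total_s = minutes * 60.0
    n_rep = max(1, int(round(total_s / _TEMPLATE_SECONDS)))
    chain = _TEMPLATE * n_rep
    trans_total = sum(
        TRANSITION_MEANS_S[_TRANSITION_OF[frozenset((a, b))]]
        for a, b in zip(chain, chain[1:]))
    budget = total_s - trans_total
    if budget <= 0:
        raise ValueError("session too short for the schedule template")
    share_sum = sum(ACTIVITY_SHARES_PCT.values())
    counts = Counter(chain)
    class_total = {c: ACTIVITY_SHARES_PCT[c] / share_sum * budget
                   for c in counts}
    jitter = {c: rng.uniform(0.85, 1.15, counts[c]) for c in counts}
    for c in jitter:  # renormalize: class totals stay exact
        jitter[c] *= counts[c] / jitter[c].sum()
    seen: Counter = Counter()
    bouts = []
    for cls in chain:
        k = seen[cls]
        seen[cls] += 1
        bouts.append((cls, class_total[cls] / counts[cls] * jitter[cls][k]))
    return ActivityScript(bouts=bouts)


def default_cohort(n_subjects: int, seed: int = DEFAULT_SEED,
                   minutes: float = 27.0) -> list[RecordingSession]:
    """Seeded cohort of labeled sessions with varied subject profiles.

    Defaults emulate the study scale: 14 subjects at ~27 min each. Profile
    variation covers cadence, arm-swing amplitude, paretic-side
    attenuation and stair timing; clinical scores are drawn within the
    study's reported ranges, loosely tied to the attenuation so that
    score-vs-performance correlations are exercisable.
    """
    if n_subjects < 3:
        raise ValueError("cohort needs at least 3 subjects")
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_subjects):
        atten = rng.uniform(0.35, 0.70)
        profile = SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            affected_side="left" if i % 2 == 0 else "right",
            cadence_hz=rng.uniform(0.6, 1.0),
            walk_speed_mps=0.3 + 1.1 * atten + rng.normal(0, 0.05),
            arm_swing_amp=rng.uniform(18.0, 32.0),
            affected_attenuation=atten,
            step_time_stairs_s=rng.uniform(0.9, 1.3),
            step_over_step=bool(rng.uniform() < 0.5),
        )
        clinical = {
            "bbs": float(np.clip(round(30 + 40 * atten + rng.normal(0, 3)),
                                 35, 56)),
            "walk_speed_10mwt": float(np.clip(profile.walk_speed_mps, 0.3, 1.4)),
            "tug_s": float(np.clip(60 - 60 * atten + rng.normal(0, 4),
                                   10.8, 68.6)),
            "fac": float(rng.integers(3, 6)),
        }
        script = build_script(minutes, rng)
        child_seed = int(rng.integers(0, 2 ** 31 - 1))
        sessions.append(generate_session(profile, script, seed=child_seed,
                                         clinical=clinical))
    return sessions


def class_fractions(session: RecordingSession) -> dict:
    """Fraction of label-track samples per label (in %)."""
    labels, counts = np.unique(session.label_track.labels.astype(str),
                               return_counts=True)
    total = counts.sum()
    return {lab: 100.0 * c / total for lab, c in zip(labels, counts)}
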