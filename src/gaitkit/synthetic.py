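"""Parametric 2D gait simulator.

Generates COCO-17 tracklets with per-identity kinematic signatures so the
whole curation/training/evaluation pipeline can be exercised without
external data. The simulator is deliberately sinusoidal rather than
biomechanically exact: what the pipeline needs is identity-discriminative,
filter-exercising structure, not anatomical fidelity.

Each identity owns a parameter vector (cadence, stride/knee/arm swing
amplitudes, per-limb phase jitter around left/right antiphase, relative
bone lengths, vertical bounce). A scene places that walker at a viewpoint
angle, scales it to pixels, adds temporally smoothed Gaussian joint noise
and draws per-joint confidences. Three modes exist:

* ``walking`` — full gait kinematics (passes the default filters);
* ``standing`` — all oscillation amplitudes zero (fails the velocity
  filter);
* ``low-confidence`` — walking, but a contiguous block of >= 4 frames has
  both ankle confidences below 0.5 (fails the feet-visibility filter).

Viewpoint model: joints live on a lateral (body-width) and a sagittal
(walking-direction) axis. The image x is ``f(theta) * lateral +
sin(theta) * sagittal`` where f maps ``cos(theta)`` into ``[f_min, 1]``;
a strict ``cos(theta)`` would collapse the shoulder width at 90 degrees
and with it the normalization denominator. The vertical axis is
unaffected by the viewpoint. A walking-direction drift translates the
whole body across the frame; normalization removes it again.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import coco
from .io import Tracklet, TrackletDataset

MODES = ("walking", "standing", "low-confidence")


@dataclass
class GaitIdentityParams:
    """Kinematic signature of one synthetic walker (normalized units:
    torso length = 1, shoulder width = 1)."""

    cadence: float                 # strides / second
    stride_amplitude: float        # ankle sagittal swing half-range
    knee_amplitude: float          # knee swing half-range
    arm_amplitude: float           # wrist counter-swing half-range
    phase_left: float              # left-leg phase offset (rad)
    phase_right: float             # right-leg phase = left + pi + jitter
    vertical_bounce_amplitude: float
    #: relative bone lengths (torso = 1) with identity jitter
    leg_length: float = 1.8
    arm_length: float = 0.95
    hip_halfwidth: float = 0.25
    head_height: float = 0.33
    lateral_sway_ratio: float = 0.35  # lateral ankle sway as fraction of stride

    def __post_init__(self) -> None:
        if min(self.stride_amplitude, self.knee_amplitude, self.arm_amplitude,
               self.vertical_bounce_amplitude) < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class PopulationConfig:
    """Sampling distributions for identity parameters."""

    cadence_mean: float = 0.9
    cadence_sd: float = 0.1
    cadence_min: float = 0.5
    stride_mean: float = 0.35
    stride_sd: float = 0.05
    knee_mean: float = 0.18
    knee_sd: float = 0.04
    arm_mean: float = 0.25
    arm_sd: float = 0.05
    phase_jitter_sd: float = 0.1
    bounce_mean: float = 0.05
    bounce_sd: float = 0.015
    proportion_jitter: float = 0.05   # +-5% bone-length jitter


@dataclass
class SceneParams:
    """Rendering conditions for one tracklet."""

    viewpoint_angle: float = 0.0      # degrees
    fps: float = 24.0
    noise_sd: float = 0.01            # normalized units
    mode: str = "walking"
    min_foreshorten: float = 0.35     # f_min of the viewpoint model
    scale_px: float = 150.0           # torso length in pixels
    base_confidence: float = 0.85
    confidence_sd: float = 0.05
    walking_speed: float = 0.04       # drift, normalized units / frame

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


def sample_identity(rng: np.random.Generator,
                    pop: PopulationConfig | None = None) -> GaitIdentityParams:
    """Draw one identity from the population distributions (seeded)."""
    pop = pop or PopulationConfig()
    cadence = rng.normal(pop.cadence_mean, pop.cadence_sd)
    while cadence <= pop.cadence_min:
        cadence = rng.normal(pop.cadence_mean, pop.cadence_sd)
    jit = lambda: 1.0 + rng.uniform(-pop.proportion_jitter, pop.proportion_jitter)
    return GaitIdentityParams(
        cadence=cadence,
        stride_amplitude=max(0.05, rng.normal(pop.stride_mean, pop.stride_sd)),
        knee_amplitude=max(0.02, rng.normal(pop.knee_mean, pop.knee_sd)),
        arm_amplitude=max(0.02, rng.normal(pop.arm_mean, pop.arm_sd)),
        phase_left=rng.uniform(0, 2 * np.pi),
        phase_right=np.pi + rng.normal(0.0, pop.phase_jitter_sd),
        vertical_bounce_amplitude=max(0.0, rng.normal(pop.bounce_mean, pop.bounce_sd)),
        leg_length=1.8 * jit(),
        arm_length=0.95 * jit(),
        hip_halfwidth=0.25 * jit(),
        head_height=0.33 * jit(),
    )


def _skeleton_tracks(ident: GaitIdentityParams, scene: SceneParams,
                     n_frames: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free (lateral, sagittal, vertical) trajectories, each
    (n_frames, 17)."""
    J = coco.JOINT_INDEX
    t = np.arange(n_frames) / scene.fps
    walking = scene.mode != "standing"
    amp = 1.0 if walking else 0.0

    phi_l = 2 * np.pi * ident.cadence * t + ident.phase_left
    # phase_right already contains the pi antiphase plus identity jitter
    phi_r = phi_l + ident.phase_right

    lat = np.zeros((n_frames, coco.N_JOINTS))
    sag = np.zeros((n_frames, coco.N_JOINTS))
    vert = np.zeros((n_frames, coco.N_JOINTS))

    def place(j, lateral, sagittal, vertical):
        lat[:, j] = lateral
        sag[:, j] = sagittal
        vert[:, j] = vertical

    hw = ident.hip_halfwidth
    leg = ident.leg_length
    knee_y, ankle_y = 0.5 * leg, leg
    head = ident.head_height

    bounce = amp * ident.vertical_bounce_amplitude * np.sin(2 * phi_l)

    # head and torso (static in the body frame apart from the bounce)
    place(J["nose"], 0.0, 0.0, -1.0 - head)
    place(J["left_eye"], +0.10, 0.02, -1.0 - head - 0.08)
    place(J["right_eye"], -0.10, 0.02, -1.0 - head - 0.08)
    place(J["left_ear"], +0.18, -0.02, -1.0 - head)
    place(J["right_ear"], -0.18, -0.02, -1.0 - head)
    place(J["left_shoulder"], +0.5, 0.0, -1.0)
    place(J["right_shoulder"], -0.5, 0.0, -1.0)
    place(J["left_hip"], +hw, 0.0, 0.0)
    place(J["right_hip"], -hw, 0.0, 0.0)

    # legs: sagittal stride with lateral sway and a vertical lift component
    for side, phi in (("left", phi_l), ("right", phi_r)):
        stride = amp * ident.stride_amplitude * np.sin(phi)
        sway = amp * ident.lateral_sway_ratio * ident.stride_amplitude * np.sin(phi)
        knee = amp * ident.knee_amplitude * np.sin(phi)
        lift = amp * 0.5 * ident.knee_amplitude * np.sin(phi + 0.5 * np.pi)
        s = +1 if side == "left" else -1
        place(J[f"{side}_knee"], s * hw + 0.6 * sway, knee, knee_y - 0.5 * lift)
        place(J[f"{side}_ankle"], s * hw + sway, stride, ankle_y - lift)

    # arms counter-swing: the left arm follows the right leg
    for side, phi in (("left", phi_r), ("right", phi_l)):
        swing = amp * ident.arm_amplitude * np.sin(phi)
        s = +1 if side == "left" else -1
        place(J[f"{side}_elbow"], s * 0.55, 0.5 * swing, -1.0 + 0.45 * ident.arm_length)
        place(J[f"{side}_wrist"], s * 0.60, swing, -1.0 + 0.95 * ident.arm_length)

    vert += bounce[:, None]
    if walking:
        sag += (scene.walking_speed * scene.fps * t)[:, None]  # drift across frame
    return lat, sag, vert


def _smoothed_noise(rng: np.random.Generator, shape: tuple, sd: float) -> np.ndarray:
    """Temporally correlated jitter: white noise smoothed with a 9-frame
    moving average along axis 0. Pose-estimator jitter is not white, and
    white noise of the default magnitude would register as walking: for a
    moving average of width k the frame-to-frame difference has standard
    deviation sd*sqrt(2)/k. The window must keep the standing-mode mean leg
    speed clearly below the 0.01 velocity threshold even at the most
    foreshortened viewpoint, where normalization inflates x-noise by
    1/f_min and jitter of the per-frame shoulder/torso denominators
    propagates to every joint; k=9 (about a third of a second at 24 fps)
    leaves a comfortable margin on both sides of the threshold."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.normal(0.0, sd, size=shape)
    kernel = np.ones(9) / 9.0
    out = np.empty_like(white)
    flat = white.reshape(shape[0], -1)
    of = out.reshape(shape[0], -1)
    for c in range(flat.shape[1]):
        of[:, c] = np.convolve(flat[:, c], kernel, mode="same")
    return out


def synthesize_tracklet(ident: GaitIdentityParams, scene: SceneParams,
                        n_frames: int, rng: np.random.Generator,
                        track_id: str = "synthetic") -> Tracklet:
    """Render one tracklet of ``n_frames`` frames in image pixels."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    lat, sag, vert = _skeleton_tracks(ident, scene, n_frames)

    theta = np.deg2rad(scene.viewpoint_angle)
    f = scene.min_foreshorten + (1 - scene.min_foreshorten) * abs(np.cos(theta))
    x = f * lat + np.sin(theta) * sag
    y = vert

    x = x + _smoothed_noise(rng, x.shape, scene.noise_sd)
    y = y + _smoothed_noise(rng, y.shape, scene.noise_sd)

    # to image pixels: y-down already (vertical grows downward from neck at -1)
    offset = rng.uniform(200, 800, size=2)
    px = x * scene.scale_px + offset[0]
    py = y * scene.scale_px + offset[1]

    conf = np.clip(rng.normal(scene.base_confidence, scene.confidence_sd,
                              size=(n_frames, coco.N_JOINTS)), 0.0, 1.0)
    if scene.mode == "low-confidence":
        block = int(rng.integers(4, max(5, n_frames // 4) + 1))
        start = int(rng.integers(0, n_frames - block + 1))
        for j in coco.FEET:
            conf[start:start + block, j] = rng.uniform(0.1, 0.45, size=block)

    data = np.stack([px, py, conf], axis=2)
    return Tracklet(track_id, data, fps=scene.fps,
                    meta={"mode": scene.mode, "angle": scene.viewpoint_angle})


#: first failing filter expected for each mode (None = passes everything)
EXPECTED_VERDICT = {"walking": "pass", "standing": "velocity",
                    "low-confidence": "feet_visibility"}


def make_benchmark(n_ids: int, runs_per_id: int, angles=(0.0, 90.0),
                   rng: np.random.Generator | None = None,
                   length_mean: float = 108.0, length_sd: float = 20.0,
                   length_range: tuple = (60, 180),
                   standing_fraction: float = 0.0,
                   low_conf_fraction: float = 0.0,
                   pop: PopulationConfig | None = None,
                   noise_sd: float = 0.01,
                   ) -> tuple[TrackletDataset, pd.DataFrame]:
    """Generate a labeled multi-run, multi-view benchmark.

    Per identity, ``runs_per_id`` tracklets are produced with viewpoint
    angles assigned round-robin and lengths drawn around a mean of 108
    frames. ``standing_fraction`` / ``low_conf_fraction`` of all tracklets
    (rounded) are re-rendered as contaminants, chosen at random, with their
    expected filter verdict recorded in the ground-truth table.

    Returns the dataset and a table with columns
    (track_id, identity, run, angle, mode, expected_verdict).
    """
    if n_ids < 2:
        raise ValueError("need at least 2 identities")
    rng = rng or np.random.default_rng(0)
    identities = [sample_identity(rng, pop) for _ in range(n_ids)]

    n_total = n_ids * runs_per_id
    n_standing = int(round(standing_fraction * n_total))
    n_lowconf = int(round(low_conf_fraction * n_total))
    modes = ["walking"] * n_total
    contaminated = rng.choice(n_total, size=n_standing + n_lowconf, replace=False)
    for k in contaminated[:n_standing]:
        modes[k] = "standing"
    for k in contaminated[n_standing:]:
        modes[k] = "low-confidence"

    tracklets, rows = [], []
    flat = 0
    for i, ident in enumerate(identities):
        for r in range(runs_per_id):
            angle = float(angles[r % len(angles)])
            mode = modes[flat]
            n_frames = int(np.clip(round(rng.normal(length_mean, length_sd)),
                                   *length_range))
            scene = SceneParams(viewpoint_angle=angle, mode=mode, noise_sd=noise_sd)
            tid = f"id{i:03d}_run{r}"
            t = synthesize_tracklet(ident, scene, n_frames, rng, track_id=tid)
            t.meta.update(identity=f"id{i:03d}", run=r)
            tracklets.append(t)
            rows.append({"track_id": tid, "identity": f"id{i:03d}", "run": r,
                         "angle": angle, "mode": mode,
                         "expected_verdict": EXPECTED_VERDICT[mode]})
            flat += 1
    table = pd.DataFrame(rows)
    return TrackletDataset(tracklets, {"generator": "gaitkit.synthetic"}), table
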