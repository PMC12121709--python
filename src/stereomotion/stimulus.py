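"""Dot-field engine for binocular 3D-motion stimuli.

Generates per-eye retinal dot trajectories for a field of dots moving
toward or away from the observer inside an annular aperture.  Motion in
depth can be signalled three ways:

* ``stereoscopic`` — changing binocular disparity plus interocular
  velocity differences: each eye's dot images translate horizontally at
  the per-eye retinal speed, in opposite directions in the two eyes, so
  disparity changes at twice the monocular speed.  Dot size is constant.
* ``perspectiveL`` / ``perspectiveR`` — a single eye views dots whose
  world depth changes; looming size change, density change and radial
  optic flow follow from perspective projection.  The other eye sees a
  blank field.
* ``combined`` — both eyes view the perspective-projected stimulus, so
  stereoscopic and perspective cues co-occur.

A 90-deg retinal rotation of any condition preserves every dot's
monocular speed exactly; for the stereoscopic stimulus it turns the
toward/away percept into transparent vertical 2D motion (one eye sees
upward, the other downward motion).

Conventions (configurable where noted): azimuth positive rightward,
elevation positive upward, degrees; polar angle counter-clockwise from
the right horizontal meridian in (-180, 180]; disparity = right minus
left azimuth; *toward* motion makes disparity more crossed (more
negative), i.e. the left-eye image moves rightward.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEFT, RIGHT = 0, 1
EYE_NAMES = ("left", "right")

CONDITION_NAMES = ("stereoscopic", "perspectiveL", "perspectiveR", "combined")
DIRECTIONS = ("toward", "away")

#: columns of the long-format frame table
FRAME_TABLE_COLUMNS = (
    "frame", "dot", "eye", "azimuth_deg", "elevation_deg", "diameter_deg", "polarity",
)


@dataclass(frozen=True)
class ViewingGeometry:
    """Observer/display geometry, lengths in mm."""

    viewing_distance: float = 880.0
    interocular_distance: float = 63.0
    screen_width: float = 385.0

    def __post_init__(self) -> None:
        if min(self.viewing_distance, self.interocular_distance, self.screen_width) <= 0:
            raise ValueError("all geometry lengths must be positive")
        if self.interocular_distance >= self.viewing_distance:
            raise ValueError("interocular distance must be smaller than viewing distance")

    @property
    def eye_x(self) -> tuple[float, float]:
        """Horizontal eye positions (left, right), mm from the cyclopean axis."""
        half = self.interocular_distance / 2.0
        return (-half, half)


@dataclass(frozen=True)
class Aperture:
    """Annular aperture, radii in degrees of visual angle."""

    outer_radius: float = 8.0
    inner_radius: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("require 0 < inner_radius < outer_radius")

    def contains(self, ecc: np.ndarray) -> np.ndarray:
        return (ecc >= self.inner_radius) & (ecc <= self.outer_radius)


@dataclass(frozen=True)
class MotionParams:
    """Kinematics of the motion-in-depth stimulus.

    ``per_eye_retinal_speed`` governs stereoscopic frames (retinal units
    are authoritative there); ``world_speed`` governs perspective and
    combined frames.  The two printed speeds are not mutually derivable
    from the viewing geometry, so both are carried explicitly.
    """

    world_speed: float = 51.83          # mm/s
    per_eye_retinal_speed: float = 1.2  # deg/s
    disparity_rate: float = 2.4         # deg/s, = 2 x per-eye speed
    trial_duration: float = 1.0         # s
    frame_rate: float = 120.0           # Hz

    def __post_init__(self) -> None:
        if not np.isclose(self.disparity_rate, 2 * self.per_eye_retinal_speed):
            raise ValueError("disparity_rate must equal 2 x per_eye_retinal_speed")


@dataclass(frozen=True)
class CueCondition:
    """A cue condition x motion direction cell of the design."""

    name: str
    direction: str = "toward"
    rotated: bool = False

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise ValueError(f"unknown condition {self.name!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def presented_eyes(self) -> tuple[bool, bool]:
        if self.name == "perspectiveL":
            return (True, False)
        if self.name == "perspectiveR":
            return (False, True)
        return (True, True)


@dataclass
class DotField:
    """State of the dot field on one frame.

    Retinal coordinates are stored per eye as ``(2, n)`` arrays indexed
    by ``LEFT``/``RIGHT``; entries of non-presented eyes are NaN.  World
    coordinates are mm, with z the distance from the observer along the
    line of sight (z > 0 in front of the eyes).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    polarity: np.ndarray           # +1 white, -1 black
    azimuth: np.ndarray            # (2, n) deg
    elevation: np.ndarray          # (2, n) deg
    diameter: np.ndarray           # (2, n) deg
    presented: tuple[bool, bool]
    aperture: Aperture
    geometry: ViewingGeometry
    dot_diameter_mm: float
    rng: np.random.Generator = field(repr=False, default_factory=np.random.default_rng)

    @property
    def n_dots(self) -> int:
        return int(self.x.size)

    def copy(self) -> "DotField":
        return replace(
            self,
            x=self.x.copy(), y=self.y.copy(), z=self.z.copy(),
            polarity=self.polarity.copy(),
            azimuth=self.azimuth.copy(), elevation=self.elevation.copy(),
            diameter=self.diameter.copy(),
        )

    def cyclopean(self) -> tuple[np.ndarray, np.ndarray]:
        """Cyclopean (azimuth, elevation): mean over presented eyes."""
        mask = np.array(self.presented)
        if not mask.any():
            raise ValueError("no presented eye")
        az = np.nanmean(self.azimuth[mask], axis=0)
        el = np.nanmean(self.elevation[mask], axis=0)
        return az, el

    def cyclopean_eccentricity(self) -> np.ndarray:
        az, el = self.cyclopean()
        return np.hypot(az, el)


def _sample_annulus(rng: np.random.Generator, n: int, aperture: Aperture):
    """Uniform-over-area sample of (azimuth, elevation) in the annulus."""
    r = np.sqrt(rng.uniform(aperture.inner_radius**2, aperture.outer_radius**2, n))
    theta = rng.uniform(0.0, 2 * np.pi, n)
    return r * np.cos(theta), r * np.sin(theta)


def _project_eye(x, y, z, eye_x: float, z0: float):
    """Retinal (azimuth, elevation) of world points for one eye.

    Angles are measured from the eye's fixation direction (fixation at
    (0, 0, z0)), so a fixation-plane midline dot has azimuth ~ x/z0.
    """
    az = np.degrees(np.arctan2(x - eye_x, z) - np.arctan2(-eye_x, z0))
    el = np.degrees(np.arctan2(y, z))
    return az, el


def _angular_diameter(dot_mm: float, z) -> np.ndarray:
    """Angular size of a dot at perpendicular distance z (screen-plane projection)."""
    return 2.0 * np.degrees(np.arctan2(dot_mm / 2.0, z))


def _recompute_retina(fld: DotField) -> None:
    """Refresh per-eye retinal coordinates from world state (in place)."""
    z0 = fld.geometry.viewing_distance
    for eye, eye_x in zip((LEFT, RIGHT), fld.geometry.eye_x):
        if fld.presented[eye]:
            az, el = _project_eye(fld.x, fld.y, fld.z, eye_x, z0)
            fld.azimuth[eye] = az
            fld.elevation[eye] = el
            fld.diameter[eye] = _angular_diameter(fld.dot_diameter_mm, fld.z)
        else:
            fld.azimuth[eye] = np.nan
            fld.elevation[eye] = np.nan
            fld.diameter[eye] = np.nan


def make_dot_field(
    n_dots: int,
    aperture: Aperture = Aperture(),
    seed: int | None = None,
    *,
    geometry: ViewingGeometry = ViewingGeometry(),
    dot_diameter_deg: float = 0.16,
    presented: tuple[bool, bool] = (True, True),
    rng: np.random.Generator | None = None,
) -> DotField:
    """Create a fresh dot field on the fixation plane.

    Dots are uniform over the annulus area, polarity alternates
    black/white, and the angular diameter at the fixation plane equals
    ``dot_diameter_deg``.
    """
    if n_dots < 0:
        raise ValueError("n_dots must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    z0 = geometry.viewing_distance
    az, el = _sample_annulus(rng, n_dots, aperture)
    x = z0 * np.tan(np.radians(az))
    y = z0 * np.tan(np.radians(el))
    z = np.full(n_dots, z0)
    polarity = np.where(np.arange(n_dots) % 2 == 0, 1, -1).astype(np.int8)
    dot_mm = 2.0 * z0 * np.tan(np.radians(dot_diameter_deg / 2.0))
    fld = DotField(
        x=x, y=y, z=z, polarity=polarity,
        azimuth=np.empty((2, n_dots)), elevation=np.empty((2, n_dots)),
        diameter=np.empty((2, n_dots)),
        presented=presented, aperture=aperture, geometry=geometry,
        dot_diameter_mm=dot_mm, rng=rng,
    )
    _recompute_retina(fld)
    return fld


def disparity(left_azimuth, right_azimuth):
    """Binocular disparity, deg: right minus left azimuth (negative = crossed/near)."""
    return np.asarray(right_azimuth, float) - np.asarray(left_azimuth, float)


def _direction_sign(direction: str) -> int:
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    return 1 if direction == "toward" else -1


def advance_stereoscopic(
    fld: DotField, direction: str, dt: float, params: MotionParams = MotionParams()
) -> DotField:
    """Advance one stereoscopic-cue step: opposite horizontal drift in the two eyes.

    Toward motion drives disparity more crossed: the left-eye image
    moves rightward and the right-eye image leftward.  Elevation and
    angular diameter are unchanged.  Dots whose cyclopean eccentricity
    leaves the aperture are redrawn uniformly inside it with zero
    disparity (fresh phase).
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    out = fld.copy()
    s = _direction_sign(direction)
    step = params.per_eye_retinal_speed * dt
    out.azimuth[LEFT] += s * step
    out.azimuth[RIGHT] -= s * step
    _reseed_escaped(out, keep_depth=True)
    return out


def advance_perspective(
    fld: DotField,
    direction: str,
    dt: float,
    params: MotionParams = MotionParams(),
    geometry: ViewingGeometry | None = None,
    eye: str = "left",
) -> DotField:
    """Advance one perspective-cue step: depth change + projective update.

    ``eye`` is ``"left"``/``"right"`` for the monocular perspective
    conditions (the other eye is blanked) or ``"both"`` for the
    combined-cue condition.  Toward motion decreases z; retinal
    position and angular diameter follow from perspective projection.
    A dot crossing the eye plane (z <= 0) is re-seeded at far depth and
    the event is logged.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if eye not in ("left", "right", "both"):
        raise ValueError("eye must be 'left', 'right' or 'both'")
    out = fld.copy()
    if geometry is not None and geometry != out.geometry:
        out.geometry = geometry
    out.presented = {
        "left": (True, False), "right": (False, True), "both": (True, True),
    }[eye]
    s = _direction_sign(direction)
    out.z = out.z - s * params.world_speed * dt

    crossed = out.z <= 0
    if crossed.any():
        logger.warning("%d dot(s) crossed the eye plane; re-seeded at far depth",
                       int(crossed.sum()))
        far_z = out.geometry.viewing_distance + params.world_speed * params.trial_duration
        az, el = _sample_annulus(out.rng, int(crossed.sum()), out.aperture)
        out.z[crossed] = far_z
        out.x[crossed] = far_z * np.tan(np.radians(az))
        out.y[crossed] = far_z * np.tan(np.radians(el))

    _recompute_retina(out)
    _reseed_escaped(out, keep_depth=False)
    return out


def _reseed_escaped(fld: DotField, keep_depth: bool) -> None:
    """Redraw dots whose cyclopean eccentricity left the annulus (in place)."""
    ecc = fld.cyclopean_eccentricity()
    bad = ~fld.aperture.contains(ecc)
    if not bad.any():
        return
    n_bad = int(bad.sum())
    az, el = _sample_annulus(fld.rng, n_bad, fld.aperture)
    if keep_depth:
        # stereoscopic frames live in retinal coordinates: reset both eyes
        # to the new cyclopean position (zero disparity) at fixation depth
        z0 = fld.geometry.viewing_distance
        fld.z[bad] = z0
        fld.x[bad] = z0 * np.tan(np.radians(az))
        fld.y[bad] = z0 * np.tan(np.radians(el))
        for eye in (LEFT, RIGHT):
            if fld.presented[eye]:
                fld.azimuth[eye, bad] = az
                fld.elevation[eye, bad] = el
                fld.diameter[eye, bad] = _angular_diameter(fld.dot_diameter_mm, fld.z[bad])
    else:
        z = fld.z[bad]
        fld.x[bad] = z * np.tan(np.radians(az))
        fld.y[bad] = z * np.tan(np.radians(el))
        _recompute_retina(fld)


def rotate_retinal(fld: DotField, angle: float = 90.0) -> DotField:
    """Rotate each eye's retinal image by ``angle`` (CCW, about fixation).

    Only multiples of 90 deg are allowed.  Per-dot displacement
    magnitudes (hence monocular speeds) are preserved exactly; in the
    rotated stereoscopic condition the two eyes carry vertically
    opposite motion.  World x/y are rotated consistently.
    """
    if angle % 90 != 0:
        raise ValueError("angle must be a multiple of 90 degrees")
    out = fld.copy()
    a = np.radians(angle)
    c, s = np.cos(a), np.sin(a)
    for eye in (LEFT, RIGHT):
        az = fld.azimuth[eye].copy()
        el = fld.elevation[eye].copy()
        out.azimuth[eye] = c * az - s * el
        out.elevation[eye] = s * az + c * el
    x, y = fld.x.copy(), fld.y.copy()
    out.x = c * x - s * y
    out.y = s * x + c * y
    return out


def simulate_trial(
    condition: CueCondition,
    n_dots: int = 80,
    seed: int | None = None,
    *,
    params: MotionParams = MotionParams(),
    geometry: ViewingGeometry = ViewingGeometry(),
    aperture: Aperture = Aperture(),
    dot_diameter_deg: float = 0.16,
    rotation_angle: float = 90.0,
) -> list[DotField]:
    """Generate the frame sequence of one trial (frame 0 plus one per refresh).

    For rotated control conditions every frame's retinal image is
    rotated by ``rotation_angle`` (default 90 deg, counter-clockwise in
    both eyes).
    """
    n_frames = int(round(params.frame_rate * params.trial_duration))
    fld = make_dot_field(
        n_dots, aperture, seed, geometry=geometry, dot_diameter_deg=dot_diameter_deg,
        presented=condition.presented_eyes,
    )
    frames = [fld]
    for _ in range(n_frames):
        if condition.name == "stereoscopic":
            fld = advance_stereoscopic(fld, condition.direction, 1.0 / params.frame_rate, params)
        else:
            eye = {"perspectiveL": "left", "perspectiveR": "right", "combined": "both"}[condition.name]
            fld = advance_perspective(
                fld, condition.direction, 1.0 / params.frame_rate, params, geometry, eye
            )
        frames.append(fld)
    if condition.rotated:
        frames = [rotate_retinal(f, rotation_angle) for f in frames]
    return frames


def disparity_series(frames: Sequence[DotField]) -> np.ndarray:
    """Mean over dots of binocular disparity, one value per frame."""
    return np.array([
        np.mean(disparity(f.azimuth[LEFT], f.azimuth[RIGHT])) for f in frames
    ])


def disparity_rate(frames: Sequence[DotField], frame_rate: float) -> float:
    """Least-squares slope (deg/s) of mean disparity against time."""
    d = disparity_series(frames)
    t = np.arange(len(frames)) / frame_rate
    return float(np.polyfit(t, d, 1)[0])


def frame_table(frames: Sequence[DotField], condition: CueCondition | None = None) -> pd.DataFrame:
    """Long-format per-frame table (one row per frame x dot x presented eye)."""
    frames = list(frames)
    if frames:
        counts = {f.n_dots for f in frames}
        if len(counts) > 1:
            raise ValueError(f"mixed dot counts across frames: {sorted(counts)}")
    rows = []
    for i, f in enumerate(frames):
        for eye in (LEFT, RIGHT):
            if not f.presented[eye]:
                continue
            rows.append(pd.DataFrame({
                "frame": i,
                "dot": np.arange(f.n_dots),
                "eye": EYE_NAMES[eye],
                "azimuth_deg": f.azimuth[eye],
                "elevation_deg": f.elevation[eye],
                "diameter_deg": f.diameter[eye],
                "polarity": np.where(f.polarity > 0, "white", "black"),
            }))
    if not rows:
        return pd.DataFrame(columns=FRAME_TABLE_COLUMNS)
    return pd.concat(rows, ignore_index=True)[list(FRAME_TABLE_COLUMNS)]


def write_frame_table(
    table: pd.DataFrame, path: str | Path, condition: CueCondition | None = None
) -> None:
    """Write a frame table as TSV with a JSON sidecar of condition metadata."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")
    if condition is not None:
        meta = {"name": condition.name, "direction": condition.direction,
                "rotated": condition.rotated}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_frame_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(FRAME_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"frame table missing columns: {sorted(missing)}")
    return table[list(FRAME_TABLE_COLUMNS)]
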