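"""Synthetic pRF-structured BOLD generator.

Stands in for surface-sampled scanner data: vertex populations with
population-receptive-field (pRF) structure and tuning regimes, observers
that do or do not perceive motion in depth from stereoscopic cues, and
run-level BOLD time series with injectable coarse-scale biases.

Per-trial vertex amplitude follows the encoding equation

    A(v, t) = beta0 + g_ecc * (ecc_v - ecc_ref) + g_rad * 1[v in HM wedge]
              + d_eff(v, t) * (s_v + g_int * (ecc_v - ecc_ref))

with d_eff in {+1, -1, 0}.  For ``retinal_2d`` vertices d_eff follows the
retinal stimulus: coherent retinal motion distinguishes toward from away
labels in every condition, including rotated stereoscopic trials (a 90-deg
rotation preserves retinal motion energy).  For ``percept_3d`` vertices
d_eff follows the perceived direction: the true direction on perspective
and combined trials; for unrotated stereoscopic trials, the true
direction for stereo-pros and a coin flip for stereo-strugglers; zero on
rotated stereoscopic trials, which yield no 3D percept.

Vertex signal per run is the trial-amplitude impulse train convolved with
a canonical double-gamma HRF, plus linear and slow sinusoidal drift, a
shared global confound, motion-regressor leakage, and AR(1) noise.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .stimulus import CONDITION_NAMES, DIRECTIONS

ROI_NAMES = ("V1", "MT", "MST", "FST")
TUNING_REGIMES = ("retinal_2d", "percept_3d")
OBSERVER_GROUPS = ("stereo_pro", "stereo_struggler")

VERTEX_COLUMNS = (
    "roi", "ecc", "polar", "ve", "tuning", "s_v", "g_ecc", "g_rad", "g_int", "beta0",
)


# --------------------------------------------------------------------------
# vertex populations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiSpec:
    """Generative recipe for one ROI's vertex population.

    ``ecc_dist`` is one of ``areal`` (uniform over area between the two
    ``ecc_params``, density proportional to r) or ``lognormal``
    (``ecc_params = (median_deg, sigma_log)``), truncated to [0, 10].
    ``hm_weight`` is the extra probability mass placed uniformly inside
    the +-30 deg horizontal-meridian wedges (0 = uniform polar angle).
    ``s_scale``/``s_scale_hm`` set the SD of the signed direction
    sensitivity off/on the HM wedge (``s_scale_hm=None`` means uniform).
    """

    name: str
    n_vertices: int = 200
    ecc_dist: str = "lognormal"
    ecc_params: tuple[float, float] = (3.0, 0.6)
    hm_weight: float = 0.0
    ve_beta: tuple[float, float] = (2.0, 8.0)
    tuning: str = "retinal_2d"
    s_scale: float = 0.10
    s_scale_hm: float | None = None
    g_ecc: float = 0.0
    g_rad: float = 0.0
    g_int: float = 0.0
    beta0: float = 0.35

    def __post_init__(self) -> None:
        if self.tuning not in TUNING_REGIMES:
            raise ValueError(f"unknown tuning regime {self.tuning!r}")
        if self.n_vertices < 1:
            raise ValueError("n_vertices must be >= 1")


#: ROI presets reproducing the qualitative bias taxonomy: V1 dense and
#: strongly eccentricity-biased; MT retinally tuned with direction
#: sensitivity concentrated near the horizontal meridian; MST retinally
#: tuned with a positive radial (HM) BOLD bias; FST percept-tuned, flat
#: in eccentricity, with a central (foveal) pRF distribution.
ROI_PRESETS: dict[str, RoiSpec] = {
    "V1": RoiSpec("V1", n_vertices=400, ecc_dist="areal", ecc_params=(0.1, 10.0),
                  tuning="retinal_2d", s_scale=0.10, g_ecc=0.06, g_rad=0.05),
    "MT": RoiSpec("MT", n_vertices=180, ecc_dist="lognormal", ecc_params=(3.0, 0.6),
                  tuning="retinal_2d", s_scale=0.05, s_scale_hm=0.16,
                  g_ecc=0.025, g_rad=0.0),
    "MST": RoiSpec("MST", n_vertices=140, ecc_dist="lognormal", ecc_params=(4.5, 0.6),
                   tuning="retinal_2d", s_scale=0.10, g_ecc=0.03, g_rad=0.15),
    "FST": RoiSpec("FST", n_vertices=200, ecc_dist="lognormal", ecc_params=(2.0, 0.7),
                   tuning="percept_3d", s_scale=0.12, g_ecc=0.0, g_rad=0.0),
}

ECC_TRUNC = (0.0, 10.0)
HM_HALF_WIDTH = 30.0


@dataclass
class VertexPopulation:
    """Vertex table with pRF and encoding parameters.

    ``table`` columns: roi, ecc (deg), polar (deg, (-180, 180]), ve
    (fraction), tuning, s_v, g_ecc, g_rad, g_int, beta0.  ``ecc_ref`` is
    the reference eccentricity of the encoding equation (population mean
    at creation).
    """

    table: pd.DataFrame
    ecc_ref: float

    def __post_init__(self) -> None:
        missing = set(VERTEX_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"vertex table missing columns: {sorted(missing)}")
        if (self.table["ecc"] < 0).any():
            raise ValueError("eccentricity must be >= 0")
        if ((self.table["ve"] < 0) | (self.table["ve"] > 1)).any():
            raise ValueError("variance explained must lie in [0, 1]")

    @property
    def n_vertices(self) -> int:
        return len(self.table)

    def hm_mask(self, half_width: float = HM_HALF_WIDTH) -> np.ndarray:
        """True for vertices within ``half_width`` of either horizontal meridian."""
        return hm_wedge_mask(self.table["polar"].to_numpy(), half_width)

    def subset(self, idx) -> "VertexPopulation":
        return VertexPopulation(self.table.iloc[idx].reset_index(drop=True), self.ecc_ref)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, ecc_ref: float | None = None) -> "VertexPopulation":
        table = pd.read_csv(path, sep="\t")
        ref = float(table["ecc"].mean()) if ecc_ref is None else ecc_ref
        return cls(table, ref)


def hm_wedge_mask(polar_deg: np.ndarray, half_width: float = HM_HALF_WIDTH) -> np.ndarray:
    """Membership of the horizontal-meridian wedge (both meridians).

    Angular distance to the nearer of 0 or 180 deg must be <= half_width.
    """
    p = np.abs((np.asarray(polar_deg, float) + 180.0) % 360.0 - 180.0)  # to [0, 180]
    return np.minimum(p, 180.0 - p) <= half_width


def _sample_ecc(rng: np.random.Generator, spec: RoiSpec, n: int) -> np.ndarray:
    lo, hi = ECC_TRUNC
    out = np.empty(0)
    while out.size < n:
        m = 2 * (n - out.size) + 16
        if spec.ecc_dist == "areal":
            a, b = spec.ecc_params
            draw = np.sqrt(rng.uniform(a**2, b**2, m))
        elif spec.ecc_dist == "lognormal":
            med, sig = spec.ecc_params
            draw = rng.lognormal(np.log(med), sig, m)
        elif spec.ecc_dist == "uniform":
            a, b = spec.ecc_params
            draw = rng.uniform(a, b, m)
        else:
            raise ValueError(f"unknown eccentricity distribution {spec.ecc_dist!r}")
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def _sample_polar(rng: np.random.Generator, spec: RoiSpec, n: int) -> np.ndarray:
    base = rng.uniform(-180.0, 180.0, n)
    if spec.hm_weight <= 0:
        return base
    in_wedge = rng.random(n) < spec.hm_weight
    k = int(in_wedge.sum())
    centers = rng.choice([0.0, 180.0], k)
    wedge = centers + rng.uniform(-HM_HALF_WIDTH, HM_HALF_WIDTH, k)
    base[in_wedge] = (wedge + 180.0) % 360.0 - 180.0
    return base


def sample_vertices(
    roi_spec: RoiSpec | str, n_vertices: int | None = None, seed: int | None = None,
    *, rng: np.random.Generator | None = None,
) -> VertexPopulation:
    """Draw a seeded vertex population from an ROI spec (or preset name)."""
    if isinstance(roi_spec, str):
        try:
            roi_spec = ROI_PRESETS[roi_spec]
        except KeyError:
            raise ValueError(f"unknown ROI preset {roi_spec!r}") from None
    if roi_spec is None:
        raise ValueError("empty ROI spec")
    n = roi_spec.n_vertices if n_vertices is None else int(n_vertices)
    if n < 1:
        raise ValueError("n_vertices must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    ecc = _sample_ecc(rng, roi_spec, n)
    polar = _sample_polar(rng, roi_spec, n)
    a, b = roi_spec.ve_beta
    ve = rng.beta(a, b, n)
    hm = hm_wedge_mask(polar)
    scale = np.full(n, roi_spec.s_scale)
    if roi_spec.s_scale_hm is not None:
        scale[hm] = roi_spec.s_scale_hm
    s_v = rng.normal(0.0, 1.0, n) * scale
    table = pd.DataFrame({
        "roi": roi_spec.name, "ecc": ecc, "polar": polar, "ve": ve,
        "tuning": roi_spec.tuning, "s_v": s_v,
        "g_ecc": roi_spec.g_ecc, "g_rad": roi_spec.g_rad, "g_int": roi_spec.g_int,
        "beta0": roi_spec.beta0,
    })
    return VertexPopulation(table, ecc_ref=float(ecc.mean()))


def concat_populations(pops: Sequence[VertexPopulation]) -> VertexPopulation:
    """Stack per-ROI populations into one table (shared ecc_ref = pooled mean)."""
    table = pd.concat([p.table for p in pops], ignore_index=True)
    return VertexPopulation(table, ecc_ref=float(table["ecc"].mean()))


# --------------------------------------------------------------------------
# observers, schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Observer:
    id: str
    group: str = "stereo_pro"
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in OBSERVER_GROUPS:
            raise ValueError(f"unknown observer group {self.group!r}")
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")


@dataclass
class TrialSchedule:
    """Event schedule: one row per trial (run, onset s, condition, direction, rotated)."""

    table: pd.DataFrame
    tr: float = 1.0
    run_length: int = 360

    def __post_init__(self) -> None:
        need = {"run", "onset", "condition", "direction", "rotated"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"schedule missing columns: {sorted(missing)}")
        last = self.table["onset"].max() if len(self.table) else 0.0
        if last / self.tr >= self.run_length:
            raise ValueError("onset beyond run end")

    @property
    def n_trials(self) -> int:
        return len(self.table)

    def runs(self):
        for run_id, sub in self.table.groupby("run", sort=True):
            yield run_id, sub.reset_index(drop=True)

    def onsets_tr(self, table: pd.DataFrame | None = None) -> np.ndarray:
        t = self.table if table is None else table
        return np.round(t["onset"].to_numpy() / self.tr).astype(int)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float = 1.0, run_length: int = 360):
        return cls(pd.read_csv(path, sep="\t"), tr=tr, run_length=run_length)


def make_schedule(
    n_runs: int = 10,
    n_repeats: int = 5,
    seed: int | None = None,
    *,
    rotated: bool = False,
    tr: float = 1.0,
    trial_duration: float = 1.0,
    offset_duration: float = 8.0,
    run_length: int = 360,
) -> TrialSchedule:
    """Event-related schedule: 8 motion types x ``n_repeats`` per run.

    Trials last ``trial_duration`` s followed by ``offset_duration`` s of
    blank, so onsets are spaced 9 s apart; 5 repeats give 40 trials and
    exactly fill a 360 s run.  Type order is shuffled independently per
    run (seeded).
    """
    rng = np.random.default_rng(seed)
    types = [(c, d) for c in CONDITION_NAMES for d in DIRECTIONS]
    spacing = trial_duration + offset_duration
    rows = []
    for run in range(n_runs):
        order = np.repeat(np.arange(len(types)), n_repeats)
        rng.shuffle(order)
        for i, k in enumerate(order):
            cond, direction = types[k]
            rows.append((run, i * spacing, cond, direction, rotated))
    table = pd.DataFrame(rows, columns=["run", "onset", "condition", "direction", "rotated"])
    return TrialSchedule(table, tr=tr, run_length=run_length)


# --------------------------------------------------------------------------
# percepts, reports, amplitudes
# --------------------------------------------------------------------------

def perceived_direction(
    observer: Observer,
    condition: str,
    direction: str,
    rotated: bool = False,
    rng: np.random.Generator | None = None,
) -> str:
    """Perceived motion-in-depth direction on one trial.

    Perspective and combined cues are seen veridically by everyone.
    Unrotated stereoscopic cues are veridical for stereo-pros and a coin
    flip for stereo-strugglers.  Rotated stereoscopic stimuli give
    transparent 2D motion and no 3D percept (``"none"``).  The lapse
    rate applies to button presses only, not to percepts.
    """
    if condition not in CONDITION_NAMES:
        raise ValueError(f"unknown condition {condition!r}")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    if condition != "stereoscopic":
        return direction
    if rotated:
        return "none"
    if observer.group == "stereo_pro":
        return direction
    rng = rng if rng is not None else np.random.default_rng()
    return str(rng.choice(DIRECTIONS))


def simulate_behavioral_report(
    observer: Observer,
    condition: str,
    direction: str,
    rotated: bool = False,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    percept: str | None = None,
) -> str:
    """Button press on one trial: the percept, flipped with probability lapse.

    When the percept is ``"none"`` the report is a fair coin flip.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if percept is None:
        percept = perceived_direction(observer, condition, direction, rotated, rng)
    if percept == "none":
        return str(rng.choice(DIRECTIONS))
    if rng.random() < observer.lapse:
        return "away" if percept == "toward" else "toward"
    return percept


def _direction_signs(directions: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(directions) == "toward", 1.0, -1.0)


def trial_percepts(schedule_table: pd.DataFrame, observer: Observer,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorized perceived direction for every trial of a schedule table."""
    return np.array([
        perceived_direction(observer, row.condition, row.direction, bool(row.rotated), rng)
        for row in schedule_table.itertuples()
    ], dtype=object)


def trial_amplitude(
    vertex: pd.Series | dict,
    condition: str,
    direction: str,
    rotated: bool = False,
    observer: Observer | None = None,
    *,
    ecc_ref: float = 0.0,
    percept: str | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Evoked amplitude of a single vertex on a single trial (encoding equation)."""
    v = vertex
    if observer is None:
        observer = Observer("anon")
    if percept is None:
        percept = perceived_direction(observer, condition, direction, rotated, rng)
    if v["tuning"] == "retinal_2d":
        d_eff = 1.0 if direction == "toward" else -1.0
    else:
        d_eff = 0.0 if percept == "none" else (1.0 if percept == "toward" else -1.0)
    decc = float(v["ecc"]) - ecc_ref
    hm = bool(hm_wedge_mask(np.array([v["polar"]]))[0])
    return float(
        v["beta0"] + v["g_ecc"] * decc + v["g_rad"] * hm
        + d_eff * (v["s_v"] + v["g_int"] * decc)
    )


def trial_amplitudes(
    population: VertexPopulation,
    schedule_table: pd.DataFrame,
    observer: Observer,
    rng: np.random.Generator,
    *,
    percepts: np.ndarray | None = None,
) -> np.ndarray:
    """(n_trials, n_vertices) evoked amplitudes for one schedule table."""
    tab = population.table
    n_v = population.n_vertices
    if percepts is None:
        percepts = trial_percepts(schedule_table, observer, rng)
    d_true = _direction_signs(schedule_table["direction"].to_numpy())
    d_percept = np.where(
        percepts == "none", 0.0, np.where(percepts == "toward", 1.0, -1.0)
    ).astype(float)
    retinal = (tab["tuning"] == "retinal_2d").to_numpy()
    # (T, V) effective direction drive
    d_eff = np.where(retinal[None, :], d_true[:, None], d_percept[:, None])
    decc = (tab["ecc"].to_numpy() - population.ecc_ref)
    hm = population.hm_mask().astype(float)
    static = (tab["beta0"].to_numpy() + tab["g_ecc"].to_numpy() * decc
              + tab["g_rad"].to_numpy() * hm)
    direction_term = tab["s_v"].to_numpy() + tab["g_int"].to_numpy() * decc
    return static[None, :] + d_eff * direction_term[None, :]


# --------------------------------------------------------------------------
# HRF and run simulation
# --------------------------------------------------------------------------

def double_gamma_hrf(
    tr: float = 1.0,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, normalized to unit peak."""
    t = np.arange(0.0, duration, tr)
    h = (spstats.gamma.pdf(t, peak_delay, scale=1.0)
         - spstats.gamma.pdf(t, undershoot_delay, scale=1.0) / ratio)
    return h / h.max()


@dataclass(frozen=True)
class NoiseParams:
    """Run-level noise/nuisance magnitudes (amplitude units = % signal).

    Defaults put default-SNR single-trial decoding in the 60-90% range
    for the preset ROIs, leaving headroom for sensitivity tests.
    """

    white_sd: float = 0.6
    ar1: float = 0.3
    drift_linear: float = 0.5      # end-to-end amplitude of the linear trend
    drift_sin: float = 0.3         # amplitude of the slow sinusoid
    sin_period: float = 120.0      # s
    global_sd: float = 0.25        # SD of the shared confound component
    motion_sd: float = 0.15        # SD of per-vertex motion leakage weights

    def zeroed(self) -> "NoiseParams":
        return NoiseParams(0.0, 0.0, 0.0, 0.0, self.sin_period, 0.0, 0.0)


@dataclass
class RunTimeSeries:
    """One simulated run: (TR x vertex) signal plus nuisance channels.

    ``nuisance`` columns: six motion regressors followed by the global
    signal (mean over vertices of the generated data).
    """

    signal: np.ndarray
    nuisance: np.ndarray
    tr: float
    onsets: np.ndarray                 # TR indices of trial onsets
    trials: pd.DataFrame               # schedule rows for this run
    percepts: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.signal.shape[0] != self.nuisance.shape[0]:
            raise ValueError("nuisance channels must be length-matched to the signal")
        if not np.isfinite(self.signal).all():
            raise ValueError("non-finite values in simulated signal")

    @property
    def n_tr(self) -> int:
        return self.signal.shape[0]

    def save_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=self.signal)
            f.create_dataset("nuisance", data=self.nuisance)
            f.attrs["tr"] = self.tr
            f.attrs["onsets"] = self.onsets

    @classmethod
    def load_hdf5(cls, path: str | Path, trials: pd.DataFrame | None = None):
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                signal=f["signal"][...], nuisance=f["nuisance"][...],
                tr=float(f.attrs["tr"]), onsets=np.asarray(f.attrs["onsets"]),
                trials=trials if trials is not None else pd.DataFrame(),
            )


def _ar1_noise(rng, shape, phi, sd):
    white = rng.normal(0.0, sd, shape)
    if phi == 0.0 or sd == 0.0:
        return white
    # scale innovations so the stationary SD equals sd
    innov = white * np.sqrt(1.0 - phi**2)
    return sps.lfilter([1.0], [1.0, -phi], innov, axis=0)


def simulate_run(
    population: VertexPopulation,
    schedule: TrialSchedule,
    observer: Observer,
    noise: NoiseParams = NoiseParams(),
    seed: int | None = None,
    *,
    run: int | None = None,
    hrf: np.ndarray | None = None,
) -> RunTimeSeries:
    """Simulate one run's (360 x V) BOLD array plus nuisance channels.

    The trial-amplitude impulse train is convolved with the canonical
    HRF; linear/sinusoidal drift, a shared global confound, motion
    leakage and AR(1) noise are added.  Everything is drawn from a
    single seeded generator, so identical seeds give identical runs.
    """
    rng = np.random.default_rng(seed)
    if run is None:
        runs = sorted(schedule.table["run"].unique())
        if len(runs) != 1:
            raise ValueError("schedule covers multiple runs; pass run=...")
        run = runs[0]
    trials = schedule.table[schedule.table["run"] == run].reset_index(drop=True)
    n_tr = schedule.run_length
    onsets = schedule.onsets_tr(trials)
    if (onsets < 0).any() or (onsets >= n_tr).any():
        raise ValueError("trial onset beyond run end")
    n_v = population.n_vertices

    percepts = trial_percepts(trials, observer, rng)
    amps = trial_amplitudes(population, trials, observer, rng, percepts=percepts)

    impulses = np.zeros((n_tr, n_v))
    impulses[onsets] = amps
    h = double_gamma_hrf(schedule.tr) if hrf is None else np.asarray(hrf)
    sig = sps.fftconvolve(impulses, h[:, None], axes=0)[:n_tr]

    t = np.arange(n_tr) * schedule.tr
    if noise.drift_linear:
        slopes = rng.normal(0.0, noise.drift_linear, n_v)
        sig = sig + (t[:, None] / t[-1]) * slopes[None, :]
    if noise.drift_sin:
        phase = rng.uniform(0, 2 * np.pi, n_v)
        amp = rng.normal(0.0, noise.drift_sin, n_v)
        sig = sig + amp[None, :] * np.sin(2 * np.pi * t[:, None] / noise.sin_period + phase[None, :])

    motion = np.cumsum(rng.normal(0.0, 1.0, (n_tr, 6)), axis=0)
    motion -= motion.mean(axis=0)
    motion /= np.maximum(motion.std(axis=0), 1e-12)
    if noise.motion_sd:
        weights = rng.normal(0.0, noise.motion_sd, (6, n_v))
        sig = sig + motion @ weights

    if noise.global_sd:
        confound = _ar1_noise(rng, n_tr, noise.ar1, noise.global_sd)
        sig = sig + confound[:, None]

    if noise.white_sd:
        sig = sig + _ar1_noise(rng, (n_tr, n_v), noise.ar1, noise.white_sd)

    global_signal = sig.mean(axis=1)
    nuisance = np.column_stack([motion, global_signal])
    return RunTimeSeries(
        signal=sig, nuisance=nuisance, tr=schedule.tr, onsets=onsets,
        trials=trials, percepts=percepts, seed=seed,
    )
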