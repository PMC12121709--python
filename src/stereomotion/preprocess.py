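"""Run time series -> single-trial amplitude matrix.

The decoding path mirrors the standard single-trial pipeline: high-pass
filter (1 cycle / 40 s), nuisance regression (six motion regressors plus
the global signal), peristimulus z-normalization across trials at each
TR lag, and averaging of the 6th-9th post-onset z-scored TRs, yielding a
(trials x vertices) matrix with 40 rows per run and 400 per 10-run
session.

A second, ``percent`` extraction mode supports the BOLD-level bias
analyses: it skips global-signal regression and z-normalization (both
remove the mean evoked amplitude that those analyses measure) and
instead divides the windowed response by the expected window response of
a unit-amplitude trial under the canonical HRF, returning amplitudes on
the generative % -signal scale.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import RunTimeSeries, double_gamma_hrf

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 1.0 / 40.0       # Hz
DEFAULT_WINDOW = (6, 9)           # 1-based inclusive TR indices after onset
DEFAULT_MAX_LAG = 9               # peristimulus lags 0..8 are z-normalized

LABEL_COLUMNS = ("direction", "condition", "run", "rotated")


# --------------------------------------------------------------------------
# filtering and nuisance regression
# --------------------------------------------------------------------------

def _dct_basis(n: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift regressors with frequencies below ``cutoff``."""
    order = int(np.floor(2.0 * n * tr * cutoff))
    t = np.arange(n)
    ks = np.arange(1, order + 1)
    return np.cos(np.pi * np.outer(t + 0.5, ks) / n)


def highpass(
    series: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    tr: float = 1.0,
    method: str = "dct",
) -> np.ndarray:
    """High-pass filter each column of a (TR x vertex) array.

    ``dct`` (default) projects out a discrete-cosine drift basis up to
    the cutoff frequency together with the mean — exact DC removal and
    no edge ringing.  ``butterworth`` applies a zero-phase 4th-order
    Butterworth filter instead.
    """
    series = np.asarray(series, float)
    if not np.isfinite(series).all():
        raise ValueError("non-finite values in input series")
    one_d = series.ndim == 1
    x = series[:, None] if one_d else series
    n = x.shape[0]
    if method == "dct":
        basis = np.column_stack([np.ones(n), _dct_basis(n, tr, cutoff)])
        coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
        out = x - basis @ coef
    elif method == "butterworth":
        sos = sps.butter(4, cutoff, btype="highpass", fs=1.0 / tr, output="sos")
        out = sps.sosfiltfilt(sos, x, axis=0)
    else:
        raise ValueError(f"unknown high-pass method {method!r}")
    return out[:, 0] if one_d else out


def nuisance_regress(series: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Residualize each column of ``series`` against ``regressors`` (+ intercept).

    Collinear regressor columns are dropped with a logged warning.
    Residuals are orthogonal to the retained regressors.
    """
    series = np.asarray(series, float)
    one_d = series.ndim == 1
    x = series[:, None] if one_d else series
    reg = np.atleast_2d(np.asarray(regressors, float))
    if reg.shape[0] != x.shape[0]:
        reg = reg.T
    if reg.shape[0] != x.shape[0]:
        raise ValueError("regressor rows must match series rows")
    design = np.column_stack([np.ones(x.shape[0]), reg])
    # drop collinear columns via rank-revealing QR on the scaled design
    q, r, piv = _qr_pivot(design)
    tol = max(design.shape) * np.finfo(float).eps * abs(r[0, 0]) if r.size else 0.0
    rank = int(np.sum(np.abs(np.diag(r)) > tol))
    if rank < design.shape[1]:
        dropped = sorted(piv[rank:])
        logger.warning("dropping %d collinear nuisance column(s): %s",
                       len(dropped), dropped)
        design = design[:, sorted(piv[:rank])]
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    out = x - design @ coef
    return out[:, 0] if one_d else out


def _qr_pivot(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv


# --------------------------------------------------------------------------
# peristimulus normalization and amplitude extraction
# --------------------------------------------------------------------------

def znorm_peristim(
    series: np.ndarray,
    onsets: np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
) -> np.ndarray:
    """Z-score across trials at each peristimulus lag, per vertex.

    For each lag n in [0, max_lag) the values at onset+n across the
    run's trials are given mean 0 and SD 1.  TRs not covered by any
    trial window are returned unchanged.  A degenerate SD (< 1e-12)
    yields zeros with a warning rather than NaN.
    """
    series = np.asarray(series, float)
    onsets = np.asarray(onsets, int)
    if onsets.size < 2:
        raise ValueError("need at least 2 trials to z-normalize across trials")
    if (onsets.min() < 0) or (onsets.max() + max_lag - 1 >= series.shape[0]):
        raise ValueError("onset + lag outside the run")
    one_d = series.ndim == 1
    x = series[:, None] if one_d else series
    out = x.copy()
    degenerate = 0
    for lag in range(max_lag):
        idx = onsets + lag
        vals = x[idx]
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=0)
        bad = sd < 1e-12
        degenerate += int(np.count_nonzero(bad))
        z = (vals - mean) / np.where(bad, 1.0, sd)
        z[:, bad] = 0.0
        out[idx] = z
    out = out[:, 0] if one_d else out
    if degenerate:
        warnings.warn(f"{degenerate} degenerate (zero-variance) lag/vertex cells set to 0",
                      RuntimeWarning, stacklevel=2)
    return out


def extract_amplitudes(
    z_series: np.ndarray,
    onsets: np.ndarray,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> np.ndarray:
    """Average the z-scored values at the window TRs after each onset.

    ``window`` is 1-based inclusive: the default (6, 9) averages the
    6th-9th TRs after onset, i.e. 5-8 s post-onset at TR = 1 s.
    Returns (n_trials, n_vertices).
    """
    z_series = np.asarray(z_series, float)
    onsets = np.asarray(onsets, int)
    lo, hi = window
    if lo < 1 or hi < lo:
        raise ValueError("window must be 1-based inclusive with lo <= hi")
    offsets = np.arange(lo - 1, hi)
    if (onsets.min() + offsets.min() < 0) or (onsets.max() + offsets.max() >= z_series.shape[0]):
        raise ValueError("extraction window out of range")
    stack = z_series[onsets[:, None] + offsets[None, :]]
    return stack.mean(axis=1)


def unit_response_gains(
    onsets: np.ndarray,
    n_tr: int,
    tr: float = 1.0,
    window: tuple[int, int] = DEFAULT_WINDOW,
    cutoff: float = DEFAULT_CUTOFF,
    hrf: np.ndarray | None = None,
    regressors: np.ndarray | None = None,
) -> np.ndarray:
    """Per-trial window response of a unit-amplitude trial train.

    Runs a unit impulse train through the same HRF convolution,
    high-pass filter, nuisance regression and window averaging as the
    real pipeline; the result calibrates ``percent``-mode amplitudes
    back to the generative % -signal scale (including overlap from
    neighbouring trials, filter attenuation and regression leakage).
    """
    onsets = np.asarray(onsets, int)
    h = double_gamma_hrf(tr) if hrf is None else np.asarray(hrf)
    train = np.zeros(n_tr)
    train[onsets] = 1.0
    resp = sps.fftconvolve(train, h)[:n_tr]
    resp = highpass(resp, cutoff=cutoff, tr=tr)
    if regressors is not None and np.size(regressors):
        resp = nuisance_regress(resp, regressors)
    lo, hi = window
    offsets = np.arange(lo - 1, hi)
    return resp[onsets[:, None] + offsets[None, :]].mean(axis=1)


# --------------------------------------------------------------------------
# trial matrices
# --------------------------------------------------------------------------

@dataclass
class TrialMatrix:
    """(trial x vertex) single-trial amplitudes with per-trial labels."""

    data: np.ndarray
    labels: pd.DataFrame
    provenance: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one label row per trial required")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite trial amplitudes")
        missing = set(LABEL_COLUMNS) - set(self.labels.columns)
        if missing:
            raise ValueError(f"labels missing columns: {sorted(missing)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]

    def select(self, condition=None, direction=None, rotated=None) -> "TrialMatrix":
        """Row subset by condition name(s) / direction / rotated flag."""
        mask = np.ones(self.n_trials, bool)
        if condition is not None:
            conds = [condition] if isinstance(condition, str) else list(condition)
            mask &= self.labels["condition"].isin(conds).to_numpy()
        if direction is not None:
            mask &= (self.labels["direction"] == direction).to_numpy()
        if rotated is not None:
            mask &= (self.labels["rotated"].astype(bool) == rotated).to_numpy()
        return TrialMatrix(self.data[mask],
                           self.labels[mask].reset_index(drop=True),
                           dict(self.provenance))

    def vertex_subset(self, idx) -> "TrialMatrix":
        return TrialMatrix(self.data[:, np.asarray(idx)], self.labels.copy(),
                           dict(self.provenance))

    def save_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            for col in self.labels.columns:
                vals = self.labels[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                f.create_dataset(f"labels/{col}", data=vals)

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "TrialMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            data = f["data"][...]
            labels = {}
            for col in f["labels"]:
                vals = f[f"labels/{col}"][...]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                labels[col] = vals
        return cls(data, pd.DataFrame(labels))

    def save_tsv(self, path: str | Path) -> None:
        """Delimited-text fallback: labels followed by amplitude columns."""
        wide = pd.concat(
            [self.labels.reset_index(drop=True),
             pd.DataFrame(self.data, columns=[f"v{i}" for i in range(self.n_vertices)])],
            axis=1,
        )
        wide.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "TrialMatrix":
        wide = pd.read_csv(path, sep="\t")
        vcols = [c for c in wide.columns if c.startswith("v") and c[1:].isdigit()]
        labels = wide[[c for c in wide.columns if c not in vcols]]
        return cls(wide[vcols].to_numpy(float), labels)


def single_trial_matrix(
    run: RunTimeSeries,
    mode: str = "zscore",
    *,
    cutoff: float = DEFAULT_CUTOFF,
    window: tuple[int, int] = DEFAULT_WINDOW,
    max_lag: int = DEFAULT_MAX_LAG,
    highpass_method: str = "dct",
) -> TrialMatrix:
    """Full per-run pipeline: filter -> nuisance -> (z-norm) -> window average.

    ``mode="zscore"`` is the decoding path (motion + global nuisance,
    peristimulus z-normalization).  ``mode="percent"`` is the BOLD-level
    path: motion-only nuisance, no z-normalization, unit-response gain
    calibration to the generative % -signal scale.
    """
    if mode not in ("zscore", "percent"):
        raise ValueError(f"unknown extraction mode {mode!r}")
    filt = highpass(run.signal, cutoff=cutoff, tr=run.tr, method=highpass_method)
    if mode == "zscore":
        resid = nuisance_regress(filt, run.nuisance)
        z = znorm_peristim(resid, run.onsets, max_lag=max_lag)
        amps = extract_amplitudes(z, run.onsets, window=window)
    else:
        motion_only = run.nuisance[:, :-1] if run.nuisance.shape[1] else run.nuisance
        resid = nuisance_regress(filt, motion_only) if motion_only.size else filt
        raw = extract_amplitudes(resid, run.onsets, window=window)
        gains = unit_response_gains(run.onsets, run.n_tr, tr=run.tr,
                                    window=window, cutoff=cutoff,
                                    regressors=motion_only)
        amps = raw / gains[:, None]
    labels = run.trials[["direction", "condition", "run", "rotated"]].copy()
    prov = {"mode": mode, "cutoff_hz": cutoff, "window": list(window),
            "highpass": highpass_method}
    return TrialMatrix(amps, labels.reset_index(drop=True), prov)


def assemble_session(runs: Sequence[TrialMatrix]) -> TrialMatrix:
    """Concatenate per-run matrices into the session matrix (400 x V for 10 runs)."""
    runs = list(runs)
    if not runs:
        raise ValueError("no runs to assemble")
    n_v = {r.n_vertices for r in runs}
    if len(n_v) > 1:
        raise ValueError(f"vertex counts differ across runs: {sorted(n_v)}")
    data = np.vstack([r.data for r in runs])
    labels = pd.concat([r.labels for r in runs], ignore_index=True)
    counts = labels.groupby(["condition", "direction"]).size()
    if counts.nunique() > 1:
        warnings.warn("label counts unbalanced across condition x direction cells",
                      RuntimeWarning, stacklevel=2)
    return TrialMatrix(data, labels, dict(runs[0].provenance))
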