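"""Post-ICA cleaning of component time courses.

The chain, applied per component column in this order: polynomial
detrend, robust despike, zero-phase low-pass filter (cutoff 0.15 Hz),
and regression of the six head-motion parameters. Despiking uses
robust-z (median/MAD) detection with linear interpolation across spike
runs; the filter is a 5th-order Butterworth applied forward-backward.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .types import ComponentTimecourses

DESPIKE_MAX_PASSES = 5  # re-detection cap; MAD shifts after interpolation


def detrend(tc: ComponentTimecourses, order: int = 1) -> ComponentTimecourses:
    """Remove a per-column least-squares polynomial of the given order."""
    if order not in (0, 1, 2):
        raise ValueError("detrend order must be 0, 1 or 2")
    n = tc.n_timepoints
    if n < order + 1:
        raise ValueError("fewer timepoints than polynomial coefficients")
    t = np.arange(n, dtype=float)
    basis = np.vander(t, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, tc.data, rcond=None)
    return tc.with_data(tc.data - basis @ coef)


def _despike_column(x: np.ndarray, z_thresh: float) -> np.ndarray:
    for _ in range(DESPIKE_MAX_PASSES):
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            return x  # constant (or majority-constant) column: leave as is
        z = np.abs(x - med) / (1.4826 * mad)
        spikes = z > z_thresh
        if not spikes.any():
            return x
        good = np.flatnonzero(~spikes)
        if good.size == 0:
            return x
        x = x.copy()
        # linear bridge across spike runs; endpoints clamp to nearest good
        x[spikes] = np.interp(np.flatnonzero(spikes), good, x[good])
    return x


def despike(tc: ComponentTimecourses, z_thresh: float = 3.5) -> ComponentTimecourses:
    """Replace robust-z outliers (|x - med| / (1.4826 MAD) > z_thresh)
    by linear interpolation between nearest non-spike neighbours."""
    if z_thresh <= 0:
        raise ValueError("z threshold must be positive")
    out = tc.data.copy()
    for j in range(tc.n_components):
        out[:, j] = _despike_column(out[:, j], z_thresh)
    return tc.with_data(out)


def lowpass_filter(tc: ComponentTimecourses, cutoff_hz: float = 0.15) -> ComponentTimecourses:
    """Zero-phase 5th-order Butterworth low-pass at ``cutoff_hz``."""
    nyquist = 1.0 / (2.0 * tc.tr_seconds)
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz for TR {tc.tr_seconds}s")
    b, a = signal.butter(5, cutoff_hz, btype="low", fs=1.0 / tc.tr_seconds)
    return tc.with_data(signal.filtfilt(b, a, tc.data, axis=0))


def regress_nuisance(tc: ComponentTimecourses, regressors: np.ndarray) -> ComponentTimecourses:
    """Residualize each column on [intercept + regressors] (OLS).

    Rank-deficient designs fall back to the pseudo-inverse with a warning.
    Residuals are not re-centered afterwards (the intercept handles it).
    """
    R = np.asarray(regressors, dtype=float)
    if R.ndim != 2 or R.shape[0] != tc.n_timepoints:
        raise ValueError("regressors must be (n_timepoints, n_regressors)")
    design = np.column_stack([np.ones(tc.n_timepoints), R])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient nuisance design; using pseudo-inverse")
        beta = np.linalg.pinv(design) @ tc.data
    else:
        beta, *_ = np.linalg.lstsq(design, tc.data, rcond=None)
    return tc.with_data(tc.data - design @ beta)


class TimecoursePostProcessor(TransformerMixin, BaseEstimator):
    """Transformer applying detrend -> despike -> low-pass -> motion
    regression, each step optional via its parameter.

    Parameters
    ----------
    detrend_order : polynomial order (0-2), or None to skip.
    despike_z : robust-z threshold, or None to skip.
    lowpass_hz : filter cutoff in Hz, or None to skip.
    motion : (n_timepoints, 6) nuisance matrix shared by all subjects,
        a list of such matrices (one per subject), or None to skip.
    """

    def __init__(
        self,
        detrend_order: int | None = 1,
        despike_z: float | None = 3.5,
        lowpass_hz: float | None = 0.15,
        motion=None,
    ):
        self.detrend_order = detrend_order
        self.despike_z = despike_z
        self.lowpass_hz = lowpass_hz
        self.motion = motion

    def fit(self, X=None, y=None):
        return self

    def _transform_one(self, tc: ComponentTimecourses, motion) -> ComponentTimecourses:
        if self.detrend_order is not None:
            tc = detrend(tc, self.detrend_order)
        if self.despike_z is not None:
            tc = despike(tc, self.despike_z)
        if self.lowpass_hz is not None:
            tc = lowpass_filter(tc, self.lowpass_hz)
        if motion is not None:
            tc = regress_nuisance(tc, motion)
        return tc

    def transform(self, X):
        single = isinstance(X, ComponentTimecourses)
        tcs = [X] if single else list(X)
        if self.motion is None:
            motions = [None] * len(tcs)
        elif isinstance(self.motion, np.ndarray):
            motions = [self.motion] * len(tcs)
        else:
            motions = list(self.motion)
            if len(motions) != len(tcs):
                raise ValueError("one motion matrix required per subject")
        out = [self._transform_one(tc, m) for tc, m in zip(tcs, motions)]
        return out[0] if single else out
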