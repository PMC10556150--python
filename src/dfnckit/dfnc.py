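"""Sliding-window functional network connectivity.

Per subject: slide a 30-TR (60 s) window in 1-TR steps over the cleaned
component time courses; within each window standardize columns and
estimate a sparse precision matrix by L1-penalized maximum likelihood
(graphical lasso); convert the precision to partial correlations

    r_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj)

and Fisher-transform (z = atanh r) the upper triangle into a pair
vector. Concatenated over windows this gives the n_windows x n_pairs
matrix that state clustering consumes (200 x 253 at the defaults).

The penalty lambda is not dictated by the published analysis; the
default 0.1 on within-window standardized data is a documented choice,
overridable everywhere it appears.
"""
from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .types import ComponentTimecourses, WindowSpec, WindowedFNCSeries

DEFAULT_LAMBDA = 0.1


def make_windows(n_timepoints: int, spec: WindowSpec | None = None) -> list[range]:
    """Half-open 0-based window ranges [s, s + width), s = 0, step, ...

    Count convention: floor((T - width)/step), which reproduces 200
    windows for T = 230, width 30, step 1.
    """
    spec = spec or WindowSpec()
    n = spec.n_windows(n_timepoints)
    return [range(i * spec.step_tr, i * spec.step_tr + spec.width_tr) for i in range(n)]


def graphical_lasso_precision(
    sample_cov: np.ndarray, lam: float, max_iter: int = 200
) -> np.ndarray:
    """L1-penalized precision estimate; exact inverse at lam = 0.

    Maximizes log det(Theta) - tr(S Theta) - lam * ||Theta||_1(off-diag).
    """
    S = np.asarray(sample_cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("sample covariance must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("sample covariance must be symmetric")
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    if lam == 0:
        try:
            return np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular covariance with zero penalty; increase lambda"
            ) from exc
    try:
        with warnings.catch_warnings():
            # near-tolerance duality gaps (~1e-3) are routine on strongly
            # correlated 30-sample windows and harmless at this use;
            # genuine solver failure raises FloatingPointError below
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, precision = graphical_lasso(S, alpha=lam, max_iter=max_iter)
    except FloatingPointError as exc:  # pragma: no cover - solver pathology
        raise RuntimeError(f"graphical lasso failed to converge: {exc}") from exc
    return precision


def precision_to_fisher_z(precision: np.ndarray, clip: float = 1e-7) -> np.ndarray:
    """Precision -> Fisher-z partial correlations, upper triangle row-major."""
    P = np.asarray(precision, dtype=float)
    d = np.diag(P)
    if (d <= 0).any():
        raise ValueError("precision matrix has non-positive diagonal entries")
    scale = np.sqrt(d)
    r = -P / np.outer(scale, scale)
    iu, ju = np.triu_indices(P.shape[0], k=1)
    return np.arctanh(np.clip(r[iu, ju], -1 + clip, 1 - clip))


def _window_correlation(X: np.ndarray, taper: np.ndarray | None = None) -> np.ndarray:
    """Within-window correlation matrix, optionally with taper weights."""
    Xc = X - X.mean(axis=0)
    if taper is not None:
        Xc = Xc * np.sqrt(taper[:, None] / taper.sum() * X.shape[0])
        Xc = Xc - Xc.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant column inside a window; cannot standardize")
    C = (Xc / sd).T @ (Xc / sd) / (X.shape[0] - 1)
    np.fill_diagonal(C, 1.0)
    return (C + C.T) / 2


def gaussian_taper(width: int, sigma_tr: float = 3.0) -> np.ndarray:
    """Gaussian window weights (optional, for tapered estimation)."""
    t = np.arange(width) - (width - 1) / 2
    return np.exp(-0.5 * (t / sigma_tr) ** 2)


def subject_dfnc(
    tc: ComponentTimecourses,
    window_spec: WindowSpec | None = None,
    lam: float = DEFAULT_LAMBDA,
    taper_sigma_tr: float | None = None,
) -> WindowedFNCSeries:
    """Windowed Fisher-z partial-correlation series for one subject."""
    spec = window_spec or WindowSpec()
    windows = make_windows(tc.n_timepoints, spec)
    taper = gaussian_taper(spec.width_tr, taper_sigma_tr) if taper_sigma_tr else None
    n_pairs = tc.n_components * (tc.n_components - 1) // 2
    out = np.empty((len(windows), n_pairs))
    for w, rng in enumerate(windows):
        C = _window_correlation(tc.data[rng.start : rng.stop], taper)
        theta = graphical_lasso_precision(C, lam)
        out[w] = precision_to_fisher_z(theta)
    return WindowedFNCSeries(
        subject_id=tc.subject_id,
        data=out,
        window_starts=np.array([r.start for r in windows]),
        lambda_used=lam,
        partition=tc.partition,
    )


def select_lambda_cv(
    tc: ComponentTimecourses,
    grid=(0.01, 0.03, 0.1, 0.3),
    window_spec: WindowSpec | None = None,
    n_splits: int = 3,
    seed: int | None = None,
) -> tuple[float, dict[float, float]]:
    """Per-subject penalty selection by cross-validated log-likelihood.

    Non-overlapping windows are split into folds; for each candidate
    penalty, the precision fitted on the pooled training windows is
    scored by the Gaussian log-likelihood of each held-out window's
    correlation matrix, log det(Theta) - tr(S Theta). Returns the
    penalty with the highest mean held-out score plus the full curve.
    """
    spec = window_spec or WindowSpec()
    stride = max(spec.width_tr, spec.step_tr)
    disjoint = make_windows(tc.n_timepoints, WindowSpec(spec.width_tr, stride))
    if len(disjoint) < n_splits:
        raise ValueError("not enough non-overlapping windows for the folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(disjoint))
    folds = np.array_split(order, n_splits)
    corrs = [_window_correlation(tc.data[w.start : w.stop]) for w in disjoint]
    scores: dict[float, float] = {}
    for lam in grid:
        total = 0.0
        for f in range(n_splits):
            train = [corrs[i] for i in order if i not in set(folds[f])]
            theta = graphical_lasso_precision(np.mean(train, axis=0), lam)
            sign, logdet = np.linalg.slogdet(theta)
            for i in folds[f]:
                total += sign * logdet - np.trace(corrs[i] @ theta)
        scores[lam] = total / len(disjoint)
    best = max(scores, key=scores.get)
    return best, scores


class SlidingWindowConnectivity(TransformerMixin, BaseEstimator):
    """Transformer: component time courses -> windowed FNC series.

    Parameters
    ----------
    width_tr, step_tr : window geometry in TR units (defaults 30 / 1).
    lam : graphical-lasso L1 penalty on within-window standardized data.
    taper_sigma_tr : if set, Gaussian taper sd in TRs (rectangular
        window when None, the default).
    """

    def __init__(
        self,
        width_tr: int = 30,
        step_tr: int = 1,
        lam: float = DEFAULT_LAMBDA,
        taper_sigma_tr: float | None = None,
    ):
        self.width_tr = width_tr
        self.step_tr = step_tr
        self.lam = lam
        self.taper_sigma_tr = taper_sigma_tr

    def fit(self, X=None, y=None):
        self.window_spec_ = WindowSpec(self.width_tr, self.step_tr)
        return self

    def transform(self, X) -> list[WindowedFNCSeries]:
        """X: one ComponentTimecourses or a list of them."""
        if not hasattr(self, "window_spec_"):
            self.fit()
        single = isinstance(X, ComponentTimecourses)
        tcs = [X] if single else list(X)
        out = [
            subject_dfnc(tc, self.window_spec_, self.lam, self.taper_sigma_tr)
            for tc in tcs
        ]
        return out[0] if single else out
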