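"""Single-mediator bootstrap mediation with BCa confidence intervals.

Product-of-coefficients linear mediation: with binary exposure X
(controls coded 0, patients 1), mediator M and outcome Y,

    M = i1 + a X            (path a)
    Y = i2 + c' X + b M     (paths b and c')
    Y = i3 + c X            (total effect c)

the indirect effect is a*b, and c = c' + a*b identically for this
no-interaction linear system. Inference resamples subjects with
replacement (5000 draws by default), recomputing the indirect effect
per resample, and reports both percentile and bias-corrected and
accelerated (BCa) intervals; the acceleration constant comes from a
leave-one-out jackknife. "Partial mediation" is flagged when the BCa
interval excludes 0 while the direct effect c' remains nonzero at the
same level.

All resampling is vectorized through sufficient statistics (per-resample
sums of X, M, Y and their products), so 5000 resamples cost a few
matrix reductions rather than 5000 regression fits.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm


def fit_paths(X, M, Y, covariates=None) -> dict[str, float]:
    """Least-squares path coefficients for the three mediation models.

    ``covariates``: optional (n, p) matrix partialled out of X, M and Y
    (equivalent to including them in every model, by Frisch-Waugh).
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (X.size == M.size == Y.size):
        raise ValueError("X, M, Y must have equal length")
    if np.ptp(X) == 0:
        raise ValueError("exposure has a single level")
    if np.ptp(M) == 0 or np.ptp(Y) == 0:
        raise ValueError("constant mediator or outcome: degenerate fit")
    if covariates is not None:
        C = np.column_stack([np.ones(X.size), np.asarray(covariates, dtype=float)])
        proj = C @ np.linalg.pinv(C)
        X, M, Y = X - proj @ X, M - proj @ M, Y - proj @ Y
    xc = X - X.mean()
    mc = M - M.mean()
    yc = Y - Y.mean()
    sxx = xc @ xc
    sxm = xc @ mc
    smm = mc @ mc
    sxy = xc @ yc
    smy = mc @ yc
    a = sxm / sxx
    c = sxy / sxx
    det = sxx * smm - sxm**2
    if det <= 0:  # M collinear with X
        raise ValueError("mediator collinear with exposure")
    c_prime = (smm * sxy - sxm * smy) / det
    b = (sxx * smy - sxm * sxy) / det
    return {"a": float(a), "b": float(b), "c": float(c),
            "c_prime": float(c_prime), "indirect": float(a * b)}


def _indirect_from_sums(n, sx, sm, sy, sxx, sxm, smm, sxy, smy):
    """Vectorized indirect effect from per-resample raw sums."""
    cxx = sxx - sx * sx / n
    cxm = sxm - sx * sm / n
    cmm = smm - sm * sm / n
    cxy = sxy - sx * sy / n
    cmy = smy - sm * sy / n
    det = cxx * cmm - cxm**2
    with np.errstate(divide="ignore", invalid="ignore"):
        a = cxm / cxx
        b = (cxx * cmy - cxm * cxy) / det
    return a * b, cxx, det


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    indirect_standardized: float
    ci_bca: tuple[float, float]
    ci_percentile: tuple[float, float]
    level: float
    p_boot: float
    z0: float
    accel: float
    n_boot: int
    n_redrawn: int
    seed: int | None
    boot_mean: float
    boot_sd: float
    partial_mediation: bool
    boot_indirect: np.ndarray = field(repr=False, default=None)


class BootstrapMediation:
    """Estimator-style interface: ``fit(X, M, Y)`` populates fitted
    attributes (``indirect_``, ``ci_bca_``, ...).

    Parameters
    ----------
    n_boot : bootstrap resamples (default 5000).
    level : confidence level (default 0.95).
    random_state : seed; identical seeds give identical draws.
    """

    def __init__(self, n_boot: int = 5000, level: float = 0.95,
                 random_state: int | None = None):
        self.n_boot = n_boot
        self.level = level
        self.random_state = random_state

    def fit(self, X, M, Y):
        res = bootstrap_bca(X, M, Y, n_boot=self.n_boot, level=self.level,
                            seed=self.random_state)
        self.a_, self.b_, self.c_, self.c_prime_ = res.a, res.b, res.c, res.c_prime
        self.indirect_ = res.indirect
        self.ci_bca_ = res.ci_bca
        self.ci_percentile_ = res.ci_percentile
        self.p_boot_ = res.p_boot
        self.z0_, self.accel_ = res.z0, res.accel
        self.result_ = res
        return self


def bootstrap_bca(
    X, M, Y,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
    max_redraws: int = 100,
    covariates=None,
) -> MediationResult:
    """BCa bootstrap for the indirect effect a*b.

    Resamples with a degenerate-resample guard: draws in which the
    exposure collapses to one level (or mediator to a constant) are
    redrawn; the count is reported. Covariates, when given, are
    partialled out of X, M and Y on the full sample before resampling
    (a fixed-covariate approximation; the default model has none).
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if covariates is not None:
        C = np.column_stack([np.ones(X.size), np.asarray(covariates, dtype=float)])
        proj = C @ np.linalg.pinv(C)
        X, M, Y = X - proj @ X, M - proj @ M, Y - proj @ Y
    point = fit_paths(X, M, Y)
    n = X.size
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)

    def resample_sums(idx):
        xb, mb, yb = X[idx], M[idx], Y[idx]
        return (
            xb.sum(1), mb.sum(1), yb.sum(1),
            (xb * xb).sum(1), (xb * mb).sum(1), (mb * mb).sum(1),
            (xb * yb).sum(1), (mb * yb).sum(1),
        )

    idx = rng.integers(n, size=(n_boot, n))
    sx, sm, sy, sxx, sxm, smm, sxy, smy = resample_sums(idx)
    theta, cxx, det = _indirect_from_sums(n, sx, sm, sy, sxx, sxm, smm, sxy, smy)
    n_redrawn = 0
    for _ in range(max_redraws):
        bad = ~np.isfinite(theta) | (cxx <= 0) | (det <= 0)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        idx_bad = rng.integers(n, size=(int(bad.sum()), n))
        sums = resample_sums(idx_bad)
        theta_new, cxx_new, det_new = _indirect_from_sums(n, *sums)
        theta[bad], cxx[bad], det[bad] = theta_new, cxx_new, det_new
    theta = theta[np.isfinite(theta)]
    if theta.size == 0:
        raise RuntimeError("all bootstrap resamples degenerate")

    alpha = 1.0 - level
    # bias correction
    frac_below = np.clip(
        np.mean(theta < point["indirect"]), 1.0 / (theta.size + 1),
        theta.size / (theta.size + 1.0),
    )
    z0 = float(norm.ppf(frac_below))
    # jackknife acceleration via sum downdating
    tsx, tsm, tsy = X.sum(), M.sum(), Y.sum()
    tsxx, tsxm, tsmm = X @ X, X @ M, M @ M
    tsxy, tsmy = X @ Y, M @ Y
    jack, _, _ = _indirect_from_sums(
        n - 1,
        tsx - X, tsm - M, tsy - Y,
        tsxx - X * X, tsxm - X * M, tsmm - M * M,
        tsxy - X * Y, tsmy - M * Y,
    )
    jack = jack[np.isfinite(jack)]
    dev = jack.mean() - jack
    denom = 6.0 * (dev @ dev) ** 1.5
    accel = float((dev**3).sum() / denom) if denom > 0 else 0.0

    def bca_quantile(a_level: float) -> float:
        z = norm.ppf(a_level)
        adj = norm.cdf(z0 + (z0 + z) / (1.0 - accel * (z0 + z)))
        return float(np.quantile(theta, adj))

    ci_bca = (bca_quantile(alpha / 2), bca_quantile(1 - alpha / 2))
    ci_pct = (float(np.quantile(theta, alpha / 2)),
              float(np.quantile(theta, 1 - alpha / 2)))
    p_pos = np.mean(theta > 0)
    p_boot = float(2 * min(p_pos, 1 - p_pos))

    # direct effect c' t-check at the same level for the partial-mediation flag
    resid = _direct_effect_tstat(X, M, Y, point)
    crit = norm.ppf(1 - alpha / 2)
    excludes_zero = ci_bca[0] > 0 or ci_bca[1] < 0
    partial = bool(excludes_zero and abs(resid) > crit)

    sd_y = Y.std(ddof=1)
    return MediationResult(
        a=point["a"], b=point["b"], c=point["c"], c_prime=point["c_prime"],
        indirect=point["indirect"],
        indirect_standardized=point["indirect"] / sd_y if sd_y > 0 else np.nan,
        ci_bca=ci_bca, ci_percentile=ci_pct, level=level, p_boot=p_boot,
        z0=z0, accel=accel, n_boot=n_boot, n_redrawn=n_redrawn, seed=seed,
        boot_mean=float(theta.mean()), boot_sd=float(theta.std(ddof=1)),
        partial_mediation=partial, boot_indirect=theta,
    )


def _direct_effect_tstat(X, M, Y, point) -> float:
    """t statistic of c' in the outcome model Y ~ 1 + X + M."""
    n = X.size
    design = np.column_stack([np.ones(n), X, M])
    fitted = design @ np.array([
        Y.mean() - point["c_prime"] * X.mean() - point["b"] * M.mean(),
        point["c_prime"], point["b"],
    ])
    resid = Y - fitted
    sigma2 = resid @ resid / (n - 3)
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(cov[1, 1])
    return point["c_prime"] / se if se > 0 else np.inf
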