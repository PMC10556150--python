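"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes:
each subject's 23-component time series (230 samples at TR = 2 s)
switches among a small number of covariance regimes ("states") under a
first-order hidden Markov chain, the two groups (patients / controls)
differ in state occupancy, and clinical covariates are linearly coupled
to per-subject occupancy statistics. The real study is empirical and
defines no generative model; everything here is a documented stand-in
whose only job is to make every pipeline stage testable without the
original fMRI data.

All randomness flows from a single master seed fanned out with
``numpy.random.SeedSequence.spawn`` (one child per subject, in subject
order, plus one for the clinical table), so full-cohort regeneration
with the same spec and seed is bit-identical.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .types import ComponentTimecourses, NetworkPartition, WindowSpec

STATE_PROFILES = ("weak_sparse", "intermediate_1", "intermediate_2", "strong_dense")

#: Per-profile planted *partial* correlations: within-network chain
#: strengths (DMN, CEN, SN) and between-network link strengths
#: (DMN-CEN, DMN-SN, CEN-SN). States are planted in precision space —
#: the pipeline estimates regularized inverse covariances, so regimes
#: must differ in their conditional-dependence structure to be
#: recoverable; block-constant marginal correlations would collapse to
#: near-zero partial correlations in blocks this large.
_PROFILE_BLOCKS: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    # near-diagonal: weak connections everywhere
    "weak_sparse": ((0.05, 0.05, 0.05), (0.0, 0.0, 0.0)),
    # DMN-dominant regime with DMN-SN coupling and an anticorrelated CEN
    "intermediate_1": ((0.48, -0.25, 0.30), (0.0, 0.25, 0.0)),
    # CEN-dominant regime with an anticorrelated DMN
    "intermediate_2": ((-0.25, 0.45, -0.15), (0.0, 0.0, 0.22)),
    # strong intra- and inter-network coupling, elevated DMN and DMN-SN
    "strong_dense": ((0.40, 0.38, 0.38), (0.12, 0.25, 0.12)),
}

#: number of cross-network component pairs linked when a between-network
#: strength is nonzero
_N_CROSS_LINKS = 3


def _profile_precision(partition: NetworkPartition, profile: str) -> np.ndarray:
    within, between = _PROFILE_BLOCKS[profile]
    n = partition.n_components
    names = list(partition.names)
    offsets = np.concatenate(([0], np.cumsum(partition.sizes)))
    theta = np.eye(n)
    for b, rho in enumerate(within):
        lo, hi = offsets[b], offsets[b + 1]
        for i in range(lo, hi - 1):  # chain over adjacent components
            theta[i, i + 1] = theta[i + 1, i] = -rho
    pairs = [(0, 1), (0, 2), (1, 2)]
    for (ba, bb), rho in zip(pairs, between):
        if rho == 0:
            continue
        for i in range(min(_N_CROSS_LINKS, partition.sizes[ba], partition.sizes[bb])):
            a, b2 = offsets[ba] + i, offsets[bb] + i
            theta[a, b2] = theta[b2, a] = -rho
    return theta


def make_state_covariance(partition: NetworkPartition, profile: str) -> np.ndarray:
    """Build one state's component covariance from a named profile.

    The profile plants a sparse precision matrix (unit diagonal, chain
    partial correlations within each network block, a few cross-network
    links); the covariance is its inverse rescaled to a correlation
    matrix. Raises if the construction is not positive definite.
    """
    if profile not in _PROFILE_BLOCKS:
        raise ValueError(
            f"unknown profile {profile!r}; choose from {STATE_PROFILES}"
        )
    theta = _profile_precision(partition, profile)
    check_spd(theta, name=f"{profile} precision")
    cov = np.linalg.inv(theta)
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    cov = (cov + cov.T) / 2
    check_spd(cov, name=profile)
    return cov


def block_correlation_matrix(
    partition: NetworkPartition, within: float, between: float
) -> np.ndarray:
    """Block-constant correlation matrix (unit diagonal), for ad-hoc
    covariance specs and tests; raises if not positive definite."""
    n = partition.n_components
    nets = partition.component_networks
    same = nets[:, None] == nets[None, :]
    cov = np.where(same, within, between)
    np.fill_diagonal(cov, 1.0)
    check_spd(cov, name="block correlation matrix")
    return cov


def check_spd(matrix: np.ndarray, name: str = "matrix") -> None:
    """Raise with the offending eigenvalue if ``matrix`` is not SPD."""
    if not np.allclose(matrix, matrix.T):
        raise ValueError(f"{name} is not symmetric")
    eigmin = float(np.linalg.eigvalsh(matrix)[0])
    if eigmin <= 0:
        raise ValueError(
            f"{name} is not positive definite (smallest eigenvalue {eigmin:.3e})"
        )


def make_state_covariances(
    partition: NetworkPartition | None = None,
    profiles: Sequence[str] = STATE_PROFILES,
) -> list[np.ndarray]:
    """Covariances for all states, one named block profile per state."""
    partition = partition or NetworkPartition()
    return [make_state_covariance(partition, p) for p in profiles]


def _validate_transition_matrix(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if (P < 0).any():
        raise ValueError("transition probabilities must be non-negative")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("each transition-matrix row must sum to 1")
    return P


def transition_matrix_from_stay(stay: Sequence[float]) -> np.ndarray:
    """Markov matrix with given diagonal; off-row mass spread uniformly."""
    stay = np.asarray(stay, dtype=float)
    k = stay.size
    P = np.tile(((1.0 - stay) / (k - 1))[:, None], (1, k))
    P[np.diag_indices(k)] = stay
    return _validate_transition_matrix(P)


# Default stay probabilities. Patients (group A) dwell longer in the
# weakly connected state 1 and shorter in the strongly connected state 4
# than controls (group B); expected dwell time is 1/(1 - p_ss), i.e.
# roughly 125 vs 40 TRs for state 1. Dwell times sit well above the
# 30-TR window width (as in the emulated study, where mean dwell times
# reach 57-89 windows) so that windowed estimates see mostly-pure
# regimes; windows straddling a regime switch are genuinely ambiguous.
DEFAULT_STAY_A = (0.992, 0.985, 0.985, 0.975)
DEFAULT_STAY_B = (0.975, 0.985, 0.985, 0.992)


@dataclass(frozen=True)
class ClinicalCoupling:
    """One covariate as a linear-Gaussian function of an occupancy
    statistic: ``intercept + coef * stat + Normal(0, resid_sd)``."""

    intercept: float
    coef: float
    stat: str  # e.g. "frac_state1", "dwell_state4", "n_transitions"
    resid_sd: float

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise ValueError("residual sd must be non-negative")


# Default clinical model, loosely emulating the published covariate
# structure: cognition declines with time spent in the weakly connected
# state 1; anxiety/depression and endocrine measures rise with it (or
# fall with state-4 occupancy). Residual sds are sized so planted
# population correlations are moderate (|r| ~ 0.25-0.55).
DEFAULT_CLINICAL_MODEL: dict[str, ClinicalCoupling] = {
    "moca": ClinicalCoupling(26.0, -20.0, "frac_state1", 5.5),
    "sas": ClinicalCoupling(40.0, 25.0, "frac_state1", 9.0),
    "sds": ClinicalCoupling(48.0, -30.0, "frac_state4", 10.0),
    "cortisol_0800": ClinicalCoupling(300.0, 900.0, "frac_state1", 250.0),
    "acth_0800": ClinicalCoupling(8.0, 30.0, "frac_state1", 9.0),
    "ufc": ClinicalCoupling(150.0, 1200.0, "frac_state1", 350.0),
}


@dataclass
class SyntheticSpec:
    """Full description of one synthetic cohort.

    Defaults mirror the study design: 50 patients vs 57 controls, 23
    components partitioned 7/9/7 into DMN/CEN/SN, 230 timepoints at
    TR = 2 s, 4 covariance states.
    """

    n_group_a: int = 50
    n_group_b: int = 57
    partition: NetworkPartition = field(default_factory=NetworkPartition)
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    state_profiles: tuple[str, ...] = STATE_PROFILES
    state_covariances: list[np.ndarray] | None = None
    transition_matrix_a: np.ndarray | None = None
    transition_matrix_b: np.ndarray | None = None
    observation_noise_sd: float = 0.2
    clinical_model: Mapping[str, ClinicalCoupling] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_MODEL)
    )
    group_labels: tuple[str, str] = ("CD", "HC")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("each group needs at least one subject")
        if self.observation_noise_sd < 0:
            raise ValueError("observation noise sd must be non-negative")
        if self.state_covariances is None:
            self.state_covariances = make_state_covariances(
                self.partition, self.state_profiles
            )
        for i, cov in enumerate(self.state_covariances):
            check_spd(np.asarray(cov, dtype=float), name=f"state {i + 1} covariance")
            if np.asarray(cov).shape != (self.n_components, self.n_components):
                raise ValueError("state covariance shape mismatch")
        k = self.n_states
        if self.transition_matrix_a is None:
            self.transition_matrix_a = transition_matrix_from_stay(DEFAULT_STAY_A[:k])
        if self.transition_matrix_b is None:
            self.transition_matrix_b = transition_matrix_from_stay(DEFAULT_STAY_B[:k])
        self.transition_matrix_a = _validate_transition_matrix(self.transition_matrix_a)
        self.transition_matrix_b = _validate_transition_matrix(self.transition_matrix_b)
        if self.transition_matrix_a.shape != (k, k):
            raise ValueError("transition matrix A has wrong shape")
        if self.transition_matrix_b.shape != (k, k):
            raise ValueError("transition matrix B has wrong shape")

    @property
    def n_components(self) -> int:
        return self.partition.n_components

    @property
    def n_states(self) -> int:
        return len(self.state_covariances)

    def to_jsonable(self) -> dict:
        return {
            "n_group_a": self.n_group_a,
            "n_group_b": self.n_group_b,
            "partition_sizes": list(self.partition.sizes),
            "n_timepoints": self.n_timepoints,
            "tr_seconds": self.tr_seconds,
            "state_profiles": list(self.state_profiles),
            "observation_noise_sd": self.observation_noise_sd,
            "transition_matrix_a": np.asarray(self.transition_matrix_a).tolist(),
            "transition_matrix_b": np.asarray(self.transition_matrix_b).tolist(),
            "clinical_model": {
                name: {
                    "intercept": c.intercept,
                    "coef": c.coef,
                    "stat": c.stat,
                    "resid_sd": c.resid_sd,
                }
                for name, c in self.clinical_model.items()
            },
            "group_labels": list(self.group_labels),
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_jsonable(), indent=2)


@dataclass
class GroundTruth:
    """Generative truth for one subject: timepoint-level state labels
    (1-based), the transition matrix that produced them, and window-level
    labels by majority vote once a window spec is applied."""

    subject_id: str
    group: str
    state_labels: np.ndarray  # per timepoint, values 1..k
    transition_matrix: np.ndarray
    n_states: int

    def window_labels(self, window_spec: WindowSpec | None = None) -> np.ndarray:
        """Majority-vote state per sliding window; ties go to the lowest
        state label (np.argmax convention)."""
        spec = window_spec or WindowSpec()
        n_win = spec.n_windows(self.state_labels.size)
        out = np.empty(n_win, dtype=int)
        for w in range(n_win):
            s = w * spec.step_tr
            seg = self.state_labels[s : s + spec.width_tr]
            out[w] = np.bincount(seg, minlength=self.n_states + 1)[1:].argmax() + 1
        return out

    def occupancy_stat(self, stat: str, window_spec: WindowSpec | None = None) -> float:
        """Named occupancy statistic on the window-level label sequence."""
        from . import temporal

        labels = self.window_labels(window_spec)
        if stat.startswith("frac_state"):
            return temporal.fraction_time(labels, int(stat[len("frac_state"):]))
        if stat.startswith("dwell_state"):
            return temporal.mean_dwell_time(
                labels, int(stat[len("dwell_state"):]), n_states=self.n_states
            )
        if stat == "n_transitions":
            return float(temporal.n_transitions(labels))
        raise ValueError(f"unknown occupancy statistic {stat!r}")


def simulate_state_sequence(
    transition_matrix: np.ndarray,
    n_steps: int,
    rng: np.random.Generator | int,
    initial_state: int | None = None,
) -> np.ndarray:
    """Sample a 1-based label sequence from a first-order Markov chain.

    ``initial_state`` (1-based) defaults to a uniform draw over states.
    """
    P = _validate_transition_matrix(transition_matrix)
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = P.shape[0]
    cdf = np.cumsum(P, axis=1)
    labels = np.empty(n_steps, dtype=int)
    if initial_state is None:
        state = int(rng.integers(k))
    else:
        if not 1 <= initial_state <= k:
            raise ValueError("initial_state out of range")
        state = initial_state - 1
    labels[0] = state
    u = rng.random(n_steps)
    for t in range(1, n_steps):
        state = int(np.searchsorted(cdf[state], u[t], side="right"))
        state = min(state, k - 1)  # guard u == 1.0 edge
        labels[t] = state
    return labels + 1


def simulate_subject(
    spec: SyntheticSpec,
    group: str,
    subject_id: str,
    rng: np.random.Generator | int,
) -> tuple[ComponentTimecourses, GroundTruth]:
    """One subject: Markov state path + per-state Gaussian draws.

    Sample t is N(0, Sigma_state(t)) plus isotropic observation noise.
    """
    if group not in spec.group_labels:
        raise ValueError(f"group must be one of {spec.group_labels}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    P = spec.transition_matrix_a if group == spec.group_labels[0] else spec.transition_matrix_b
    labels = simulate_state_sequence(P, spec.n_timepoints, rng)
    chols = [np.linalg.cholesky(np.asarray(c, dtype=float)) for c in spec.state_covariances]
    z = rng.standard_normal((spec.n_timepoints, spec.n_components))
    data = np.empty_like(z)
    for s in range(spec.n_states):
        mask = labels == s + 1
        if mask.any():
            data[mask] = z[mask] @ chols[s].T
    if spec.observation_noise_sd > 0:
        data += spec.observation_noise_sd * rng.standard_normal(data.shape)
    tc = ComponentTimecourses(
        data=data,
        tr_seconds=spec.tr_seconds,
        subject_id=subject_id,
        partition=spec.partition,
    )
    gt = GroundTruth(
        subject_id=subject_id,
        group=group,
        state_labels=labels,
        transition_matrix=P,
        n_states=spec.n_states,
    )
    return tc, gt


def simulate_clinical(
    ground_truths: Sequence[GroundTruth],
    spec: SyntheticSpec,
    rng: np.random.Generator | int,
    window_spec: WindowSpec | None = None,
):
    """Clinical table: covariate = intercept + coef * occupancy + noise.

    Occupancy statistics are computed on majority-vote window labels so
    the planted couplings refer to the same quantities the analysis
    measures.
    """
    import pandas as pd

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows: dict[str, list] = {"subject_id": [], "group": []}
    for name in spec.clinical_model:
        rows[name] = []
    for gt in ground_truths:
        rows["subject_id"].append(gt.subject_id)
        rows["group"].append(gt.group)
        for name, coupling in spec.clinical_model.items():
            stat = gt.occupancy_stat(coupling.stat, window_spec)
            noise = coupling.resid_sd * rng.standard_normal() if coupling.resid_sd > 0 else 0.0
            rows[name].append(coupling.intercept + coupling.coef * stat + noise)
    return pd.DataFrame(rows)


@dataclass
class CohortBundle:
    """Everything the pipeline consumes plus generative ground truth."""

    spec: SyntheticSpec
    timecourses: list[ComponentTimecourses]
    ground_truths: list[GroundTruth]
    clinical: "object"  # pandas.DataFrame

    @property
    def groups(self) -> list[str]:
        return [gt.group for gt in self.ground_truths]


def make_cohort(spec: SyntheticSpec, window_spec: WindowSpec | None = None) -> CohortBundle:
    """Generate the full two-group cohort deterministically from spec.seed."""
    n_total = spec.n_group_a + spec.n_group_b
    children = np.random.SeedSequence(spec.seed).spawn(n_total + 1)
    tcs: list[ComponentTimecourses] = []
    gts: list[GroundTruth] = []
    idx = 0
    for group, n in zip(spec.group_labels, (spec.n_group_a, spec.n_group_b)):
        for i in range(n):
            sid = f"{group.lower()}{i + 1:03d}"
            tc, gt = simulate_subject(
                spec, group, sid, np.random.default_rng(children[idx])
            )
            tcs.append(tc)
            gts.append(gt)
            idx += 1
    clinical = simulate_clinical(
        gts, spec, np.random.default_rng(children[-1]), window_spec
    )
    return CohortBundle(spec=spec, timecourses=tcs, ground_truths=gts, clinical=clinical)
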