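"""Core domain containers shared across the pipeline.

The analysis operates on per-subject component time courses (time x
component matrices from a group ICA decomposition), a partition of
components into the three cognitive-control networks (default mode,
central executive, salience), and windowed functional network
connectivity (FNC) series derived from them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NETWORK_NAMES = ("DMN", "CEN", "SN")
DEFAULT_PARTITION_SIZES = (7, 9, 7)


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of components to networks, in component order.

    Components are assumed sorted by network: DMN block first, then CEN,
    then SN. ``sizes`` gives the block sizes (default 7/9/7, 23 total).
    """

    sizes: tuple[int, ...] = DEFAULT_PARTITION_SIZES
    names: tuple[str, ...] = NETWORK_NAMES

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.names):
            raise ValueError("sizes and names must have equal length")
        if any(s < 1 for s in self.sizes):
            raise ValueError("every network needs at least one component")

    @property
    def n_components(self) -> int:
        return int(sum(self.sizes))

    @property
    def component_networks(self) -> np.ndarray:
        """Network name of each component, length n_components."""
        return np.repeat(np.asarray(self.names, dtype=object), self.sizes)

    def block_labels(self) -> list[str]:
        """The 6 unordered network-block names: within blocks then between."""
        names = list(self.names)
        within = [f"{a}-{a}" for a in names]
        between = [
            f"{names[i]}-{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        return within + between

    def pair_block_index(self) -> np.ndarray:
        """For each upper-triangle component pair (row-major), the index of
        its network block in :meth:`block_labels` order."""
        nets = self.component_networks
        iu, ju = np.triu_indices(self.n_components, k=1)
        labels = self.block_labels()
        out = np.empty(iu.size, dtype=int)
        for idx, (i, j) in enumerate(zip(iu, ju)):
            a, b = nets[i], nets[j]
            key = f"{a}-{b}" if a == b else (
                f"{a}-{b}" if f"{a}-{b}" in labels else f"{b}-{a}"
            )
            out[idx] = labels.index(key)
        return out


@dataclass
class ComponentTimecourses:
    """One subject's time x component matrix with sampling metadata."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str
    partition: NetworkPartition = field(default_factory=NetworkPartition)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time courses must be a 2-D time x component array")
        if not np.isfinite(self.data).all():
            raise ValueError("time courses contain non-finite values")
        if self.data.shape[1] != self.partition.n_components:
            raise ValueError(
                f"{self.data.shape[1]} columns but partition declares "
                f"{self.partition.n_components} components"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "ComponentTimecourses":
        return ComponentTimecourses(
            data=data,
            tr_seconds=self.tr_seconds,
            subject_id=self.subject_id,
            partition=self.partition,
        )


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 60 s windows (30 TR at TR = 2 s) stepped
    by one TR. The window count convention is floor((T - width)/step),
    which yields 200 windows for a 230-sample scan."""

    width_tr: int = 30
    step_tr: int = 1

    def __post_init__(self) -> None:
        if self.width_tr < 2:
            raise ValueError("window width must be at least 2 samples")
        if self.step_tr < 1:
            raise ValueError("window step must be at least 1 sample")

    def n_windows(self, n_timepoints: int) -> int:
        if n_timepoints <= self.width_tr:
            raise ValueError(
                f"need more than {self.width_tr} timepoints, got {n_timepoints}"
            )
        return (n_timepoints - self.width_tr) // self.step_tr


@dataclass
class WindowedFNCSeries:
    """Per-subject windowed connectivity: n_windows x n_pairs Fisher-z
    partial correlations, plus window start indices (0-based)."""

    subject_id: str
    data: np.ndarray
    window_starts: np.ndarray
    lambda_used: float
    partition: NetworkPartition = field(default_factory=NetworkPartition)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("windowed FNC must be 2-D (windows x pairs)")
        if self.data.shape[0] != self.window_starts.size:
            raise ValueError("one start index required per window")
        if not np.isfinite(self.data).all():
            raise ValueError("windowed FNC contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.data.shape[1]


def pair_names(n_components: int) -> list[str]:
    """Upper-triangle row-major pair labels ``p_<i>_<j>`` (0-based)."""
    iu, ju = np.triu_indices(n_components, k=1)
    return [f"p_{i}_{j}" for i, j in zip(iu, ju)]
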