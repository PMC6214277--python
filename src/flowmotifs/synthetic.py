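"""Synthetic phase ensembles and planted weighted connectivity matrices.

Every downstream stage (PTE estimation, thresholding, motif census,
clustering) is testable against known ground truth generated here: directed
Kuramoto-style couplings for the phase generator, and two-level weight
matrices with planted bidirectional hubs for the network/motif stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pte import PTEMatrix
from .utils import wrap_phase

__all__ = [
    "CouplingSpec",
    "PhaseEnsemble",
    "PlantedStructure",
    "generate_coupled_phases",
    "generate_planted_weight_matrix",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Parameters of the coupled phase-oscillator generator.

    ``coupling[j, i]`` is the strength of the directed influence j -> i,
    applied through a sine of the lagged phase difference.
    """

    n_regions: int
    n_subjects: int
    n_epochs: int
    n_samples: int
    intrinsic_freqs: np.ndarray
    coupling: np.ndarray
    coupling_lag: int = 1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "intrinsic_freqs", np.asarray(self.intrinsic_freqs, dtype=float)
        )
        object.__setattr__(self, "coupling", np.asarray(self.coupling, dtype=float))
        if self.n_regions < 1 or self.n_subjects < 1 or self.n_epochs < 1:
            raise ValueError("n_regions, n_subjects and n_epochs must be >= 1")
        if self.intrinsic_freqs.shape != (self.n_regions,):
            raise ValueError("intrinsic_freqs must have one entry per region")
        if self.coupling.shape != (self.n_regions, self.n_regions):
            raise ValueError("coupling must be n_regions x n_regions")
        if np.any(np.diag(self.coupling) != 0.0):
            raise ValueError("coupling diagonal must be zero")
        if np.any(self.coupling < 0.0):
            raise ValueError("coupling strengths must be nonnegative")
        if int(self.coupling_lag) < 1:
            raise ValueError("coupling_lag must be >= 1")
        if self.coupling_lag >= self.n_samples:
            raise ValueError("coupling_lag must be smaller than n_samples")
        if self.n_samples < self.coupling_lag + 2:
            raise ValueError("n_samples must be >= coupling_lag + 2")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class PhaseEnsemble:
    """subjects x epochs x regions x samples array of phases in (-pi, pi]."""

    data: np.ndarray
    region_labels: list | None = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4:
            raise ValueError("data must be 4-D (subjects, epochs, regions, samples)")
        if not np.all((d > -np.pi) & (d <= np.pi)):
            raise ValueError("phases must lie in (-pi, pi]")
        self.data = d
        n_reg = d.shape[2]
        if self.region_labels is None:
            self.region_labels = [f"R{i:02d}" for i in range(n_reg)]
        else:
            self.region_labels = list(self.region_labels)
            if len(self.region_labels) != n_reg:
                raise ValueError("region_labels length does not match regions axis")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_regions(self) -> int:
        return self.data.shape[2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]


@dataclass
class PlantedStructure:
    """Ground truth for recovery tests: cluster labels and bidirectional hubs.

    ``cluster_assignment`` maps each region index to cluster 1 or 2;
    ``apex_nodes`` are the regions planted as bidirectional hubs.
    """

    cluster_assignment: np.ndarray
    apex_nodes: frozenset

    def __post_init__(self):
        a = np.asarray(self.cluster_assignment, dtype=int)
        if not set(np.unique(a)) <= {1, 2}:
            raise ValueError("cluster assignment values must be 1 or 2")
        if not (np.any(a == 1) and np.any(a == 2)):
            raise ValueError("both clusters must be non-empty")
        self.cluster_assignment = a
        self.apex_nodes = frozenset(int(v) for v in self.apex_nodes)
        if any(v < 0 or v >= a.size for v in self.apex_nodes):
            raise ValueError("apex node index out of range")


def generate_coupled_phases(spec: CouplingSpec) -> PhaseEnsemble:
    """Simulate lag-coupled phase oscillators, one independent run per epoch.

    x_i(t+1) = wrap(x_i(t) + w_i + sum_j c_ji * sin(x_j(t-lag) - x_i(t)) + eps),
    eps ~ N(0, noise_sd^2); each subject/epoch re-initialized from
    Uniform(-pi, pi].  The coupling term is active once lagged history exists
    (t >= lag).  Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n_reg, n_samp = spec.n_regions, spec.n_samples
    lag = int(spec.coupling_lag)
    omega = spec.intrinsic_freqs
    c = spec.coupling
    coupled = bool(np.any(c > 0))
    out = np.empty((spec.n_subjects, spec.n_epochs, n_reg, n_samp), dtype=float)
    for s in range(spec.n_subjects):
        for e in range(spec.n_epochs):
            x = np.empty((n_reg, n_samp), dtype=float)
            # -uniform(-pi, pi) lands in (-pi, pi]
            x[:, 0] = -rng.uniform(-np.pi, np.pi, size=n_reg)
            if spec.noise_sd > 0:
                noise = rng.normal(0.0, spec.noise_sd, size=(n_samp - 1, n_reg))
            else:
                noise = np.zeros((n_samp - 1, n_reg))
            for t in range(n_samp - 1):
                incr = omega + noise[t]
                if coupled and t >= lag:
                    diff = np.sin(x[:, t - lag][:, None] - x[:, t][None, :])
                    incr = incr + (c * diff).sum(axis=0)
                x[:, t + 1] = wrap_phase(x[:, t] + incr)
            out[s, e] = x
    return PhaseEnsemble(data=out)


def generate_planted_weight_matrix(
    n: int,
    structure: PlantedStructure,
    w_in: float,
    w_out: float,
    jitter_sd: float = 0.0,
    seed: int = 0,
    direction_offset: float = 0.0,
) -> PTEMatrix:
    """Two-level weight matrix with planted bidirectional hubs.

    Within-cluster entries incident to an apex node are drawn around ``w_in``
    in both directions (bidirectional after thresholding anywhere between the
    two levels); everything else is drawn around ``w_out``.  Jitter is
    |N(base, jitter_sd)| so weights stay nonnegative and are almost surely
    distinct.  ``direction_offset`` biases apex->other entries to
    w_in + offset and other->apex entries to w_in - offset (sender/receiver
    asymmetry).
    """
    if w_out < 0 or not (w_in > w_out):
        raise ValueError("require w_in > w_out >= 0")
    if n < 6:
        raise ValueError("require n >= 6")
    if structure.cluster_assignment.size != n:
        raise ValueError("structure size does not match n")
    rng = np.random.default_rng(seed)
    clusters = structure.cluster_assignment
    apex = structure.apex_nodes
    w = np.zeros((n, n), dtype=float)

    def draw(base):
        if jitter_sd > 0:
            return abs(rng.normal(base, jitter_sd))
        return float(base)

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            same_cluster = clusters[i] == clusters[j]
            i_apex, j_apex = i in apex, j in apex
            if same_cluster and (i_apex or j_apex):
                if i_apex and not j_apex:
                    base = w_in + direction_offset
                elif j_apex and not i_apex:
                    base = w_in - direction_offset
                else:
                    base = w_in
            else:
                base = w_out
            w[i, j] = draw(base)
    np.fill_diagonal(w, 0.0)
    meta = {
        "w_in": w_in,
        "w_out": w_out,
        "jitter_sd": jitter_sd,
        "seed": seed,
        "direction_offset": direction_offset,
    }
    return PTEMatrix(values=w, meta=meta)
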