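"""End-to-end orchestration: simulate -> PTE -> interval -> motifs -> clusters."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import io as fio
from .clustering import NoMotifParticipationError, cluster_pipeline
from .motifs import (
    apex_degree_correlation,
    apex_ratio,
    call_overexpression,
    census,
    enumerate_3motifs,
    high_degree_nodes,
    null_distribution,
)
from .netbuild import find_threshold_interval, network_properties, threshold_network
from .pte import pte_matrix
from .synthetic import CouplingSpec, generate_coupled_phases

__all__ = ["RunConfig", "PipelineStageError", "run_full_pipeline", "default_coupling"]


class PipelineStageError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    """All stage parameters of one reproducible run.

    An explicit ``seed`` is mandatory: runs with identical configs must be
    byte-identical.
    """

    seed: int | None = None
    out_dir: str = "flowmotifs_out"
    input_pte: str | None = None
    # synthetic stage
    n_regions: int = 10
    n_subjects: int = 1
    n_epochs: int = 4
    n_samples: int = 512
    noise_sd: float = 0.4
    coupling_strength: float = 0.8
    coupling_lag: int = 1
    freq_low: float = 0.2
    freq_high: float = 0.6
    # pte stage
    n_bins: int | None = None
    log_base: float | None = None
    # network stage
    percentile: float = 0.30
    # motif stage
    n_random: int = 200
    switch_factor: int = 100
    motif: int = 78
    delta: float = 0.005
    # clustering stage
    ties: str = "error"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat key=value (or key: value) config file."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            sep = "=" if "=" in line else ":"
            if sep not in line:
                raise ValueError(f"cannot parse config line {raw!r}")
            key, val = (part.strip() for part in line.split(sep, 1))
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = _coerce(key, val)
        return cls(**kwargs)


_INT_KEYS = {
    "seed", "n_regions", "n_subjects", "n_epochs", "n_samples",
    "coupling_lag", "n_bins", "n_random", "switch_factor", "motif",
}
_FLOAT_KEYS = {
    "noise_sd", "coupling_strength", "freq_low", "freq_high",
    "log_base", "percentile", "delta",
}


def _coerce(key: str, val: str):
    if val.lower() in ("none", ""):
        return None
    if key in _INT_KEYS:
        return int(val)
    if key in _FLOAT_KEYS:
        return float(val)
    return val


def default_coupling(n: int, strength: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-cluster coupling with one bidirectional hub per cluster.

    Returns (coupling matrix, cluster assignment).  Hubs are nodes 0 and
    n//2; each hub couples bidirectionally with its cluster members, seeding
    bidirectional-2-hop-path structure downstream.
    """
    c = np.zeros((n, n))
    assignment = np.ones(n, dtype=int)
    half = n // 2
    assignment[half:] = 2
    for hub, members in ((0, range(1, half)), (half, range(half + 1, n))):
        for m in members:
            c[hub, m] = strength
            c[m, hub] = strength
    return c, assignment


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage, write the artifacts, and return the JSON-able report."""
    if config.seed is None:
        raise ValueError("config must set an explicit seed (reproducibility contract)")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package": "flowmotifs",
        "seed": config.seed,
        # out_dir is a location, not a parameter: identical configs that only
        # differ in destination must produce byte-identical reports
        "parameters": {
            f.name: getattr(config, f.name)
            for f in fields(RunConfig)
            if f.name != "out_dir"
        },
    }

    if config.input_pte:
        pte = _stage("read_pte", fio.read_pte_tsv, config.input_pte)
    else:
        coupling, _ = default_coupling(config.n_regions, config.coupling_strength)
        freqs = np.linspace(config.freq_low, config.freq_high, config.n_regions)
        spec = CouplingSpec(
            n_regions=config.n_regions,
            n_subjects=config.n_subjects,
            n_epochs=config.n_epochs,
            n_samples=config.n_samples,
            intrinsic_freqs=freqs,
            coupling=coupling,
            coupling_lag=config.coupling_lag,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        ensemble = _stage("simulate", generate_coupled_phases, spec)
        pte = _stage(
            "pte", pte_matrix, ensemble, n_bins=config.n_bins, log_base=config.log_base
        )
    fio.write_pte_tsv(pte, out / "pte.tsv")
    report["pte"] = {"n_regions": pte.n, "meta": pte.meta}

    interval = _stage("interval", find_threshold_interval, pte, config.percentile)
    report["interval"] = {
        "tau_min": interval.tau_min,
        "tau_max": interval.tau_max,
        "percentile": interval.percentile_used,
    }

    taus = []
    k = 1
    while interval.tau_min + k * config.delta <= interval.tau_max:
        taus.append(interval.tau_min + k * config.delta)
        k += 1
    if not taus:
        # PTE scale smaller than delta: fall back to the interval midpoint
        taus = [(interval.tau_min + interval.tau_max) / 2.0]
        report["interval"]["delta_fallback_midpoint"] = True

    motif_ids = enumerate_3motifs()
    census_rows = []
    apex_sums: dict[int, float] = {}
    apex_counts: dict[int, int] = {}
    apex_corrs = []
    for t_index, tau in enumerate(taus):
        net = _stage("threshold", threshold_network, pte, tau)
        cens = _stage("census", census, net)
        null = _stage(
            "null_model",
            null_distribution,
            net,
            n_random=config.n_random,
            switch_factor=config.switch_factor,
            seed=config.seed + t_index,
        )
        calls = _stage("overexpression", call_overexpression, cens, null)
        props = network_properties(net)
        for m in motif_ids:
            c = calls.calls[m]
            census_rows.append(
                {
                    "tau": tau,
                    "motif": m,
                    "count": c.j,
                    "mu": c.mu,
                    "sigma": c.sigma,
                    "z": c.z,
                    "p": c.p,
                    "overexpressed": c.overexpressed,
                }
            )
        ratios = _stage("apex", apex_ratio, cens, net)
        for node, r in ratios.items():
            apex_sums[node] = apex_sums.get(node, 0.0) + r
            apex_counts[node] = apex_counts.get(node, 0) + 1
        corr = apex_degree_correlation(ratios, net)
        apex_corrs.append({"tau": tau, "pearson_r": corr})
        report.setdefault("networks", []).append(
            {
                "tau": tau,
                "n_uni": props.n_uni,
                "n_bi": props.n_bi,
                "avg_degree": props.avg_degree,
                "link_density": props.link_density,
                "assortativity": props.assortativity,
                "n_motif_ids": len(motif_ids),
            }
        )

    _write_census_tsv(census_rows, out / "motif_census.tsv")
    tau_mid = (interval.tau_min + interval.tau_max) / 2.0
    mid_net = threshold_network(pte, tau_mid)
    hubs = high_degree_nodes(mid_net)
    _write_apex_tsv(
        pte.region_labels, apex_sums, apex_counts, mid_net.total_degrees(), hubs,
        out / "apex.tsv",
    )
    report["apex"] = {
        "tau_mid": tau_mid,
        "n_high_degree_nodes": len(hubs),
        "correlations": apex_corrs,
    }

    try:
        partition = _stage(
            "cluster",
            cluster_pipeline,
            pte,
            motif=config.motif,
            percentile=config.percentile,
            ties=config.ties,
        )
        fio.write_partition_tsv(partition, out / "partition.tsv")
        report["partition"] = {
            "cluster1": partition.cluster1,
            "cluster2": partition.cluster2,
            "non_participants": partition.non_participants,
            "conductance": partition.conductance,
            "meta": partition.meta,
        }
    except PipelineStageError as exc:
        cause = exc.__cause__
        if isinstance(cause, NoMotifParticipationError):
            report["partition"] = {"refused": str(cause)}
        else:
            raise

    fio.write_json_report(report, out / "report.json")
    return report


def _write_census_tsv(rows, path):
    cols = ["tau", "motif", "count", "mu", "sigma", "z", "p", "overexpressed"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(repr(row[c]) for c in cols) + "\n")


def _write_apex_tsv(labels, sums, counts, degrees, hubs, path):
    with open(path, "w") as fh:
        fh.write("node\tmean_apex_ratio\tdegree\tis_high_degree\n")
        for i, label in enumerate(labels):
            ratio = repr(sums[i] / counts[i]) if i in counts else "NA"
            fh.write(f"{label}\t{ratio}\t{int(degrees[i])}\t{i in hubs}\n")
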