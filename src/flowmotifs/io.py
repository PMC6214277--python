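"""Plain-text readers and writers for matrices, networks and reports."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .clustering import MotifAdjacency, Partition
from .netbuild import DirectedBinaryNetwork
from .pte import PTEMatrix
from .synthetic import PhaseEnsemble

__all__ = [
    "read_pte_tsv",
    "write_pte_tsv",
    "write_matrix_tsv",
    "write_edge_list",
    "write_partition_tsv",
    "write_json_report",
    "save_phase_ensemble",
    "load_phase_ensemble",
]


def read_pte_tsv(path) -> PTEMatrix:
    """Read a labeled square TSV matrix.

    Header row and row labels must match in order.  A nonzero diagonal is
    coerced to zero with a warning; ragged or non-numeric rows raise with the
    offending row named.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError("matrix file needs a header and at least one row")
    header = lines[0].split("\t")
    labels = header[1:]
    n = len(labels)
    if n < 2:
        raise ValueError("matrix must have at least 2 columns")
    values = np.zeros((n, n), dtype=float)
    if len(lines) - 1 != n:
        raise ValueError(f"expected {n} data rows, found {len(lines) - 1}")
    row_labels = []
    for r, ln in enumerate(lines[1:]):
        parts = ln.split("\t")
        label = parts[0]
        if len(parts) != n + 1:
            raise ValueError(
                f"row {label!r} has {len(parts) - 1} values, expected {n}"
            )
        row_labels.append(label)
        try:
            values[r] = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"row {label!r} contains a non-numeric value") from exc
    if row_labels != labels:
        raise ValueError("row labels do not match header labels")
    if np.any(np.diag(values) != 0.0):
        warnings.warn("nonzero diagonal in PTE matrix; coercing to zero", stacklevel=2)
        np.fill_diagonal(values, 0.0)
    return PTEMatrix(values=values, region_labels=labels)


def write_matrix_tsv(values: np.ndarray, labels, path) -> None:
    values = np.asarray(values)
    labels = list(labels)
    with open(path, "w") as fh:
        fh.write("\t".join(["region"] + labels) + "\n")
        for label, row in zip(labels, values):
            fh.write("\t".join([label] + [repr(float(v)) for v in row]) + "\n")


def write_pte_tsv(pte: PTEMatrix, path) -> None:
    write_matrix_tsv(pte.values, pte.region_labels, path)


def write_motif_adjacency_tsv(wm: MotifAdjacency, path) -> None:
    write_matrix_tsv(wm.w, wm.node_labels, path)


def write_edge_list(net: DirectedBinaryNetwork, path) -> None:
    """Directed edge list, one 'source<TAB>target' line per link."""
    labels = net.node_labels
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(net.adjacency)):
            fh.write(f"{labels[i]}\t{labels[j]}\n")


def write_partition_tsv(partition: Partition, path) -> None:
    assignment = partition.assignment()
    with open(path, "w") as fh:
        fh.write("node\tgroup\n")
        for node in sorted(assignment, key=str):
            fh.write(f"{node}\t{assignment[node]}\n")


def write_json_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_phase_ensemble(ens: PhaseEnsemble, prefix) -> None:
    """Dense array (.npy) plus a JSON sidecar with labels and shape."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), ens.data)
    sidecar = {
        "region_labels": ens.region_labels,
        "shape": list(ens.data.shape),
        "axes": ["subjects", "epochs", "regions", "samples"],
    }
    write_json_report(sidecar, prefix.with_suffix(".json"))


def load_phase_ensemble(prefix) -> PhaseEnsemble:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return PhaseEnsemble(data=data, region_labels=sidecar["region_labels"])
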