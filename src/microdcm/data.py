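"""Evoked-response dataset containers and plain-text I/O.

ERP matrices travel as tab-delimited text: first column is peristimulus
time in ms, one column per source, with a header row of source names.  A
JSON sidecar carries sampling metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ERPDataset",
    "write_erp_tsv",
    "read_erp_tsv",
    "write_dataset",
    "read_dataset",
]


@dataclass
class ERPDataset:
    """Per-subject, per-condition source x time evoked responses."""

    subject: str
    sources: list[str]
    times: np.ndarray
    fs: float
    conditions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nt = len(self.times)
        ns = len(self.sources)
        for cond, mat in self.conditions.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (ns, nt):
                raise ValueError(
                    f"condition {cond!r}: expected shape {(ns, nt)}, got {mat.shape}"
                )
            self.conditions[cond] = mat

    def stacked(self, order: tuple[str, ...] = ("novel", "repeated")) -> np.ndarray:
        """Concatenate condition matrices into one (n_cond, S, T) array."""
        return np.stack([self.conditions[c] for c in order])


def write_erp_tsv(path, times, matrix, sources) -> None:
    """Write one (S, T) ERP matrix as time x sources tab-delimited text."""
    matrix = np.asarray(matrix, dtype=float)
    table = np.column_stack([np.asarray(times, dtype=float), matrix.T])
    header = "\t".join(["time_ms"] + list(sources))
    np.savetxt(path, table, delimiter="\t", header=header, comments="", fmt="%.10g")


def read_erp_tsv(path):
    """Read an ERP matrix written by :func:`write_erp_tsv`.

    Returns ``(times, matrix (S, T), sources)``.
    """
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    if header[0] != "time_ms":
        raise ValueError(f"{path}: expected 'time_ms' as first column")
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return data[:, 0], data[:, 1:].T, header[1:]


def write_dataset(dataset: ERPDataset, out_dir) -> Path:
    """Write one subject's conditions plus a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cond, mat in dataset.conditions.items():
        write_erp_tsv(out / f"{cond}.tsv", dataset.times, mat, dataset.sources)
    meta = {
        "subject": dataset.subject,
        "sources": dataset.sources,
        "fs": dataset.fs,
        "t_start_ms": float(dataset.times[0]),
        "t_end_ms": float(dataset.times[-1]),
        "n_times": int(len(dataset.times)),
        "conditions": sorted(dataset.conditions),
    }
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def read_dataset(subj_dir) -> ERPDataset:
    subj_dir = Path(subj_dir)
    with open(subj_dir / "meta.json") as fh:
        meta = json.load(fh)
    conditions = {}
    times = None
    sources = meta["sources"]
    for cond in meta["conditions"]:
        t, mat, src = read_erp_tsv(subj_dir / f"{cond}.tsv")
        if src != list(sources):
            raise ValueError(f"{subj_dir}: source mismatch in {cond}.tsv")
        conditions[cond] = mat
        times = t
    return ERPDataset(
        subject=meta["subject"],
        sources=list(sources),
        times=times,
        fs=float(meta["fs"]),
        conditions=conditions,
    )
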