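"""File formats: coupling/topology triplets, trajectory exports, spike and
bout tables, subject manifests.

All tabular formats are plain delimited text; couplings optionally
gzip-compressed.  Neuron indices are 0-based throughout.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from critmem.network import CoupledNetwork, Topology
from critmem.branching import SpikeDataset
from critmem.dynamics import TrajectorySummary

__all__ = [
    "write_coupling",
    "read_coupling",
    "write_trajectory",
    "write_spikes",
    "read_spikes",
    "write_bouts",
    "read_bouts",
    "read_spike_dataset",
    "read_manifest",
]


def write_coupling(network: CoupledNetwork, path: str | Path, metadata: dict | None = None):
    """Sparse triplet export (source, target, weight; tab-separated,
    gzipped if the path ends in .gz) with a JSON parameter sidecar."""
    path = Path(path)
    coo = network.weights.tocoo()
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("source\ttarget\tweight\n")
        for s, t, w in zip(coo.col, coo.row, coo.data):
            fh.write(f"{s}\t{t}\t{w:.12g}\n")
    meta = {
        "n_neurons": network.n_neurons,
        "in_degree": network.in_degree,
        "rewire_prob": network.topology.rewire_prob,
        "seed": network.topology.seed,
        "n_input_sources": int(network.input_sources.size),
        "input_sources": network.input_sources.tolist(),
    }
    if metadata:
        meta.update(metadata)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))


def read_coupling(path: str | Path) -> CoupledNetwork:
    """Read a triplet coupling file and its JSON sidecar back into a
    CoupledNetwork (sources table reconstructed from the edges)."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path, sep="\t")
    n = int(meta["n_neurons"])
    k = int(meta["in_degree"])
    mat = sp.csr_matrix(
        (df["weight"].values, (df["target"].values, df["source"].values)),
        shape=(n, n),
    )
    order = np.lexsort((df["source"].values, df["target"].values))
    sources = df["source"].values[order].reshape(n, k)
    topo = Topology(
        n_neurons=n,
        in_degree=k,
        rewire_prob=float(meta["rewire_prob"]),
        sources=sources,
        seed=meta.get("seed"),
    )
    return CoupledNetwork(
        topology=topo,
        weights=mat,
        input_sources=np.asarray(meta.get("input_sources", []), dtype=np.intp),
    )


def write_trajectory(
    summary: TrajectorySummary, path: str | Path, metadata: dict | None = None
):
    """Tidy CSV (iteration, memory_index, overlap_native, overlap_new,
    flip_fraction) plus a JSON metadata sidecar."""
    path = Path(path)
    n_iter, p = summary.overlaps_native.shape
    rows = []
    for t in range(n_iter):
        for mu in range(p):
            rows.append(
                {
                    "iteration": t,
                    "memory_index": mu,
                    "overlap_native": summary.overlaps_native[t, mu],
                    "overlap_new": summary.overlap_new[t],
                    "flip_fraction": summary.flip_fraction[t],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(metadata, indent=2)
        )


def write_spikes(dataset: SpikeDataset, path: str | Path):
    """Two-column spike file: unit_id <TAB> spike_time_s, time-sorted within
    unit."""
    with open(path, "w") as fh:
        fh.write("unit_id\tspike_time_s\n")
        for u, times in enumerate(dataset.units):
            for t in times:
                fh.write(f"{u}\t{t:.6f}\n")


def read_spikes(path: str | Path) -> list[np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    n_units = int(df["unit_id"].max()) + 1 if len(df) else 0
    return [
        np.sort(df.loc[df["unit_id"] == u, "spike_time_s"].values)
        for u in range(n_units)
    ]


def write_bouts(bouts: pd.DataFrame, path: str | Path):
    bouts.to_csv(path, sep="\t", index=False)


def read_bouts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_spike_dataset(
    spike_file: str | Path,
    bout_file: str | Path,
    subject_id: str = "",
    condition: str = "",
) -> SpikeDataset:
    return SpikeDataset(
        units=read_spikes(spike_file),
        bouts=read_bouts(bout_file),
        subject_id=subject_id,
        condition=condition,
    )


def read_manifest(manifest_file: str | Path) -> list[SpikeDataset]:
    """Load every subject listed in a manifest.tsv (subject, condition,
    spike_file, bout_file; paths relative to the manifest)."""
    manifest_file = Path(manifest_file)
    df = pd.read_csv(manifest_file, sep="\t")
    base = manifest_file.parent
    return [
        read_spike_dataset(
            base / row["spike_file"],
            base / row["bout_file"],
            subject_id=row["subject"],
            condition=row["condition"],
        )
        for _, row in df.iterrows()
    ]
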