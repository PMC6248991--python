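"""Per-phenotype analysis orchestration and cross-phenotype comparison.

A :class:`StudyConfig` names one phenotype's topology, replica trajectories
(R0 plus restarts), selections, strides and network parameters.
:func:`run_study` runs the full stage chain — superposition → RMSD/RMSF →
secondary structure → PCA/cosine content → DCCM → correlation network →
community connectivity — writing every stage table under a run directory
with a manifest, deterministically for a fixed config + seed.
:func:`compare_phenotypes` lines up the per-phenotype reports side by side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_model import (
    Selection,
    Topology,
    Trajectory,
    read_topology,
    read_trajectory,
    select,
)
from .fit_fluct import rmsd_series, rmsf
from .essential_dynamics import covariance, project, cosine_content
from .dynamic_network import (
    build_network,
    connectivity_report,
    dccm,
    filter_communities,
    girvan_newman,
)
from .structure_env import assign_secondary_structure, helix_counts

__all__ = ["StudyConfig", "StudyReport", "run_study", "compare_phenotypes"]

_FLOAT_FMT = "%.10g"


@dataclass
class StudyConfig:
    """One phenotype's inputs and parameters."""

    label: str
    topology: str
    replicas: list[str]  # trajectory paths; first entry is R0
    segment_config: str | dict | None = None
    temperature: str = "310K"
    fit_selection: str = "name CA"
    measure_selection: str = "name CA"
    pca_stride_ps: float = 4.0
    network_stride_ps: float = 100.0
    cutoff: float = 0.7
    min_seq_separation: int = 2
    min_community_size: int = 10
    connectivity_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("TM2", "TM5")]
    )
    secondary_structure: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["connectivity_pairs"] = [
            tuple(p) for p in data.get("connectivity_pairs", [["TM2", "TM5"]])
        ]
        return cls(**data)

    def validate(self) -> None:
        if not Path(self.topology).exists():
            raise FileNotFoundError(f"topology not found: {self.topology}")
        if not self.replicas:
            raise ValueError("at least one replica trajectory is required")
        for p in self.replicas:
            if not Path(p).exists():
                raise FileNotFoundError(f"replica trajectory not found: {p}")
        if isinstance(self.segment_config, str) and not Path(self.segment_config).exists():
            raise FileNotFoundError(f"segment config not found: {self.segment_config}")


@dataclass
class StudyReport:
    """Aggregated per-phenotype results with file provenance."""

    label: str
    measure_selection: str
    out_dir: str
    rmsf_table: pd.DataFrame
    rmsd_table: pd.DataFrame
    helix_table: pd.DataFrame | None
    eigenvalue_table: pd.DataFrame
    cc_table: pd.DataFrame
    community_table: pd.DataFrame
    final_q: float
    connectivity: dict[str, bool]
    files: dict[str, str]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _concatenate(replicas: list[Trajectory]) -> Trajectory:
    coords = np.concatenate([t.coordinates for t in replicas], axis=0)
    dt = (
        float(np.median(np.diff(replicas[0].times)))
        if replicas[0].n_frames > 1
        else 1.0
    )
    return Trajectory(
        coordinates=coords,
        times=np.arange(coords.shape[0]) * dt,
        box=None,
        topology=replicas[0].topology,
    )


def run_study(config: StudyConfig, out_dir: str | Path) -> StudyReport:
    """Run the full analysis chain for one phenotype.

    All stage outputs land under ``out_dir`` together with a ``manifest.json``
    recording inputs, parameters, seed and package version.  Reruns with the
    same config and seed reproduce every table byte-for-byte.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    top = read_topology(config.topology, config.segment_config)
    replicas = [read_trajectory(p, top) for p in config.replicas]
    r0 = replicas[0]
    fit = select(top, config.fit_selection)
    meas = select(top, config.measure_selection)

    # --- fluctuations -----------------------------------------------------
    prof = rmsf(r0, fit, meas, replicas=replicas[1:])
    rmsf_df = pd.DataFrame(
        {
            "resid": prof.resids,
            "segment": top.segments[meas],
            "rmsf": prof.rmsf,
            "replica_mean": prof.replica_mean,
            "replica_sd": prof.replica_sd,
        }
    )
    _write_csv(rmsf_df, out / "rmsf.csv")
    files["rmsf"] = "rmsf.csv"

    seg_labels = [s for s in pd.unique(top.segments[meas]) if s.startswith(("TM", "H8"))]
    rmsd_df = pd.DataFrame({"time_ps": r0.times})
    for seg in seg_labels:
        seg_sel = meas[top.segments[meas] == seg]
        rmsd_df[seg] = rmsd_series(r0, fit, seg_sel)
    _write_csv(rmsd_df, out / "rmsd_segments.csv")
    files["rmsd"] = "rmsd_segments.csv"

    # --- secondary structure ---------------------------------------------
    helix_df = None
    if config.secondary_structure:
        assignments = [assign_secondary_structure(t) for t in replicas]
        helix_df = helix_counts(assignments, segments=seg_labels)
        _write_csv(helix_df, out / "helix_counts.csv")
        files["helix_counts"] = "helix_counts.csv"

    # --- essential dynamics ----------------------------------------------
    model = covariance(r0, fit, meas, stride_ps=config.pca_stride_ps)
    n_eig = min(20, len(model.eigenvalues))
    eig_df = pd.DataFrame(
        {
            "component": np.arange(1, n_eig + 1),
            "eigenvalue_A2": model.eigenvalues[:n_eig],
        }
    )
    _write_csv(eig_df, out / "pca_eigenvalues.csv")
    files["eigenvalues"] = "pca_eigenvalues.csv"

    cc_rows = []
    for k, t in enumerate(replicas):
        series = project(t, model, component=0)
        cc_rows.append({"replica": f"R{k}", "cosine_content": cosine_content(series)})
        if k == 0:
            proj_df = pd.DataFrame({"time_ps": series.times, "pc1_A": series.values})
            _write_csv(proj_df, out / "projection_pc1.csv")
            files["projection"] = "projection_pc1.csv"
    cc_df = pd.DataFrame(cc_rows)
    _write_csv(cc_df, out / "cosine_content.csv")
    files["cosine_content"] = "cosine_content.csv"

    # --- correlation network ----------------------------------------------
    pooled = _concatenate(replicas)
    matrix = dccm(pooled, meas, stride_ps=config.network_stride_ps, fit_selection=fit)
    net = girvan_newman(
        build_network(matrix, cutoff=config.cutoff,
                      min_seq_separation=config.min_seq_separation)
    )
    net = filter_communities(net, config.min_community_size)
    node_rows = []
    node_to_comm = {}
    for k, comm in enumerate(net.reported_communities):
        for n in comm:
            node_to_comm[n] = k
    for i in range(matrix.n_nodes):
        node_rows.append(
            {
                "resid": int(matrix.resids[i]) if matrix.resids is not None else i,
                "segment": str(matrix.segments[i]) if matrix.segments is not None else "",
                "community": node_to_comm.get(i, -1),
            }
        )
    comm_df = pd.DataFrame(node_rows)
    _write_csv(comm_df, out / "communities.csv")
    files["communities"] = "communities.csv"

    connectivity = {}
    for seg_a, seg_b in config.connectivity_pairs:
        ok, _pairs = connectivity_report(net, seg_a, seg_b)
        connectivity[f"{seg_a}:{seg_b}"] = bool(ok)

    summary = {
        "label": config.label,
        "modularity": net.final_q,
        "n_reported_communities": len(net.reported_communities),
        "connectivity": connectivity,
    }
    (out / "network_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    files["network_summary"] = "network_summary.json"

    manifest = {
        "label": config.label,
        "inputs": {"topology": config.topology, "replicas": list(config.replicas)},
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("label", "topology", "replicas", "segment_config")
        },
        "seed": config.seed,
        "version": __version__,
        "outputs": files,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )

    return StudyReport(
        label=config.label,
        measure_selection=config.measure_selection,
        out_dir=str(out),
        rmsf_table=rmsf_df,
        rmsd_table=rmsd_df,
        helix_table=helix_df,
        eigenvalue_table=eig_df,
        cc_table=cc_df,
        community_table=comm_df,
        final_q=net.final_q,
        connectivity=connectivity,
        files=files,
    )


def compare_phenotypes(reports: list[StudyReport]) -> dict[str, pd.DataFrame]:
    """Side-by-side comparison tables across phenotype reports.

    Requires ≥ 2 reports computed over matching measure selections.  Returns
    RMSF deltas (vs the first report), helix-count deltas with replica SDs,
    the cosine-content table, and the pairwise connectivity matrix.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    base = reports[0]
    for r in reports[1:]:
        if r.measure_selection != base.measure_selection:
            raise ValueError(
                f"mismatched selections: {r.measure_selection!r} vs "
                f"{base.measure_selection!r}"
            )
    rmsf_cmp = base.rmsf_table[["resid", "segment"]].copy()
    for r in reports:
        rmsf_cmp[f"rmsf_{r.label}"] = r.rmsf_table["replica_mean"].to_numpy()
        rmsf_cmp[f"sd_{r.label}"] = r.rmsf_table["replica_sd"].to_numpy()
    for r in reports[1:]:
        rmsf_cmp[f"delta_{r.label}"] = (
            rmsf_cmp[f"rmsf_{r.label}"] - rmsf_cmp[f"rmsf_{base.label}"]
        )

    helix_cmp = None
    if all(r.helix_table is not None for r in reports):
        helix_cmp = reports[0].helix_table[["segment"]].copy()
        for r in reports:
            helix_cmp[f"mean_{r.label}"] = r.helix_table["mean"].to_numpy()
            helix_cmp[f"sd_{r.label}"] = r.helix_table["sd"].to_numpy()
        for r in reports[1:]:
            helix_cmp[f"delta_{r.label}"] = (
                helix_cmp[f"mean_{r.label}"] - helix_cmp[f"mean_{base.label}"]
            )

    cc_rows = []
    for r in reports:
        for _, row in r.cc_table.iterrows():
            cc_rows.append(
                {"label": r.label, "replica": row["replica"],
                 "cosine_content": row["cosine_content"]}
            )
    cc_cmp = pd.DataFrame(cc_rows)

    pairs = sorted({p for r in reports for p in r.connectivity})
    conn_rows = []
    for p in pairs:
        row = {"pair": p}
        for r in reports:
            row[r.label] = r.connectivity.get(p, None)
        conn_rows.append(row)
    conn_cmp = pd.DataFrame(conn_rows)

    out = {"rmsf": rmsf_cmp, "cosine_content": cc_cmp, "connectivity": conn_cmp}
    if helix_cmp is not None:
        out["helix_counts"] = helix_cmp
    return out
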