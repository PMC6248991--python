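#!/usr/bin/env python
"""Generate the synthetic study systems.

Builds an idealized 7-helix transmembrane bundle (residues numbered from
358, as in the receptor's author numbering) and samples two phenotypes of
harmonic Cα ensembles, three replicas each:

* ``functional``     — a planted correlation block coupling TM2 and TM5
                       (ρ = 0.9), emulating the concerted inter-helix motion
                       of a signalling-competent receptor;
* ``dysfunctional``  — the same fluctuation amplitudes with no inter-helix
                       coupling (null plant).

Trajectories are written as plain frame tables under scratch/data/ (large,
regenerable; not part of the repository deliverable), together with the PDB
reference and the segment configuration.  A short manifest lands in
results/.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from memdyn.io_model import write_topology, write_trajectory
from memdyn.synthetic import EnsembleSpec, make_bundle_reference, sample_ensemble

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

N_HELICES = 7
RESIDUES_PER_HELIX = 12
N_FRAMES = 600          # per replica, at 100-ps spacing: 60 ns of sampling
DT_PS = 100.0
SIGMA = 0.5             # Å per coordinate: RMSF σ√3 ≈ 0.87 Å (rigid regime)
PHENOTYPES = {"functional": 0.9, "dysfunctional": None}
BASE_SEED = 20260920


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    top, ref = make_bundle_reference(N_HELICES, RESIDUES_PER_HELIX)
    write_topology(DATA / "bundle.pdb", top, ref)
    first = int(top.resids.min())
    seg_cfg = {
        "segments": {
            f"TM{i + 1}": [[first + i * RESIDUES_PER_HELIX,
                            first + (i + 1) * RESIDUES_PER_HELIX - 1]]
            for i in range(N_HELICES)
        }
    }
    (DATA / "segments.yaml").write_text(yaml.safe_dump(seg_cfg))

    manifest = {"topology": "bundle.pdb", "segments": "segments.yaml",
                "phenotypes": {}}
    for idx, (label, rho) in enumerate(PHENOTYPES.items()):
        blocks = [("TM2", "TM5", rho)] if rho is not None else []
        paths = []
        for r in range(3):
            spec = EnsembleSpec(
                topology=top, reference=ref, per_atom_sigma=SIGMA,
                correlation_blocks=blocks, n_frames=N_FRAMES, dt=DT_PS,
                seed=BASE_SEED + 1000 * idx + r,
            )
            traj, _ = sample_ensemble(spec)
            name = f"{label}_R{r}.traj"
            write_trajectory(DATA / name, traj)
            paths.append(name)
        manifest["phenotypes"][label] = {
            "rho_tm2_tm5": rho, "replicas": paths,
            "n_frames": N_FRAMES, "dt_ps": DT_PS, "sigma_A": SIGMA,
        }
        print(f"{label}: 3 replicas x {N_FRAMES} frames "
              f"({N_FRAMES * DT_PS / 1000:.0f} ns at {DT_PS:.0f} ps), "
              f"TM2-TM5 rho = {rho}")
    (RESULTS / "ensembles_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    print(f"wrote trajectories under {DATA}")


if __name__ == "__main__":
    main()
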