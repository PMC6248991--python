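"""Shared fixtures: small synthetic bundles, anchored toy systems, helpers."""

from __future__ import annotations

import numpy as np
import pytest

from memdyn.io_model import Topology, Trajectory
from memdyn.synthetic import EnsembleSpec, make_bundle_reference, sample_ensemble


@pytest.fixture(scope="session")
def small_bundle():
    """7-helix bundle, 12 residues per helix (84 residues, backbone only)."""
    return make_bundle_reference(n_helices=7, residues_per_helix=12)


@pytest.fixture(scope="session")
def bundle_25():
    """7-helix bundle, 25 residues per helix (the study-scale fixture)."""
    return make_bundle_reference(n_helices=7, residues_per_helix=25)


def anchored_system(n_moving: int, extra_names=None):
    """Topology with 4 static tetrahedral anchor atoms + n moving CA atoms.

    The anchors give superposition a rigid, motion-free frame so planted
    per-atom displacements survive fitting exactly.  Returns
    ``(topology, base_coordinates, anchor_idx, moving_idx)``.
    """
    anchors = np.array(
        [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0], [0.0, 0.0, 10.0]]
    )
    rng = np.random.default_rng(42)
    moving = rng.uniform(15.0, 25.0, size=(n_moving, 3))
    names = ["CA"] * (4 + n_moving) if extra_names is None else extra_names
    top = Topology(
        names=names,
        elements=["C"] * (4 + n_moving),
        resids=list(range(1, 4 + n_moving + 1)),
        resnames=["ALA"] * (4 + n_moving),
        chains=["A"] * (4 + n_moving),
        segments=["NT"] * 4 + ["TM1"] * n_moving,
    )
    coords = np.vstack([anchors, moving])
    return top, coords, np.arange(4), np.arange(4, 4 + n_moving)


def make_trajectory(base, displacements, times=None, topology=None):
    """Stack ``base + displacement`` frames into a Trajectory."""
    disp = np.asarray(displacements, dtype=float)
    coords = base[None, :, :] + disp
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(coordinates=coords, times=times, topology=topology)


@pytest.fixture()
def block_ensemble_factory():
    """Factory for bundle ensembles with an optional planted TM2-TM5 block."""

    def _make(rho=None, n_frames=1500, seed=0, sigma=0.5, residues=12, dt=100.0):
        top, ref = make_bundle_reference(7, residues)
        blocks = [("TM2", "TM5", rho)] if rho is not None else []
        spec = EnsembleSpec(
            topology=top,
            reference=ref,
            per_atom_sigma=sigma,
            correlation_blocks=blocks,
            n_frames=n_frames,
            dt=dt,
            seed=seed,
        )
        traj, cov = sample_ensemble(spec)
        return top, traj, cov

    return _make
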