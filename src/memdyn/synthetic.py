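"""Synthetic ensembles with planted statistical structure.

The study system — a seven-helix transmembrane bundle fluctuating in a lipid
bilayer — is emulated at three levels, each with exact ground truth so every
analysis stage can be tested against known answers:

* :func:`make_bundle_reference` builds an idealized α-helix bundle
  (φ = −57°, ψ = −47°, rise ≈ 1.5 Å/residue) with TM1..TMn segment labels;
* :func:`sample_ensemble` draws harmonic Gaussian fluctuations about the
  reference with planted per-atom variances, planted inter-segment correlation
  blocks, and optional slow diffusive drift of the mean (the regime the
  cosine-content diagnostic flags as unconverged sampling);
* :func:`make_membrane_box` places water / phosphate-like / methyl-like
  pseudo-atom slabs in a box for density profiling, with a planted hydrophobic
  core and interface geometry.

All generators are pure functions of ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_model import Topology, Trajectory

__all__ = [
    "EnsembleSpec",
    "MembraneBoxSpec",
    "make_bundle_reference",
    "make_chain",
    "sample_ensemble",
    "make_membrane_box",
]

# Ideal backbone internal coordinates (Å, degrees), trans peptide.
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.2, 121.7, 120.8
_PHI_HELIX, _PSI_HELIX, _OMEGA = -57.0, -47.0, 180.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D given A-B-C."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.cos(dih) * np.sin(ang),
         bond * np.sin(dih) * np.sin(ang)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_helix_backbone(n_res: int, phi: float, psi: float) -> np.ndarray:
    """Backbone (N, CA, C, O) coordinates of an ideal polypeptide helix.

    Returns an array of shape (n_res, 4, 3); atom order N, CA, C, O.
    """
    if n_res < 1:
        raise ValueError("residue count must be positive")
    atoms = np.zeros((n_res, 4, 3))
    # seed residue in an arbitrary frame
    atoms[0, 0] = [0.0, 0.0, 0.0]                                  # N
    atoms[0, 1] = [_B_N_CA, 0.0, 0.0]                              # CA
    ang = np.deg2rad(_A_N_CA_C)
    atoms[0, 2] = atoms[0, 1] + [
        -_B_CA_C * np.cos(ang), _B_CA_C * np.sin(ang), 0.0]        # C
    for i in range(n_res):
        n_i, ca_i, c_i = atoms[i, 0], atoms[i, 1], atoms[i, 2]
        if i + 1 < n_res:
            n_next = _place_atom(n_i, ca_i, c_i, _B_C_N, _A_CA_C_N, psi)
            atoms[i + 1, 0] = n_next
            atoms[i + 1, 1] = _place_atom(ca_i, c_i, n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
            atoms[i + 1, 2] = _place_atom(
                c_i, n_next, atoms[i + 1, 1], _B_CA_C, _A_N_CA_C, phi)
        # carbonyl O in the peptide plane: dihedral N-CA-C-O = psi + 180
        atoms[i, 3] = _place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, psi + 180.0)
    return atoms


def _align_to_z(coords: np.ndarray, ca: np.ndarray) -> np.ndarray:
    """Rotate so the first-to-last CA vector points along +z, axis at origin."""
    axis = ca[-1] - ca[0]
    if np.linalg.norm(axis) < 1e-9:
        return coords - ca.mean(axis=0)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    out = coords @ rot.T
    center = (ca @ rot.T).mean(axis=0)
    return out - center


def make_bundle_reference(
    n_helices: int = 7,
    residues_per_helix: int | Sequence[int] = 25,
    bundle_radius: float | None = None,
    first_resid: int = 358,
    antiparallel: bool = True,
) -> tuple[Topology, np.ndarray]:
    """Build an idealized α-helix bundle as a reference conformation.

    Helices use ideal geometry (1.5 Å rise, ≈100°/residue twist, consecutive
    Cα–Cα ≈ 3.8 Å) and are arranged on a circle with alternating up/down
    orientation like a transmembrane bundle.  Segments are labeled TM1..TMn
    (n ≤ 7, then H8 for an eighth helix); residues are numbered consecutively
    from ``first_resid`` so author-numbering conventions (e.g. a 358–646
    transmembrane range) can be reproduced.

    Returns ``(topology, coordinates)`` with backbone atoms N, CA, C, O per
    residue; residue names are ALA.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    if isinstance(residues_per_helix, int):
        lengths = [residues_per_helix] * n_helices
    else:
        lengths = list(residues_per_helix)
        if len(lengths) != n_helices:
            raise ValueError("residues_per_helix list length must equal n_helices")
    if any(l <= 0 for l in lengths):
        raise ValueError("residue counts must be positive")
    if bundle_radius is None:
        bundle_radius = 0.0 if n_helices == 1 else 10.0 / (2 * np.sin(np.pi / max(n_helices, 2)))

    names, elements, resids, resnames, chains, segments = [], [], [], [], [], []
    coords: list[np.ndarray] = []
    resid = first_resid
    for h, n_res in enumerate(lengths):
        bb = _build_helix_backbone(n_res, _PHI_HELIX, _PSI_HELIX)
        flat = bb.reshape(-1, 3)
        flat = _align_to_z(flat, bb[:, 1, :])
        if antiparallel and h % 2 == 1:
            flat = flat @ np.diag([1.0, -1.0, -1.0])  # flip about x-axis
        theta = 2 * np.pi * h / n_helices
        offset = np.array(
            [bundle_radius * np.cos(theta), bundle_radius * np.sin(theta), 0.0]
        )
        flat = flat + offset
        seg = f"TM{h + 1}" if h < 7 else "H8"
        for r in range(n_res):
            for a, (nm, el) in enumerate(
                [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
            ):
                names.append(nm)
                elements.append(el)
                resids.append(resid)
                resnames.append("ALA")
                chains.append("A")
                segments.append(seg)
                coords.append(flat[r * 4 + a])
            resid += 1
    top = Topology(
        names=names, elements=elements, resids=resids, resnames=resnames,
        chains=chains, segments=segments,
    )
    return top, np.array(coords)


def make_chain(
    n_residues: int,
    phi: float = _PHI_HELIX,
    psi: float = _PSI_HELIX,
    first_resid: int = 1,
    segment: str = "OTHER",
) -> tuple[Topology, np.ndarray]:
    """Build a single ideal polypeptide chain at given backbone dihedrals.

    Defaults give an ideal α-helix; ``phi = psi = 180`` gives a fully
    extended chain.  Backbone atoms N, CA, C, O per residue.
    """
    bb = _build_helix_backbone(n_residues, phi, psi)
    coords = bb.reshape(-1, 3)
    names, elements, resids, resnames = [], [], [], []
    for r in range(n_residues):
        for nm, el in [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]:
            names.append(nm)
            elements.append(el)
            resids.append(first_resid + r)
            resnames.append("ALA")
    top = Topology(
        names=names, elements=elements, resids=resids, resnames=resnames,
        chains=["A"] * len(names), segments=[segment] * len(names),
    )
    return top, coords.copy()


@dataclass
class EnsembleSpec:
    """Specification of a harmonic Gaussian ensemble with planted structure.

    Parameters
    ----------
    topology, reference
        The bundle topology and its reference coordinates (Å).
    per_atom_sigma
        Per-coordinate fluctuation σ in Å (scalar or per-atom array); the
        planted 3D RMSF of an atom is ``σ·√3``.
    correlation_blocks
        ``(segmentA, segmentB, rho)`` triples.  Every atom pair inside
        ``segmentA ∪ segmentB`` (within- and between-segment) gets pairwise
        displacement correlation ``rho`` on each axis, realised through a
        shared latent factor with loading ``√rho`` — positive semi-definite by
        construction.  An atom may belong to at most one block.
    drift
        Optional diffusion coefficient D (Ų/ps, scalar or per-atom) for a
        slow random walk of the mean position; ``drift_mode`` selects
        independent per-atom walks or one walk shared by all drifting atoms.
    drift_segments
        Restrict drift to these segments (default: all atoms).
    """

    topology: Topology
    reference: np.ndarray
    per_atom_sigma: float | np.ndarray = 0.5
    correlation_blocks: list[tuple[str, str, float]] = field(default_factory=list)
    drift: float | np.ndarray | None = None
    drift_mode: str = "independent"  # or "shared"
    drift_segments: list[str] | None = None
    n_frames: int = 1000
    dt: float = 4.0
    seed: int = 0

    def sigma_array(self) -> np.ndarray:
        sig = np.broadcast_to(
            np.asarray(self.per_atom_sigma, dtype=float), (self.topology.n_atoms,)
        ).copy()
        if np.any(sig < 0):
            raise ValueError("per_atom_sigma must be non-negative")
        return sig

    def planted_axis_covariance(self) -> np.ndarray:
        """The exact planted N×N per-axis covariance matrix (Å²)."""
        n = self.topology.n_atoms
        sig = self.sigma_array()
        corr = np.eye(n)
        claimed = np.zeros(n, dtype=bool)
        for seg_a, seg_b, rho in self.correlation_blocks:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"correlation rho {rho} outside [-1, 1]")
            members = np.nonzero(
                np.isin(self.topology.segments, [seg_a, seg_b])
            )[0]
            if members.size == 0:
                raise ValueError(f"block ({seg_a}, {seg_b}) matches no atoms")
            if np.any(claimed[members]):
                raise ValueError("correlation blocks must not share atoms")
            claimed[members] = True
            block = np.ix_(members, members)
            corr[block] = rho
            corr[members, members] = 1.0
        cov = corr * np.outer(sig, sig)
        return cov

    def planted_covariance(self) -> np.ndarray:
        """The planted 3N×3N covariance (axes independent and identical)."""
        axis_cov = self.planted_axis_covariance()
        n = axis_cov.shape[0]
        cov = np.zeros((3 * n, 3 * n))
        for a in range(3):
            cov[a::3, a::3] = axis_cov
        return cov


def sample_ensemble(spec: EnsembleSpec) -> tuple[Trajectory, np.ndarray]:
    """Draw a trajectory from the planted Gaussian model.

    Returns ``(trajectory, planted_covariance)`` where the covariance is the
    exact 3N×3N matrix (Å²) of the stationary fluctuation component, for use
    as an oracle.  The planted per-axis covariance is checked to be positive
    semi-definite (eigenvalue floor −1e−10) before any sampling.
    """
    top = spec.topology
    ref = np.asarray(spec.reference, dtype=float)
    if ref.shape != (top.n_atoms, 3):
        raise ValueError("reference coordinates shape mismatch")
    axis_cov = spec.planted_axis_covariance()
    min_eig = float(np.linalg.eigvalsh(axis_cov).min())
    if min_eig < -1e-10:
        raise ValueError(
            f"planted covariance is not positive semi-definite (min eig {min_eig:g})"
        )
    rng = np.random.default_rng(spec.seed)
    n, f = top.n_atoms, spec.n_frames
    sig = spec.sigma_array()

    # latent-factor construction: x_i = sigma_i (sqrt(rho) z_block + sqrt(1-rho) eps_i)
    loadings = np.zeros(n)
    block_id = np.full(n, -1, dtype=int)
    for b, (seg_a, seg_b, rho) in enumerate(spec.correlation_blocks):
        members = np.nonzero(np.isin(top.segments, [seg_a, seg_b]))[0]
        if rho < 0:
            raise ValueError("negative block correlations are not supported")
        loadings[members] = np.sqrt(rho)
        block_id[members] = b
    eps = rng.standard_normal((f, n, 3))
    disp = eps * np.sqrt(1.0 - loadings[None, :, None] ** 2)
    if spec.correlation_blocks:
        z = rng.standard_normal((f, len(spec.correlation_blocks), 3))
        for b in range(len(spec.correlation_blocks)):
            members = block_id == b
            disp[:, members, :] += loadings[None, members, None] * z[:, b: b + 1, :]
    disp *= sig[None, :, None]

    if spec.drift is not None:
        d_arr = np.broadcast_to(np.asarray(spec.drift, dtype=float), (n,)).copy()
        if spec.drift_segments is not None:
            mask = np.isin(top.segments, spec.drift_segments)
            d_arr = np.where(mask, d_arr, 0.0)
        step_sd = np.sqrt(2.0 * d_arr * spec.dt)  # per-axis random-walk step, Å
        if spec.drift_mode == "shared":
            steps = rng.standard_normal((f, 1, 3)) * step_sd[None, :, None]
        elif spec.drift_mode == "independent":
            steps = rng.standard_normal((f, n, 3)) * step_sd[None, :, None]
        else:
            raise ValueError("drift_mode must be 'independent' or 'shared'")
        steps[0] = 0.0
        disp += np.cumsum(steps, axis=0)

    coords = ref[None, :, :] + disp
    span = ref.max(axis=0) - ref.min(axis=0) + 30.0
    traj = Trajectory(
        coordinates=coords,
        times=np.arange(f) * spec.dt,
        box=np.tile(span, (f, 1)),
        topology=top,
    )
    return traj, spec.planted_covariance()


@dataclass
class MembraneBoxSpec:
    """A toy membrane box: pseudo-atom slabs along the bilayer normal z.

    Each group is a list of ``(z_lo, z_hi)`` slab intervals (Å, origin at the
    bilayer midplane); the group's atoms are split evenly across its slabs and
    placed uniformly at random.  Defaults emulate a bilayer whose hydrophobic
    core spans −10..10 Å (terminal methyls) with phosphate interfaces at
    15..25 Å in each leaflet and water outside.
    """

    box: tuple[float, float, float] = (60.0, 60.0, 80.0)
    n_water: int = 2000
    n_phosphate: int = 128
    n_methyl: int = 256
    water_slabs: list[tuple[float, float]] = field(
        default_factory=lambda: [(-40.0, -25.0), (25.0, 40.0)]
    )
    phosphate_slabs: list[tuple[float, float]] = field(
        default_factory=lambda: [(-25.0, -15.0), (15.0, 25.0)]
    )
    methyl_slabs: list[tuple[float, float]] = field(
        default_factory=lambda: [(-10.0, 10.0)]
    )
    planted_core_interval: tuple[float, float] = (-10.0, 10.0)
    n_frames: int = 25
    seed: int = 0


def _fill_slabs(
    rng: np.random.Generator,
    count: int,
    slabs: list[tuple[float, float]],
    box: tuple[float, float, float],
    n_frames: int,
) -> np.ndarray:
    lz = box[2]
    for lo, hi in slabs:
        if hi <= lo:
            raise ValueError(f"inverted slab ({lo}, {hi})")
        if lo < -lz / 2 or hi > lz / 2:
            raise ValueError(f"slab ({lo}, {hi}) outside box half-height {lz / 2}")
    out = np.empty((n_frames, count, 3))
    per = np.full(len(slabs), count // len(slabs))
    per[: count % len(slabs)] += 1
    start = 0
    for (lo, hi), k in zip(slabs, per):
        xy = (rng.random((n_frames, k, 2)) - 0.5) * np.array(box[:2])
        z = rng.random((n_frames, k, 1)) * (hi - lo) + lo
        out[:, start: start + k, :2] = xy
        out[:, start: start + k, 2:] = z
        start += k
    return out


def make_membrane_box(spec: MembraneBoxSpec) -> tuple[Topology, Trajectory]:
    """Generate the toy membrane box described by ``spec``.

    Water pseudo-atoms are oxygens (resname HOH, segment WATER); phosphate-
    and methyl-like pseudo-atoms carry names P / CM on LIP residues (segment
    LIPID), mirroring the groups profiled in a lipid bilayer.
    """
    if min(spec.n_water, spec.n_phosphate, spec.n_methyl) < 0:
        raise ValueError("pseudo-atom counts must be non-negative")
    rng = np.random.default_rng(spec.seed)
    parts = []
    names, elements, resids, resnames, segments = [], [], [], [], []
    resid = 1
    if spec.n_water:
        parts.append(_fill_slabs(rng, spec.n_water, spec.water_slabs, spec.box, spec.n_frames))
        for _ in range(spec.n_water):
            names.append("OW"); elements.append("O")
            resids.append(resid); resnames.append("HOH"); segments.append("WATER")
            resid += 1
    if spec.n_phosphate:
        parts.append(_fill_slabs(rng, spec.n_phosphate, spec.phosphate_slabs, spec.box, spec.n_frames))
        for _ in range(spec.n_phosphate):
            names.append("P"); elements.append("P")
            resids.append(resid); resnames.append("LIP"); segments.append("LIPID")
            resid += 1
    if spec.n_methyl:
        parts.append(_fill_slabs(rng, spec.n_methyl, spec.methyl_slabs, spec.box, spec.n_frames))
        for _ in range(spec.n_methyl):
            names.append("CM"); elements.append("C")
            resids.append(resid); resnames.append("LIP"); segments.append("LIPID")
            resid += 1
    if not parts:
        raise ValueError("box contains no atoms")
    coords = np.concatenate(parts, axis=1)
    top = Topology(
        names=names, elements=elements, resids=resids, resnames=resnames,
        chains=["A"] * len(names), segments=segments,
    )
    traj = Trajectory(
        coordinates=coords,
        times=np.arange(spec.n_frames, dtype=float),
        box=np.tile(np.array(spec.box), (spec.n_frames, 1)),
        topology=top,
    )
    return top, traj
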