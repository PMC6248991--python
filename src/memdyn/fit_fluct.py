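"""Least-squares superposition, RMSD time series, and Cα RMSF profiles.

The fitting convention follows the standard trajectory-analysis recipe:
every frame is rigid-body fitted (mass-unweighted Kabsch) onto the
conformation at time 0 of its own run, and deviations/fluctuations are
measured after that fit.  Replica aggregation is an unweighted mean ± SD
across runs (R0, R1, R2 in the three-replica scheme).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import Trajectory

__all__ = [
    "SuperpositionResult",
    "RMSFProfile",
    "superpose",
    "apply_superposition",
    "superpose_frames",
    "rmsd_series",
    "rmsf",
]


@dataclass
class SuperpositionResult:
    """A proper rotation + translation minimizing least-squares deviation."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å, minimized over the fit selection

    def transform(self, coordinates: np.ndarray) -> np.ndarray:
        return coordinates @ self.rotation.T + self.translation


@dataclass
class RMSFProfile:
    """Per-atom RMSF (Å) with replica statistics."""

    atom_indices: np.ndarray  # measure-selection atom indices
    resids: np.ndarray | None  # author residue numbers, if topology known
    per_replica: np.ndarray  # (n_replicas, n_atoms) Å
    rmsf: np.ndarray  # (n_atoms,) first replica's profile, Å
    replica_mean: np.ndarray  # (n_atoms,) Å
    replica_sd: np.ndarray  # (n_atoms,) Å


def _as_indices(selection, n_atoms: int) -> np.ndarray:
    if selection is None:
        return np.arange(n_atoms)
    idx = np.asarray(selection, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= n_atoms):
        raise ValueError("selection index out of range")
    return idx


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> SuperpositionResult:
    """Kabsch fit of ``mobile`` onto ``reference`` over ``fit_selection``.

    Mass-unweighted; requires at least 3 non-collinear fit atoms so the
    rotation is determined.  The reported RMSD is the minimized value over the
    fit selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"mobile shape {mobile.shape} != reference shape {reference.shape}"
        )
    sel = _as_indices(fit_selection, mobile.shape[0])
    if sel.size < 3:
        raise ValueError("fit selection must contain at least 3 atoms")
    p = mobile[sel]
    q = reference[sel]
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    if np.linalg.matrix_rank(p0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) fit selection")
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    fitted = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - q) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def apply_superposition(result: SuperpositionResult, coordinates: np.ndarray) -> np.ndarray:
    return result.transform(np.asarray(coordinates, dtype=float))


def superpose_frames(
    coordinates: np.ndarray,
    reference: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Fit every frame of a (F, N, 3) stack onto ``reference`` (batched Kabsch)."""
    coords = np.asarray(coordinates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    sel = _as_indices(fit_selection, coords.shape[1])
    if sel.size < 3:
        raise ValueError("fit selection must contain at least 3 atoms")
    p = coords[:, sel, :]
    q = ref[sel]
    pc = p.mean(axis=1, keepdims=True)
    qc = q.mean(axis=0)
    h = np.einsum("fni,nj->fij", p - pc, q - qc)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(vt, (0, 2, 1)),
                                  np.transpose(u, (0, 2, 1))))
    flip = np.ones((coords.shape[0], 3))
    flip[:, 2] = np.sign(det)
    rot = np.einsum("fij,fj,fkj->fik", np.transpose(vt, (0, 2, 1)), flip, u)
    fitted = np.einsum("fni,fji->fnj", coords - pc, rot) + qc
    return fitted


def rmsd_series(
    trajectory: Trajectory,
    fit_selection: np.ndarray | None = None,
    measure_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) against the conformation at time 0.

    Each frame is fitted on ``fit_selection`` and measured on
    ``measure_selection`` (they may differ — e.g. fit on the whole
    transmembrane domain, measure a single helix).  The frame-0 value is 0.
    """
    coords = trajectory.coordinates
    fit = _as_indices(fit_selection, trajectory.n_atoms)
    meas = _as_indices(measure_selection, trajectory.n_atoms)
    if meas.size == 0:
        raise ValueError("measure selection is empty")
    fitted = superpose_frames(coords, coords[0], fit)
    dev = fitted[:, meas, :] - coords[0][meas]
    out = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=1))
    out[0] = 0.0
    return out


def _single_rmsf(
    trajectory: Trajectory,
    fit: np.ndarray,
    meas: np.ndarray,
) -> np.ndarray:
    if trajectory.n_frames < 2:
        raise ValueError("RMSF is undefined for a single-frame trajectory")
    fitted = superpose_frames(trajectory.coordinates, trajectory.coordinates[0], fit)
    x = fitted[:, meas, :]
    dev = x - x.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def rmsf(
    trajectory: Trajectory,
    fit_selection: np.ndarray | None = None,
    measure_selection: np.ndarray | None = None,
    replicas: list[Trajectory] | None = None,
) -> RMSFProfile:
    """Cα RMSF about the time-mean position, with replica aggregation.

    Every frame is superposed to frame 0 of its own replica before averaging;
    the profile's ``rmsf`` field is the first trajectory's, and
    ``replica_mean``/``replica_sd`` aggregate over the trajectory plus any
    supplied replicas (one value per atom per replica; unequal lengths are
    fine).
    """
    fit = _as_indices(fit_selection, trajectory.n_atoms)
    meas = _as_indices(measure_selection, trajectory.n_atoms)
    if meas.size == 0:
        raise ValueError("measure selection is empty")
    runs = [trajectory] + list(replicas or [])
    per = np.array([_single_rmsf(t, fit, meas) for t in runs])
    resids = (
        trajectory.topology.resids[meas] if trajectory.topology is not None else None
    )
    return RMSFProfile(
        atom_indices=meas,
        resids=resids,
        per_replica=per,
        rmsf=per[0],
        replica_mean=per.mean(axis=0),
        replica_sd=per.std(axis=0, ddof=0),
    )
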