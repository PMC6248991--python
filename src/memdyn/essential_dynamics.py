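"""Essential dynamics: Cα covariance/PCA, projections, cosine content,
principal-motion displacement fields, and dummy-variable regression planes.

The covariance matrix C = ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩ is accumulated mass-unweighted
over Cα coordinates after superposition of every frame onto the conformation
at time 0.  PC1 of its eigen-decomposition carries the largest collective
motion; projecting the trajectory onto a component and computing the overlap
of that projection with a half-period cosine (the cosine content) diagnoses
whether the sampled motion is distinguishable from random diffusion — values
near 1 indicate a random-diffusion-like, unconverged regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit_fluct import superpose_frames
from .io_model import Trajectory

__all__ = [
    "CovarianceModel",
    "ProjectionSeries",
    "MotionField",
    "PlaneFit",
    "covariance",
    "project",
    "cosine_content",
    "motion_field",
    "fit_motion_planes",
]


@dataclass
class CovarianceModel:
    """3N×3N Cα positional covariance with its eigen-decomposition."""

    mean_structure: np.ndarray  # (N, 3) Å, post-fit time mean of the selection
    c: np.ndarray  # (3N, 3N) Å²
    eigenvalues: np.ndarray  # (3N,) Å², descending
    eigenvectors: np.ndarray  # (3N, 3N), columns orthonormal
    fit_selection: np.ndarray  # atom indices used for superposition
    pca_selection: np.ndarray  # atom indices entering the covariance
    reference: np.ndarray  # (n_atoms, 3) frame-0 coordinates (fit target)

    @property
    def n_atoms(self) -> int:
        return self.mean_structure.shape[0]


@dataclass
class ProjectionSeries:
    """Projection of a trajectory on one principal component."""

    component_index: int  # 0-based
    values: np.ndarray  # (F,) Å
    times: np.ndarray  # (F,) ps

    @property
    def total_time(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class MotionField:
    """Per-Cα displacement vectors spanned along a principal component."""

    component_index: int
    vectors: np.ndarray  # (N, 3) Å, extreme A → extreme B
    extreme_low: np.ndarray  # (N, 3) conformation at the low quantile
    extreme_high: np.ndarray  # (N, 3) conformation at the high quantile


@dataclass
class PlaneFit:
    """OLS plane with categorical (dummy) group offsets.

    response = b0 + b1·x + b2·y + Σ_g offset_g, with two-sided t-tests on the
    group offsets, Holm-corrected across coefficients.
    """

    coefficients: pd.Series
    std_errors: pd.Series
    residual_sd: float
    pvalues: pd.Series  # raw two-sided p-values
    pvalues_holm: pd.Series  # Holm-adjusted, group-offset terms
    significant_offsets: list[str]  # offsets differing from baseline at alpha
    alpha: float


def covariance(
    trajectory: Trajectory,
    fit_selection: np.ndarray | None = None,
    pca_selection: np.ndarray | None = None,
    stride_ps: float | None = 4.0,
) -> CovarianceModel:
    """Accumulate the Cα variance–covariance matrix and eigen-decompose it.

    Frames are resampled at ``stride_ps`` (None keeps every frame) and
    superposed onto frame 0 over ``fit_selection`` before accumulation.
    """
    coords = trajectory.coordinates
    n_atoms = trajectory.n_atoms
    fit = np.arange(n_atoms) if fit_selection is None else np.asarray(fit_selection, int)
    pca = np.arange(n_atoms) if pca_selection is None else np.asarray(pca_selection, int)
    if pca.size == 0:
        raise ValueError("pca selection is empty")
    keep = _stride_mask(trajectory.times, stride_ps)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 frames retained after striding")
    fitted = superpose_frames(coords[keep], coords[0], fit)
    x = fitted[:, pca, :].reshape(keep.sum(), -1)  # (F, 3N)
    mean = x.mean(axis=0)
    dev = x - mean
    c = dev.T @ dev / dev.shape[0]
    evals, evecs = np.linalg.eigh(c)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    return CovarianceModel(
        mean_structure=mean.reshape(-1, 3),
        c=c,
        eigenvalues=evals,
        eigenvectors=evecs,
        fit_selection=fit,
        pca_selection=pca,
        reference=coords[0].copy(),
    )


def _stride_mask(times: np.ndarray, stride_ps: float | None) -> np.ndarray:
    if stride_ps is None:
        return np.ones(len(times), dtype=bool)
    if stride_ps <= 0:
        raise ValueError("stride must be positive")
    t0 = times[0]
    keep = np.zeros(len(times), dtype=bool)
    next_t = t0
    for i, t in enumerate(times):
        if t >= next_t - 1e-9:
            keep[i] = True
            next_t = t + stride_ps
    return keep


def project(
    trajectory: Trajectory,
    model: CovarianceModel,
    component: int = 0,
) -> ProjectionSeries:
    """Project every frame on eigenvector ``component`` (0-based).

    p_i(t) = v_i · (x(t) − ⟨x⟩) after superposing each frame onto the model's
    reference with the model's fit selection.
    """
    rank = int(np.sum(model.eigenvalues > max(1e-12 * model.eigenvalues[0], 0.0)))
    if component < 0 or component >= max(rank, 1):
        raise ValueError(
            f"component {component} exceeds covariance rank {rank}"
        )
    fitted = superpose_frames(
        trajectory.coordinates, model.reference, model.fit_selection
    )
    x = fitted[:, model.pca_selection, :].reshape(trajectory.n_frames, -1)
    p = (x - model.mean_structure.reshape(-1)) @ model.eigenvectors[:, component]
    return ProjectionSeries(
        component_index=component, values=p, times=trajectory.times.copy()
    )


def cosine_content(series: ProjectionSeries | tuple[np.ndarray, np.ndarray]) -> float:
    """Single half-period cosine content of a projection time series.

    CC = (2/T)·(∫₀ᵀ cos(πt/T)·p(t) dt)² / ∫₀ᵀ p(t)² dt, integrals by the
    trapezoid rule over the frame times.  CC ∈ [0, 1]; values near 1 are the
    signature of random-diffusion-like sampling.
    """
    if isinstance(series, ProjectionSeries):
        p, t = series.values, series.times
    else:
        p, t = np.asarray(series[0], float), np.asarray(series[1], float)
    if len(p) < 8:
        raise ValueError("cosine content requires at least 8 frames")
    tt = t - t[0]
    big_t = tt[-1]
    denom = np.trapezoid(p * p, tt)
    if denom <= 0:
        raise ValueError("cosine content undefined for an all-zero projection")
    num = np.trapezoid(np.cos(np.pi * tt / big_t) * p, tt)
    cc = (2.0 / big_t) * num**2 / denom
    return float(min(cc, 1.0))


def motion_field(
    model: CovarianceModel,
    series: ProjectionSeries,
    quantile_pair: tuple[float, float] = (0.01, 0.99),
) -> MotionField:
    """Displacement field spanned between two projection quantiles.

    The per-atom vector is ``(p_high − p_low)·v_i`` reshaped to atoms — the
    arrows of a "porcupine" rendering of the collective motion; the two
    extreme conformations are also emitted.  Equal quantiles give a zero
    field with a warning.  Swapping the quantiles negates the field.
    """
    q_lo, q_hi = quantile_pair
    p_lo, p_hi = np.quantile(series.values, [q_lo, q_hi])
    if abs(p_hi - p_lo) <= 1e-10:  # Å: no resolvable motion along this PC
        warnings.warn("projection quantiles coincide; motion field is zero")
        p_hi = p_lo
    v = model.eigenvectors[:, series.component_index]
    span = (p_hi - p_lo) * v
    mean = model.mean_structure
    return MotionField(
        component_index=series.component_index,
        vectors=span.reshape(-1, 3),
        extreme_low=mean + (p_lo * v).reshape(-1, 3),
        extreme_high=mean + (p_hi * v).reshape(-1, 3),
    )


def fit_motion_planes(
    data: pd.DataFrame,
    response: str = "response",
    covariates: tuple[str, str] = ("x", "y"),
    group: str = "group",
    alpha: float = 0.05,
) -> PlaneFit:
    """Parametrize designated Cα motions by a regression plane with dummies.

    Fits ``response ~ 1 + x + y + C(group)`` by ordinary least squares
    (treatment coding, first group as baseline) and reports which group
    offsets differ from the baseline at ``alpha`` after Holm correction.
    Requires ≥ 2 groups with ≥ 3 points each; a rank-deficient design is an
    error naming the collinear columns.
    """
    import statsmodels.api as sm

    levels = list(pd.unique(data[group]))
    if len(levels) < 2:
        raise ValueError("dummy-variable design requires at least 2 groups")
    counts = data[group].value_counts()
    if counts.min() < 3:
        raise ValueError("each group needs at least 3 points")
    x1, x2 = covariates
    design = pd.DataFrame(
        {"const": 1.0, x1: data[x1].astype(float), x2: data[x2].astype(float)}
    )
    offset_cols = []
    for lvl in levels[1:]:
        col = f"{group}[{lvl}]"
        design[col] = (data[group] == lvl).astype(float)
        offset_cols.append(col)
    mat = design.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        collinear = []
        cols_ok: list[int] = []
        for j in range(mat.shape[1]):
            if np.linalg.matrix_rank(mat[:, cols_ok + [j]]) > len(cols_ok):
                cols_ok.append(j)
            else:
                collinear.append(design.columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    model = sm.OLS(data[response].astype(float).to_numpy(), mat).fit()
    names = list(design.columns)
    coefs = pd.Series(model.params, index=names)
    ses = pd.Series(model.bse, index=names)
    pvals = pd.Series(model.pvalues, index=names)
    from statsmodels.stats.multitest import multipletests

    raw = pvals[offset_cols].to_numpy()
    reject, adj, _, _ = multipletests(raw, alpha=alpha, method="holm")
    adj_s = pd.Series(adj, index=offset_cols)
    significant = [c for c, r in zip(offset_cols, reject) if r]
    return PlaneFit(
        coefficients=coefs,
        std_errors=ses,
        residual_sd=float(np.sqrt(model.scale)),
        pvalues=pvals,
        pvalues_holm=adj_s,
        significant_offsets=significant,
        alpha=alpha,
    )
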