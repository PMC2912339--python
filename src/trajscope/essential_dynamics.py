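"""Essential dynamics: positional covariance PCA of a trajectory.

The positional covariance matrix of an N-atom selection over M retained
frames,

    C = ⟨ (r − ⟨r⟩)(r − ⟨r⟩)ᵀ ⟩        (3N × 3N),

is eigen-decomposed into orthonormal modes V with eigenvalues λ (Å²),
sorted descending. The leading eigenvectors describe the collective
motions; λ_i / Σλ is the fraction of total positional variance each mode
carries. Trajectory frames are projected onto modes as
p_i(t) = V_iᵀ · (r(t) − ⟨r⟩), and the frames attaining the extreme
projections on a mode (plus linear interpolants along the eigenvector)
summarize the motion it encodes.

Frames are superposed to the iterated mean structure on the analyzed
selection before the covariance is accumulated, so rigid-body motion does
not leak into the low modes. Eigenvector signs follow a fixed convention
(largest-magnitude component positive) for reproducible projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import Selection, Trajectory
from .superpose import iterated_mean_fit

__all__ = [
    "CovarianceModel",
    "ProjectionSeries",
    "build_covariance",
    "variance_captured",
    "project",
    "extreme_conformers",
]

_EIG_CLIP = -1e-8  # Å²; round-off negatives below this are an error


@dataclass
class CovarianceModel:
    mean_coords: np.ndarray        # (N, 3) Å
    eigenvalues: np.ndarray        # (3N,) Å², descending, clipped at 0
    eigenvectors: np.ndarray       # (3N, 3N), columns orthonormal
    n_frames: int
    n_atoms: int
    atom_indices: np.ndarray       # selection indices the model was built on

    @property
    def matrix_dim(self) -> int:
        return 3 * self.n_atoms

    @property
    def variance_fraction(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


@dataclass
class ProjectionSeries:
    values: np.ndarray    # (frames, k) Å
    mode_ids: tuple[int, ...]


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude component positive."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] *= -1
    return out


def build_covariance(
    traj: Trajectory,
    sel: Selection | None = None,
    equilibration_drop: int | None = None,
) -> CovarianceModel:
    """Covariance model of the selection over the equilibrated frames.

    ``equilibration_drop`` defaults to the first 25% of frames. The 3N×3N
    covariance is accumulated from mean-fitted frames and symmetrized
    before diagonalization; eigenvalues in [−1e−8, 0) are clipped to 0.
    """
    idx = sel.asarray() if sel is not None else np.arange(traj.n_atoms)
    if len(idx) == 0:
        raise ValueError("empty selection")
    if equilibration_drop is None:
        equilibration_drop = traj.n_frames // 4
    X = traj.frames[equilibration_drop:, idx, :]
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 frames retained")
    fitted, mean = iterated_mean_fit(X)
    M, N = fitted.shape[0], fitted.shape[1]
    D = (fitted - mean).reshape(M, 3 * N)
    C = (D.T @ D) / M
    C = 0.5 * (C + C.T)
    lam, vec = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    if np.any(lam < _EIG_CLIP):
        raise ValueError("covariance matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    vec = _fix_signs(vec)
    return CovarianceModel(
        mean_coords=mean,
        eigenvalues=lam,
        eigenvectors=vec,
        n_frames=M,
        n_atoms=N,
        atom_indices=idx,
    )


def variance_captured(model: CovarianceModel, k: int) -> float:
    """Cumulative variance fraction of the top-k modes, Σ_{i≤k} λ_i / Σλ."""
    if not 1 <= k <= model.matrix_dim:
        raise ValueError(f"k must be in [1, {model.matrix_dim}], got {k}")
    return float(model.variance_fraction[:k].sum())


def project(
    traj_or_coords: Trajectory | np.ndarray,
    model: CovarianceModel,
    modes: list[int] | tuple[int, ...] = (0, 1),
    refit: bool = True,
) -> ProjectionSeries:
    """Project frames onto the model's eigenvectors.

    Accepts a Trajectory (the model's selection is applied) or a raw
    (M, N, 3) coordinate array already matching the model's atoms. Each
    frame is superposed onto the model mean first unless ``refit=False``.
    """
    if isinstance(traj_or_coords, Trajectory):
        X = traj_or_coords.frames[:, model.atom_indices, :]
    else:
        X = np.asarray(traj_or_coords, dtype=float)
        if X.ndim == 2:
            X = X[None]
    if X.shape[1] != model.n_atoms:
        raise ValueError(
            f"atom count {X.shape[1]} does not match model ({model.n_atoms})"
        )
    modes = tuple(int(m) for m in modes)
    if any(m < 0 or m >= model.matrix_dim for m in modes):
        raise ValueError("mode index out of range")
    if refit:
        from .superpose import apply_transform, kabsch

        X = np.array([
            apply_transform(f, kabsch(f, model.mean_coords)) for f in X
        ])
    D = (X - model.mean_coords).reshape(X.shape[0], -1)
    V = model.eigenvectors[:, list(modes)]
    return ProjectionSeries(values=D @ V, mode_ids=modes)


def extreme_conformers(
    series: ProjectionSeries,
    traj: Trajectory,
    model: CovarianceModel,
    mode: int,
    n_interpolants: int = 0,
) -> dict:
    """Frames attaining the min/max projection on a mode, plus interpolants.

    Interpolants are generated along the eigenvector between the two
    extreme projection values, starting from the mean structure; the
    interpolant at t=0 equals the min-extreme projection structure
    reconstructed in mode space.
    """
    if mode not in series.mode_ids:
        raise ValueError(f"mode {mode} not present in the projection series")
    col = series.values[:, series.mode_ids.index(mode)]
    if np.ptp(col) < 1e-12:
        raise ValueError("degenerate mode: projection is constant")
    i_min = int(np.argmin(col))
    i_max = int(np.argmax(col))
    v = model.eigenvectors[:, mode].reshape(model.n_atoms, 3)
    interpolants = []
    if n_interpolants > 0:
        for t in np.linspace(0.0, 1.0, n_interpolants):
            p = col[i_min] + t * (col[i_max] - col[i_min])
            interpolants.append(model.mean_coords + p * v)
    return {
        "min_frame": i_min,
        "max_frame": i_max,
        "min_coords": traj.frames[i_min][model.atom_indices],
        "max_coords": traj.frames[i_max][model.atom_indices],
        "interpolants": interpolants,
    }
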