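"""Least-squares superposition and fluctuation statistics.

Provides the weighted Kabsch solver, per-frame RMSD series against a
reference frame, and per-atom RMSF with the derived B-factor
``B = (8π²/3)·RMSF²`` and its z-score normalization (mean 0, unit sample
standard deviation over the analyzed selection) for cross-system comparison.

RMSF follows the iterated mean-structure protocol: frames are fit to the
current mean, the mean is recomputed, and the cycle repeats until the mean
shifts by less than ``tol`` — this removes rigid-body drift before measuring
internal fluctuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import Selection, Trajectory

__all__ = [
    "SuperpositionResult",
    "FluctuationProfile",
    "kabsch",
    "apply_transform",
    "rmsd_series",
    "iterated_mean_fit",
    "rmsf",
]

B_FROM_RMSF2 = 8.0 * np.pi**2 / 3.0


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3×3 proper rotation
    translation: np.ndarray   # Å; maps mobile -> reference as R@x + t
    rmsd: float               # Å after superposition


@dataclass
class FluctuationProfile:
    per_atom_rmsf: np.ndarray          # Å
    per_atom_b: np.ndarray             # Å²
    per_atom_b_normalized: np.ndarray  # z-score, dimensionless


def kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (reflections rejected via the sign of the
    smallest singular value) and translation minimizing the weighted RMSD.
    Requires at least 3 non-collinear points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    pc = P - (w[:, None] * P).sum(axis=0)
    qc = Q - (w[:, None] * Q).sum(axis=0)
    H = (w[:, None] * pc).T @ qc
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12:  # rank < 2: collinear or coincident points
        raise ValueError("degenerate geometry: points are collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = (w[:, None] * Q).sum(axis=0) - R @ (w[:, None] * P).sum(axis=0)
    diff = (R @ P.T).T + t - Q
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return (result.rotation @ np.asarray(coords, float).T).T + result.translation


def rmsd_series(
    traj: Trajectory,
    ref_frame: int = 0,
    sel: Selection | None = None,
    weights: np.ndarray | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) against a reference frame.

    Each frame is least-squares fit onto the reference on the selection
    before the deviation is measured, so rigid-body motion contributes
    nothing; ``fit=False`` skips the superposition and measures the raw
    coordinate deviation.
    """
    idx = sel.asarray() if sel is not None else np.arange(traj.n_atoms)
    if len(idx) == 0:
        raise ValueError("empty selection")
    ref = traj.frames[ref_frame][idx]
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        if fit:
            out[i] = kabsch(frame[idx], ref, weights).rmsd
        else:
            out[i] = float(np.sqrt(np.mean(np.sum((frame[idx] - ref) ** 2, axis=1))))
    return out


def iterated_mean_fit(
    coords: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose frames to their mean, iterating to self-consistency.

    ``coords`` is (M, N, 3). Returns (fitted coords, mean structure). The
    iteration stops when the mean structure moves less than ``tol`` Å (RMS)
    between cycles; convergence is typically 2–3 cycles.
    """
    X = np.array(coords, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    mean = X[0].copy()
    for _ in range(max_iter):
        for i in range(X.shape[0]):
            X[i] = apply_transform(X[i], kabsch(X[i], mean))
        new_mean = X.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return X, mean


def rmsf(
    traj: Trajectory,
    sel: Selection | None = None,
    equilibration_drop: int | None = None,
) -> FluctuationProfile:
    """Per-atom RMSF, B-factor, and z-normalized B over a selection.

    ``equilibration_drop`` frames are discarded from the start (default:
    the first 25% of frames). Frames are superposed to the iterated mean
    structure before fluctuations are measured.
    """
    idx = sel.asarray() if sel is not None else np.arange(traj.n_atoms)
    if len(idx) == 0:
        raise ValueError("empty selection")
    if equilibration_drop is None:
        equilibration_drop = traj.n_frames // 4
    X = traj.frames[equilibration_drop:, idx, :]
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 frames retained after equilibration drop")
    fitted, mean = iterated_mean_fit(X)
    dev2 = np.sum((fitted - mean) ** 2, axis=2)   # (M, N)
    rmsf_vals = np.sqrt(dev2.mean(axis=0))
    b = B_FROM_RMSF2 * rmsf_vals**2
    sd = b.std(ddof=1)
    if sd == 0:
        b_norm = np.zeros_like(b)
    else:
        b_norm = (b - b.mean()) / sd
    return FluctuationProfile(rmsf_vals, b, b_norm)
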