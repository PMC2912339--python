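"""Quasi-rigid domain decomposition and hinge parameters between two conformers.

The analysis follows the classic sliding-window strategy: for every residue,
the optimal rigid transform of a short window of the chain from conformer A
to conformer B is fit, and its rotation vector (axis × angle, degrees) forms
a per-residue rotation field. Residues moving together share a rotation
vector; single-linkage clustering of the field therefore partitions the chain
into quasi-rigid domains, with the largest cluster taken as the fixed domain
and the inter-cluster residues along the sequence as hinges.

For a moving domain, its rigid transform is re-fit in the fixed domain's
reference frame and decomposed into a screw motion: an effective rotation
angle about a best axis, and a translation along that axis. The *closure*
percentage classifies the motion: with n̂ the unit rotation axis and ĉ the
closure axis (the axis direction that maximally changes the interdomain
centroid distance under infinitesimal rotation — perpendicular to the
centroid line by construction),

    closure% = 100 · (n̂ · ĉ)².

A pure closing/opening motion scores ~100, a pure interdomain twist ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.transform import Rotation

from .superpose import apply_transform, kabsch

__all__ = [
    "DomainPartition",
    "HingeParameters",
    "local_rotation_field",
    "partition_domains",
    "hinge_parameters",
]

MIN_DOMAIN_SIZE = 20       # residues
CLUSTER_RADIUS_DEG = 5.0   # single-linkage radius in rotation-vector space
DEGENERATE_ANGLE_DEG = 0.1


@dataclass
class DomainPartition:
    fixed_domain: tuple[int, ...]                 # residue indices (0-based into sel)
    moving_domains: list[tuple[int, ...]]
    hinge_residues: list[tuple[int, ...]]         # one tuple per moving domain
    unassigned: tuple[int, ...] = ()

    @property
    def n_domains(self) -> int:
        return 1 + len(self.moving_domains)


@dataclass
class HingeParameters:
    rotation_angle: float          # degrees in [0, 180]
    translation: float             # Å, signed screw component along the axis
    closure: float | None          # % in [0, 100]; None when undefined
    axis: np.ndarray               # unit 3-vector (right-hand rule)
    axis_point: np.ndarray         # Å, a point on the screw axis


def local_rotation_field(
    conf_a: np.ndarray,
    conf_b: np.ndarray,
    window: int = 5,
) -> np.ndarray:
    """Per-residue rotation vectors (axis × angle, degrees) from A to B.

    ``conf_a``/``conf_b`` are (N, 3) matched coordinate sets (one point per
    residue, e.g. Cα). For each residue the optimal rigid fit of its
    centered sliding window is converted to a rotation vector. The window
    must be odd; edge residues use the nearest full window.
    """
    A = np.asarray(conf_a, float)
    B = np.asarray(conf_b, float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("conformers must be matched (N, 3) arrays")
    n = A.shape[0]
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if n < window:
        raise ValueError(f"chain of {n} residues is shorter than window {window}")
    half = window // 2
    field = np.empty((n, 3))
    for i in range(n):
        lo = min(max(i - half, 0), n - window)
        sl = slice(lo, lo + window)
        res = kabsch(A[sl], B[sl])
        field[i] = Rotation.from_matrix(res.rotation).as_rotvec(degrees=True)
    return field


def _smooth_field(field: np.ndarray, window: int) -> np.ndarray:
    """Boxcar-average the rotation vectors along the sequence."""
    if window <= 1:
        return field
    half = window // 2
    padded = np.pad(field, ((half, half), (0, 0)), mode="edge")
    kernel = np.ones(window) / window
    return np.stack(
        [np.convolve(padded[:, k], kernel, mode="valid") for k in range(3)],
        axis=1,
    )


def partition_domains(
    field: np.ndarray,
    min_domain: int = MIN_DOMAIN_SIZE,
    cluster_radius: float = CLUSTER_RADIUS_DEG,
    smooth_window: int = 5,
    refine_iterations: int = 3,
) -> DomainPartition:
    """Cluster the rotation field into quasi-rigid domains.

    The field is boxcar-smoothed along the sequence (window
    ``smooth_window`` residues) to suppress per-window fit noise, clustered
    by average linkage at ``cluster_radius`` (degrees) in rotation-vector
    space, and the assignment is refined by nearest-cluster-center passes —
    this breaks the chains of intermediate vectors that sliding windows
    straddling a hinge produce. Clusters smaller than ``min_domain``
    residues are dissolved into their nearest surviving cluster. The
    largest cluster becomes the fixed domain; hinge residues are those at
    sequence boundaries between different domain assignments.

    Separating a hinge whose rotation is smaller than ``cluster_radius`` is
    not possible; choose the radius below the expected rotation magnitude.
    """
    field = np.asarray(field, float)
    n = field.shape[0]
    if n < 2:
        raise ValueError("rotation field too short to partition")
    smoothed = _smooth_field(field, smooth_window)
    Z = linkage(smoothed, method="average")
    labels = fcluster(Z, t=cluster_radius, criterion="distance")

    def cluster_map(labs):
        out: dict[int, list[int]] = {}
        for i, lab in enumerate(labs):
            out.setdefault(int(lab), []).append(i)
        return out

    clusters = cluster_map(labels)
    big_labs = [lab for lab, idx in clusters.items() if len(idx) >= min_domain]
    if not big_labs:
        raise ValueError("no cluster reaches the minimum domain size")

    # refinement: every residue joins the nearest surviving cluster center
    for _ in range(max(refine_iterations, 1)):
        centers = {
            lab: smoothed[clusters[lab]].mean(axis=0)
            for lab in big_labs
            if clusters.get(lab)
        }
        labs_arr = np.empty(n, dtype=int)
        center_labs = list(centers)
        C = np.stack([centers[lab] for lab in center_labs])
        d = np.linalg.norm(smoothed[:, None, :] - C[None, :, :], axis=2)
        labs_arr = np.array([center_labs[k] for k in d.argmin(axis=1)])
        clusters = cluster_map(labs_arr)
        big_labs = [lab for lab in center_labs
                    if len(clusters.get(lab, [])) >= min_domain]
        if not big_labs:
            raise ValueError("no cluster reaches the minimum domain size")

    clusters = {lab: clusters[lab] for lab in big_labs}
    fixed_lab = max(clusters, key=lambda k: len(clusters[k]))
    moving_domains = [
        tuple(sorted(clusters[lab])) for lab in clusters if lab != fixed_lab
    ]

    # hinge residues: sequence-boundary residues between assignments
    assignment = np.empty(n, dtype=int)
    for lab, idx in clusters.items():
        assignment[idx] = lab
    hinges: list[tuple[int, ...]] = []
    for dom in moving_domains:
        h = set()
        for i in dom:
            for j in (i - 1, i + 1):
                if 0 <= j < n and assignment[j] != assignment[i]:
                    h.update({i, j})
        hinges.append(tuple(sorted(h)))
    return DomainPartition(
        fixed_domain=tuple(sorted(clusters[fixed_lab])),
        moving_domains=moving_domains,
        hinge_residues=hinges,
        unassigned=(),
    )


def _closure_axis(
    fixed_centroid: np.ndarray,
    moving_centroid: np.ndarray,
    axis_point: np.ndarray,
) -> np.ndarray | None:
    """Unit rotation-axis direction maximizing interdomain distance change.

    Rotating the moving domain about an axis with direction n̂ through
    ``axis_point`` changes the centroid distance at a rate proportional to
    n̂·((c_m − p) × d̂); the maximizing direction is the (normalized) cross
    product itself, which is perpendicular to the centroid line d̂.
    Undefined (None) when the axis point lies on the centroid line.
    """
    d = moving_centroid - fixed_centroid
    dn = np.linalg.norm(d)
    if dn < 1e-9:
        return None
    d_hat = d / dn
    r = moving_centroid - axis_point
    c = np.cross(r, d_hat)
    cn = np.linalg.norm(c)
    if cn < 1e-9:
        return None
    return c / cn


def hinge_parameters(
    conf_a: np.ndarray,
    conf_b: np.ndarray,
    partition: DomainPartition,
    moving: int = 0,
    boundary_trim: int = 3,
) -> HingeParameters:
    """Screw decomposition of one moving domain's motion A → B.

    Both conformers are first expressed in the fixed domain's frame (A's
    fixed domain superposed onto B's), then the moving domain's residual
    rigid transform is decomposed into rotation angle, screw axis, a point
    on the axis, and the signed translation along the axis (sign by the
    right-hand rule of the rotation). Residues within ``boundary_trim`` of
    a hinge are excluded from both rigid fits — their sliding windows mix
    the two bodies and would bias the angle. Closure is None for near-zero
    rotations (< 0.1°); a degenerate closure axis (the screw axis passes
    through the moving centroid or lies on the centroid line, so no
    first-order centroid-distance change exists) reports closure 0.
    """
    A = np.asarray(conf_a, float)
    B = np.asarray(conf_b, float)
    mov = list(partition.moving_domains[moving]) if partition.moving_domains else []
    if not mov:
        raise ValueError("moving domain is empty")
    fix = list(partition.fixed_domain)
    hinge_all = {h for hs in partition.hinge_residues for h in hs}
    if hinge_all and boundary_trim > 0:
        def away(i):
            return min(abs(i - h) for h in hinge_all) > boundary_trim
        mov_trim = [i for i in mov if away(i)]
        fix_trim = [i for i in fix if away(i)]
        if len(mov_trim) >= 3:
            mov = mov_trim
        if len(fix_trim) >= 3:
            fix = fix_trim

    # express A in B's fixed-domain frame
    fit_fixed = kabsch(A[fix], B[fix])
    A_aligned = apply_transform(A, fit_fixed)

    res = kabsch(A_aligned[mov], B[mov])
    rot = Rotation.from_matrix(res.rotation)
    rotvec = rot.as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))

    if angle < DEGENERATE_ANGLE_DEG:
        return HingeParameters(
            rotation_angle=angle,
            translation=0.0,
            closure=None,
            axis=np.array([0.0, 0.0, 1.0]),
            axis_point=A_aligned[mov].mean(axis=0),
        )

    n_hat = rotvec / np.linalg.norm(rotvec)
    R = res.rotation
    t = res.translation
    # screw decomposition: translation along the axis is invariant
    d_along = float(n_hat @ t)
    # point on the axis: solve (I − R) p = t_perp
    t_perp = t - d_along * n_hat
    M = np.eye(3) - R
    p, *_ = np.linalg.lstsq(M, t_perp, rcond=None)
    # project p onto the plane through the moving centroid for a stable report
    c_m = A_aligned[mov].mean(axis=0)
    p = p + n_hat * (n_hat @ (c_m - p))

    c_f = B[fix].mean(axis=0) if fix else A_aligned[fix].mean(axis=0)
    c_hat = _closure_axis(c_f, c_m, p)
    closure = 0.0 if c_hat is None else float(100.0 * (n_hat @ c_hat) ** 2)
    return HingeParameters(
        rotation_angle=angle,
        translation=d_along,
        closure=closure,
        axis=n_hat,
        axis_point=p,
    )
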