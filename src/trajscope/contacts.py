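"""Geometric interaction analyses on trajectories.

Covers hydrogen-bond occupancy series, base-pair (torsion) dihedrals,
hydration-site mapping with molecule-resolved residence episodes, ion
coordination geometry (pair distances, partner-partner angles, planarity),
and binding-channel metrics (interdomain centroid distance and projected
entrance area).

All quantities are purely geometric and invariant under a global rigid
transform of every frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .model_io import Selection, Trajectory

__all__ = [
    "HBondSeries",
    "HydrationSite",
    "CoordinationReport",
    "ChannelMetrics",
    "hbond_scan",
    "pair_dihedral",
    "hydration_sites",
    "coordination_geometry",
    "channel_metrics",
]

HBOND_DISTANCE_CUTOFF = 3.5    # Å, heavy-atom default
HBOND_DISTANCE_STRICT = 3.0    # Å, the stricter preset used for seed base pairs
HBOND_ANGLE_CUTOFF = 120.0     # degrees, donor–H–acceptor
HYDRATION_GRID = 1.0           # Å
HYDRATION_OCC_THRESHOLD = 0.40
HYDRATION_MERGE_RADIUS = 1.5   # Å
HYDRATION_GAP_TOLERANCE = 2    # frames


@dataclass
class HBondSeries:
    donor: int                     # atom index
    acceptor: int
    distance: np.ndarray           # Å per frame
    bonded: np.ndarray             # boolean per frame
    occupancy: float               # fraction of frames bonded


@dataclass
class HydrationSite:
    centroid: np.ndarray                       # Å
    occupancy: float                           # fraction of frames occupied
    residence_episodes: list[tuple[float, float]]  # (start ps, end ps)
    longest_residence: float                   # ns

    @property
    def n_episodes(self) -> int:
        return len(self.residence_episodes)


@dataclass
class CoordinationReport:
    pair_distances: dict[int, tuple[float, float]]   # partner -> (mean, sd) Å
    triad_angles: dict[tuple[int, int], tuple[float, float]]  # (i,j) -> (mean, sd) °
    angle_sum: float                                  # ° (mean over frames)
    out_of_plane: float                               # Å, center vs partner plane


@dataclass
class ChannelMetrics:
    centroid_distance: float   # Å
    entrance_area: float       # Å²


# ---------------------------------------------------------------------------

def hbond_scan(
    traj: Trajectory,
    donors: Selection,
    acceptors: Selection,
    mode: str = "distance-only",
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
    hydrogen_of: dict[int, int] | None = None,
) -> list[HBondSeries]:
    """Hydrogen-bond series for donor/acceptor pairs ever within ``d_cut``.

    ``distance-only`` uses the heavy-atom distance criterion; ``distance+angle``
    additionally requires the donor–H–acceptor angle ≥ ``angle_cut``
    (``hydrogen_of`` maps each donor heavy atom to its hydrogen). Pairs never
    within the cutoff are absent from the output.
    """
    if mode not in ("distance-only", "distance+angle"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(donors) == 0 or len(acceptors) == 0:
        raise ValueError("donor and acceptor selections must be non-empty")
    if mode == "distance+angle" and not hydrogen_of:
        raise ValueError("distance+angle mode requires a donor→hydrogen map")
    di = donors.asarray()
    ai = acceptors.asarray()
    D = traj.frames[:, di, :]   # (M, nd, 3)
    A = traj.frames[:, ai, :]
    out: list[HBondSeries] = []
    for p, d_atom in enumerate(di):
        dist = np.linalg.norm(D[:, p, None, :] - A, axis=2)   # (M, na)
        for q, a_atom in enumerate(ai):
            if a_atom == d_atom:
                continue
            series = dist[:, q]
            bonded = series <= d_cut
            if not bonded.any():
                continue
            if mode == "distance+angle":
                h = hydrogen_of.get(int(d_atom))
                if h is None:
                    raise ValueError(f"no hydrogen mapped for donor atom {d_atom}")
                hv = traj.frames[:, h, :]
                v1 = traj.frames[:, d_atom, :] - hv
                v2 = traj.frames[:, a_atom, :] - hv
                cosang = np.einsum("ij,ij->i", v1, v2) / (
                    np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                bonded = bonded & (ang >= angle_cut)
                if not bonded.any():
                    continue
            out.append(
                HBondSeries(
                    donor=int(d_atom),
                    acceptor=int(a_atom),
                    distance=series,
                    bonded=bonded,
                    occupancy=float(bonded.mean()),
                )
            )
    return out


def pair_dihedral(
    traj: Trajectory, a1: int, a2: int, a3: int, a4: int
) -> np.ndarray:
    """Signed torsion a1–a2–a3–a4 per frame, degrees in (−180, 180].

    Frames with a collinear middle bond geometry are reported as NaN.
    """
    ids = (a1, a2, a3, a4)
    if len(set(ids)) != 4:
        raise ValueError("the four atoms must be distinct")
    p = traj.frames[:, list(ids), :]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    # IUPAC sign convention (matches the standard MD analysis tools)
    ang = -np.degrees(np.arctan2(y, x))
    degenerate = (np.linalg.norm(n1, axis=1) < 1e-9) | (
        np.linalg.norm(n2, axis=1) < 1e-9
    )
    ang[degenerate] = np.nan
    # map −180 to +180 for the (−180, 180] convention
    ang[np.isclose(ang, -180.0)] = 180.0
    return ang


def _episodes_from_presence(
    present: np.ndarray,
    owner: np.ndarray,
    times: np.ndarray,
    gap_tolerance: int,
) -> list[tuple[float, float]]:
    """Molecule-resolved residence episodes from a per-frame presence mask.

    ``owner[f]`` is the water molecule occupying the site at frame f (−1 when
    vacant). Gaps of up to ``gap_tolerance`` frames are bridged only when the
    same molecule returns; an owner change always starts a new episode.
    """
    episodes: list[tuple[float, float]] = []
    start = None
    last_seen = None
    current_owner = None
    for f in range(len(present)):
        if present[f]:
            if start is None:
                start, last_seen, current_owner = f, f, owner[f]
            elif owner[f] != current_owner:
                episodes.append((times[start], times[last_seen]))
                start, last_seen, current_owner = f, f, owner[f]
            elif f - last_seen - 1 > gap_tolerance:
                episodes.append((times[start], times[last_seen]))
                start, last_seen, current_owner = f, f, owner[f]
            else:
                last_seen = f
        else:
            if start is not None and f - last_seen > gap_tolerance:
                episodes.append((times[start], times[last_seen]))
                start = None
    if start is not None:
        episodes.append((times[start], times[last_seen]))
    return episodes


def hydration_sites(
    traj: Trajectory,
    region_center: np.ndarray | Selection,
    region_radius: float,
    grid: float = HYDRATION_GRID,
    occ_threshold: float = HYDRATION_OCC_THRESHOLD,
    gap_tolerance: int = HYDRATION_GAP_TOLERANCE,
    merge_radius: float = HYDRATION_MERGE_RADIUS,
) -> list[HydrationSite]:
    """Map persistent water sites inside a spherical region.

    Water-oxygen positions are histogrammed on a 3-D grid (spacing ``grid``
    Å); grid cells occupied in more than ``occ_threshold`` of frames seed
    sites, which are merged within ``merge_radius`` Å. Per site, occupancy is
    the fraction of frames with any water within ``merge_radius`` of the site
    centroid, and residence episodes track one molecule's continuous
    presence, tolerating vacancies of up to ``gap_tolerance`` frames.
    """
    labels = traj.topology.molecule_labels
    water_idx = np.array([i for i, lab in enumerate(labels) if lab == "water"])
    if len(water_idx) == 0:
        raise ValueError("no water in topology")
    if isinstance(region_center, Selection):
        center = traj.frames[:, region_center.asarray(), :].mean(axis=(0, 1))
    else:
        center = np.asarray(region_center, float)

    W = traj.frames[:, water_idx, :]                  # (M, nw, 3)
    M = W.shape[0]
    in_region = np.linalg.norm(W - center, axis=2) <= region_radius

    # per-frame occupied cells
    edges = np.arange(-region_radius, region_radius + grid, grid)
    nbins = len(edges) - 1
    counts: dict[tuple[int, int, int], int] = {}
    for f in range(M):
        pts = W[f][in_region[f]] - center + region_radius
        if len(pts) == 0:
            continue
        cells = np.clip((pts // grid).astype(int), 0, nbins - 1)
        for c in {tuple(c) for c in cells}:
            counts[c] = counts.get(c, 0) + 1

    seeded = sorted(
        ((n, c) for c, n in counts.items() if n / M >= occ_threshold),
        key=lambda item: (-item[0], item[1]),
    )
    seeds = [
        (np.array(c) + 0.5) * grid - region_radius + center for _, c in seeded
    ]
    if not seeds:
        return []
    # merge seeds within merge_radius (greedy, highest count first)
    merged: list[np.ndarray] = []
    for s in seeds:
        for j, m in enumerate(merged):
            if np.linalg.norm(s - m) <= merge_radius:
                merged[j] = (m + s) / 2
                break
        else:
            merged.append(s)

    times = traj.frame_times
    sites: list[HydrationSite] = []
    for c in merged:
        d = np.linalg.norm(W - c, axis=2)             # (M, nw)
        present = (d <= merge_radius).any(axis=1)
        owner = np.where(present, d.argmin(axis=1), -1)
        occ = float(present.mean())
        episodes = _episodes_from_presence(present, owner, times, gap_tolerance)
        longest = max((e - s for s, e in episodes), default=0.0) / 1000.0  # ps→ns
        # refine centroid to the mean position of the occupying water
        occ_pts = [W[f, owner[f]] for f in range(M) if present[f]]
        centroid = np.mean(occ_pts, axis=0) if occ_pts else c
        sites.append(HydrationSite(centroid, occ, episodes, longest))
    sites.sort(key=lambda s: -s.occupancy)
    return sites


def coordination_geometry(
    traj: Trajectory,
    center: int,
    partners: Selection,
    cutoff: float = 3.0,
) -> CoordinationReport:
    """Coordination shell statistics around a center atom (e.g. Mg²⁺).

    Partners ever within ``cutoff`` of the center are retained. Reports
    per-pair mean ± sd distances, partner–center–partner angles (per-frame,
    then averaged), the per-frame angle sum averaged over frames, and the
    center's mean distance from the best-fit plane of the retained partners.
    """
    pi = partners.asarray()
    C = traj.frames[:, center, :]                      # (M, 3)
    P = traj.frames[:, pi, :]                          # (M, np, 3)
    d = np.linalg.norm(P - C[:, None, :], axis=2)      # (M, np)
    keep = (d <= cutoff).any(axis=0)
    if not keep.any():
        raise ValueError("no partners ever within the cutoff")
    kept = np.where(keep)[0]
    pair_distances = {
        int(pi[k]): (float(d[:, k].mean()), float(d[:, k].std())) for k in kept
    }

    vecs = P[:, kept, :] - C[:, None, :]
    u = vecs / np.linalg.norm(vecs, axis=2, keepdims=True)
    angles: dict[tuple[int, int], tuple[float, float]] = {}
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            cosang = np.clip(np.einsum("ij,ij->i", u[:, a], u[:, b]), -1, 1)
            ang = np.degrees(np.arccos(cosang))
            angles[(int(pi[kept[a]]), int(pi[kept[b]]))] = (
                float(ang.mean()),
                float(ang.std()),
            )

    # angle sum: consecutive partner-center-partner angles, partners ordered
    # azimuthally around the center (a planar shell sums to ~360°, a center
    # pulled out of the plane to less)
    per_frame_sums = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        uf = u[f]
        if uf.shape[0] < 3:
            per_frame_sums[f] = np.nan
            continue
        _, _, Vt = np.linalg.svd(uf - uf.mean(axis=0))
        normal = Vt[2]
        e1 = Vt[0]
        e2 = np.cross(normal, e1)
        azim = np.arctan2(uf @ e2, uf @ e1)
        order = np.argsort(azim)
        total = 0.0
        for k in range(len(order)):
            va = uf[order[k]]
            vb = uf[order[(k + 1) % len(order)]]
            total += np.degrees(np.arccos(np.clip(va @ vb, -1, 1)))
        per_frame_sums[f] = total

    # planarity: center's distance from the best-fit plane of the partners
    oop = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        pts = P[f, kept, :]
        centroid = pts.mean(axis=0)
        if len(kept) < 3:
            oop[f] = np.nan
            continue
        _, _, Vt = np.linalg.svd(pts - centroid)
        normal = Vt[2]
        oop[f] = abs((C[f] - centroid) @ normal)
    return CoordinationReport(
        pair_distances=pair_distances,
        triad_angles=angles,
        angle_sum=float(np.nanmean(per_frame_sums)),
        out_of_plane=float(np.nanmean(oop)),
    )


def channel_metrics(
    frame: np.ndarray,
    set_a: Selection,
    set_b: Selection,
    entrance: Selection,
    axis: np.ndarray | str = "auto",
) -> ChannelMetrics:
    """Interdomain centroid distance and projected entrance area.

    The entrance area is the area of the 2-D convex hull of the entrance
    atoms projected onto the plane perpendicular to the axis; the automatic
    axis is the centroid(A) → centroid(B) direction.
    """
    frame = np.asarray(frame, float)
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("set_a and set_b must be non-empty")
    if len(entrance) < 3:
        raise ValueError("entrance area needs at least 3 atoms")
    ca = frame[set_a.asarray()].mean(axis=0)
    cb = frame[set_b.asarray()].mean(axis=0)
    dist = float(np.linalg.norm(ca - cb))
    if isinstance(axis, str):
        if axis != "auto":
            raise ValueError(f"unknown axis mode {axis!r}")
        if dist < 1e-9:
            raise ValueError("auto axis undefined: coincident centroids")
        ax = (cb - ca) / dist
    else:
        ax = np.asarray(axis, float)
        ax = ax / np.linalg.norm(ax)
    # orthonormal basis of the plane perpendicular to the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ax @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ax, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(ax, e1)
    pts = frame[entrance.asarray()]
    uv = np.stack([pts @ e1, pts @ e2], axis=1)
    hull = ConvexHull(uv)
    return ChannelMetrics(centroid_distance=dist, entrance_area=float(hull.volume))
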