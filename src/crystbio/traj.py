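"""Conformational-landscape analysis of two-domain protein trajectories.

Per-frame features are the backbone-heavy-atom RMSD to a reference structure
(after optimal rigid superposition) and an inter-domain orientation angle:
the angle at the center of mass (COM) of a vertex residue group, subtended
by the COMs of two arm residue groups, one in each domain. Joint (RMSD,
angle) probability landscapes are estimated with a 2D Gaussian
product-kernel KDE; conformational states are rectangular regions of that
plane; inter-conformation structural change is summarized by residue-COM
distance matrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .fileio import StructureFrame, Trajectory, select_com, _scope_mask


@dataclass
class AngleDefinition:
    """Vertex and arm residue groups for the inter-domain orientation angle.

    Defaults follow the gamma-D-crystallin convention: vertex at the COM of
    residues 4 and 36, arms to residues 43 (N-terminal domain) and 131
    (C-terminal domain), backbone heavy atoms only.
    """

    vertex_residues: tuple = (4, 36)
    arm_a_residues: tuple = (43,)
    arm_b_residues: tuple = (131,)
    atom_scope: str = "backbone"

    def __post_init__(self):
        groups = [set(self.vertex_residues), set(self.arm_a_residues), set(self.arm_b_residues)]
        if any(not g for g in groups):
            raise ValueError("vertex and arm residue groups must be non-empty")
        for g1, g2 in itertools.combinations(groups, 2):
            if g1 & g2:
                raise ValueError("vertex/arm residue groups must be disjoint")


@dataclass
class TrajectoryFeatures:
    rmsd: np.ndarray  # Angstrom, per frame
    angle: np.ndarray  # degrees in [0, 180], per frame
    reference_label: str = ""

    def __post_init__(self):
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if len(self.rmsd) != len(self.angle):
            raise ValueError("rmsd and angle traces must have equal length")
        if (self.rmsd < 0).any():
            raise ValueError("rmsd must be non-negative")

    def __len__(self) -> int:
        return len(self.rmsd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.rmsd)), "rmsd_A": self.rmsd, "angle_deg": self.angle}
        )


# ---------------------------------------------------------------------------
# Superposition and angles
# ---------------------------------------------------------------------------


def _matched_selection(mobile: StructureFrame, reference: StructureFrame, atom_scope: str):
    """Indices of atoms matched by (residue index, atom name), in reference
    order, restricted to the given scope in the reference."""
    ref_mask = _scope_mask(reference, atom_scope)
    mob_lookup = {
        (int(r), str(a)): i
        for i, (r, a) in enumerate(zip(mobile.residue_indices, mobile.atom_names))
    }
    ref_idx, mob_idx = [], []
    for i in np.nonzero(ref_mask)[0]:
        key = (int(reference.residue_indices[i]), str(reference.atom_names[i]))
        j = mob_lookup.get(key)
        if j is not None:
            ref_idx.append(i)
            mob_idx.append(j)
    return np.array(mob_idx, dtype=int), np.array(ref_idx, dtype=int)


def superpose(mobile: StructureFrame, reference: StructureFrame, atom_scope: str = "backbone"):
    """Optimal (proper-rotation) rigid superposition of ``mobile`` onto
    ``reference`` over matched atoms of the given scope.

    Returns ``(transformed_frame, rmsd)`` where rmsd (Angstrom) is the
    minimized value over the selection. Fewer than 3 non-collinear selected
    atoms is a hard error.
    """
    mi, ri = _matched_selection(mobile, reference, atom_scope)
    if len(mi) < 3:
        raise ValueError(f"superposition needs >= 3 matched atoms, got {len(mi)}")
    X = mobile.coords[mi]
    Y = reference.coords[ri]
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    if np.linalg.matrix_rank(X0, tol=1e-9) < 2:
        raise ValueError("selected atoms are collinear; superposition is degenerate")
    rot, _ = Rotation.align_vectors(Y0, X0)
    # residual evaluated directly (the eigenvalue-based rssd loses precision
    # to cancellation for near-zero RMSD)
    diff = rot.apply(X0) - Y0
    rmsd = float(math.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    new_coords = rot.apply(mobile.coords - xc) + yc
    return mobile.with_coords(new_coords), rmsd


def orientation_angle(frame: StructureFrame, defn: AngleDefinition = AngleDefinition()) -> float:
    """Angle (degrees, [0, 180]) between the vertex->arm_a and vertex->arm_b
    COM vectors. Superposition-invariant (an internal coordinate)."""
    v0 = select_com(frame, list(defn.vertex_residues), defn.atom_scope)
    u = select_com(frame, list(defn.arm_a_residues), defn.atom_scope) - v0
    v = select_com(frame, list(defn.arm_b_residues), defn.atom_scope) - v0
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise ValueError("degenerate geometry: arm vector shorter than 1e-9 A")
    cosang = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def featurize(
    traj: Trajectory,
    reference: StructureFrame,
    defn: AngleDefinition = AngleDefinition(),
    reference_label: str = "reference",
) -> TrajectoryFeatures:
    """Per-frame backbone RMSD (after superposition onto the reference) and
    orientation angle (computed on the original, un-superposed frame)."""
    rmsds = np.empty(len(traj))
    angles = np.empty(len(traj))
    for i, fr in enumerate(traj):
        _, rmsds[i] = superpose(fr, reference, atom_scope="backbone")
        angles[i] = orientation_angle(fr, defn)
    return TrajectoryFeatures(rmsd=rmsds, angle=angles, reference_label=reference_label)


# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------


@dataclass
class LandscapeGrid:
    rmsd_centers: np.ndarray
    angle_centers: np.ndarray
    density: np.ndarray  # (n_rmsd, n_angle), normalized over the grid
    bandwidths: tuple = (0.0, 0.0)  # (rmsd, angle)
    n_samples: int = 0

    @property
    def cell_area(self) -> float:
        return float(
            (self.rmsd_centers[1] - self.rmsd_centers[0])
            * (self.angle_centers[1] - self.angle_centers[0])
        )

    def modes(self):
        """Local maxima of the gridded density, sorted by density
        (descending). Plateaus from exact ties are merged into one mode at
        their centroid. Returns a list of (rmsd, angle, density)."""
        from scipy import ndimage

        d = self.density
        is_max = ndimage.maximum_filter(d, size=3, mode="constant", cval=-np.inf) == d
        is_max &= d > d.max() * 1e-12  # ignore underflowed tails
        labeled, n = ndimage.label(is_max)
        out = []
        for k in range(1, n + 1):
            cells = np.argwhere(labeled == k)
            i, j = cells.mean(axis=0)
            r = float(np.interp(i, np.arange(len(self.rmsd_centers)), self.rmsd_centers))
            a = float(np.interp(j, np.arange(len(self.angle_centers)), self.angle_centers))
            out.append((r, a, float(d[cells[:, 0], cells[:, 1]].max())))
        out.sort(key=lambda t: -t[2])
        return out

    def to_frame(self) -> pd.DataFrame:
        rr, aa = np.meshgrid(self.rmsd_centers, self.angle_centers, indexing="ij")
        return pd.DataFrame(
            {"rmsd_A": rr.ravel(), "angle_deg": aa.ravel(), "density": self.density.ravel()}
        )


def _scott_bandwidth(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) * len(x) ** (-1.0 / 6.0))


def kde_landscape(
    features: TrajectoryFeatures,
    n_bins: tuple = (128, 128),
    bandwidths: tuple | None = None,
    ranges: tuple | None = None,
    pad_sigmas: float = 5.0,
) -> LandscapeGrid:
    """2D Gaussian product-kernel KDE of the (RMSD, angle) samples.

    Per-dimension bandwidths default to Scott's rule (std * n^(-1/6)). The
    grid spans the sample range padded by ``pad_sigmas`` bandwidths unless
    ``ranges`` overrides it; the density is normalized over the grid.
    """
    if len(features) < 10:
        raise ValueError("KDE landscape needs at least 10 frames")
    x, y = features.rmsd, features.angle
    if bandwidths is None:
        hx, hy = _scott_bandwidth(x), _scott_bandwidth(y)
    else:
        hx, hy = bandwidths
    if hx <= 0 or hy <= 0:
        raise ValueError(
            "zero variance in a landscape dimension; pass explicit bandwidths to override"
        )
    if ranges is None:
        ranges = (
            (x.min() - pad_sigmas * hx, x.max() + pad_sigmas * hx),
            (y.min() - pad_sigmas * hy, y.max() + pad_sigmas * hy),
        )
    gx = np.linspace(*ranges[0], n_bins[0])
    gy = np.linspace(*ranges[1], n_bins[1])
    # separable product kernel: density = Kx @ Ky^T / n
    Kx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / hx) ** 2) / (hx * math.sqrt(2 * math.pi))
    Ky = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / hy) ** 2) / (hy * math.sqrt(2 * math.pi))
    density = (Kx @ Ky.T) / len(x)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    density = density / (density.sum() * cell)
    return LandscapeGrid(
        rmsd_centers=gx, angle_centers=gy, density=density, bandwidths=(hx, hy), n_samples=len(x)
    )


# ---------------------------------------------------------------------------
# States
# ---------------------------------------------------------------------------


@dataclass
class StateBounds:
    """Named rectangular regions in the (rmsd A, angle deg) plane, pairwise
    disjoint. Each region is (rmsd_lo, rmsd_hi, angle_lo, angle_hi),
    inclusive."""

    regions: dict = field(default_factory=dict)

    def __post_init__(self):
        for (n1, r1), (n2, r2) in itertools.combinations(self.regions.items(), 2):
            overlap_r = r1[0] <= r2[1] and r2[0] <= r1[1]
            overlap_a = r1[2] <= r2[3] and r2[2] <= r1[3]
            if overlap_r and overlap_a:
                raise ValueError(f"state regions {n1!r} and {n2!r} overlap")

    def contains(self, name: str, rmsd, angle):
        lo, hi, alo, ahi = self.regions[name]
        return (rmsd >= lo) & (rmsd <= hi) & (angle >= alo) & (angle <= ahi)


def default_state_bounds() -> StateBounds:
    """Approximate gamma-D-crystallin state boxes: a major well below 2 A
    RMSD around a 20 deg orientation angle, a metastable transition region
    near 2.8 A / 15 deg, and a minor well near 4 A RMSD below 10 deg.
    Figure-derived and fully overridable."""
    return StateBounds(
        regions={
            "major": (0.0, 2.0, 15.0, 30.0),
            "metastable": (2.4, 3.2, 12.0, 18.0),
            "minor": (3.5, 4.5, 0.0, 10.0),
        }
    )


def assign_states(features: TrajectoryFeatures, bounds: StateBounds):
    """Label each frame by its containing region, else 'other'.

    Returns ``(labels, occupancy)``; occupancy covers every region name plus
    'other' and sums to 1.
    """
    labels = np.full(len(features), "other", dtype=object)
    for name in bounds.regions:
        mask = bounds.contains(name, features.rmsd, features.angle)
        labels[mask] = name
    occupancy = {name: float(np.mean(labels == name)) for name in bounds.regions}
    occupancy["other"] = float(np.mean(labels == "other"))
    return labels, occupancy


def pick_representative_frames(features: TrajectoryFeatures, bounds: StateBounds) -> dict:
    """For each state, the index of the assigned frame nearest the region
    centroid (features standardized before the distance). States with no
    assigned frames are omitted."""
    labels, _ = assign_states(features, bounds)
    sr = np.std(features.rmsd) or 1.0
    sa = np.std(features.angle) or 1.0
    out = {}
    for name, (lo, hi, alo, ahi) in bounds.regions.items():
        idx = np.nonzero(labels == name)[0]
        if len(idx) == 0:
            continue
        cr, ca = 0.5 * (lo + hi), 0.5 * (alo + ahi)
        d = ((features.rmsd[idx] - cr) / sr) ** 2 + ((features.angle[idx] - ca) / sa) ** 2
        out[name] = int(idx[np.argmin(d)])
    return out


# ---------------------------------------------------------------------------
# Residue-COM distances
# ---------------------------------------------------------------------------


def com_distance_matrix(
    frame: StructureFrame, group_a, group_b, atom_scope: str = "all_heavy"
) -> np.ndarray:
    """Matrix of |COM(residue a_i) - COM(residue b_j)| in Angstrom, each
    residue's COM taken over the requested atom scope."""
    group_a = list(group_a)
    group_b = list(group_b)
    coms_a = np.array([select_com(frame, [r], atom_scope) for r in group_a])
    coms_b = np.array([select_com(frame, [r], atom_scope) for r in group_b])
    diff = coms_a[:, None, :] - coms_b[None, :, :]
    return np.linalg.norm(diff, axis=2)


def acidic_residues(frame: StructureFrame) -> list:
    """Residue indices named ASP or GLU in the frame (sorted)."""
    mask = np.isin(np.array([str(n) for n in frame.residue_names]), ("ASP", "GLU"))
    return sorted(set(frame.residue_indices[mask].tolist()))


DEFAULT_SITES = (24, 33, 49, 118, 124, 137, 160)


def compare_conformations(
    frame_major: StructureFrame,
    frame_minor: StructureFrame,
    sites=DEFAULT_SITES,
    partners=None,
    cutoffs=(15.0, 20.0),
    atom_scope: str = "all_heavy",
) -> pd.DataFrame:
    """Residue-COM distances between substitution sites (and between each
    site and each acidic partner) in two conformations.

    ``partners`` defaults to the ASP/GLU residues of ``frame_major``. The
    table reports, per unordered pair, the distance in each frame, the
    signed difference (minor - major), and per-cutoff flags set when the
    distance in either frame is below the cutoff; rows are sorted by
    absolute difference, descending.
    """
    sites = [int(s) for s in sites]
    if partners is None:
        partners = acidic_residues(frame_major)
    partners = [int(p) for p in partners]
    if not partners:
        raise ValueError("partner residue list is empty")

    pairs = set()
    for a, b in itertools.combinations(sites, 2):
        pairs.add((min(a, b), max(a, b)))
    for s in sites:
        for p in partners:
            if p != s:
                pairs.add((min(s, p), max(s, p)))
    pairs = sorted(pairs)

    residues = sorted({r for pair in pairs for r in pair})
    ridx = {r: i for i, r in enumerate(residues)}
    d_major = com_distance_matrix(frame_major, residues, residues, atom_scope)
    d_minor = com_distance_matrix(frame_minor, residues, residues, atom_scope)

    rows = []
    for a, b in pairs:
        dm = float(d_major[ridx[a], ridx[b]])
        dn = float(d_minor[ridx[a], ridx[b]])
        row = {
            "res_i": a,
            "res_j": b,
            "kind": "site-site" if (a in sites and b in sites) else "site-acidic",
            "d_major_A": dm,
            "d_minor_A": dn,
            "difference_A": dn - dm,
        }
        for c in cutoffs:
            row[f"within_{c:g}A"] = (dm < c) or (dn < c)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.reindex(df["difference_A"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
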