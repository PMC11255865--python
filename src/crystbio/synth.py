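"""Seeded synthetic-data generators with known ground truth.

Each generator emulates the statistical structure one analysis stage
assumes: CSPs localized at substitution sites over near-zero baselines;
sigmoidal two-state isotherms with sloping baselines and multiplicative
Gaussian noise; linear diffusion-vs-concentration series with a small
negative slope; and two-rigid-domain toy trajectories that interconvert
between a major and a minor inter-domain orientation. All generators are
pure functions of their parameters and seed (bit-reproducible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .denaturation import predict_signal
from .fileio import DLSSeries, Isotherm, PeakList, StructureFrame, Trajectory, T_DEFAULT
from .traj import AngleDefinition, StateBounds, featurize, orientation_angle, superpose

# ---------------------------------------------------------------------------
# NMR peak lists
# ---------------------------------------------------------------------------


def gen_peak_lists(
    n_residues: int = 165,
    sites=(24, 33, 49),
    site_csp_magnitude: float = 0.15,
    baseline_noise: float = 0.003,
    neighbor_decay: float = 1.5,
    proline_fraction: float = 0.04,
    seed: int = 0,
    labels=("variant", "reference"),
):
    """Reference and variant peak lists with site-localized perturbations.

    Reference shifts are drawn uniformly in realistic amide windows (1H
    7-10 ppm, 15N 105-130 ppm). The variant adds, at each substitution
    site, a perturbation of combined-CSP magnitude ``site_csp_magnitude``
    (ppm) split between 1H and 15N along a per-site random direction,
    decaying exponentially to sequence neighbors with length scale
    ``neighbor_decay`` residues (0 disables spill-over), plus Gaussian
    baseline noise everywhere (sigma ``baseline_noise`` ppm on 1H, six-fold
    on 15N). A random subset of residues is omitted from both lists as
    "prolines".

    The reference shifts, proline draw, noise stream and per-site
    perturbation directions are seeded independently, so calls sharing a
    seed but differing in ``sites`` produce perturbation fields that add
    exactly: the union-site variant equals the sum of the domain-confined
    perturbations.
    """
    sites = tuple(int(s) for s in sites)
    if site_csp_magnitude < 0:
        raise ValueError("site_csp_magnitude must be >= 0")
    if any(s < 1 or s > n_residues for s in sites):
        raise ValueError("sites must lie within 1..n_residues")

    rng_ref = np.random.default_rng([seed, 11])
    rng_pro = np.random.default_rng([seed, 13])
    rng_noise = np.random.default_rng([seed, 17])

    res = np.arange(1, n_residues + 1)
    h_ref = rng_ref.uniform(7.0, 10.0, n_residues)
    n_ref = rng_ref.uniform(105.0, 130.0, n_residues)

    # perturbation field, summed over sites; per-site RNG keyed by (seed, site)
    dh = np.zeros(n_residues)
    dn = np.zeros(n_residues)
    for s in sites:
        rng_site = np.random.default_rng([seed, 1009, s])
        u = rng_site.uniform(0.0, 1.0)
        sign_h, sign_n = rng_site.choice([-1.0, 1.0], size=2)
        ddh = sign_h * site_csp_magnitude * u
        ddn = sign_n * 6.0 * site_csp_magnitude * math.sqrt(1.0 - u**2)
        if neighbor_decay > 0:
            decay = np.exp(-np.abs(res - s) / neighbor_decay)
        else:
            decay = (res == s).astype(float)
        dh += ddh * decay
        dn += ddn * decay

    noise_h = rng_noise.normal(0.0, baseline_noise, n_residues) if baseline_noise > 0 else 0.0
    noise_n = rng_noise.normal(0.0, 6.0 * baseline_noise, n_residues) if baseline_noise > 0 else 0.0
    h_var = h_ref + dh + noise_h
    n_var = n_ref + dn + noise_n

    n_pro = int(proline_fraction * n_residues)
    candidates = np.setdiff1d(res, np.array(sites, dtype=int))
    prolines = rng_pro.choice(candidates, size=min(n_pro, len(candidates)), replace=False)
    keep = ~np.isin(res, prolines)

    reference = PeakList(res[keep], h_ref[keep], n_ref[keep], label=labels[1])
    variant = PeakList(res[keep], h_var[keep], n_var[keep], label=labels[0])
    return reference, variant


# ---------------------------------------------------------------------------
# Unfolding isotherms
# ---------------------------------------------------------------------------

#: Default baselines: native and unfolded fluorescence-ratio intercepts and
#: slopes (arbitrary units; unfolding raises the signal).
DEFAULT_BASELINES = (0.35, 0.005, 1.0, 0.015)


def gen_isotherm(
    Cm: float,
    m: float,
    baselines=DEFAULT_BASELINES,
    noise_frac: float = 0.01,
    C_grid=None,
    replicates: int = 3,
    T: float = T_DEFAULT,
    seed: int = 0,
) -> Isotherm:
    """Two-state isotherm with sloping baselines and multiplicative Gaussian
    noise of fractional sigma ``noise_frac``. Default concentration grid is
    0-6 M in 0.25 M steps (the usual GdnHCl design)."""
    if C_grid is None:
        C_grid = np.arange(0.0, 6.0 + 1e-9, 0.25)
    C_grid = np.asarray(C_grid, dtype=float)
    aN, bN, aU, bU = baselines
    params = (np.array([Cm, m, aN, bN, aU, bU]), T)
    rng = np.random.default_rng([seed, 23])
    rows = []
    for rep in range(1, replicates + 1):
        clean = predict_signal(C_grid, params)
        noisy = clean * (1.0 + rng.normal(0.0, noise_frac, len(C_grid))) if noise_frac > 0 else clean
        rows.append(pd.DataFrame({"conc_M": C_grid, "signal": noisy, "replicate": rep}))
    return Isotherm(
        data=pd.concat(rows, ignore_index=True),
        meta={"Cm_true": Cm, "m_true": m, "baselines_true": tuple(baselines), "seed": seed},
    )


# ---------------------------------------------------------------------------
# DLS series
# ---------------------------------------------------------------------------


def gen_dls_series(
    D0: float = 8.0e-7,
    kd: float = -3.0,
    C_grid_mg_ml=(5.0, 10.0, 15.0, 20.0, 25.0),
    noise_frac: float = 0.005,
    replicates: int = 3,
    seed: int = 0,
) -> DLSSeries:
    """Linear D(C) = D0 (1 + kd C) series, C in mg/mL on input (stored in
    g/mL), with multiplicative Gaussian noise on D."""
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    C = np.asarray(C_grid_mg_ml, dtype=float)
    rng = np.random.default_rng([seed, 29])
    conc, dvals, reps = [], [], []
    for rep in range(1, replicates + 1):
        clean = D0 * (1.0 + kd * C * 1e-3)
        noisy = clean * (1.0 + rng.normal(0.0, noise_frac, len(C))) if noise_frac > 0 else clean
        conc.append(C)
        dvals.append(noisy)
        reps.append(np.full(len(C), rep))
    return DLSSeries.from_mg_ml(
        np.concatenate(conc), np.concatenate(dvals), np.concatenate(reps)
    )


# ---------------------------------------------------------------------------
# Two-domain toy trajectories
# ---------------------------------------------------------------------------

# backbone atom offsets around each C-alpha (keeps atoms distinct and
# non-collinear); pseudo-sidechain CB for acidic residues
_ATOM_OFFSETS = {
    "N": np.array([-0.60, 0.40, 0.25]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.60, -0.40, 0.25]),
    "O": np.array([1.05, 0.45, -0.30]),
}
_CB_OFFSET = np.array([0.0, 1.20, 1.00])


def _helix_ca(n: int, start: int = 0) -> np.ndarray:
    """C-alpha positions on a helical space curve with ~3.8 A spacing
    (rise 1.5 A, radius 2.28 A, 100 deg per residue), axis along +x."""
    t = np.arange(start, start + n, dtype=float)
    phi = np.deg2rad(100.0) * t
    return np.column_stack([1.5 * t, 2.28 * np.cos(phi), 2.28 * np.sin(phi)])


def _residue_names(indices, acidic_every=(5, 7)):
    names = []
    for r in indices:
        if r % acidic_every[0] == 0:
            names.append("ASP")
        elif r % acidic_every[1] == 0:
            names.append("GLU")
        else:
            names.append("GLY")
    return names


def _build_atoms(res_indices, ca_positions, res_names):
    ridx, rnames, anames, coords = [], [], [], []
    for r, ca, name in zip(res_indices, ca_positions, res_names):
        atoms = dict(_ATOM_OFFSETS)
        if name in ("ASP", "GLU"):
            atoms = {**atoms, "CB": _CB_OFFSET}
        for aname, off in atoms.items():
            ridx.append(r)
            rnames.append(name)
            anames.append(aname)
            coords.append(ca + off)
    return (
        np.array(ridx, dtype=int),
        np.array(rnames, dtype=object),
        np.array(anames, dtype=object),
        np.array(coords, dtype=float),
    )


@dataclass
class SyntheticTrajectory:
    trajectory: Trajectory
    reference: StructureFrame
    labels: np.ndarray  # per-frame ground truth: 'major' / 'minor'
    angle_definition: AngleDefinition
    bounds: StateBounds  # boxes placed around the two scripted states
    info: dict = field(default_factory=dict)


def gen_two_domain_trajectory(
    n_res_per_domain: int = 36,
    n_linker: int = 5,
    angle_major: float = 20.0,
    angle_minor: float = 8.0,
    occupancy_minor: float = 0.2,
    jitter_sigma: float = 0.2,
    n_frames: int = 2000,
    seed: int = 0,
) -> SyntheticTrajectory:
    """Two rigid pseudo-domains on helical backbones joined by a linker,
    hinging between two scripted inter-domain orientation angles.

    Domain A stays fixed; domain B is rotated rigidly about the vertex COM
    so that the measured orientation angle equals the scripted angle exactly
    (before jitter). Frames sample the minor angle with probability
    ``occupancy_minor``; per-coordinate Gaussian jitter of ``jitter_sigma``
    Angstrom is added on top. Returns the trajectory, the noiseless
    major-state reference, ground-truth labels, a matching AngleDefinition,
    and state boxes centred on the two scripted (RMSD, angle) points.
    """
    if not (0.0 < angle_major < 180.0 and 0.0 < angle_minor < 180.0):
        raise ValueError("scripted angles must lie in (0, 180)")
    if not 0.0 <= occupancy_minor <= 1.0:
        raise ValueError("occupancy_minor must be in [0, 1]")
    nA, nL, nB = n_res_per_domain, n_linker, n_res_per_domain
    if nA < 4:
        raise ValueError("need at least 4 residues per domain")

    res_A = np.arange(1, nA + 1)
    res_L = np.arange(nA + 1, nA + nL + 1)
    res_B = np.arange(nA + nL + 1, nA + nL + nB + 1)
    ca_A = _helix_ca(nA, start=0)
    ca_B_template = _helix_ca(nB, start=nA + nL + 1)

    names_A = _residue_names(res_A)
    names_L = ["GLY"] * nL
    names_B = _residue_names(res_B)

    # angle machinery: vertex at the hinge end of domain A, arm A at its far
    # end, arm B at the far end of domain B
    defn = AngleDefinition(
        vertex_residues=(int(res_A[-2]), int(res_A[-1])),
        arm_a_residues=(int(res_A[0]),),
        arm_b_residues=(int(res_B[-1]),),
        atom_scope="backbone",
    )

    idx_A, nm_A, an_A, xyz_A = _build_atoms(res_A, ca_A, names_A)
    frame_A_only = StructureFrame(idx_A, nm_A, an_A, xyz_A)
    from .fileio import select_com

    V = select_com(frame_A_only, list(defn.vertex_residues), "backbone")
    u = select_com(frame_A_only, list(defn.arm_a_residues), "backbone") - V
    u_hat = u / np.linalg.norm(u)
    if np.linalg.norm(u) < 1e-9:
        raise ValueError("degenerate hinge: zero-length vertex->arm vector")

    idx_Bt, nm_Bt, an_Bt, xyz_Bt = _build_atoms(res_B, ca_B_template, names_B)
    frame_B_template = StructureFrame(idx_Bt, nm_Bt, an_Bt, xyz_Bt)
    t = select_com(frame_B_template, list(defn.arm_b_residues), "backbone") - V
    if np.linalg.norm(t) < 1e-9:
        raise ValueError("degenerate hinge: zero-length vertex->arm_b vector")
    t_hat = t / np.linalg.norm(t)

    # rotation axis perpendicular to u_hat (so a rotation of u_hat by theta
    # about it lands exactly theta away from u_hat)
    z = np.array([0.0, 0.0, 1.0])
    axis = z - np.dot(z, u_hat) * u_hat
    if np.linalg.norm(axis) < 1e-6:
        axis = np.array([0.0, 1.0, 0.0]) - np.dot(np.array([0.0, 1.0, 0.0]), u_hat) * u_hat
    axis /= np.linalg.norm(axis)

    def _rotation_between(a: np.ndarray, b: np.ndarray) -> Rotation:
        """Proper rotation taking unit vector a onto unit vector b."""
        c = np.cross(a, b)
        d = float(np.dot(a, b))
        if np.linalg.norm(c) < 1e-12:
            if d > 0:
                return Rotation.identity()
            perp = np.cross(a, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(a, [0.0, 1.0, 0.0])
            return Rotation.from_rotvec(math.pi * perp / np.linalg.norm(perp))
        ang = math.atan2(float(np.linalg.norm(c)), d)
        return Rotation.from_rotvec(ang * c / np.linalg.norm(c))

    def domain_b_coords(theta_deg: float) -> np.ndarray:
        w = Rotation.from_rotvec(np.deg2rad(theta_deg) * axis).apply(u_hat)
        rot = _rotation_between(t_hat, w)
        return rot.apply(xyz_Bt - V) + V

    def linker_coords(b_coords: np.ndarray) -> tuple:
        anchor_a = ca_A[-1]
        anchor_b = b_coords[np.nonzero(idx_Bt == res_B[0])[0][1]]  # CA of first B residue
        ridx, rnames, anames, coords = [], [], [], []
        for k, r in enumerate(res_L, start=1):
            f = k / (nL + 1)
            ca = (1 - f) * anchor_a + f * anchor_b
            for aname, off in _ATOM_OFFSETS.items():
                ridx.append(r)
                rnames.append("GLY")
                anames.append(aname)
                coords.append(ca + off)
        return (
            np.array(ridx, dtype=int),
            np.array(rnames, dtype=object),
            np.array(anames, dtype=object),
            np.array(coords, dtype=float),
        )

    def assemble(theta_deg: float, frame_index: int) -> StructureFrame:
        b_xyz = domain_b_coords(theta_deg)
        l_idx, l_nm, l_an, l_xyz = linker_coords(b_xyz)
        return StructureFrame(
            residue_indices=np.concatenate([idx_A, l_idx, idx_Bt]),
            residue_names=np.concatenate([nm_A, l_nm, nm_Bt]),
            atom_names=np.concatenate([an_A, l_an, an_Bt]),
            coords=np.vstack([xyz_A, l_xyz, b_xyz]),
            frame_index=frame_index,
        )

    reference = assemble(angle_major, 0)
    minor_clean = assemble(angle_minor, 0)
    _, rmsd_minor = superpose(minor_clean, reference, atom_scope="backbone")

    rng = np.random.default_rng([seed, 31])
    minor_mask = rng.random(n_frames) < occupancy_minor
    labels = np.where(minor_mask, "minor", "major").astype(object)
    frames = []
    for i in range(n_frames):
        base = minor_clean if minor_mask[i] else reference
        coords = base.coords + (
            rng.normal(0.0, jitter_sigma, base.coords.shape) if jitter_sigma > 0 else 0.0
        )
        frames.append(base.with_coords(coords, frame_index=i + 1))
    trajectory = Trajectory(frames=frames)

    # state boxes around the two scripted (rmsd, angle) points, split on rmsd
    half = 0.5 * rmsd_minor
    spread = max(6.0, 0.45 * abs(angle_major - angle_minor))
    bounds = StateBounds(
        regions={
            "major": (0.0, half, angle_major - spread, angle_major + spread),
            "minor": (half + 1e-9, rmsd_minor + max(1.0, half), angle_minor - spread, angle_minor + spread),
        }
    )
    info = {
        "angle_major": float(angle_major),
        "angle_minor": float(angle_minor),
        "rmsd_minor_scripted": float(rmsd_minor),
        "occupancy_minor_requested": float(occupancy_minor),
        "occupancy_minor_drawn": float(minor_mask.mean()),
        "angle_reference_check": float(orientation_angle(reference, defn)),
    }
    return SyntheticTrajectory(
        trajectory=trajectory,
        reference=reference,
        labels=labels,
        angle_definition=defn,
        bounds=bounds,
        info=info,
    )
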