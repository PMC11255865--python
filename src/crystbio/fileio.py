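"""Readers, writers and shared structural machinery.

Tabular inputs (NMR peak lists, unfolding isotherms, DLS series) are plain
delimited text; structures and toy trajectories are PDB / multi-model PDB.
Residue numbering always follows the input file verbatim (1-based, no
renumbering), matching the crystallographic numbering conventions of the
proteins these analyses target.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Gas constant in kcal/(mol K).
R_KCAL = 1.987e-3
#: Default temperature (25 degC) in K.
T_DEFAULT = 298.15

#: Backbone heavy atoms. OXT deliberately excluded.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Standard atomic masses (u) for elements occurring in protein heavy atoms
#: plus hydrogen.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}


def element_from_atom_name(name: str) -> str:
    """Infer the element from a PDB atom name (e.g. 'CA' -> C, '1HB' -> H)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if stripped[:2].upper() in ("SE",):
        return "SE"
    return stripped[0].upper()


def atom_mass(name: str) -> float:
    elem = element_from_atom_name(name)
    try:
        return ATOMIC_MASSES[elem]
    except KeyError:
        raise ValueError(f"no mass tabulated for element {elem!r} (atom {name!r})")


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------


@dataclass
class PeakList:
    """Per-residue amide 1H/15N chemical shifts for one protein form.

    ``residues`` are 1-based indices, unique, possibly with gaps (prolines
    and unassigned residues carry no amide peak).
    """

    residues: np.ndarray
    delta_h: np.ndarray
    delta_n: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=int)
        self.delta_h = np.asarray(self.delta_h, dtype=float)
        self.delta_n = np.asarray(self.delta_n, dtype=float)
        if not (len(self.residues) == len(self.delta_h) == len(self.delta_n)):
            raise ValueError("residues, delta_h, delta_n must have equal length")
        dupes = pd.Series(self.residues)[pd.Series(self.residues).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate residue index in peak list: {sorted(set(dupes))}")
        if not (np.isfinite(self.delta_h).all() and np.isfinite(self.delta_n).all()):
            raise ValueError("non-finite chemical shift in peak list")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def entries(self):
        return list(zip(self.residues.tolist(), self.delta_h.tolist(), self.delta_n.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residues, "delta_h": self.delta_h, "delta_n": self.delta_n}
        )


def read_peak_list(path, label: str = "", column_map=None) -> PeakList:
    """Read a peak list from whitespace- or comma-delimited text.

    Expected columns are (residue, 1H shift, 15N shift), in that order unless
    ``column_map`` gives 0-based positions as ``(residue, H, N)``. A header
    row is optional. Rows whose shifts are blank or non-numeric (e.g.
    prolines) are skipped and logged; a duplicate residue index is a hard
    error.
    """
    with open(path) as fh:
        text = fh.read()
    sep = "," if "," in text.split("\n", 1)[0] or "," in text else None
    df = pd.read_csv(
        _io.StringIO(text),
        sep=sep,
        engine="python" if sep is None else "c",
        header=None,
        comment="#",
        skip_blank_lines=True,
        dtype=str,
    )
    if df.empty:
        raise ValueError(f"empty peak list file: {path}")
    cols = column_map if column_map is not None else (0, 1, 2)
    if df.shape[1] <= max(cols):
        raise ValueError(f"peak list {path} has {df.shape[1]} columns, need {max(cols) + 1}")
    sub = df.iloc[:, list(cols)].copy()
    sub.columns = ["residue", "delta_h", "delta_n"]
    # drop a header row if the first row is non-numeric
    first = sub.iloc[0]
    if not _is_number(first["residue"]):
        sub = sub.iloc[1:]
    if sub.empty:
        raise ValueError(f"peak list file {path} contains no data rows")
    # Python's float() is correctly rounded (bit-exact round trips); pandas'
    # fast parser is not
    num = sub.apply(lambda c: c.map(_float_or_nan))
    bad = num.isna().any(axis=1)
    if bad.any():
        for res in sub.loc[bad, "residue"].tolist():
            logger.info("skipping peak-list row with non-numeric shifts (residue %s)", res)
    num = num[~bad]
    if num.empty:
        raise ValueError(f"peak list file {path} contains no usable rows")
    return PeakList(
        residues=num["residue"].to_numpy(dtype=float).astype(int),
        delta_h=num["delta_h"].to_numpy(dtype=float),
        delta_n=num["delta_n"].to_numpy(dtype=float),
        label=label,
    )


def _float_or_nan(x) -> float:
    try:
        return float(x)
    except (TypeError, ValueError):
        return float("nan")


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_peak_list(peaks: PeakList, path) -> None:
    """Write a peak list as CSV with header (full float precision)."""
    df = peaks.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Structures and trajectories
# ---------------------------------------------------------------------------


@dataclass
class StructureFrame:
    """One set of atomic coordinates for a single-chain structure."""

    residue_indices: np.ndarray  # per atom, 1-based
    residue_names: np.ndarray  # per atom
    atom_names: np.ndarray  # per atom
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    frame_index: int = 0

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_indices)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinate in structure frame")

    @property
    def n_atoms(self) -> int:
        return len(self.residue_indices)

    def atom_table(self):
        """Hashable identity of the atom list (order matters)."""
        return tuple(zip(self.residue_indices.tolist(), self.residue_names, self.atom_names))

    def with_coords(self, coords, frame_index=None) -> "StructureFrame":
        return StructureFrame(
            residue_indices=self.residue_indices,
            residue_names=self.residue_names,
            atom_names=self.atom_names,
            coords=np.asarray(coords, dtype=float),
            frame_index=self.frame_index if frame_index is None else frame_index,
        )

    def residue_name(self, residue_index: int) -> str:
        mask = self.residue_indices == residue_index
        if not mask.any():
            raise KeyError(f"residue {residue_index} not in frame")
        return str(self.residue_names[mask][0])

    @property
    def residues(self) -> np.ndarray:
        """Sorted unique residue indices present in the frame."""
        return np.unique(self.residue_indices)


@dataclass
class Trajectory:
    """Ordered frames sharing one atom table. ``time_step`` is ps per frame
    (metadata only)."""

    frames: list
    time_step: float = 1.0

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        ref = self.frames[0].atom_table()
        for i, fr in enumerate(self.frames):
            if fr.atom_table() != ref:
                raise ValueError(
                    f"frame {fr.frame_index if fr.frame_index else i + 1} has a different "
                    "atom table from frame 1"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


def read_structure_frames(path) -> Trajectory:
    """Read a (multi-model) PDB into a Trajectory.

    MODEL/ENDMDL delimits frames; a single-model file yields one frame. All
    frames must share the same atom table; a mismatch is a hard error naming
    the offending frame. Only the first altloc is kept; a single chain is
    assumed.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("traj", str(path))
    frames = []
    for mi, model in enumerate(structure):
        res_idx, res_names, atom_names, coords = [], [], [], []
        for chain in model:
            for residue in chain:
                het, seq, icode = residue.get_id()
                if het.strip():
                    continue  # skip HETATM records
                for atom in residue:
                    if atom.get_altloc() not in (" ", "A"):
                        continue
                    res_idx.append(seq)
                    res_names.append(residue.get_resname().strip())
                    atom_names.append(atom.get_name().strip())
                    coords.append(atom.get_coord())
        if not res_idx:
            raise ValueError(f"model {mi + 1} of {path} contains no atoms")
        frames.append(
            StructureFrame(
                residue_indices=np.array(res_idx),
                residue_names=np.array(res_names, dtype=object),
                atom_names=np.array(atom_names, dtype=object),
                coords=np.array(coords, dtype=float),
                frame_index=mi + 1,
            )
        )
    if not frames:
        raise ValueError(f"no models found in {path}")
    ref = frames[0].atom_table()
    for fr in frames[1:]:
        if fr.atom_table() != ref:
            raise ValueError(
                f"frame {fr.frame_index} of {path} has a different atom table "
                f"({fr.n_atoms} atoms) from frame 1 ({len(ref)} atoms)"
            )
    return Trajectory(frames=frames)


def write_structure_frames(traj, path) -> None:
    """Write frames as a multi-model PDB (fixed-column ATOM records)."""
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for k, fr in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {k:4d}\n")
            for i in range(fr.n_atoms):
                name = str(fr.atom_names[i])
                # PDB column rules: 1-3 char names start in column 14
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = fr.coords[i]
                fh.write(
                    f"ATOM  {i + 1:5d} {pdb_name}{'':1s}{str(fr.residue_names[i]):<3s} "
                    f"A{int(fr.residue_indices[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{element_from_atom_name(name):>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selections and centers of mass
# ---------------------------------------------------------------------------


def _scope_mask(frame: StructureFrame, atom_scope: str) -> np.ndarray:
    names = np.array([str(a) for a in frame.atom_names])
    if atom_scope == "backbone":
        return np.isin(names, BACKBONE_ATOMS)
    if atom_scope == "all_heavy":
        elems = np.array([element_from_atom_name(a) for a in names])
        return elems != "H"
    raise ValueError(f"unknown atom_scope {atom_scope!r} (use 'backbone' or 'all_heavy')")


def select_com(frame: StructureFrame, residue_indices, atom_scope: str = "backbone") -> np.ndarray:
    """Mass-weighted center of mass of the chosen atoms pooled over all
    listed residues. Masses are standard atomic masses, element inferred from
    the atom name. Empty selection is a hard error."""
    residue_indices = np.atleast_1d(np.asarray(residue_indices, dtype=int))
    mask = np.isin(frame.residue_indices, residue_indices) & _scope_mask(frame, atom_scope)
    if not mask.any():
        raise ValueError(
            f"empty selection: residues {residue_indices.tolist()} with scope {atom_scope!r}"
        )
    masses = np.array([atom_mass(a) for a in frame.atom_names[mask]])
    return (frame.coords[mask] * masses[:, None]).sum(axis=0) / masses.sum()


# ---------------------------------------------------------------------------
# Tabular experiment containers
# ---------------------------------------------------------------------------


@dataclass
class Isotherm:
    """Chemical-denaturation isotherm: fluorescence signal vs denaturant
    molarity, possibly replicated."""

    data: pd.DataFrame  # columns: conc_M, signal, replicate
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"conc_M", "signal", "replicate"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"isotherm needs columns {sorted(required)}")
        if (self.data["conc_M"] < 0).any():
            raise ValueError("denaturant concentration must be >= 0")

    @property
    def n_distinct_conc(self) -> int:
        return self.data["conc_M"].nunique()


def read_isotherm(path, meta=None) -> Isotherm:
    df = pd.read_csv(path)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return Isotherm(data=df[["conc_M", "signal", "replicate"]], meta=meta or {})


def write_isotherm(iso: Isotherm, path) -> None:
    iso.data.to_csv(path, index=False, float_format="%.17g")


@dataclass
class DLSSeries:
    """Diffusion coefficient vs protein concentration. Concentration is
    stored in g/mL internally; files use mg/mL (converted on read)."""

    data: pd.DataFrame  # columns: conc_g_ml, D, replicate

    def __post_init__(self):
        required = {"conc_g_ml", "D", "replicate"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"DLS series needs columns {sorted(required)}")
        if (self.data["conc_g_ml"] < 0).any():
            raise ValueError("concentration must be >= 0")
        if (self.data["D"] <= 0).any():
            raise ValueError("diffusion coefficients must be positive")

    @classmethod
    def from_mg_ml(cls, conc_mg_ml, D, replicate=None) -> "DLSSeries":
        conc = np.asarray(conc_mg_ml, dtype=float) * 1e-3
        D = np.asarray(D, dtype=float)
        rep = np.ones(len(D), dtype=int) if replicate is None else np.asarray(replicate, dtype=int)
        return cls(pd.DataFrame({"conc_g_ml": conc, "D": D, "replicate": rep}))


def read_dls_series(path) -> DLSSeries:
    df = pd.read_csv(path)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return DLSSeries.from_mg_ml(df["conc_mg_ml"], df["D"], df["replicate"])


def write_dls_series(series: DLSSeries, path) -> None:
    out = pd.DataFrame(
        {
            "conc_mg_ml": series.data["conc_g_ml"] * 1e3,
            "D": series.data["D"],
            "replicate": series.data["replicate"],
        }
    )
    out.to_csv(path, index=False, float_format="%.17g")
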