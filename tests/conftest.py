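import numpy as np
import pytest

from crystbio import StructureFrame


def make_frame(atoms, frame_index=0):
    """Build a StructureFrame from (residue_index, residue_name, atom_name,
    (x, y, z)) tuples."""
    ridx, rnames, anames, coords = zip(*atoms)
    return StructureFrame(
        residue_indices=np.array(ridx, dtype=int),
        residue_names=np.array(rnames, dtype=object),
        atom_names=np.array(anames, dtype=object),
        coords=np.array(coords, dtype=float),
        frame_index=frame_index,
    )


def quaternion_rmsd(X, Y):
    """Independent minimal-RMSD oracle (Horn's quaternion method).

    X, Y: (n, 3) paired coordinates. Returns the least RMSD over proper
    rotations + translations, via the largest eigenvalue of the 4x4
    quaternion matrix built from the covariance of the centered sets.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S = Xc.T @ Yc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e2 = (np.sum(Xc**2) + np.sum(Yc**2) - 2.0 * lam) / len(X)
    return float(np.sqrt(max(e2, 0.0)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
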