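"""Internal helpers for building coarse peptide geometry.

Shared by the synthetic-fixture generators and the peptide grower: ideal
backbone constants, NeRF internal-to-Cartesian atom placement, a coarse
single-conformer side-chain builder (heavy atoms only), and residue-name
maps.
"""

from __future__ import annotations

import numpy as np

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# ideal backbone internals (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.5
OMEGA_TRANS = 180.0

# coarse side-chain topology: resname -> ordered (atom, parent, bond length Å,
# polar angle from the CA→CB axis in degrees).  Atoms are laid out in the
# plane spanned by the outward axis and a perpendicular reference; this is a
# single schematic conformer, not a rotamer library.
SIDECHAIN_TOPO: dict[str, list[tuple[str, str, float, float]]] = {
    "ALA": [("CB", "CA", 1.53, 0.0)],
    "ARG": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.52, 15.0), ("CD", "CG", 1.52, -15.0),
            ("NE", "CD", 1.46, 15.0), ("CZ", "NE", 1.33, -15.0),
            ("NH1", "CZ", 1.33, 45.0), ("NH2", "CZ", 1.33, -60.0)],
    "ASN": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.52, 15.0),
            ("OD1", "CG", 1.23, 60.0), ("ND2", "CG", 1.33, -45.0)],
    "ASP": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.52, 15.0),
            ("OD1", "CG", 1.25, 60.0), ("OD2", "CG", 1.25, -45.0)],
    "CYS": [("CB", "CA", 1.53, 0.0), ("SG", "CB", 1.81, 15.0)],
    "GLN": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.52, 15.0), ("CD", "CG", 1.52, -15.0),
            ("OE1", "CD", 1.23, 45.0), ("NE2", "CD", 1.33, -60.0)],
    "GLU": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.52, 15.0), ("CD", "CG", 1.52, -15.0),
            ("OE1", "CD", 1.25, 45.0), ("OE2", "CD", 1.25, -60.0)],
    "GLY": [],
    "HIS": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.50, 15.0),
            ("ND1", "CG", 1.38, 55.0), ("CD2", "CG", 1.36, -40.0),
            ("CE1", "ND1", 1.32, 15.0), ("NE2", "CD2", 1.37, 15.0)],
    "ILE": [("CB", "CA", 1.54, 0.0), ("CG1", "CB", 1.53, 30.0),
            ("CG2", "CB", 1.52, -45.0), ("CD1", "CG1", 1.51, 15.0)],
    "LEU": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.53, 15.0),
            ("CD1", "CG", 1.52, 45.0), ("CD2", "CG", 1.52, -30.0)],
    "LYS": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.52, 15.0), ("CD", "CG", 1.52, -15.0),
            ("CE", "CD", 1.52, 15.0), ("NZ", "CE", 1.49, -15.0)],
    "MET": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.52, 15.0),
            ("SD", "CG", 1.80, -15.0), ("CE", "SD", 1.79, 15.0)],
    "PHE": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.50, 15.0),
            ("CD1", "CG", 1.39, 50.0), ("CD2", "CG", 1.39, -35.0),
            ("CE1", "CD1", 1.39, 15.0), ("CE2", "CD2", 1.39, 15.0),
            ("CZ", "CE1", 1.39, -25.0)],
    "PRO": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.50, 35.0), ("CD", "CG", 1.51, -60.0)],
    "SER": [("CB", "CA", 1.53, 0.0), ("OG", "CB", 1.42, 15.0)],
    "THR": [("CB", "CA", 1.54, 0.0), ("OG1", "CB", 1.43, 40.0), ("CG2", "CB", 1.52, -40.0)],
    "TRP": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.50, 15.0),
            ("CD1", "CG", 1.37, 55.0), ("CD2", "CG", 1.43, -35.0),
            ("NE1", "CD1", 1.38, 10.0), ("CE2", "CD2", 1.40, 25.0),
            ("CE3", "CD2", 1.40, -55.0), ("CZ2", "CE2", 1.40, 10.0),
            ("CZ3", "CE3", 1.39, 5.0), ("CH2", "CZ2", 1.37, -20.0)],
    "TYR": [("CB", "CA", 1.53, 0.0), ("CG", "CB", 1.50, 15.0),
            ("CD1", "CG", 1.39, 50.0), ("CD2", "CG", 1.39, -35.0),
            ("CE1", "CD1", 1.39, 15.0), ("CE2", "CD2", 1.39, 15.0),
            ("CZ", "CE1", 1.39, -25.0), ("OH", "CZ", 1.38, 10.0)],
    "VAL": [("CB", "CA", 1.54, 0.0), ("CG1", "CB", 1.52, 35.0), ("CG2", "CB", 1.52, -35.0)],
}

ELEMENT_OF = {"N": "N", "O": "O", "S": "S"}


def element_of(atom_name: str) -> str:
    return ELEMENT_OF.get(atom_name[0], "C")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: new atom bonded to ``c`` with given internal coordinates.

    ``angle`` is the b–c–new angle, ``torsion`` the a–b–c–new dihedral.
    """
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def carbonyl_o(ca: np.ndarray, c: np.ndarray, n_next: np.ndarray) -> np.ndarray:
    """Planar sp2 carbonyl oxygen opposite the CA/N-next bisector."""
    bis = _unit(_unit(ca - c) + _unit(n_next - c))
    return c - BOND_C_O * bis


def sidechain_coords(resname: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                     axis: np.ndarray | None = None) -> list[tuple[str, np.ndarray]]:
    """Coarse heavy-atom side chain grown from CA.

    The CA→CB axis defaults to the standard tetrahedral direction away from
    the backbone; ``axis`` overrides it (fixture generators use this to point
    side chains into a pocket).  Atoms are placed in the plane spanned by the
    axis and a perpendicular reference, at the topology's schematic angles.
    """
    topo = SIDECHAIN_TOPO.get(resname, [])
    if not topo:
        return []
    if axis is None:
        axis = _unit(_unit(ca - n) + _unit(ca - c))
    else:
        axis = _unit(np.asarray(axis, dtype=float))
    # perpendicular reference in the plane
    ref = np.cross(axis, _unit(c - n)) if abs(np.dot(axis, _unit(c - n))) < 0.99 else np.cross(axis, [0.0, 0.0, 1.0])
    ref = _unit(ref)
    placed: dict[str, np.ndarray] = {"CA": ca}
    out: list[tuple[str, np.ndarray]] = []
    for name, parent, bond, polar in topo:
        p = placed[parent]
        ang = np.deg2rad(polar)
        direction = _unit(np.cos(ang) * axis + np.sin(ang) * ref)
        pos = p + bond * direction
        placed[name] = pos
        out.append((name, pos))
    return out
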