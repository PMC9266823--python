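"""Distance-based structural descriptors.

All criteria here are heavy-atom and purely distance-based, so fixtures and
real structures need no hydrogens: the salt-bridge reaction coordinate d_SB,
interface residues at a contact cutoff, hydrogen bonds, salt bridges, water
bridges, β-turns, disulfides, and Kabsch rigid superposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structio import Complex, SelectionError, Structure, select

__all__ = [
    "DsbSpec",
    "HBond",
    "WaterBridge",
    "TurnAnnotation",
    "dsb",
    "interface_residues",
    "hbonds",
    "salt_bridges",
    "water_bridges",
    "beta_turns",
    "disulfides",
    "kabsch_superpose",
    "apply_transform",
]

POLAR_ELEMENTS = frozenset({"N", "O", "S"})

BASIC_GROUPS = {  # resname -> side-chain nitrogen atoms carrying positive charge
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
}
ACIDIC_GROUPS = {  # resname -> carboxylate oxygens
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass
class DsbSpec:
    """Atom pair defining the salt-bridge distance d_SB.

    Defaults follow the convention of measuring from the ligand lysine
    side-chain amino nitrogen (NZ) to the receptor aspartate carboxylate
    carbon (CG).
    """

    ligand_chain: str = "L"
    ligand_resid: int = 9
    ligand_atom: str = "NZ"
    receptor_chain: str = "R"
    receptor_resid: int = 126
    receptor_atom: str = "CG"

    def _resolve_one(self, structure: Structure, chain: str, resid: int, name: str) -> int:
        hits = [
            i
            for i, a in enumerate(structure.atoms)
            if a.chain == chain and a.resid == resid and a.name == name
        ]
        if len(hits) != 1:
            raise SelectionError(
                f"d_SB selection (chain {chain}, resid {resid}, name {name}) "
                f"resolved to {len(hits)} atoms (need exactly 1)"
            )
        return hits[0]

    def resolve(self, structure: Structure) -> tuple[int, int]:
        i = self._resolve_one(structure, self.ligand_chain, self.ligand_resid, self.ligand_atom)
        j = self._resolve_one(structure, self.receptor_chain, self.receptor_resid, self.receptor_atom)
        return i, j


@dataclass
class HBond:
    donor: tuple[str, int, str]      # (chain, resid, atom name)
    acceptor: tuple[str, int, str]
    distance: float

    donor_index: int = -1
    acceptor_index: int = -1


@dataclass
class WaterBridge:
    water: tuple[str, int]           # (chain, resid) of the bridging water
    ligand_hbond: HBond
    receptor_hbond: HBond


@dataclass
class TurnAnnotation:
    chain: str
    start_resid: int
    kind: str
    ca_distance: float               # |Cα(i) − Cα(i+3)| in Å


def dsb(cplx: Complex, spec: DsbSpec | None = None) -> float:
    """The salt-bridge distance d_SB (Å) for one complex."""
    spec = spec or DsbSpec()
    i, j = spec.resolve(cplx.structure)
    return float(np.linalg.norm(cplx.structure.atoms[i].coords - cplx.structure.atoms[j].coords))


def interface_residues(
    cplx: Complex, cutoff: float = 3.5, side: str = "receptor"
) -> list[tuple[str, int, str, float]]:
    """Residues of one molecule with any heavy atom within ``cutoff`` of the other.

    Waters are excluded; returns (chain, resid, resname, min distance) sorted
    by (chain, resid).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if side == "receptor":
        own, other = cplx.receptor_indices(heavy_only=True), cplx.ligand_indices(heavy_only=True)
    elif side == "ligand":
        own, other = cplx.ligand_indices(heavy_only=True), cplx.receptor_indices(heavy_only=True)
    else:
        raise ValueError("side must be 'receptor' or 'ligand'")
    if not own or not other:
        return []
    xyz = cplx.structure.coords
    d = cdist(xyz[own], xyz[other]).min(axis=1)
    best: dict[tuple[str, int], tuple[str, float]] = {}
    for k, i in enumerate(own):
        a = cplx.structure.atoms[i]
        key = (a.chain, a.resid)
        if key not in best or d[k] < best[key][1]:
            best[key] = (a.resname, float(d[k]))
    out = [
        (chain, resid, resname, dist)
        for (chain, resid), (resname, dist) in best.items()
        if dist <= cutoff
    ]
    return sorted(out, key=lambda t: (t[0], t[1]))


def _polar_indices(structure: Structure, indices: Sequence[int]) -> list[int]:
    return [i for i in indices if structure.atoms[i].element.upper() in POLAR_ELEMENTS]


def hbonds(
    structure: Structure,
    group_a: Sequence[int] | None = None,
    group_b: Sequence[int] | None = None,
    max_da: float = 3.5,
) -> list[HBond]:
    """Heavy-atom hydrogen bonds: N/O/S pairs with distance ≤ ``max_da``.

    Without hydrogens any N/O/S counts as a plausible donor, so the criterion
    is symmetric in the two partners; the donor slot simply carries the first
    group's atom.  Pairs within one residue closer than 1.8 Å (covalent) are
    excluded.  When no groups are given, all intra-structure N/O/S pairs are
    enumerated once.
    """
    if max_da <= 0:
        raise ValueError("max_da must be > 0")
    atoms = structure.atoms
    if group_a is None:
        polar = _polar_indices(structure, range(len(atoms)))
        pairs = [(polar[i], polar[j]) for i in range(len(polar)) for j in range(i + 1, len(polar))]
    else:
        pa = _polar_indices(structure, group_a)
        pb = _polar_indices(structure, group_b if group_b is not None else range(len(atoms)))
        pairs = [(i, j) for i in pa for j in pb if i != j]
    out: list[HBond] = []
    for i, j in pairs:
        ai, aj = atoms[i], atoms[j]
        d = float(np.linalg.norm(ai.coords - aj.coords))
        if d > max_da:
            continue
        if (ai.chain, ai.resid) == (aj.chain, aj.resid) and d < 1.8:
            continue  # covalently bonded within one residue
        out.append(HBond(donor=ai.key(), acceptor=aj.key(), distance=d, donor_index=i, acceptor_index=j))
    return out


def hbonds_between(cplx: Complex, max_da: float = 3.5) -> list[HBond]:
    """Intermolecular H-bonds between the receptor and ligand molecules."""
    return hbonds(
        cplx.structure,
        group_a=cplx.ligand_indices(heavy_only=True),
        group_b=cplx.receptor_indices(heavy_only=True),
        max_da=max_da,
    )


def _terminal_n_indices(structure: Structure, chain_atoms: dict[int, list[int]]) -> list[int]:
    """Index of the backbone N of the first residue of a chain (N-terminus)."""
    if not chain_atoms:
        return []
    first_resid = next(iter(chain_atoms))
    return [
        i for i in chain_atoms[first_resid] if structure.atoms[i].name == "N"
    ]


def salt_bridges(cplx: Complex, cutoff: float = 4.0) -> list[tuple]:
    """Intermolecular salt bridges as (basic group, acidic group, min N–O distance).

    Basic groups: Lys NZ, Arg NH1/NH2/NE, chain N-terminal N.  Acidic groups:
    Asp OD1/OD2, Glu OE1/OE2, backbone carbonyl O, C-terminal OXT.  Groups are
    identified by (chain, resid, kind); a bridge is reported when the minimum
    heavy-atom N–O distance is ≤ ``cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    st = cplx.structure

    def collect(indices: list[int]):
        basic: dict[tuple, list[int]] = {}
        acidic: dict[tuple, list[int]] = {}
        by_chain: dict[str, dict[int, list[int]]] = {}
        for i in indices:
            a = st.atoms[i]
            by_chain.setdefault(a.chain, {}).setdefault(a.resid, []).append(i)
            if a.resname in BASIC_GROUPS and a.name in BASIC_GROUPS[a.resname]:
                basic.setdefault((a.chain, a.resid, "sidechain-N"), []).append(i)
            if a.resname in ACIDIC_GROUPS and a.name in ACIDIC_GROUPS[a.resname]:
                acidic.setdefault((a.chain, a.resid, "carboxylate"), []).append(i)
            if a.name == "O":
                acidic.setdefault((a.chain, a.resid, "backbone-O"), []).append(i)
            if a.name == "OXT":
                acidic.setdefault((a.chain, a.resid, "C-terminus"), []).append(i)
        for chain, res_atoms in by_chain.items():
            for i in _terminal_n_indices(st, res_atoms):
                a = st.atoms[i]
                basic.setdefault((a.chain, a.resid, "N-terminus"), []).append(i)
        return basic, acidic

    rec = cplx.receptor_indices(heavy_only=True)
    lig = cplx.ligand_indices(heavy_only=True)
    basic_r, acidic_r = collect(rec)
    basic_l, acidic_l = collect(lig)

    xyz = st.coords
    out = []
    for basic, acidic in ((basic_r, acidic_l), (basic_l, acidic_r)):
        for bkey, bidx in basic.items():
            for akey, aidx in acidic.items():
                d = float(cdist(xyz[bidx], xyz[aidx]).min())
                if d <= cutoff:
                    out.append((bkey, akey, d))
    return sorted(out, key=lambda t: t[2])


def water_bridges(
    cplx: Complex,
    ligand_sel: Sequence[int] | None = None,
    receptor_sel: Sequence[int] | None = None,
    max_da: float = 3.5,
) -> list[WaterBridge]:
    """Waters H-bonded simultaneously to the ligand and receptor selections.

    One bridge per water (deduplicated); the shortest H-bond on each side is
    reported.  Selections default to all polar heavy atoms of each molecule.
    """
    st = cplx.structure
    lig = list(ligand_sel) if ligand_sel is not None else cplx.ligand_indices(heavy_only=True)
    rec = list(receptor_sel) if receptor_sel is not None else cplx.receptor_indices(heavy_only=True)
    waters: dict[tuple[str, int], list[int]] = {}
    for i in cplx.water_indices():
        a = st.atoms[i]
        if a.element.upper() == "O":
            waters.setdefault((a.chain, a.resid), []).append(i)
    out: list[WaterBridge] = []
    for wkey, oidx in sorted(waters.items()):
        lig_hb = hbonds(st, group_a=oidx, group_b=lig, max_da=max_da)
        rec_hb = hbonds(st, group_a=oidx, group_b=rec, max_da=max_da)
        if lig_hb and rec_hb:
            out.append(
                WaterBridge(
                    water=wkey,
                    ligand_hbond=min(lig_hb, key=lambda h: h.distance),
                    receptor_hbond=min(rec_hb, key=lambda h: h.distance),
                )
            )
    return out


def beta_turns(structure: Structure, chain: str, dmax: float = 7.0, helix_dmax: float = 6.5) -> list[TurnAnnotation]:
    """β-turn annotations: residues i with |Cα(i) − Cα(i+3)| ≤ ``dmax``.

    Helical windows are excluded: a candidate is dropped when the i → i+4 Cα
    distances around it (at i−1 and i, where defined) all show the compact
    helical pattern (≤ ``helix_dmax``).  Chains shorter than 4 residues give
    an empty list.
    """
    ca: list[tuple[int, np.ndarray]] = []
    for (ch, resid, _resname) in structure.residues(chain):
        try:
            i = structure.atom_index(ch, resid, "CA")
        except KeyError:
            continue
        ca.append((resid, structure.atoms[i].coords))
    if len(ca) < 4:
        return []

    def d(i: int, j: int) -> float:
        return float(np.linalg.norm(ca[i][1] - ca[j][1]))

    out: list[TurnAnnotation] = []
    n = len(ca)
    for i in range(n - 3):
        dist = d(i, i + 3)
        if dist > dmax:
            continue
        window = [j for j in (i - 1, i) if 0 <= j and j + 4 < n]
        if window and all(d(j, j + 4) <= helix_dmax for j in window):
            continue  # contiguous helical pattern
        out.append(TurnAnnotation(chain=chain, start_resid=ca[i][0], kind="beta-turn", ca_distance=dist))
    return out


def disulfides(structure: Structure, max_ss: float = 2.5) -> list[tuple]:
    """Cys SG pairs within ``max_ss`` Å as ((chain, resid), (chain, resid), d)."""
    sg = [
        (i, structure.atoms[i])
        for i in range(len(structure))
        if structure.atoms[i].resname == "CYS" and structure.atoms[i].name == "SG"
    ]
    out = []
    for k in range(len(sg)):
        for m in range(k + 1, len(sg)):
            d = float(np.linalg.norm(sg[k][1].coords - sg[m][1].coords))
            if d <= max_ss:
                out.append(((sg[k][1].chain, sg[k][1].resid), (sg[m][1].chain, sg[m][1].resid), d))
    return sorted(out, key=lambda t: t[2])


# --------------------------------------------------------------------------
# Rigid superposition


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation R, translation t, RMSD) such that ``mobile @ R.T + t``
    best fits ``reference``; R is a proper rotation (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition requires >= 3 points of dimension 3")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(R).T + np.asarray(t)
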