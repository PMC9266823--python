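"""Seeded generators for every fixture the analysis pipeline needs.

The generators emulate the study system at fixture scale: a toy pseudo-
receptor with a buried acidic pocket residue on the pocket floor, a tyrosine
mid-pocket, and an arginine-bearing extracellular "lid"; a 14-residue cyclic
somatostatin-like peptide (AGCKNFFWKTFTSC) with a C3–C14 disulfide contact
and an apical turn at the FWKT region; rigid-body trajectories whose ligand–
receptor salt-bridge distance d_SB follows programmed state means; an
intermediate-state complex with three bridging waters plus decoys; and
known-answer energy systems.

Every generator is a pure function of its seed and parameters: re-running
with the same seed reproduces byte-identical PDB output.  Fixtures are
coarse — backbone plus key heavy side-chain atoms — which is sufficient for
all distance- and energy-based criteria in the package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from ._buildlib import ONE_TO_THREE, element_of, sidechain_coords
from .energetics import ParamStructure, ParamTable, ParameterizedComplex, assign_parameters
from .geometry import DsbSpec
from .structio import Atom, Complex, Structure, Trajectory

__all__ = [
    "SST_SEQUENCE",
    "ScenarioSpec",
    "ScenarioSegment",
    "FixtureManifest",
    "make_toy_receptor",
    "make_sst_peptide",
    "make_scenario_trajectory",
    "make_intermediate_fixture",
    "make_energy_fixture",
    "pose_ligand",
]

#: Somatostatin-14 (UniProt P61278 residues 103–116).
SST_SEQUENCE = "AGCKNFFWKTFTSC"

RECEPTOR_CHAIN = "R"
LIGAND_CHAIN = "L"
WATER_CHAIN = "W"

ASP_RESID = 126
ARG_RESIDS = (188, 191)
TYR_RESID = 301


@dataclass
class ScenarioSegment:
    label: str
    mean: float      # Å
    sigma: float     # Å
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("segment frame count must be >= 1")
        if self.sigma <= 0:
            raise ValueError("segment sigma must be > 0")
        if self.mean < 2.0:
            raise ValueError(f"requested d_SB mean {self.mean} Å below 2 Å is unphysical")


@dataclass
class ScenarioSpec:
    """Programmed d_SB segments for a mechanism trajectory.

    The default scenario walks the association pathway: external (18.5 Å) →
    far intermediate (10 Å) → near intermediate (5.5 Å) → internal (3 Å),
    with 100 ns of simulated time over 2000 frames.
    """

    segments: list[ScenarioSegment] = field(default_factory=lambda: [
        ScenarioSegment("external", 18.5, 0.4, 500),
        ScenarioSegment("intermediate_far", 10.0, 0.4, 500),
        ScenarioSegment("intermediate_near", 5.5, 0.4, 400),
        ScenarioSegment("internal", 3.0, 0.4, 600),
    ])
    dt: float = 0.05  # ns per frame
    seed: int = 42

    @property
    def n_frames(self) -> int:
        return sum(s.n_frames for s in self.segments)

    @property
    def occupancies(self) -> dict[str, float]:
        n = self.n_frames
        return {s.label: s.n_frames / n for s in self.segments}


@dataclass
class FixtureManifest:
    """Ground truth of a generated fixture; every value is recomputable from
    the emitted coordinates."""

    generator: str
    seed: int
    parameters: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    @property
    def digest(self) -> str:
        payload = repr(sorted(self.parameters.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_text(self, path) -> None:
        lines = [f"generator: {self.generator}", f"seed: {self.seed}", f"digest: {self.digest}"]
        for k, v in sorted(self.parameters.items()):
            lines.append(f"param.{k}: {v}")
        for k, v in sorted(self.ground_truth.items()):
            lines.append(f"truth.{k}: {v}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _atom(serial: int, name: str, resname: str, resid: int, chain: str, xyz) -> Atom:
    return Atom(
        serial=serial,
        name=name,
        element=element_of(name),
        resname=resname,
        resid=resid,
        chain=chain,
        coords=np.asarray(xyz, dtype=float),
    )


# --------------------------------------------------------------------------
# Toy receptor


def make_toy_receptor(seed_rng: int = 42) -> tuple[Structure, FixtureManifest]:
    """A ~22-residue pseudo-receptor around a cylindrical pocket (axis = z).

    Pocket floor at z≈0 carries the buried aspartate (resid 126, carboxylate
    carbon CG at the origin — the d_SB anchor); a tyrosine (301) sits
    mid-pocket with its hydroxyl pointing inward; two arginines (188, 191)
    form the extracellular lid at z≈16; three rings of backbone-only glycines
    (radius 8 Å) form the walls.
    """
    rng = np.random.default_rng(seed_rng)
    atoms: list[Atom] = []
    serial = [0]

    def add(name, resname, resid, xyz):
        serial[0] += 1
        atoms.append(_atom(serial[0], name, resname, resid, RECEPTOR_CHAIN, xyz))

    # wall rings: 3 z-levels x 6 glycines, backbone only
    resid = 101
    radius = 8.0
    for z in (3.5, 8.5, 13.5):
        for k in range(6):
            theta = 2 * np.pi * k / 6
            jitter = rng.uniform(-0.05, 0.05, size=3)
            ca = np.array([radius * np.cos(theta), radius * np.sin(theta), z]) + jitter
            tang = np.array([-np.sin(theta), np.cos(theta), 0.0])
            out = np.array([np.cos(theta), np.sin(theta), 0.0])
            add("N", "GLY", resid, ca - 1.46 * tang + 0.2 * out)
            add("CA", "GLY", resid, ca)
            add("C", "GLY", resid, ca + 1.52 * tang + 0.2 * out)
            add("O", "GLY", resid, ca + 1.52 * tang + 1.4 * out)  # carbonyl points outward
            resid += 1

    # pocket-floor aspartate: carboxylate C (CG) at the origin, oxygens up
    add("N", "ASP", ASP_RESID, (2.30, -1.00, -2.40))
    add("CA", "ASP", ASP_RESID, (1.40, -1.40, -1.80))
    add("C", "ASP", ASP_RESID, (2.00, -2.50, -1.20))
    add("O", "ASP", ASP_RESID, (2.00, -3.40, -2.00))
    add("CB", "ASP", ASP_RESID, (0.70, -0.70, -0.90))
    add("CG", "ASP", ASP_RESID, (0.00, 0.00, 0.00))
    add("OD1", "ASP", ASP_RESID, (0.95, 0.00, 0.70))
    add("OD2", "ASP", ASP_RESID, (-0.95, 0.00, 0.70))

    # lid arginines on a loop above the walls (z ~17), guanidinium pointing
    # inward over the pocket mouth (CZ at ~5 Å from the axis)
    for resid_arg, theta in zip(ARG_RESIDS, (0.0, np.pi)):
        out = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = 11.0 * out + np.array([0, 0, 17.0])
        add("N", "ARG", resid_arg, ca + np.array([0.4, 1.3, 0.5]))
        add("CA", "ARG", resid_arg, ca)
        add("C", "ARG", resid_arg, ca + np.array([0.4, -1.4, 0.4]))
        add("O", "ARG", resid_arg, ca + np.array([0.4, -1.4, 1.6]))
        for name, dist in (("CB", 1.5), ("CG", 2.9), ("CD", 4.3), ("NE", 5.3), ("CZ", 6.0)):
            add(name, "ARG", resid_arg, ca - dist * out)
        cz = ca - 6.0 * out
        add("NH1", "ARG", resid_arg, cz - 1.2 * out + np.array([0, 0, 0.6]))
        add("NH2", "ARG", resid_arg, cz - 1.2 * out + np.array([0, 0, -0.6]))

    # mid-pocket tyrosine, hydroxyl pointing inward at z ~5
    ca = np.array([7.8, 0.0, 6.5])
    add("N", "TYR", TYR_RESID, ca + np.array([0.5, 1.3, 0.4]))
    add("CA", "TYR", TYR_RESID, ca)
    add("C", "TYR", TYR_RESID, ca + np.array([0.5, -1.4, 0.3]))
    add("O", "TYR", TYR_RESID, ca + np.array([0.5, -1.4, 1.5]))
    inward = np.array([-0.95, 0.0, -0.31])  # toward (4.0, 0, 5.2)
    for name, dist in (("CB", 1.5), ("CG", 2.2), ("CD1", 3.0), ("CD2", 3.2),
                       ("CE1", 3.8), ("CE2", 4.0)):
        off = np.array([0.0, 0.6 if name.endswith("1") else -0.6, 0.0]) if name.startswith(("CD", "CE")) else np.zeros(3)
        add(name, "TYR", TYR_RESID, ca + dist * inward + off)
    add("CZ", "TYR", TYR_RESID, ca + 4.6 * inward)
    add("OH", "TYR", TYR_RESID, np.array([4.0, 0.0, 5.2]))

    structure = Structure(atoms, title="toy pseudo-receptor")
    cg = structure.atoms[structure.atom_index(RECEPTOR_CHAIN, ASP_RESID, "CG")].coords
    nh1 = structure.atoms[structure.atom_index(RECEPTOR_CHAIN, ARG_RESIDS[0], "NH1")].coords
    manifest = FixtureManifest(
        generator="make_toy_receptor",
        seed=seed_rng,
        parameters={"radius": radius, "n_residues": len(structure.residues())},
        ground_truth={
            "asp_resid": ASP_RESID,
            "arg_resids": ARG_RESIDS,
            "tyr_resid": TYR_RESID,
            "asp_cg_to_arg_nh1": float(np.linalg.norm(cg - nh1)),
        },
    )
    return structure, manifest


# --------------------------------------------------------------------------
# SST-like peptide


def _hairpin_ca_trace() -> np.ndarray:
    """14 Cα positions: antiparallel strands (1–7, 10–14) joined by a cap so
    the apical turn sits at residues 7–10 and C3/C14 face each other."""
    step, sep = 3.8, 5.5
    pts = [np.array([i * step, 0.0, 0.0]) for i in range(7)]  # res 1..7
    b = 1.3
    center = np.array([6 * step + b, sep / 2, 0.0])
    R = float(np.hypot(b, sep / 2))
    a0 = np.arctan2(0.0 - center[1], 6 * step - center[0])
    a1 = np.arctan2(sep - center[1], 6 * step - center[0])
    sweep = a1 - a0  # passes through angle 0 (the +x bulge)
    for k in (1, 2):  # res 8, 9
        a = a0 + k * sweep / 3
        pts.append(center + np.array([R * np.cos(a), R * np.sin(a), 0.0]))
    for k in range(5):  # res 10..14
        pts.append(np.array([6 * step - k * step, sep, 0.0]))
    return np.array(pts)


def make_sst_peptide(cyclic: bool = True, seed_rng: int = 42) -> tuple[Structure, FixtureManifest]:
    """A coarse 14-residue somatostatin-like hairpin (chain L, resids 1–14).

    Backbone N/C atoms lie on the Cα trace segments (consecutive C–N exactly
    1.33 Å); side chains are single schematic conformers pointing away from
    the hairpin centroid.  With ``cyclic`` the C3/C14 SG atoms are placed
    facing each other at 2.05 Å (a disulfide *contact*; the schematic CB–SG
    bond lengths are not chemical).
    """
    ca = _hairpin_ca_trace()
    centroid = ca.mean(axis=0)
    atoms: list[Atom] = []
    serial = [0]

    def add(name, resname, resid, xyz):
        serial[0] += 1
        atoms.append(_atom(serial[0], name, resname, resid, LIGAND_CHAIN, xyz))

    n_pos: list[np.ndarray] = []
    c_pos: list[np.ndarray] = []
    for i in range(14):
        if i < 13:
            u = (ca[i + 1] - ca[i]) / np.linalg.norm(ca[i + 1] - ca[i])
        else:
            u = (ca[i] - ca[i - 1]) / np.linalg.norm(ca[i] - ca[i - 1])
        u_prev = u if i == 0 else (ca[i] - ca[i - 1]) / np.linalg.norm(ca[i] - ca[i - 1])
        # N sits off the Cα trace (0.3 Å out of plane) so the backbone frame
        # is never collinear; the 0.984/0.3 split keeps C(i-1)–N(i) at 1.33 Å
        n_pos.append(ca[i] - 0.984 * u_prev + np.array([0.0, 0.0, 0.3]))
        c_pos.append(ca[i] + 1.52 * u)

    sg_override: dict[int, np.ndarray] = {}
    if cyclic:
        # CBs of C3/C14 point at each other across the strand gap; SGs sit
        # symmetric about the midpoint at the disulfide contact distance
        cb3 = ca[2] + 1.53 * np.array([0.0, 1.0, 0.0])
        cb14 = ca[13] + 1.53 * np.array([0.0, -1.0, 0.0])
        mid = (cb3 + cb14) / 2
        u = (cb14 - cb3) / np.linalg.norm(cb14 - cb3)
        off = np.array([0.0, 0.0, -1.0])
        sg_override[3] = mid - 1.025 * u + 0.0 * off
        sg_override[14] = mid + 1.025 * u + 0.0 * off

    for i, letter in enumerate(SST_SEQUENCE):
        resid = i + 1
        resname = ONE_TO_THREE[letter]
        add("N", resname, resid, n_pos[i])
        add("CA", resname, resid, ca[i])
        add("C", resname, resid, c_pos[i])
        # carbonyl O perpendicular to the trace, out of plane
        add("O", resname, resid, c_pos[i] + np.array([0.0, 0.0, 1.23]))
        outward = ca[i] - centroid
        outward[2] = 0.0
        if np.linalg.norm(outward) < 1e-6:
            outward = np.array([1.0, 0.0, 0.0])
        if cyclic and resid in sg_override:
            cb = ca[i] + 1.53 * ((sg_override[resid] - ca[i]) / np.linalg.norm(sg_override[resid] - ca[i]))
            add("CB", resname, resid, cb)
            add("SG", resname, resid, sg_override[resid])
            continue
        for name, pos in sidechain_coords(resname, n_pos[i], ca[i], c_pos[i], axis=outward):
            add(name, resname, resid, pos)

    structure = Structure(atoms, title="coarse cyclic SST-14 model" if cyclic else "coarse SST-14 model")
    truth = {"n_residues": 14, "turn_start": 7, "sequence": SST_SEQUENCE}
    if cyclic:
        sg3 = structure.atoms[structure.atom_index(LIGAND_CHAIN, 3, "SG")].coords
        sg14 = structure.atoms[structure.atom_index(LIGAND_CHAIN, 14, "SG")].coords
        truth["ss_distance"] = float(np.linalg.norm(sg3 - sg14))
    manifest = FixtureManifest(
        generator="make_sst_peptide", seed=seed_rng,
        parameters={"cyclic": cyclic}, ground_truth=truth,
    )
    return structure, manifest


# --------------------------------------------------------------------------
# Posing and trajectories


def pose_ligand(ligand: Structure, receptor: Structure, dsb_target: float,
                spec: DsbSpec | None = None) -> Structure:
    """Rigidly pose the ligand so its d_SB anchor sits on the pocket axis.

    The ligand apex direction (Cα(K9) → NZ) is rotated onto −z and the anchor
    nitrogen translated to (0, 0, d_SB target above the receptor anchor).
    """
    spec = spec or DsbSpec()
    nz = ligand.atoms[ligand.atom_index(spec.ligand_chain, spec.ligand_resid, spec.ligand_atom)].coords
    ca = ligand.atoms[ligand.atom_index(spec.ligand_chain, spec.ligand_resid, "CA")].coords
    anchor = receptor.atoms[
        receptor.atom_index(spec.receptor_chain, spec.receptor_resid, spec.receptor_atom)
    ].coords
    u = (nz - ca) / np.linalg.norm(nz - ca)
    target_u = np.array([0.0, 0.0, -1.0])
    v = np.cross(u, target_u)
    s = np.linalg.norm(v)
    c = float(np.dot(u, target_u))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    xyz = ligand.coords
    xyz = (xyz - nz) @ R.T
    # orient the ligand's widest lateral direction along y, clear of the ±x lid
    lateral = xyz[:, :2] - xyz[:, :2].mean(axis=0)
    cov = lateral.T @ lateral
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    phi = np.pi / 2 - np.arctan2(major[1], major[0])
    Rz = np.array(
        [[np.cos(phi), -np.sin(phi), 0.0], [np.sin(phi), np.cos(phi), 0.0], [0.0, 0.0, 1.0]]
    )
    pivot = xyz[ligand.atom_index(spec.ligand_chain, spec.ligand_resid, spec.ligand_atom)].copy()
    xyz = (xyz - pivot) @ Rz.T + pivot
    xyz = xyz - xyz[ligand.atom_index(spec.ligand_chain, spec.ligand_resid, spec.ligand_atom)]
    xyz = xyz + anchor + np.array([0.0, 0.0, dsb_target])
    return ligand.with_coords(xyz)


def make_scenario_trajectory(
    spec: ScenarioSpec | None = None,
    receptor: Structure | None = None,
    ligand: Structure | None = None,
) -> tuple[Trajectory, FixtureManifest]:
    """Rigid-body trajectory whose d_SB follows the programmed segments.

    The ligand is translated along the pocket axis so that each frame's d_SB
    equals its segment mean plus Gaussian noise.
    """
    spec = spec or ScenarioSpec()
    if receptor is None:
        receptor, _ = make_toy_receptor(spec.seed)
    if ligand is None:
        ligand, _ = make_sst_peptide(cyclic=True, seed_rng=spec.seed)
    rng = np.random.default_rng(spec.seed)
    dsb_spec = DsbSpec()
    base = pose_ligand(ligand, receptor, dsb_target=10.0, spec=dsb_spec)

    topology = Structure(
        [a for a in receptor.atoms] + [a for a in base.atoms],
        title="scenario trajectory topology",
    )
    n_rec = len(receptor)
    base_xyz = topology.coords
    nz_row = n_rec + base.atom_index(dsb_spec.ligand_chain, dsb_spec.ligand_resid, dsb_spec.ligand_atom)
    anchor = receptor.atoms[
        receptor.atom_index(dsb_spec.receptor_chain, dsb_spec.receptor_resid, dsb_spec.receptor_atom)
    ].coords

    frames: list[np.ndarray] = []
    programmed: list[float] = []
    for seg in spec.segments:
        targets = seg.mean + rng.normal(0.0, seg.sigma, size=seg.n_frames)
        targets = np.clip(targets, 2.0, None)  # physical floor for noise excursions
        for t in targets:
            frame = base_xyz.copy()
            shift = anchor + np.array([0.0, 0.0, t]) - base_xyz[nz_row]
            frame[n_rec:] += shift
            frames.append(frame)
            programmed.append(float(t))

    times = spec.dt * np.arange(len(frames))
    traj = Trajectory(topology=topology, frames=frames, times=times)
    manifest = FixtureManifest(
        generator="make_scenario_trajectory",
        seed=spec.seed,
        parameters={
            "dt": spec.dt,
            "segments": [(s.label, s.mean, s.sigma, s.n_frames) for s in spec.segments],
        },
        ground_truth={
            "occupancies": spec.occupancies,
            "state_means": {s.label: s.mean for s in spec.segments},
            "n_frames": spec.n_frames,
        },
    )
    return traj, manifest


# --------------------------------------------------------------------------
# Intermediate-state fixture with bridging waters


def _bridge_water(p: np.ndarray, q: np.ndarray, d1: float, d2: float, azimuth: float) -> np.ndarray:
    """A point at distances (d1, d2) from (p, q), chosen by azimuth about p→q."""
    w = q - p
    L = float(np.linalg.norm(w))
    if L >= d1 + d2:
        raise ValueError(f"anchors too far apart for a bridge ({L:.2f} Å)")
    u = w / L
    a = (d1**2 - d2**2 + L**2) / (2 * L)
    r = float(np.sqrt(max(d1**2 - a**2, 0.0)))
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return p + a * u + r * (np.cos(azimuth) * e1 + np.sin(azimuth) * e2)


def make_intermediate_fixture(seed_rng: int = 42) -> tuple[Complex, FixtureManifest]:
    """The near-intermediate state (d_SB ≈ 5.5 Å) with its water network.

    Exactly three waters bridge the ligand K9 ammonium nitrogen to the
    receptor aspartate carboxylate / tyrosine hydroxyl (each water oxygen
    2.7–3.2 Å from both partners); two decoy waters are H-bonded to one side
    only and must not be reported as bridges.
    """
    receptor, _ = make_toy_receptor(seed_rng)
    ligand, _ = make_sst_peptide(cyclic=True, seed_rng=seed_rng)
    posed = pose_ligand(ligand, receptor, dsb_target=5.5)

    st = receptor.atoms
    idx = receptor.atom_index
    nz = posed.atoms[posed.atom_index(LIGAND_CHAIN, 9, "NZ")].coords
    od1 = st[idx(RECEPTOR_CHAIN, ASP_RESID, "OD1")].coords
    od2 = st[idx(RECEPTOR_CHAIN, ASP_RESID, "OD2")].coords
    oh = st[idx(RECEPTOR_CHAIN, TYR_RESID, "OH")].coords

    waters = [
        _bridge_water(nz, od1, 2.85, 2.85, azimuth=0.3),
        _bridge_water(nz, od2, 2.85, 2.85, azimuth=np.pi - 0.3),
        _bridge_water(nz, oh, 2.90, 2.90, azimuth=np.pi / 2),
    ]
    decoys = [
        nz + np.array([-2.0, 2.0, 0.5]),       # ligand-side only
        oh + np.array([0.0, 2.9, 0.0]),        # receptor-side only
    ]

    atoms = [a for a in receptor.atoms] + [a for a in posed.atoms]
    serial = max(a.serial for a in atoms)
    for k, w in enumerate(waters + decoys):
        serial += 1
        atoms.append(_atom(serial, "O", "HOH", 401 + k, WATER_CHAIN, w))
    structure = Structure(atoms, title="intermediate-state fixture")
    cplx = Complex(structure, receptor_chains={RECEPTOR_CHAIN}, ligand_chains={LIGAND_CHAIN})
    manifest = FixtureManifest(
        generator="make_intermediate_fixture",
        seed=seed_rng,
        parameters={"dsb": 5.5},
        ground_truth={
            "n_bridging_waters": 3,
            "n_decoy_waters": 2,
            "bridge_water_resids": [401, 402, 403],
            "ligand_sel": f"chain {LIGAND_CHAIN} and resid 9 and name NZ",
            "receptor_sel": f"chain {RECEPTOR_CHAIN} and (resid {ASP_RESID} or resid {TYR_RESID})",
        },
    )
    return cplx, manifest


# --------------------------------------------------------------------------
# Known-answer energy systems


def make_energy_fixture(kind: str = "unit_charges") -> ParameterizedComplex:
    """Parameterized known-answer complexes for the energetics oracles."""
    if kind == "unit_charges":
        atoms = [
            _atom(1, "Q1", "CHG", 1, "R", (0.0, 0.0, 0.0)),
            _atom(2, "Q2", "CHG", 1, "L", (1.0, 0.0, 0.0)),
        ]
        st = Structure(atoms, title="unit charges at 1 Å")
        params = ParamStructure(st, q=np.array([1.0, -1.0]), eps=np.zeros(2), rmin2=np.ones(2))
    elif kind == "lj_dimer":
        eps, rmin2 = 0.1, 1.9084
        atoms = [
            _atom(1, "C1", "LJD", 1, "R", (0.0, 0.0, 0.0)),
            _atom(2, "C2", "LJD", 1, "L", (2 * rmin2, 0.0, 0.0)),
        ]
        st = Structure(atoms, title="LJ dimer at Rmin")
        params = ParamStructure(st, q=np.zeros(2), eps=np.full(2, eps), rmin2=np.full(2, rmin2))
    elif kind == "two_residue":
        atoms = []
        # aspartate on the receptor side, carboxylate C at the origin
        for name, xyz in (
            ("N", (2.3, -1.0, -2.4)), ("CA", (1.4, -1.4, -1.8)), ("C", (2.0, -2.5, -1.2)),
            ("O", (2.0, -3.4, -2.0)), ("CB", (0.7, -0.7, -0.9)), ("CG", (0.0, 0.0, 0.0)),
            ("OD1", (0.95, 0.0, 0.7)), ("OD2", (-0.95, 0.0, 0.7)),
        ):
            atoms.append(_atom(len(atoms) + 1, name, "ASP", 126, "R", xyz))
        # lysine above, NZ 3.0 Å from the carboxylate carbon
        for name, xyz in (
            ("N", (0.9, 0.9, 11.2)), ("CA", (0.0, 0.0, 10.5)), ("C", (-0.9, 0.9, 11.2)),
            ("O", (-0.9, 1.9, 11.9)), ("CB", (0.0, 0.0, 9.0)), ("CG", (0.0, 0.0, 7.5)),
            ("CD", (0.0, 0.0, 6.0)), ("CE", (0.0, 0.0, 4.5)), ("NZ", (0.0, 0.0, 3.0)),
        ):
            atoms.append(_atom(len(atoms) + 1, name, "LYS", 9, "L", xyz))
        st = Structure(atoms, title="Lys/Asp salt-bridge pair")
        params = assign_parameters(st, ParamTable.default())
    else:
        raise ValueError(f"unknown energy fixture kind {kind!r}")
    cplx = Complex(st, receptor_chains={"R"}, ligand_chains={"L"})
    return ParameterizedComplex(complex=cplx, params=params)
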