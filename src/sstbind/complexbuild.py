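"""Complex construction and manipulation.

``grow_peptide`` extends a docked seed fragment into a full-length peptide by
greedy torsion-grid search over ideal backbone geometry — a transparent,
deliberately simple stand-in for homology-model-based ligand growing.  Each
appended residue is chosen from a coarse φ/ψ grid (broad Ramachandran boxes,
30° steps with per-model jitter) by minimizing clash count, then
intermolecular Coulomb+LJ energy plus quadratic restraint penalties
(disulfide closure, target d_SB).  Restraints that involve a not-yet-placed
partner act through a distance-to-go guidance term so the chain can steer
toward the partner before it exists.

``transplant_ligand`` moves a ligand between receptors by Kabsch
superposition of mapped Cα atoms; ``relax`` is a steepest-descent local
relaxation of the package's own intermolecular energy plus a soft clash
penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ._buildlib import (
    ANG_C_N_CA,
    ANG_CA_C_N,
    ANG_N_CA_C,
    BOND_C_N,
    BOND_CA_C,
    BOND_N_CA,
    OMEGA_TRANS,
    ONE_TO_THREE,
    THREE_TO_ONE,
    carbonyl_o,
    element_of,
    place_atom,
    sidechain_coords,
)
from .energetics import (
    COULOMB_K,
    DielectricModel,
    ParamTable,
    ParameterizedComplex,
    coulomb_inter,
    lj_inter,
)
from .geometry import DsbSpec, kabsch_superpose, apply_transform
from .structio import Atom, Complex, Structure

__all__ = [
    "GrowSpec",
    "BuildResult",
    "grow_peptide",
    "transplant_ligand",
    "detect_clashes",
    "relax",
    "RelaxResult",
]

CLASH_CUTOFF = 2.0  # Å, heavy-atom
SS_TARGET = 2.05    # Å, disulfide S–S
CA_STEP = 3.8       # Å per residue of chain "reach"


@dataclass
class GrowSpec:
    """Inputs for growing a full peptide from a placed seed fragment."""

    sequence: str
    seed_start: int
    seed_end: int
    disulfide_pairs: list[tuple[int, int]] = field(default_factory=list)
    dsb_spec: DsbSpec | None = None
    dsb_target: float | None = None       # Å; None = unrestrained
    torsion_step: float = 30.0            # degrees
    seed_frozen: bool = True
    restraint_weight: float = 50.0        # kcal/mol/Å²

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not (1 <= self.seed_start <= self.seed_end <= len(self.sequence)):
            raise ValueError(
                f"seed span {self.seed_start}-{self.seed_end} outside sequence of length {len(self.sequence)}"
            )
        for a, b in self.disulfide_pairs:
            for r in (a, b):
                if not (1 <= r <= len(self.sequence)) or self.sequence[r - 1] != "C":
                    raise ValueError(f"disulfide partner {r} is not a Cys in the sequence")


@dataclass
class BuildResult:
    complex: Complex
    clash_count: int
    e_inter: float
    scheme: str
    dsb: float | None
    ss_distances: dict[tuple[int, int], float]
    all_candidates_clashed: bool = False


# Ramachandran boxes: (phi_lo, phi_hi, psi_lo, psi_hi) in degrees
_GENERAL_BOXES = [(-160.0, -50.0, -60.0, -10.0), (-170.0, -60.0, 110.0, 175.0)]
_GLY_BOXES = _GENERAL_BOXES + [(50.0, 160.0, 10.0, 60.0)]
_PRO_BOXES = [(-75.0, -55.0, -40.0, -10.0), (-75.0, -55.0, 120.0, 160.0)]


def _boxes_for(resname: str):
    if resname == "GLY":
        return _GLY_BOXES
    if resname == "PRO":
        return _PRO_BOXES
    return _GENERAL_BOXES


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    return np.arange(lo, hi + 1e-9, step)


def _phi_candidates(resname: str, step: float) -> np.ndarray:
    return np.unique(np.concatenate([_grid(b[0], b[1], step) for b in _boxes_for(resname)]))


def _psi_candidates(resname: str, step: float) -> np.ndarray:
    return np.unique(np.concatenate([_grid(b[2], b[3], step) for b in _boxes_for(resname)]))


class _PartialChain:
    """Mutable ligand under construction: per-residue named heavy atoms."""

    def __init__(self, chain: str) -> None:
        self.chain = chain
        self.residues: dict[int, dict[str, np.ndarray]] = {}
        self.resnames: dict[int, str] = {}

    def add(self, resid: int, resname: str, atoms: dict[str, np.ndarray]) -> None:
        self.residues.setdefault(resid, {}).update(atoms)
        self.resnames[resid] = resname

    def coords_except(self, skip_resids: set[int]) -> np.ndarray:
        rows = [
            xyz
            for resid, atoms in self.residues.items()
            if resid not in skip_resids
            for xyz in atoms.values()
        ]
        return np.array(rows) if rows else np.empty((0, 3))

    def get(self, resid: int, name: str) -> np.ndarray | None:
        return self.residues.get(resid, {}).get(name)


def _residue_charges_lj(resname: str, names: Sequence[str], table: ParamTable):
    q = np.zeros(len(names))
    eps = np.zeros(len(names))
    rmin2 = np.ones(len(names))
    for k, n in enumerate(names):
        entry = table.entries.get((resname, n))
        if entry is not None:
            q[k], eps[k], rmin2[k] = entry
    return q, eps, rmin2


def _pair_energy(xyz_a, q_a, eps_a, rmin2_a, xyz_b, q_b, eps_b, rmin2_b, dielectric: DielectricModel) -> float:
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return 0.0
    r = cdist(xyz_a, xyz_b)
    r = np.maximum(r, 0.5)  # guard: clash term handles overlaps
    ec = COULOMB_K * np.outer(q_a, q_b) / (dielectric.epsilon(r) * r)
    eps_ij = np.sqrt(np.outer(eps_a, eps_b))
    rmin_ij = np.add.outer(rmin2_a, rmin2_b)
    x6 = (rmin_ij / r) ** 6
    return float((ec + eps_ij * (x6 * x6 - 2 * x6)).sum())


def grow_peptide(
    receptor: Structure,
    seed: Structure,
    spec: GrowSpec,
    n_models: int = 10,
    seed_rng: int = 42,
    table: ParamTable | None = None,
    dielectric: DielectricModel | None = None,
    receptor_chains: frozenset | None = None,
) -> list[BuildResult]:
    """Grow the full sequence N- and C-ward from the seed; returns one
    BuildResult per model (distinct RNG streams, deterministic per seed)."""
    table = table or ParamTable.default()
    dielectric = dielectric or DielectricModel()
    receptor_chains = frozenset(receptor_chains or {a.chain for a in receptor.atoms})

    seed_res = seed.residues()
    seed_resids = [r for (_c, r, _n) in seed_res]
    expected = list(range(spec.seed_start, spec.seed_end + 1))
    if seed_resids != expected:
        raise ValueError(f"seed resids {seed_resids} do not match the seed span {expected}")
    for (_c, resid, resname) in seed_res:
        want = ONE_TO_THREE[spec.sequence[resid - 1]]
        if resname != want:
            raise ValueError(f"seed residue {resid} is {resname}, sequence says {want}")
    lig_chain = seed.atoms[0].chain
    if lig_chain in receptor_chains:
        raise ValueError("seed chain id collides with a receptor chain")

    rec_xyz = np.array([a.coords for a in receptor.atoms if a.is_heavy])
    rec_names = [(a.resname, a.name) for a in receptor.atoms if a.is_heavy]
    rec_q = np.zeros(len(rec_names))
    rec_eps = np.zeros(len(rec_names))
    rec_rmin2 = np.ones(len(rec_names))
    for k, key in enumerate(rec_names):
        entry = table.entries.get(key)
        if entry is not None:
            rec_q[k], rec_eps[k], rec_rmin2[k] = entry

    results: list[BuildResult] = []
    for model in range(n_models):
        rng = np.random.default_rng([int(seed_rng), model])
        chain = _PartialChain(lig_chain)
        for (_c, resid, resname) in seed_res:
            atoms = {
                a.name: a.coords.copy()
                for a in seed.atoms
                if a.resid == resid
            }
            chain.add(resid, resname, atoms)

        flagged = False
        # grow N-ward first, then C-ward: restraint partners placed early can
        # then steer the later-grown arm (e.g. a C-terminal disulfide Cys)
        for resid in list(range(spec.seed_start - 1, 0, -1)):
            ok = _append_residue(chain, resid, "N", spec, table, dielectric,
                                 rec_xyz, rec_q, rec_eps, rec_rmin2, receptor, rng)
            flagged = flagged or not ok
            if resid not in chain.residues:
                break  # geometry failure: arm cannot be extended further
        for resid in list(range(spec.seed_end + 1, len(spec.sequence) + 1)):
            ok = _append_residue(chain, resid, "C", spec, table, dielectric,
                                 rec_xyz, rec_q, rec_eps, rec_rmin2, receptor, rng)
            flagged = flagged or not ok
            if resid not in chain.residues:
                break

        ligand = _chain_to_structure(chain)
        combined = Structure(
            [a for a in receptor.atoms] + [a for a in ligand.atoms],
            title=f"grown model {model}",
        )
        cplx = Complex(combined, receptor_chains=receptor_chains, ligand_chains={lig_chain})
        pcx = ParameterizedComplex(
            complex=cplx,
            params=_permissive_params(combined, table),
        )
        e_inter = coulomb_inter(pcx, dielectric) + lj_inter(pcx)
        clashes = len(detect_clashes(cplx))
        dsb_val = None
        if spec.dsb_spec is not None:
            try:
                from .geometry import dsb as _dsb

                dsb_val = _dsb(cplx, spec.dsb_spec)
            except Exception:
                dsb_val = None
        ss = {}
        for a, b in spec.disulfide_pairs:
            sa, sb = chain.get(a, "SG"), chain.get(b, "SG")
            ss[(a, b)] = float(np.linalg.norm(sa - sb)) if sa is not None and sb is not None else float("nan")
        results.append(
            BuildResult(
                complex=cplx,
                clash_count=clashes,
                e_inter=e_inter,
                scheme="coulomb+lj",
                dsb=dsb_val,
                ss_distances=ss,
                all_candidates_clashed=flagged,
            )
        )
    return results


def _permissive_params(structure: Structure, table: ParamTable):
    from .energetics import assign_parameters

    return assign_parameters(structure, table, permissive=True)


def _chain_to_structure(chain: _PartialChain) -> Structure:
    atoms: list[Atom] = []
    serial = 0
    for resid in sorted(chain.residues):
        resname = chain.resnames[resid]
        named = chain.residues[resid]
        order = ["N", "CA", "C", "O"] + [n for n in named if n not in ("N", "CA", "C", "O")]
        for name in order:
            if name not in named:
                continue
            serial += 1
            atoms.append(
                Atom(serial, name, element_of(name), resname, resid, chain.chain, named[name])
            )
    return Structure(atoms)


def _restraint_penalty(chain: _PartialChain, resid: int, new_atoms: dict[str, np.ndarray],
                       spec: GrowSpec, receptor: Structure) -> float:
    """Quadratic disulfide / d_SB penalties with distance-to-go guidance."""
    w = spec.restraint_weight
    pen = 0.0
    for a, b in spec.disulfide_pairs:
        if resid not in (a, b):
            partner_done = None
            target_res = None
            if a in chain.residues and b not in chain.residues:
                partner_done, target_res = a, b
            elif b in chain.residues and a not in chain.residues:
                partner_done, target_res = b, a
            if partner_done is None:
                continue
            sg = chain.get(partner_done, "SG")
            ca = new_atoms.get("CA")
            if sg is None or ca is None:
                continue
            reach = CA_STEP * abs(target_res - resid) + 2.0  # remaining chain + side chain
            d = float(np.linalg.norm(ca - sg))
            pen += w * max(0.0, d - reach) ** 2
        else:
            other = b if resid == a else a
            sg_other = chain.get(other, "SG")
            sg_new = new_atoms.get("SG")
            if sg_other is not None and sg_new is not None:
                d = float(np.linalg.norm(sg_new - sg_other))
                pen += w * (d - SS_TARGET) ** 2
    if spec.dsb_target is not None and spec.dsb_spec is not None:
        ds = spec.dsb_spec
        try:
            anchor = receptor.atoms[
                receptor.atom_index(ds.receptor_chain, ds.receptor_resid, ds.receptor_atom)
            ].coords
        except KeyError:
            anchor = None
        if anchor is not None:
            if resid == ds.ligand_resid and ds.ligand_atom in new_atoms:
                d = float(np.linalg.norm(new_atoms[ds.ligand_atom] - anchor))
                pen += w * (d - spec.dsb_target) ** 2
            elif ds.ligand_resid not in chain.residues and "CA" in new_atoms:
                # require steady descent: ~3.4 Å of progress per remaining
                # residue plus the lysine side-chain reach
                reach = 3.4 * abs(ds.ligand_resid - resid) + 6.0
                d = float(np.linalg.norm(new_atoms["CA"] - anchor))
                pen += w * max(0.0, d - reach - spec.dsb_target) ** 2
    return pen


def _append_residue(chain: _PartialChain, resid: int, direction: str, spec: GrowSpec,
                    table: ParamTable, dielectric: DielectricModel,
                    rec_xyz, rec_q, rec_eps, rec_rmin2,
                    receptor: Structure, rng: np.random.Generator) -> bool:
    """Greedy placement of one residue; returns False when every candidate clashed."""
    resname = ONE_TO_THREE[spec.sequence[resid - 1]]
    anchor_resid = resid - 1 if direction == "C" else resid + 1
    anchor = chain.residues[anchor_resid]
    anchor_resname = chain.resnames[anchor_resid]

    if direction == "C":
        tor_a = _psi_candidates(anchor_resname, spec.torsion_step)
        tor_b = _phi_candidates(resname, spec.torsion_step)
    else:
        tor_a = _phi_candidates(anchor_resname, spec.torsion_step)
        tor_b = _psi_candidates(resname, spec.torsion_step)

    jitter = spec.torsion_step / 2
    context = chain.coords_except({anchor_resid})
    best = None
    for ta in tor_a:
        for tb in tor_b:
            t1 = float(ta + rng.uniform(-jitter, jitter))
            t2 = float(tb + rng.uniform(-jitter, jitter))
            new_atoms = _build_backbone(anchor, t1, t2, direction, resname)
            if new_atoms is None:
                continue
            # restrained side chains point at their target: a disulfide Cys at
            # the partner SG, the d_SB lysine at the receptor anchor atom
            sc_axis = None
            if resname == "CYS":
                for pa, pb in spec.disulfide_pairs:
                    if resid in (pa, pb):
                        sg = chain.get(pb if resid == pa else pa, "SG")
                        if sg is not None:
                            sc_axis = sg - new_atoms["CA"]
            if (
                spec.dsb_target is not None
                and spec.dsb_spec is not None
                and resid == spec.dsb_spec.ligand_resid
            ):
                ds = spec.dsb_spec
                try:
                    anchor_xyz = receptor.atoms[
                        receptor.atom_index(ds.receptor_chain, ds.receptor_resid, ds.receptor_atom)
                    ].coords
                    sc_axis = anchor_xyz - new_atoms["CA"]
                except KeyError:
                    pass
            sc = sidechain_coords(resname, new_atoms["N"], new_atoms["CA"], new_atoms["C"], axis=sc_axis)
            new_atoms.update({n: p for n, p in sc})
            xyz_new = np.array(list(new_atoms.values()))
            # clash count vs receptor and non-adjacent ligand context
            n_clash = 0
            if len(rec_xyz):
                n_clash += int((cdist(xyz_new, rec_xyz) < CLASH_CUTOFF).sum())
            if len(context):
                n_clash += int((cdist(xyz_new, context) < CLASH_CUTOFF).sum())
            names = list(new_atoms)
            q, eps, rmin2 = _residue_charges_lj(resname, names, table)
            e = _pair_energy(xyz_new, q, eps, rmin2, rec_xyz, rec_q, rec_eps, rec_rmin2, dielectric)
            e += _restraint_penalty(chain, resid, new_atoms, spec, receptor)
            key = (n_clash, e)
            if best is None or key < best[0]:
                best = (key, new_atoms)
    if best is None:
        return False
    (_n_clash, _e), new_atoms = best
    chain.add(resid, resname, new_atoms)
    # carbonyl O of the junction residue on the C-ward side
    if direction == "C":
        prev = chain.residues[anchor_resid]
        if "O" not in prev or not spec.seed_frozen or anchor_resid < spec.seed_start or anchor_resid > spec.seed_end:
            if all(k in prev for k in ("CA", "C")):
                prev["O"] = carbonyl_o(prev["CA"], prev["C"], new_atoms["N"])
    return _n_clash == 0


def _build_backbone(anchor: dict[str, np.ndarray], t1: float, t2: float,
                    direction: str, resname: str) -> dict[str, np.ndarray] | None:
    """Backbone of the appended residue from two torsions (ψ_prev/φ_new C-ward,
    φ_next/ψ_new N-ward); ω is trans."""
    try:
        if direction == "C":
            n_prev, ca_prev, c_prev = anchor["N"], anchor["CA"], anchor["C"]
            n_new = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANG_CA_C_N, t1)      # ψ_prev
            ca_new = place_atom(ca_prev, c_prev, n_new, BOND_N_CA, ANG_C_N_CA, OMEGA_TRANS)
            c_new = place_atom(c_prev, n_new, ca_new, BOND_CA_C, ANG_N_CA_C, t2)       # φ_new
            o_new = place_atom(n_new, ca_new, c_new, 1.231, 120.5, 180.0)              # provisional
            return {"N": n_new, "CA": ca_new, "C": c_new, "O": o_new}
        else:
            c_nxt, ca_nxt, n_nxt = anchor["C"], anchor["CA"], anchor["N"]
            c_new = place_atom(c_nxt, ca_nxt, n_nxt, BOND_C_N, ANG_C_N_CA, t1)         # φ_next
            ca_new = place_atom(ca_nxt, n_nxt, c_new, BOND_CA_C, ANG_CA_C_N, OMEGA_TRANS)
            n_new = place_atom(n_nxt, c_new, ca_new, BOND_N_CA, ANG_N_CA_C, t2)        # ψ_new
            o_new = carbonyl_o(ca_new, c_new, n_nxt)
            return {"N": n_new, "CA": ca_new, "C": c_new, "O": o_new}
    except (ValueError, KeyError):
        return None


# --------------------------------------------------------------------------


def transplant_ligand(source: Complex, target_receptor: Structure,
                      mapping: Sequence[tuple]) -> Complex:
    """Move the source ligand onto a new receptor by Cα superposition.

    ``mapping`` pairs source-receptor residues with target residues, either as
    (resid, resid) or ((chain, resid), (chain, resid)); at least 3 pairs.  The
    Kabsch transform fitting source Cα onto target Cα is applied rigidly to
    the source ligand, preserving its internal geometry exactly.
    """
    if len(mapping) < 3:
        raise ValueError("mapping must contain at least 3 residue pairs")
    src = source.structure
    src_chain = next(iter(source.receptor_chains))
    tgt_chain = target_receptor.atoms[0].chain

    def resolve(st: Structure, default_chain: str, ref) -> np.ndarray:
        chain, resid = ref if isinstance(ref, tuple) else (default_chain, ref)
        try:
            return st.atoms[st.atom_index(chain, resid, "CA")].coords
        except KeyError:
            raise KeyError(f"mapping atom CA of ({chain}, {resid}) not found") from None

    mob = np.array([resolve(src, src_chain, a) for a, _b in mapping])
    ref = np.array([resolve(target_receptor, tgt_chain, b) for _a, b in mapping])
    R, t, _rmsd = kabsch_superpose(mob, ref)

    tgt_chains = {a.chain for a in target_receptor.atoms}
    lig_chains = set(source.ligand_chains)
    remap: dict[str, str] = {}
    pool = iter("LMNOPQZYXWV")
    for ch in sorted(lig_chains):
        if ch in tgt_chains:
            new = next(c for c in pool if c not in tgt_chains and c not in lig_chains)
            remap[ch] = new
    atoms = [a for a in target_receptor.atoms]
    serial = max((a.serial for a in atoms), default=0)
    for a in src.atoms:
        if a.chain not in source.ligand_chains or a.resname in source.water_resnames:
            continue
        serial += 1
        atoms.append(
            Atom(serial, a.name, a.element, a.resname, a.resid,
                 remap.get(a.chain, a.chain), apply_transform(a.coords, R, t),
                 a.occupancy, a.bfactor)
        )
    new_lig = {remap.get(c, c) for c in source.ligand_chains}
    return Complex(Structure(atoms), receptor_chains=frozenset(tgt_chains), ligand_chains=frozenset(new_lig))


def detect_clashes(cplx: Complex, cutoff: float = CLASH_CUTOFF) -> list[tuple]:
    """Intermolecular heavy-atom pairs closer than ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    rec = cplx.receptor_indices(heavy_only=True)
    lig = cplx.ligand_indices(heavy_only=True)
    if not rec or not lig:
        return []
    xyz = cplx.structure.coords
    d = cdist(xyz[rec], xyz[lig])
    out = []
    for i, j in zip(*np.where(d < cutoff)):
        ar = cplx.structure.atoms[rec[i]]
        al = cplx.structure.atoms[lig[j]]
        out.append((ar.key(), al.key(), float(d[i, j])))
    return sorted(out, key=lambda t: t[2])


# --------------------------------------------------------------------------
# Local relaxation


@dataclass
class RelaxResult:
    complex: ParameterizedComplex
    trace: list[float]
    converged: bool
    n_steps: int


def _relax_energy_grad(xyz, rec, lig, q, eps, rmin2, dielectric, soft_w=10.0, soft_cut=CLASH_CUTOFF):
    """Intermolecular Coulomb + LJ + soft-clash energy and per-atom gradient."""
    e_total = 0.0
    grad = np.zeros_like(xyz)
    ri = xyz[rec]
    rj = xyz[lig]
    diff = ri[:, None, :] - rj[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    r = np.maximum(r, 1e-6)
    qq = np.outer(q[rec], q[lig])
    if dielectric.kind == "constant":
        ec = COULOMB_K * qq / (dielectric.D * r)
        dec = -ec / r
    elif dielectric.kind == "linear":
        ec = COULOMB_K * qq / (dielectric.D * r * r)
        dec = -2.0 * ec / r
    else:  # numeric derivative for the sigmoidal model
        ec = COULOMB_K * qq / (dielectric.epsilon(r) * r)
        h = 1e-5
        ec2 = COULOMB_K * qq / (dielectric.epsilon(r + h) * (r + h))
        dec = (ec2 - ec) / h
    eps_ij = np.sqrt(np.outer(eps[rec], eps[lig]))
    rmin_ij = np.add.outer(rmin2[rec], rmin2[lig])
    x6 = (rmin_ij / r) ** 6
    el = eps_ij * (x6 * x6 - 2 * x6)
    del_ = 12.0 * eps_ij * (x6 - x6 * x6) / r
    soft = np.where(r < soft_cut, soft_w * (soft_cut - r) ** 2, 0.0)
    dsoft = np.where(r < soft_cut, -2.0 * soft_w * (soft_cut - r), 0.0)
    e_total = float((ec + el + soft).sum())
    dU = dec + del_ + dsoft
    unit = diff / r[:, :, None]
    f = dU[:, :, None] * unit
    np.add.at(grad, rec, f.sum(axis=1))
    np.add.at(grad, lig, -f.sum(axis=0))
    return e_total, grad


def relax(
    pc: ParameterizedComplex,
    mobile: Sequence[int],
    max_steps: int = 200,
    step: float = 0.05,
    dielectric: DielectricModel | None = None,
    gtol: float = 1e-4,
) -> RelaxResult:
    """Steepest-descent relaxation of mobile atoms on the intermolecular
    Coulomb + LJ + soft-clash energy; the accepted-energy trace never rises.
    """
    if len(mobile) == 0:
        raise ValueError("mobile selection is empty")
    dielectric = dielectric or DielectricModel()
    mobile = np.asarray(sorted(mobile), dtype=int)
    rec = np.asarray(pc.complex.receptor_indices(), dtype=int)
    lig = np.asarray(pc.complex.ligand_indices(), dtype=int)
    q, eps, rmin2 = pc.params.q, pc.params.eps, pc.params.rmin2

    xyz = pc.structure.coords
    e, g = _relax_energy_grad(xyz, rec, lig, q, eps, rmin2, dielectric)
    trace = [e]
    converged = False
    n_done = 0
    alpha = step
    for _ in range(max_steps):
        gm = np.zeros_like(xyz)
        gm[mobile] = g[mobile]
        gnorm = float(np.linalg.norm(gm[mobile]))
        if gnorm < gtol:
            converged = True
            break
        direction = -gm / gnorm
        accepted = False
        a = alpha
        for _bt in range(30):
            trial = xyz + a * direction
            e_t, g_t = _relax_energy_grad(trial, rec, lig, q, eps, rmin2, dielectric)
            if e_t < e:
                xyz, e, g = trial, e_t, g_t
                trace.append(e)
                alpha = min(a * 1.2, 1.0)
                accepted = True
                break
            a *= 0.5
        n_done += 1
        if not accepted:
            break  # no downhill direction at any step size: stop, flagged via converged
    new_structure = pc.structure.with_coords(xyz)
    new_cplx = Complex(
        new_structure, pc.complex.receptor_chains, pc.complex.ligand_chains, pc.complex.water_resnames
    )
    from .energetics import ParamStructure

    new_pc = ParameterizedComplex(
        complex=new_cplx,
        params=ParamStructure(new_structure, q.copy(), eps.copy(), rmin2.copy(),
                              list(pc.params.unparameterized)),
    )
    return RelaxResult(complex=new_pc, trace=trace, converged=converged, n_steps=n_done)
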