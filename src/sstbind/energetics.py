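"""Intermolecular nonbonded energetics: Coulomb with a distance-dependent
dielectric, Lennard-Jones 12-6, per-residue decomposition, and model ranking.

Energies are in kcal/mol, distances in Å, charges in elementary charges.
Only receptor↔ligand pairs contribute (the intermolecular interaction energy
``E_inter``); intramolecular terms and waters are excluded throughout.

The Coulomb constant ``k = 332.0636 kcal·Å·mol⁻¹·e⁻²`` is the conversion of
``N_A·e²/(4πϵ0)`` into kcal·Å/mol.  The default dielectric is the linear
screening model ``ε(r) = 4r``, a common implicit-solvent choice; a constant
model and the Mehler–Solmajer sigmoidal form are selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structio import Complex, Structure

__all__ = [
    "COULOMB_K",
    "ParamTable",
    "ParamStructure",
    "DielectricModel",
    "ResidueEnergyProfile",
    "assign_parameters",
    "parameterize_complex",
    "coulomb_inter",
    "lj_inter",
    "per_residue_decomposition",
    "rank_models",
    "ClashError",
    "ParameterizationError",
]

COULOMB_K = 332.0636  # kcal·Å·mol⁻¹·e⁻²

R_MIN_CLASH = 0.1  # Å; closer pairs are treated as input errors


class ClashError(ValueError):
    """Raised when two interacting atoms (nearly) overlap."""


class ParameterizationError(KeyError):
    """Raised in strict mode when atoms cannot be matched in the table."""


class ParamTable:
    """Per-atom charges and LJ parameters keyed by ``(resname, atomname)``."""

    def __init__(self, entries: dict, combining: str = "lorentz-berthelot") -> None:
        self.entries = dict(entries)
        self.combining = combining
        for key, (q, eps, rmin2) in self.entries.items():
            if eps < 0:
                raise ValueError(f"{key}: epsilon must be >= 0")
            if rmin2 <= 0:
                raise ValueError(f"{key}: rmin_half must be > 0")

    @classmethod
    def from_file(cls, path) -> "ParamTable":
        entries = {}
        combining = "lorentz-berthelot"
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                if "combining:" in line:
                    combining = line.split("combining:")[1].strip()
                continue
            resname, atomname, q, eps, rmin2 = line.split()
            entries[(resname, atomname)] = (float(q), float(eps), float(rmin2))
        return cls(entries, combining)

    @classmethod
    def default(cls) -> "ParamTable":
        with resources.as_file(resources.files("sstbind.data") / "params_amber_heavy.dat") as p:
            return cls.from_file(p)

    def residue_charge(self, resname: str) -> float:
        return sum(q for (rn, _), (q, _, _) in self.entries.items() if rn == resname)

    def __contains__(self, key) -> bool:
        return key in self.entries


@dataclass
class ParamStructure:
    """A structure with congruent per-atom charge/LJ vectors bound on."""

    structure: Structure
    q: np.ndarray
    eps: np.ndarray
    rmin2: np.ndarray
    unparameterized: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.structure)
        for name in ("q", "eps", "rmin2"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (n,):
                raise ValueError(f"{name} vector length {v.shape} does not match atom count {n}")
            setattr(self, name, v)


@dataclass
class DielectricModel:
    """ε(r) model for Coulomb screening.

    constant: ε(r) = D;  linear: ε(r) = D·r;
    sigmoidal: the Mehler–Solmajer form saturating at D for large r.
    """

    kind: Literal["constant", "linear", "sigmoidal"] = "linear"
    D: float = 4.0

    # Mehler–Solmajer constants
    _MS_A = -8.5525
    _MS_K = 7.7839
    _MS_LAMBDA = 0.003627

    def epsilon(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self.kind == "constant":
            return np.full_like(r, float(self.D))
        if self.kind == "linear":
            return self.D * r
        if self.kind == "sigmoidal":
            B = self.D - self._MS_A
            return self._MS_A + B / (1.0 + self._MS_K * np.exp(-self._MS_LAMBDA * B * r))
        raise ValueError(f"unknown dielectric kind {self.kind!r}")


@dataclass
class ParameterizedComplex:
    """A Complex plus its bound parameter vectors."""

    complex: Complex
    params: ParamStructure

    @property
    def structure(self) -> Structure:
        return self.complex.structure


class ResidueEnergyProfile:
    """Per-residue Coulomb/LJ contributions to the intermolecular energy.

    ``side`` names the molecule whose residues index the rows; both sides of a
    decomposition sum to the same global total.
    """

    COLUMNS = ["chain", "resid", "resname", "e_coulomb", "e_lj", "e_total"]

    def __init__(self, side: str, table: pd.DataFrame) -> None:
        if side not in ("receptor", "ligand"):
            raise ValueError("side must be 'receptor' or 'ligand'")
        self.side = side
        self.table = table.reset_index(drop=True)

    @property
    def total_coulomb(self) -> float:
        return float(self.table["e_coulomb"].sum())

    @property
    def total_lj(self) -> float:
        return float(self.table["e_lj"].sum())

    @property
    def total(self) -> float:
        return float(self.table["e_total"].sum())

    def energy_by_resid(self, column: str = "e_total") -> dict[int, float]:
        return dict(zip(self.table["resid"].astype(int), self.table[column].astype(float)))

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "side", self.side)
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "ResidueEnergyProfile":
        df = pd.read_csv(path, sep="\t")
        side = str(df["side"].iloc[0])
        return cls(side, df[cls.COLUMNS])

    def __len__(self) -> int:
        return len(self.table)


# --------------------------------------------------------------------------


def assign_parameters(structure: Structure, table: ParamTable, permissive: bool = False) -> ParamStructure:
    """Bind charges and LJ parameters onto every atom by (resname, atomname).

    Strict mode raises listing every unmatched pair; permissive mode assigns
    q=0, ε=0 and records the atom index in ``unparameterized``.
    """
    n = len(structure)
    q = np.zeros(n)
    eps = np.zeros(n)
    rmin2 = np.ones(n)
    missing: list[int] = []
    missing_keys: list[tuple[str, str]] = []
    for i, a in enumerate(structure.atoms):
        key = (a.resname, a.name)
        if key in table.entries:
            q[i], eps[i], rmin2[i] = table.entries[key]
        else:
            missing.append(i)
            if key not in missing_keys:
                missing_keys.append(key)
    if missing and not permissive:
        raise ParameterizationError(f"unparameterized atoms: {missing_keys}")
    return ParamStructure(structure=structure, q=q, eps=eps, rmin2=rmin2, unparameterized=missing)


def parameterize_complex(cplx: Complex, table: ParamTable | None = None, permissive: bool = False) -> ParameterizedComplex:
    table = table if table is not None else ParamTable.default()
    return ParameterizedComplex(complex=cplx, params=assign_parameters(cplx.structure, table, permissive))


def _pair_arrays(pc: ParameterizedComplex):
    """Receptor/ligand index lists, the pair distance matrix, and a clash check."""
    rec = pc.complex.receptor_indices()
    lig = pc.complex.ligand_indices()
    xyz = pc.structure.coords
    r = cdist(xyz[rec], xyz[lig])
    if r.size and r.min() < R_MIN_CLASH:
        i, j = np.unravel_index(np.argmin(r), r.shape)
        ar = pc.structure.atoms[rec[i]]
        al = pc.structure.atoms[lig[j]]
        raise ClashError(
            f"overlapping atoms ({ar.chain}/{ar.resid}/{ar.name}) and "
            f"({al.chain}/{al.resid}/{al.name}) at r={r[i, j]:.4f} Å"
        )
    return rec, lig, r


def _coulomb_pairs(pc: ParameterizedComplex, dielectric: DielectricModel, rec, lig, r) -> np.ndarray:
    qq = np.outer(pc.params.q[rec], pc.params.q[lig])
    return COULOMB_K * qq / (dielectric.epsilon(r) * r)


def _lj_pairs(pc: ParameterizedComplex, rec, lig, r) -> np.ndarray:
    eps_ij = np.sqrt(np.outer(pc.params.eps[rec], pc.params.eps[lig]))
    rmin_ij = np.add.outer(pc.params.rmin2[rec], pc.params.rmin2[lig])
    with np.errstate(divide="ignore"):
        x6 = (rmin_ij / r) ** 6
    return eps_ij * (x6 * x6 - 2.0 * x6)


def coulomb_inter(pc: ParameterizedComplex, dielectric: DielectricModel | None = None, cutoff: float | None = None) -> float:
    """Intermolecular Coulomb energy (kcal/mol); no distance cutoff by default."""
    dielectric = dielectric or DielectricModel()
    rec, lig, r = _pair_arrays(pc)
    e = _coulomb_pairs(pc, dielectric, rec, lig, r)
    if cutoff is not None:
        e = np.where(r <= cutoff, e, 0.0)
    return float(e.sum())


def lj_inter(pc: ParameterizedComplex, cutoff: float | None = None) -> float:
    """Intermolecular Lennard-Jones 12-6 energy (kcal/mol)."""
    rec, lig, r = _pair_arrays(pc)
    e = _lj_pairs(pc, rec, lig, r)
    if cutoff is not None:
        e = np.where(r <= cutoff, e, 0.0)
    return float(e.sum())


def per_residue_decomposition(
    pc: ParameterizedComplex, dielectric: DielectricModel | None = None
) -> tuple[ResidueEnergyProfile, ResidueEnergyProfile]:
    """Group pair energies by receptor residue and by ligand residue.

    Returns (receptor-side, ligand-side) profiles; each side's rows sum to the
    same global Coulomb+LJ total.
    """
    dielectric = dielectric or DielectricModel()
    rec, lig, r = _pair_arrays(pc)
    ec = _coulomb_pairs(pc, dielectric, rec, lig, r)
    el = _lj_pairs(pc, rec, lig, r)

    profiles = []
    for side, idx, axis in (("receptor", rec, 1), ("ligand", lig, 0)):
        rows: dict[tuple[str, int], list] = {}
        ec_side = ec.sum(axis=axis)
        el_side = el.sum(axis=axis)
        order: list[tuple[str, int]] = []
        for k, i in enumerate(idx):
            a = pc.structure.atoms[i]
            key = (a.chain, a.resid)
            if key not in rows:
                rows[key] = [a.chain, a.resid, a.resname, 0.0, 0.0]
                order.append(key)
            rows[key][3] += float(ec_side[k])
            rows[key][4] += float(el_side[k])
        df = pd.DataFrame(
            [rows[k] for k in order], columns=["chain", "resid", "resname", "e_coulomb", "e_lj"]
        )
        df["e_total"] = df["e_coulomb"] + df["e_lj"]
        profiles.append(ResidueEnergyProfile(side, df))
    return profiles[0], profiles[1]


def rank_models(
    complexes: Sequence[ParameterizedComplex],
    scheme: Literal["lj", "coulomb", "sum"] = "lj",
    dielectric: DielectricModel | None = None,
) -> list[tuple[int, float]]:
    """Order candidate complexes ascending by energy (lowest = best).

    Ties keep input order.  Returns (input index, score) pairs.
    """
    if not complexes:
        raise ValueError("rank_models requires at least one complex")
    dielectric = dielectric or DielectricModel()
    scores = []
    for pc in complexes:
        if scheme == "lj":
            s = lj_inter(pc)
        elif scheme == "coulomb":
            s = coulomb_inter(pc, dielectric)
        elif scheme == "sum":
            s = lj_inter(pc) + coulomb_inter(pc, dielectric)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        scores.append(s)
    order = sorted(range(len(scores)), key=lambda i: (scores[i], i))
    return [(i, scores[i]) for i in order]
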