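"""Receptor-subtype comparison: global sequence alignment plus juxtaposition
of per-residue interaction-energy profiles.

The aligner is a Needleman–Wunsch / Gotoh affine-gap dynamic program with the
EMBOSS Needle defaults (BLOSUM62, gap open 10, gap extend 0.5, end gaps not
penalized): a gap of length L costs ``open + extend·(L−1)`` unless it touches
a sequence end.  Ties prefer match/mismatch columns over gaps, then a gap in
the first sequence.

Energy mapping is offset-aware because structure residue numbering routinely
drifts from sequence numbering (model vs UniProt numbering); offsets are
explicit inputs, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .energetics import ResidueEnergyProfile
from .structio import AMINO_ALPHABET

__all__ = [
    "Alignment",
    "EnergyComparisonTable",
    "needleman_wunsch",
    "percent_identity",
    "map_energies",
    "shared_key_residues",
]

NEG_INF = float("-inf")


def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


@dataclass
class Alignment:
    """A global pairwise alignment with per-column source positions."""

    aligned_a: str
    aligned_b: str
    score: float
    gap_open: float
    gap_extend: float
    matrix_name: str
    columns: list[tuple[int | None, int | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        if not self.columns:
            pa = pb = 0
            cols = []
            for ca, cb in zip(self.aligned_a, self.aligned_b):
                ia = ib = None
                if ca != "-":
                    pa += 1
                    ia = pa
                if cb != "-":
                    pb += 1
                    ib = pb
                cols.append((ia, ib))
            self.columns = cols

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace("-", "")

    @property
    def identity(self) -> float:
        return percent_identity(self)

    def __len__(self) -> int:
        return len(self.aligned_a)

    def to_pair_format(self) -> str:
        """A simplified EMBOSS pair-style rendering."""
        lines = [
            "# Aligned sequences: 2",
            f"# Matrix: {self.matrix_name}",
            f"# Gap_penalty: {self.gap_open}",
            f"# Extend_penalty: {self.gap_extend}",
            f"# Length: {len(self)}",
            f"# Identity: {self.identity:.1f}%",
            f"# Score: {self.score:.1f}",
            "",
        ]
        width = 60
        for start in range(0, len(self), width):
            a = self.aligned_a[start : start + width]
            b = self.aligned_b[start : start + width]
            marks = "".join("|" if x == y and x != "-" else " " for x, y in zip(a, b))
            lines += [f"A {a}", f"  {marks}", f"B {b}", ""]
        return "\n".join(lines)


def _validate(seq: str, which: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"sequence {which} is empty")
    bad = set(seq) - AMINO_ALPHABET
    if bad:
        raise ValueError(f"sequence {which} has invalid characters: {sorted(bad)}")
    return seq


def needleman_wunsch(
    seq_a: str,
    seq_b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix_name: str = "BLOSUM62",
) -> Alignment:
    """Optimal global alignment under affine gaps with free end gaps."""
    a = _validate(seq_a, "A")
    b = _validate(seq_b, "B")
    if matrix is None:
        matrix = load_matrix(matrix_name)
    n, m = len(a), len(b)

    def sub(i: int, j: int) -> float:
        return float(matrix[a[i - 1], b[j - 1]])

    # M: a[i] ~ b[j]; X: gap in B (consuming A); Y: gap in A (consuming B)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    X[1:, 0] = 0.0  # leading end gaps free
    Y[0, 1:] = 0.0

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub(i, j)
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend, Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend, X[i, j - 1] - gap_open)

    # free trailing end gaps: best interior cell on the last row/column
    best = (M[n, m], "M", n, m)
    for state, Z in (("M", M), ("X", X), ("Y", Y)):
        for i in range(n + 1):
            if Z[i, m] > best[0]:
                best = (Z[i, m], state, i, m)
        for j in range(m + 1):
            if Z[n, j] > best[0]:
                best = (Z[n, j], state, n, j)
    score, state, i, j = best

    out_a: list[str] = []
    out_b: list[str] = []
    # trailing free gaps
    for k in range(n, i, -1):
        out_a.append(a[k - 1])
        out_b.append("-")
    for k in range(m, j, -1):
        out_a.append("-")
        out_b.append(b[k - 1])

    tol = 1e-9
    while i > 0 and j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - sub(i, j)
            i, j = i - 1, j - 1
            # tie-break: prefer continuing with match, then gap in A (Y), then X
            for cand, Z in (("M", M), ("Y", Y), ("X", X)):
                if abs(Z[i, j] - target) < tol:
                    state = cand
                    break
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in M")
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            val = X[i, j]
            i -= 1
            if i == 0 and abs(val) < tol:
                break  # reached the free leading-gap boundary
            if abs(M[i, j] - gap_open - val) < tol:
                state = "M"
            elif abs(X[i, j] - gap_extend - val) < tol:
                state = "X"
            elif abs(Y[i, j] - gap_open - val) < tol:
                state = "Y"
            elif i == 0:
                break
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in X")
        else:  # Y
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if j == 0 and abs(val) < tol:
                break
            if abs(M[i, j] - gap_open - val) < tol:
                state = "M"
            elif abs(Y[i, j] - gap_extend - val) < tol:
                state = "Y"
            elif abs(X[i, j] - gap_open - val) < tol:
                state = "X"
            elif j == 0:
                break
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed in Y")
    # leading free gaps
    while i > 0:
        out_a.append(a[i - 1])
        out_b.append("-")
        i -= 1
    while j > 0:
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1

    return Alignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(score),
        gap_open=gap_open,
        gap_extend=gap_extend,
        matrix_name=matrix_name,
    )


def score_alignment(
    aligned_a: str,
    aligned_b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Score an emitted alignment directly (end gaps free); self-consistency oracle."""
    if matrix is None:
        matrix = load_matrix()
    n = len(aligned_a)
    # identify end-gap spans
    interior = [True] * n
    for s, seq in enumerate((aligned_a, aligned_b)):
        i = 0
        while i < n and seq[i] == "-":
            interior[i] = False
            i += 1
        i = n - 1
        while i >= 0 and seq[i] == "-":
            interior[i] = False
            i -= 1
    score = 0.0
    in_gap_a = in_gap_b = False
    for k, (x, y) in enumerate(zip(aligned_a, aligned_b)):
        if x != "-" and y != "-":
            score += float(matrix[x, y])
            in_gap_a = in_gap_b = False
        elif x == "-":
            if interior[k]:
                score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        else:
            if interior[k]:
                score -= gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
    return score


def percent_identity(alignment: Alignment) -> float:
    """Identical columns / alignment length × 100."""
    same = sum(
        1 for x, y in zip(alignment.aligned_a, alignment.aligned_b) if x == y and x != "-"
    )
    return 100.0 * same / len(alignment)


class EnergyComparisonTable:
    """Per-residue energies of two subtypes placed on alignment columns."""

    COLUMNS = [
        "column",
        "resid_a",
        "resname_a",
        "e_a",
        "resid_b",
        "resname_b",
        "e_b",
        "shared_key",
    ]

    def __init__(self, table: pd.DataFrame, key_threshold: float, scheme: str = "e_total") -> None:
        self.table = table.reset_index(drop=True)
        self.key_threshold = key_threshold
        self.scheme = scheme

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _profile_maps(profile: ResidueEnergyProfile, offset: int, seq_len: int, which: str, column: str):
    energies: dict[int, float] = {}
    resnames: dict[int, str] = {}
    bad = []
    for _, row in profile.table.iterrows():
        pos = int(row["resid"]) - offset
        if not (1 <= pos <= seq_len):
            bad.append(int(row["resid"]))
            continue
        energies[pos] = float(row[column])
        resnames[pos] = str(row["resname"])
    if bad:
        raise ValueError(
            f"profile {which} resids not mappable with offset {offset}: {sorted(bad)}"
        )
    return energies, resnames


def map_energies(
    alignment: Alignment,
    profile_a: ResidueEnergyProfile,
    profile_b: ResidueEnergyProfile,
    offset_a: int = 0,
    offset_b: int = 0,
    key_threshold: float = 1.0,
    column: str = "e_total",
) -> EnergyComparisonTable:
    """Place both profiles on alignment columns and flag shared key residues.

    Profiles index residues by structure resid; ``offset`` maps resid to
    sequence position (``position = resid − offset``).  Positions without a
    profile row carry zero energy (non-contacting residue); a profile resid
    that maps outside the sequence raises listing the offenders.
    """
    ea, rn_a = _profile_maps(profile_a, offset_a, len(alignment.seq_a), "A", column)
    eb, rn_b = _profile_maps(profile_b, offset_b, len(alignment.seq_b), "B", column)
    rows = []
    for k, (pa, pb) in enumerate(alignment.columns, start=1):
        e_a = ea.get(pa, 0.0) if pa is not None else np.nan
        e_b = eb.get(pb, 0.0) if pb is not None else np.nan
        shared = (
            pa is not None
            and pb is not None
            and abs(e_a) >= key_threshold
            and abs(e_b) >= key_threshold
        )
        rows.append(
            {
                "column": k,
                "resid_a": (pa + offset_a) if pa is not None else None,
                "resname_a": rn_a.get(pa, alignment.seq_a[pa - 1] if pa else None) if pa is not None else None,
                "e_a": e_a,
                "resid_b": (pb + offset_b) if pb is not None else None,
                "resname_b": rn_b.get(pb, alignment.seq_b[pb - 1] if pb else None) if pb is not None else None,
                "e_b": e_b,
                "shared_key": bool(shared),
            }
        )
    return EnergyComparisonTable(pd.DataFrame(rows, columns=EnergyComparisonTable.COLUMNS), key_threshold, column)


def shared_key_residues(
    table: EnergyComparisonTable, threshold: float | None = None
) -> tuple[list[dict], dict[str, list[dict]]]:
    """Split table rows into shared key residues and subtype-specific ones.

    Shared: both sides exceed the threshold in magnitude.  Specific: exactly
    one side exceeds it.  Returns (shared rows, {'a': rows, 'b': rows}).
    """
    thr = table.key_threshold if threshold is None else threshold
    shared: list[dict] = []
    specific: dict[str, list[dict]] = {"a": [], "b": []}
    for _, row in table.table.iterrows():
        big_a = row["resid_a"] is not None and not pd.isna(row["e_a"]) and abs(row["e_a"]) >= thr
        big_b = row["resid_b"] is not None and not pd.isna(row["e_b"]) and abs(row["e_b"]) >= thr
        d = row.to_dict()
        if big_a and big_b:
            shared.append(d)
        elif big_a:
            specific["a"].append(d)
        elif big_b:
            specific["b"].append(d)
    return shared, specific
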