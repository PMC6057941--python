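"""Contact selection and the energy model.

The energy driving the structure calculation is

    E = E_clash + E_rest

where E_rest sums, over all selected predicted contacts, a flat-bottom
switchable restraint

    E_rest,i = lam_i (d_i - d0)^2 + D^2 (1 - lam_i^2)   if d_i > d0
               0                                        otherwise

with d_i the CB-CB (CA for Gly) distance, d0 = 7 A the violation onset,
and lam_i in [0, 1] a per-restraint weight.  Because E_rest,i is concave
in lam_i, each restraint is bistable: switching it off (lam = 0) costs
D^2 but saves the violation penalty, so turning off is favorable exactly
when (d - d0)^2 > D^2.  Annealing D downward progressively removes
restraints that the geometry cannot satisfy.

E_clash is a purely repulsive soft-core term between backbone atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .geometry import ChainCoordinates, SecondarySegment, pair_distance

__all__ = [
    "ContactRecord",
    "RestraintSet",
    "select_input_contacts",
    "restraint_term",
    "total_restraint_energy",
    "lambda_gradient",
    "clash_energy",
    "violation_energy",
]

D0_DEFAULT = 7.0  # violation onset (A)
CLASH_RMIN = 3.0  # soft-core onset (A)


@dataclass
class ContactRecord:
    """One predicted contact: residue pair (1-based, i<j) and score."""

    i: int
    j: int
    score: float
    lam: float = 1.0
    on: bool = True

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"self-contact ({self.i},{self.j})")
        if self.i > self.j:
            self.i, self.j = self.j, self.i
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda {self.lam} outside [0,1]")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class RestraintSet:
    """Selected contacts plus the restraint parameters in force."""

    contacts: list[ContactRecord]
    d0: float = D0_DEFAULT
    D: float = 150.0

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.D <= 0:
            raise ValueError("d0 and D must be positive")
        pairs = [c.pair for c in self.contacts]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate contact pair in restraint set")

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([c.lam for c in self.contacts])


def _same_segment(i: int, j: int, segments: list[SecondarySegment]) -> bool:
    return any(i in seg and j in seg for seg in segments)


def select_input_contacts(
    ranked: list[ContactRecord],
    segments: list[SecondarySegment],
    n_aa: int,
    factor: float = 1.2,
    d0: float = D0_DEFAULT,
) -> RestraintSet:
    """Pick the top floor(factor * n_aa) long-range contacts.

    Walks the score-ranked list, skipping pairs whose two residues fall
    inside one predicted secondary-structure segment (those carry no
    tertiary information), until the quota is filled.  If the list runs
    out first, a warning is issued and the shorter set returned.
    """
    if n_aa <= 0:
        raise ValueError("n_aa must be positive")
    quota = int(np.floor(factor * n_aa))
    selected: list[ContactRecord] = []
    seen: set[tuple[int, int]] = set()
    for rec in ranked:
        if len(selected) >= quota:
            break
        if _same_segment(rec.i, rec.j, segments):
            continue
        if rec.pair in seen:
            continue
        seen.add(rec.pair)
        selected.append(ContactRecord(rec.i, rec.j, rec.score, lam=1.0, on=True))
    if len(selected) < quota:
        warnings.warn(
            f"ranked list exhausted: {len(selected)} eligible contacts "
            f"found, quota was {quota}",
            stacklevel=2,
        )
    return RestraintSet(selected, d0=d0)


def restraint_term(d: float, lam: float, D: float, d0: float = D0_DEFAULT) -> float:
    """Switchable flat-bottom restraint energy for one contact."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0,1]")
    if d <= d0:
        return 0.0
    return lam * (d - d0) ** 2 + D**2 * (1.0 - lam**2)


def lambda_gradient(d: float, lam: float, D: float, d0: float = D0_DEFAULT) -> float:
    """dE_rest,i/dlam: (d-d0)^2 - 2 D^2 lam above d0, else 0."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0,1]")
    if d <= d0:
        return 0.0
    return (d - d0) ** 2 - 2.0 * D**2 * lam


def total_restraint_energy(rset: RestraintSet, coords: ChainCoordinates) -> float:
    """Sum of restraint_term over all contacts in the set."""
    return sum(
        restraint_term(pair_distance(coords, c.i, c.j), c.lam, rset.D, rset.d0)
        for c in rset.contacts
    )


def _atom_table(coords: ChainCoordinates) -> tuple[np.ndarray, np.ndarray]:
    """Stack backbone atoms; returns (positions, residue index per atom)."""
    pos, res = [], []
    L = len(coords)
    for i in range(L):
        for arr in (coords.n, coords.ca, coords.c):
            pos.append(arr[i])
            res.append(i)
        if coords.sequence[i] != "G":
            pos.append(coords.cb[i])
            res.append(i)
    return np.asarray(pos), np.asarray(res)


def clash_energy(
    coords: ChainCoordinates, r_min: float = CLASH_RMIN, k: float = 1.0
) -> float:
    """Soft-core repulsion: k (r_min - r)^2 for r < r_min.

    Runs over all N/CA/C/CB atom pairs except those within the same or
    sequence-adjacent residues (covalent neighbourhood).
    """
    pos, res = _atom_table(coords)
    r = squareform(pdist(pos))
    sep = np.abs(res[:, None] - res[None, :])
    mask = np.triu(sep > 1) & (r < r_min)
    return float(k * ((r_min - r[mask]) ** 2).sum())


def violation_energy(distances) -> float:
    """Mean squared violation beyond 9 A of the contact distances.

    Evaluation-time quantity: the per-contact average of (d - 9)^2 for
    d > 9, measured on reference-structure distances.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    excess = np.clip(d - 9.0, 0.0, None)
    return float(np.mean(excess**2))
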