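"""Torsion-space polypeptide model.

A chain is represented by its backbone dihedral angles (phi, psi, omega)
plus per-residue "fixed" flags that lock residues inside predicted
secondary-structure segments to canonical helix/strand angles.  Cartesian
coordinates for a reduced backbone (N, CA, C and a CB side-chain proxy;
no CB for glycine) are derived deterministically from the torsion state
by sequential internal-to-Cartesian (NeRF) construction with ideal bond
lengths and angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SecondarySegment",
    "TorsionChain",
    "ChainCoordinates",
    "segments_from_ss",
    "build_torsion_chain",
    "to_coordinates",
    "pair_distance",
    "HELIX_PHI",
    "HELIX_PSI",
    "STRAND_PHI",
    "STRAND_PSI",
]

# Canonical secondary-structure dihedrals (degrees).
HELIX_PHI, HELIX_PSI = -60.0, -45.0
STRAND_PHI, STRAND_PSI = -135.0, 135.0

# Ideal backbone geometry (Engh–Huber-style values), lengths in Å,
# angles in degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7


@dataclass(frozen=True)
class SecondarySegment:
    """A maximal predicted helix or strand run, 1-based inclusive."""

    start: int
    end: int
    kind: str  # "helix" or "strand"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.kind not in ("helix", "strand"):
            raise ValueError(f"unknown segment kind {self.kind!r}")

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass
class TorsionChain:
    """Sequence plus per-residue (phi, psi, omega) and fixed flags.

    Angles are degrees in (-180, 180]; ``fixed[i]`` means residue i+1
    is locked to its canonical segment angles and must never be moved.
    """

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    fixed: np.ndarray  # bool

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in ("phi", "psi", "omega", "fixed"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != sequence length {n}")
            setattr(self, name, arr.copy())
        self.fixed = self.fixed.astype(bool)

    def __len__(self) -> int:
        return len(self.sequence)

    def copy(self) -> "TorsionChain":
        return TorsionChain(self.sequence, self.phi, self.psi, self.omega, self.fixed)

    @property
    def n_free(self) -> int:
        return int((~self.fixed).sum())


@dataclass
class ChainCoordinates:
    """Backbone coordinates (Å): N, CA, C per residue; CB except glycine."""

    n: np.ndarray  # (L, 3)
    ca: np.ndarray
    c: np.ndarray
    cb: np.ndarray  # (L, 3); rows are NaN for glycine
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def contact_atom(self, i: int) -> np.ndarray:
        """CB of residue i (1-based), or CA for glycine."""
        if not 1 <= i <= len(self):
            raise IndexError(f"residue index {i} out of range 1..{len(self)}")
        if self.sequence[i - 1] == "G":
            return self.ca[i - 1]
        return self.cb[i - 1]


def segments_from_ss(ss_labels: str) -> list[SecondarySegment]:
    """Run-length encode an H/E/C string into helix/strand segments.

    Coil runs produce no segment; order follows the sequence.
    """
    if not ss_labels:
        raise ValueError("empty secondary structure")
    bad = set(ss_labels) - set("HEC")
    if bad:
        raise ValueError(f"invalid secondary-structure labels: {sorted(bad)}")
    segments: list[SecondarySegment] = []
    start = 0
    for pos in range(1, len(ss_labels) + 1):
        if pos == len(ss_labels) or ss_labels[pos] != ss_labels[start]:
            label = ss_labels[start]
            if label == "H":
                segments.append(SecondarySegment(start + 1, pos, "helix"))
            elif label == "E":
                segments.append(SecondarySegment(start + 1, pos, "strand"))
            start = pos
    return segments


def build_torsion_chain(
    sequence: str, segments: list[SecondarySegment]
) -> TorsionChain:
    """Extended chain with canonical dihedrals fixed inside segments.

    Helix residues get (phi, psi) = (-60, -45), strand residues
    (-135, 135), both flagged fixed; every other residue is free and
    initialized to the extended strand conformation.  All omega = 180.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    phi = np.full(n, STRAND_PHI)
    psi = np.full(n, STRAND_PSI)
    omega = np.full(n, 180.0)
    fixed = np.zeros(n, dtype=bool)
    for seg in segments:
        if seg.start < 1 or seg.end > n:
            raise ValueError(f"segment {seg} out of range for length-{n} sequence")
        sl = slice(seg.start - 1, seg.end)
        if seg.kind == "helix":
            phi[sl] = HELIX_PHI
            psi[sl] = HELIX_PSI
        else:
            phi[sl] = STRAND_PHI
            psi[sl] = STRAND_PSI
        fixed[sl] = True
    return TorsionChain(sequence, phi, psi, omega, fixed)


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of atom d bonded to c, given frame a-b-c."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(torsion) * np.sin(angle),
            bond * np.sin(torsion) * np.sin(angle),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _place_cb(n_at: np.ndarray, ca: np.ndarray, c_at: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral CB from the N, CA, C frame (L-amino acid)."""
    u1 = n_at - ca
    u1 /= np.linalg.norm(u1)
    u2 = c_at - ca
    u2 /= np.linalg.norm(u2)
    bisector = u1 + u2
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    # 50.1 deg tilt out of the N-CA-C plane reproduces ~110 deg
    # N-CA-CB / C-CA-CB angles with the ideal backbone angle.
    tilt = np.deg2rad(50.1)
    direction = -np.cos(tilt) * bisector + np.sin(tilt) * perp
    return ca + BOND_CA_CB * direction


def to_coordinates(chain: TorsionChain) -> ChainCoordinates:
    """Sequential internal-to-Cartesian build of the reduced backbone.

    Deterministic: the first residue is placed in a canonical frame
    (N at origin, CA on +x, C in the xy-plane); identical chains give
    bit-identical coordinates.
    """
    L = len(chain)
    n_xyz = np.zeros((L, 3))
    ca_xyz = np.zeros((L, 3))
    c_xyz = np.zeros((L, 3))
    cb_xyz = np.full((L, 3), np.nan)

    n_xyz[0] = (0.0, 0.0, 0.0)
    ca_xyz[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    c_xyz[0] = ca_xyz[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, L):
        n_xyz[i] = _place_atom(
            n_xyz[i - 1], ca_xyz[i - 1], c_xyz[i - 1],
            BOND_C_N, ANGLE_CA_C_N, chain.psi[i - 1],
        )
        ca_xyz[i] = _place_atom(
            ca_xyz[i - 1], c_xyz[i - 1], n_xyz[i],
            BOND_N_CA, ANGLE_C_N_CA, chain.omega[i - 1],
        )
        c_xyz[i] = _place_atom(
            c_xyz[i - 1], n_xyz[i], ca_xyz[i],
            BOND_CA_C, ANGLE_N_CA_C, chain.phi[i],
        )
    for i in range(L):
        if chain.sequence[i] != "G":
            cb_xyz[i] = _place_cb(n_xyz[i], ca_xyz[i], c_xyz[i])
    return ChainCoordinates(n_xyz, ca_xyz, c_xyz, cb_xyz, chain.sequence)


def pair_distance(coords: ChainCoordinates, i: int, j: int) -> float:
    """CB–CB distance (Å) between residues i and j, CA for glycine."""
    return float(np.linalg.norm(coords.contact_atom(i) - coords.contact_atom(j)))
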