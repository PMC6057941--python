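"""Readers and writers for the standard formats the tool touches.

Input side: FASTA query sequences, FASTA/A3M alignments, PSIPRED
secondary-structure predictions (.ss2 vertical and horizontal layouts),
contact lists (plain whitespace tables or the CASP-RR dialect) and PDB
reference structures.  Output side: filtered contact tables and reduced
backbone models as PDB.

Residue indices are 1-based everywhere on disk, matching PDB and
CASP-RR conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .geometry import ChainCoordinates
from .restraints import ContactRecord

__all__ = [
    "MSA",
    "ReferenceStructure",
    "read_fasta",
    "read_msa",
    "read_psipred",
    "read_contacts",
    "read_reference_structure",
    "write_contacts",
    "write_model_pdb",
]


@dataclass
class MSA:
    """Aligned sequences: list of (identifier, row) with equal widths."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty MSA")
        widths = {len(s) for _, s in self.records}
        if len(widths) != 1:
            raise ValueError(f"ragged alignment: row widths {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.records[0][1])

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ReferenceStructure:
    """Experimental reference mapped onto the query numbering (1-based).

    ``cb`` rows hold the contact atom (CB, or CA for glycine);
    unresolved query positions have ``resolved`` False and NaN
    coordinates.  phi/psi are NaN where any defining atom is missing.
    """

    sequence: str
    ca: np.ndarray  # (L, 3)
    cb: np.ndarray  # (L, 3), contact atom
    resolved: np.ndarray  # (L,) bool
    phi: np.ndarray  # (L,) degrees, NaN if undefined
    psi: np.ndarray
    ss_labels: Optional[str] = None

    def __len__(self) -> int:
        return len(self.sequence)

    def pair_distance(self, i: int, j: int) -> float:
        """Contact-atom distance between query residues i and j (1-based)."""
        if not (self.resolved[i - 1] and self.resolved[j - 1]):
            return math.nan
        return float(np.linalg.norm(self.cb[i - 1] - self.cb[j - 1]))


def read_fasta(path) -> str:
    """First record's sequence, uppercased, '*' stripped."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return str(records[0].seq).upper().replace("*", "")


def read_msa(path) -> MSA:
    """FASTA or A3M alignment.

    A3M lowercase columns are insertions relative to the query and are
    removed, which restores a rectangular alignment.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(c for c in str(rec.seq) if not c.islower())
        records.append((rec.id, seq.replace(".", "-").upper()))
    return MSA(records)


def read_psipred(path) -> str:
    """Per-residue H/E/C string from PSIPRED .ss2 or horizontal output.

    G/I helix codes collapse to H, B bridge codes to E and any other
    letter to C, so plain DSSP-style strings also parse.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    horizontal = any(ln.lstrip().startswith("Pred:") for ln in lines)
    labels: list[str] = []
    if horizontal:
        for ln in lines:
            if ln.lstrip().startswith("Pred:"):
                labels.extend(ln.split(":", 1)[1].strip())
    else:
        for ln in lines:
            s = ln.strip()
            if s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 3 or not parts[0].isdigit():
                continue
            labels.append(parts[2])
    if not labels:
        raise ValueError(f"no secondary-structure labels found in {path}")
    mapped = []
    for n, lab in enumerate(labels, start=1):
        lab = lab.upper()
        if lab in ("H", "G", "I"):
            mapped.append("H")
        elif lab in ("E", "B"):
            mapped.append("E")
        elif lab.isalpha() and len(lab) == 1:
            mapped.append("C")
        else:
            raise ValueError(f"invalid secondary-structure label {lab!r} at entry {n}")
    return "".join(mapped)


def read_contacts(path) -> list[ContactRecord]:
    """Ranked contact list from a whitespace table or CASP-RR file.

    Plain rows are "i j score" (extra columns ignored); CASP-RR rows are
    "i j d1 d2 score" with the probability in column 5, and the header
    keywords (PFRMAT, TARGET, ...) are skipped.  Pairs are normalized to
    i < j, duplicates collapse keeping the maximum score, and the output
    is sorted by descending score with (i, j) tie-breaks.
    """
    skip = ("PFRMAT", "TARGET", "AUTHOR", "METHOD", "MODEL", "REMARK", "END")
    best: dict[tuple[int, int], float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.split()[0].upper() in skip:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected at least 3 columns")
        try:
            i, j = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer residue index") from exc
        if i == j:
            raise ValueError(f"{path}:{lineno}: self-contact ({i},{j})")
        score = float(parts[4]) if len(parts) >= 5 else float(parts[2])
        if i > j:
            i, j = j, i
        if (i, j) not in best or score > best[(i, j)]:
            best[(i, j)] = score
    recs = [ContactRecord(i, j, s) for (i, j), s in best.items()]
    recs.sort(key=lambda r: (-r.score, r.i, r.j))
    return recs


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items() if k != "MSE"}


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(
        np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))
    )


def read_reference_structure(
    path, query_sequence: str, chain: Optional[str] = None
) -> ReferenceStructure:
    """Load a PDB reference and map it onto the query by alignment.

    Uses the first model; picks the requested chain or the one whose
    one-letter sequence aligns to the query at >= 90% identity (over
    aligned positions).  Author residue numbers are ignored — mapping is
    purely by sequence alignment, which absorbs numbering offsets.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    chains = [ch for ch in model if chain is None or ch.name == chain]
    if not chains:
        raise ValueError(f"chain {chain!r} not found in {path}")

    aligner = PairwiseAligner(mode="global", open_gap_score=-10,
                              extend_gap_score=-0.5, match_score=2,
                              mismatch_score=-1)
    best = None
    for ch in chains:
        residues = [r for r in ch if r.name in _THREE_TO_ONE]
        if not residues:
            continue
        seq = "".join(_THREE_TO_ONE[r.name] for r in residues)
        aln = aligner.align(query_sequence, seq)[0]
        ident = sum(
            1
            for qs, ts in zip(*aln.indices)
            if qs >= 0 and ts >= 0 and query_sequence[qs] == seq[ts]
        )
        frac = ident / max(min(len(query_sequence), len(seq)), 1)
        if best is None or frac > best[0]:
            best = (frac, residues, aln)
    if best is None or best[0] < 0.9:
        got = 0.0 if best is None else best[0]
        raise ValueError(
            f"no chain in {path} matches the query sequence "
            f"(best identity {got:.2f} < 0.90)"
        )
    _, residues, aln = best

    L = len(query_sequence)
    ca = np.full((L, 3), np.nan)
    cb = np.full((L, 3), np.nan)
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    resolved = np.zeros(L, dtype=bool)

    def atom_pos(res, name):
        at = res.find_atom(name, "*")
        return np.array(at.pos.tolist()) if at else None

    # query position -> structure residue (or None)
    mapping: list[Optional[int]] = [None] * L
    for qs, ts in zip(*aln.indices):
        if qs >= 0 and ts >= 0:
            mapping[qs] = ts

    for q in range(L):
        t = mapping[q]
        if t is None:
            continue
        res = residues[t]
        pos_ca = atom_pos(res, "CA")
        if pos_ca is None:
            continue
        ca[q] = pos_ca
        pos_cb = atom_pos(res, "CB")
        cb[q] = pos_ca if (res.name == "GLY" or pos_cb is None) else pos_cb
        resolved[q] = True

    for q in range(L):
        t = mapping[q]
        if t is None:
            continue
        res = residues[t]
        n_ = atom_pos(res, "N")
        ca_ = atom_pos(res, "CA")
        c_ = atom_pos(res, "C")
        if n_ is None or ca_ is None or c_ is None:
            continue
        tp = mapping[q - 1] if q > 0 else None
        if tp is not None and tp == t - 1:
            cprev = atom_pos(residues[tp], "C")
            if cprev is not None:
                phi[q] = _dihedral(cprev, n_, ca_, c_)
        tn = mapping[q + 1] if q < L - 1 else None
        if tn is not None and tn == t + 1:
            nnext = atom_pos(residues[tn], "N")
            if nnext is not None:
                psi[q] = _dihedral(n_, ca_, c_, nnext)

    return ReferenceStructure(query_sequence, ca, cb, resolved, phi, psi)


def write_contacts(path, records: Sequence[ContactRecord],
                   on_fraction=None, kept=None) -> None:
    """Tab-separated contact table: i, j, score, on_fraction, kept.

    ``kept`` is encoded "1"/"0"; both extra columns default to kept=1,
    on_fraction=1.0 when not supplied.
    """
    n = len(records)
    on_fraction = [1.0] * n if on_fraction is None else list(on_fraction)
    kept = [True] * n if kept is None else list(kept)
    lines = ["i\tj\tscore\ton_fraction\tkept"]
    for rec, frac, kp in zip(records, on_fraction, kept):
        lines.append(
            f"{rec.i}\t{rec.j}\t{rec.score:.6g}\t{frac:.6f}\t{1 if kp else 0}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_contact_table(path):
    """Round-trip reader for write_contacts output."""
    rows = Path(path).read_text().splitlines()
    recs, fracs, kept = [], [], []
    for ln in rows[1:]:
        i, j, score, frac, kp = ln.split("\t")
        recs.append(ContactRecord(int(i), int(j), float(score)))
        fracs.append(float(frac))
        kept.append(kp == "1")
    return recs, fracs, kept


def write_model_pdb(path, coords: ChainCoordinates) -> None:
    """Write the reduced N/CA/C/CB backbone as standard PDB ATOM records."""
    lines = []
    serial = 1
    for i in range(len(coords)):
        aa = coords.sequence[i]
        res3 = _ONE_TO_THREE.get(aa, "UNK")
        atoms = [("N", coords.n[i], "N"), ("CA", coords.ca[i], "C"),
                 ("C", coords.c[i], "C")]
        if aa != "G":
            atoms.append(("CB", coords.cb[i], "C"))
        for name, xyz, element in atoms:
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res3} A{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
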