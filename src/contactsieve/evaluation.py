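"""Evaluation against reference structures and alignments.

Contacts are judged true if the reference CB-CB (CA for glycine)
distance is at or below 9 A.  Structure quality uses GDT: the fraction
of CA atoms within a distance cutoff of the reference after optimal
superposition (5 A single cutoff, or the 1/2/4/8 A GDT-TS average).
Alignment depth is summarized as the effective sequence count N_eff,
down-weighting each sequence by the size of its >80%-identity
neighbourhood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fileio import MSA, ReferenceStructure
from .geometry import (
    HELIX_PHI,
    HELIX_PSI,
    STRAND_PHI,
    STRAND_PSI,
    TorsionChain,
)
from .restraints import ContactRecord, violation_energy

__all__ = [
    "EvaluationReport",
    "classify_contacts",
    "precision_recall",
    "kabsch_superpose",
    "gdt",
    "gdt_ts",
    "n_effective",
    "reference_dihedral_chain",
    "evaluate_contacts",
]

TP_CUTOFF = 9.0


@dataclass
class EvaluationReport:
    """Summary of one filtering run against a reference structure."""

    n_input: int
    n_kept: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    violation_energy: float
    input_precision: Optional[float] = None
    input_violation_energy: Optional[float] = None
    gdt5: Optional[float] = None
    gdt_ts: Optional[float] = None
    n_eff: Optional[float] = None

    def to_text(self) -> str:
        out = []
        for key, val in self.__dict__.items():
            if val is None:
                continue
            if isinstance(val, float):
                out.append(f"{key}\t{val:.6g}")
            else:
                out.append(f"{key}\t{val}")
        return "\n".join(out) + "\n"


def classify_contacts(
    contacts: Sequence[ContactRecord],
    reference: ReferenceStructure,
    cutoff: float = TP_CUTOFF,
) -> list[str]:
    """Label each contact "TP", "FP" or "unverifiable".

    TP means the reference contact-atom distance is at or below the
    cutoff; contacts touching unresolved residues are unverifiable and
    excluded from precision/recall denominators.
    """
    labels = []
    for c in contacts:
        if c.j > len(reference):
            raise IndexError(f"contact ({c.i},{c.j}) beyond reference length")
        d = reference.pair_distance(c.i, c.j)
        if math.isnan(d):
            labels.append("unverifiable")
        elif d <= cutoff:
            labels.append("TP")
        else:
            labels.append("FP")
    return labels


def precision_recall(
    input_labels: Sequence[str],
    kept: Sequence[bool],
) -> tuple[float, float]:
    """(precision, recall) of the kept subset of a classified input set.

    Precision = TP_kept / (TP_kept + FP_kept); recall counts input TPs
    that survive filtering, TP_kept / (TP_kept + TP_dropped).
    Unverifiable contacts are ignored.  Undefined ratios (empty kept
    set, or no input TPs) come back as NaN.
    """
    if len(input_labels) != len(kept):
        raise ValueError("label/kept length mismatch")
    tp_kept = sum(1 for l, k in zip(input_labels, kept) if k and l == "TP")
    fp_kept = sum(1 for l, k in zip(input_labels, kept) if k and l == "FP")
    tp_all = sum(1 for l in input_labels if l == "TP")
    precision = tp_kept / (tp_kept + fp_kept) if tp_kept + fp_kept else math.nan
    recall = tp_kept / tp_all if tp_all else math.nan
    return precision, recall


def kabsch_superpose(
    model_ca: np.ndarray, ref_ca: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation/translation of model onto reference.

    Returns (R, t, rmsd) with ref ~ model @ R.T + t and det(R) = +1.
    """
    P = np.asarray(model_ca, dtype=float)
    Q = np.asarray(ref_ca, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 paired atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    moved = (R @ P.T).T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum() / len(P)))
    return R, t, rmsd


def _gdt_one_cutoff(P: np.ndarray, Q: np.ndarray, cutoff: float,
                    max_iter: int = 10) -> float:
    """Seeded, iteratively trimmed Kabsch approximation of the GDT search.

    Superpositions are seeded from the full chain and from short
    contiguous fragments; each seed is refined by alternately keeping
    the pairs within the cutoff and re-superposing on them.  The best
    fraction over all seeds is returned (a deterministic, desk-scale
    stand-in for the exhaustive LGA search).
    """
    n = len(P)
    seeds = [np.arange(n)]
    frag = 4
    for start in range(0, n - frag + 1, 2):
        seeds.append(np.arange(start, start + frag))
    if n >= 8:
        half = n // 2
        for start in range(0, n - half + 1, max(half // 2, 1)):
            seeds.append(np.arange(start, start + half))
    best = 0.0
    for idx in seeds:
        for _ in range(max_iter):
            if len(idx) < 3:
                break
            R, t, _ = kabsch_superpose(P[idx], Q[idx])
            moved = (R @ P.T).T + t
            dist = np.linalg.norm(moved - Q, axis=1)
            within = dist <= cutoff
            best = max(best, within.sum() / n)
            new_idx = np.flatnonzero(within)
            if np.array_equal(new_idx, idx):
                break
            idx = new_idx
    return best


def gdt(model_ca, ref_ca, cutoffs=(5.0,)) -> dict[float, float]:
    """GDT fractions of CA atoms within each cutoff after superposition."""
    P = np.asarray(model_ca, dtype=float)
    Q = np.asarray(ref_ca, dtype=float)
    if len(P) < 3:
        raise ValueError("need at least 3 paired CA atoms")
    return {c: _gdt_one_cutoff(P, Q, c) for c in cutoffs}


def gdt_ts(model_ca, ref_ca) -> float:
    """Mean GDT fraction over the 1, 2, 4, 8 A cutoffs."""
    scores = gdt(model_ca, ref_ca, cutoffs=(1.0, 2.0, 4.0, 8.0))
    return float(np.mean(list(scores.values())))


def _seq_to_ints(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def n_effective(msa: MSA, identity_threshold: float = 0.8) -> float:
    """Effective sequence count with >80%-identity down-weighting.

    Each sequence gets weight 1/n where n counts alignment rows
    (including itself) with pairwise identity above the threshold;
    identity is matches over columns where both rows are non-gap
    (doubly-gapped columns are excluded).  N_eff is the weight sum.
    """
    if len(msa) == 0:
        raise ValueError("empty MSA")
    rows = np.vstack([_seq_to_ints(s) for _, s in msa.records])
    gap = ord("-")
    nongap = rows != gap
    m = len(rows)
    counts = np.ones(m)
    for a in range(m):
        both = nongap[a] & nongap[a + 1:]
        match = (rows[a] == rows[a + 1:]) & both
        denom = both.sum(axis=1)
        ident = np.where(denom > 0, match.sum(axis=1) / np.maximum(denom, 1), 0.0)
        close = ident > identity_threshold
        counts[a] += close.sum()
        counts[a + 1:] += close
    return float(np.sum(1.0 / counts))


def reference_dihedral_chain(
    reference: ReferenceStructure, ss_assignment: str
) -> TorsionChain:
    """Benchmark-mode chain: experimental dihedrals fixed in structured regions.

    ``ss_assignment`` marks residues H/E (fixed to the experimental phi/psi
    from the reference) or C (free).  Where an assigned residue's phi or
    psi is undefined (chain terminus, unresolved neighbour) the canonical
    angle for its class substitutes, with a warning.
    """
    L = len(reference)
    if len(ss_assignment) != L:
        raise ValueError(
            f"assignment length {len(ss_assignment)} != sequence length {L}"
        )
    phi = np.full(L, STRAND_PHI)
    psi = np.full(L, STRAND_PSI)
    omega = np.full(L, 180.0)
    fixed = np.zeros(L, dtype=bool)
    for k, lab in enumerate(ss_assignment.upper()):
        if lab not in ("H", "E"):
            continue
        fixed[k] = True
        canon_phi = HELIX_PHI if lab == "H" else STRAND_PHI
        canon_psi = HELIX_PSI if lab == "H" else STRAND_PSI
        if math.isnan(reference.phi[k]):
            warnings.warn(
                f"residue {k + 1}: phi undefined in reference, using canonical",
                stacklevel=2,
            )
            phi[k] = canon_phi
        else:
            phi[k] = reference.phi[k]
        if math.isnan(reference.psi[k]):
            warnings.warn(
                f"residue {k + 1}: psi undefined in reference, using canonical",
                stacklevel=2,
            )
            psi[k] = canon_psi
        else:
            psi[k] = reference.psi[k]
    return TorsionChain(reference.sequence, phi, psi, omega, fixed)


def evaluate_contacts(
    input_contacts: Sequence[ContactRecord],
    kept: Sequence[bool],
    reference: ReferenceStructure,
    model_ca: Optional[np.ndarray] = None,
    msa: Optional[MSA] = None,
) -> EvaluationReport:
    """Full report for a filtering run: counts, precision/recall,
    violation energy of the kept set, optional GDT and N_eff."""
    labels = classify_contacts(input_contacts, reference)
    precision, recall = precision_recall(labels, kept)
    tp = sum(1 for l, k in zip(labels, kept) if k and l == "TP")
    fp = sum(1 for l, k in zip(labels, kept) if k and l == "FP")
    fn = sum(1 for l in labels if l == "TP") - tp
    kept_d = [
        reference.pair_distance(c.i, c.j)
        for c, k, l in zip(input_contacts, kept, labels)
        if k and l != "unverifiable"
    ]
    input_d = [
        reference.pair_distance(c.i, c.j)
        for c, l in zip(input_contacts, labels)
        if l != "unverifiable"
    ]
    energy = violation_energy(kept_d) if kept_d else math.nan
    input_energy = violation_energy(input_d) if input_d else math.nan
    input_precision, _ = precision_recall(labels, [True] * len(labels))
    report = EvaluationReport(
        n_input=len(input_contacts),
        n_kept=int(sum(kept)),
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        violation_energy=energy,
        input_precision=input_precision,
        input_violation_energy=input_energy,
    )
    if model_ca is not None:
        mask = reference.resolved
        if mask.sum() >= 3:
            ref_ca = reference.ca[mask]
            mca = np.asarray(model_ca)[mask]
            report.gdt5 = gdt(mca, ref_ca)[5.0]
            report.gdt_ts = gdt_ts(mca, ref_ca)
    if msa is not None:
        report.n_eff = n_effective(msa)
    return report
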