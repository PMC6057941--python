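"""Synthetic fixtures: toy folds, noisy contact predictions, toy MSAs.

Everything here is generated programmatically so the whole pipeline can
be exercised without downloading any structure or alignment.  The toy
folds are built directly in torsion space — strand residues carry the
canonical fixed dihedrals and only loop residues take curated turn
angles — which guarantees that the ground-truth conformation is
reachable by a sampler that moves loop dihedrals only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fileio import MSA, ReferenceStructure
from .geometry import (
    ChainCoordinates,
    SecondarySegment,
    TorsionChain,
    build_torsion_chain,
    pair_distance,
    segments_from_ss,
    to_coordinates,
)
from .restraints import ContactRecord

__all__ = ["ToyFold", "make_toy_sheet", "gsgs_fixture", "make_prediction",
           "make_toy_msa"]

# Turn dihedrals for two-residue loops between antiparallel strands,
# found by matching cross-strand CB ladders at ~5 A while keeping
# non-adjacent backbone atoms apart.  A and B alternate so consecutive
# hairpins close in opposite directions (flat meander).
_TURN_A = ((100.0, 80.0), (60.0, 20.0))
_TURN_B = ((80.0, 60.0), (100.0, 0.0))

# Numerically refined per-loop dihedrals for specific topologies,
# keyed by (n_strands, strand_len, loop_len): array (n_loops, loop_len, 2).
# The 60-residue three-strand meander pairs 18-residue strands at ~5 A
# ladders with no backbone contact below 3.2 A.
_LOOP_LIBRARY: dict[tuple[int, int, int], np.ndarray] = {
    (3, 18, 3): np.array(
        [
            [[149.0, 130.5], [95.4, 0.0], [90.6, 9.6]],
            [[51.9, 80.1], [-159.5, -55.2], [104.6, -0.9]],
        ]
    ),
}


@dataclass
class ToyFold:
    """Deterministic ground-truth fold plus its derived contact truth."""

    sequence: str
    ss_labels: str
    chain: TorsionChain
    coords: ChainCoordinates
    true_contacts: list[tuple[int, int]]  # long-range pairs with d <= 9 A

    @property
    def segments(self) -> list[SecondarySegment]:
        return segments_from_ss(self.ss_labels)

    def reference(self) -> ReferenceStructure:
        """View the ground-truth coordinates as an evaluation reference."""
        L = len(self.sequence)
        cb = np.array(
            [
                self.coords.ca[i] if self.sequence[i] == "G" else self.coords.cb[i]
                for i in range(L)
            ]
        )
        return ReferenceStructure(
            sequence=self.sequence,
            ca=self.coords.ca.copy(),
            cb=cb,
            resolved=np.ones(L, dtype=bool),
            phi=self.chain.phi.copy(),
            psi=self.chain.psi.copy(),
            ss_labels=self.ss_labels,
        )


def _long_range_pairs(ss_labels: str) -> list[tuple[int, int]]:
    segs = segments_from_ss(ss_labels)
    L = len(ss_labels)
    out = []
    for i in range(1, L):
        for j in range(i + 1, L + 1):
            if not any(i in s and j in s for s in segs):
                out.append((i, j))
    return out


def make_toy_sheet(
    n_strands: int = 3,
    strand_len: int = 5,
    loop_len: int = 2,
    seed: int = 0,
) -> ToyFold:
    """Idealized antiparallel beta-meander built in torsion space.

    Strands carry the canonical fixed strand dihedrals; loop residues
    take curated turn angles that bring consecutive strands into a
    ~5 A CB-CB pairing ladder.  The sequence alternates Gly/Ser.  The
    construction is deterministic; ``seed`` is accepted for interface
    uniformity and reserved for future sequence randomization.
    """
    if n_strands < 2:
        raise ValueError("need at least 2 strands")
    ss = ("E" * strand_len + "C" * loop_len) * (n_strands - 1) + "E" * strand_len
    seq = "".join("GS"[i % 2] for i in range(len(ss)))
    chain = build_torsion_chain(seq, segments_from_ss(ss))
    key = (n_strands, strand_len, loop_len)
    library = _LOOP_LIBRARY.get(key)
    for loop_idx in range(n_strands - 1):
        base = strand_len + loop_idx * (strand_len + loop_len)
        if library is not None:
            angles = library[loop_idx]
        else:
            turn = _TURN_A if loop_idx % 2 == 0 else _TURN_B
            first, rest = turn
            angles = [first] + [rest] * (loop_len - 1)
        for r in range(loop_len):
            chain.phi[base + r] = angles[r][0]
            chain.psi[base + r] = angles[r][1]
    coords = to_coordinates(chain)
    true_contacts = [
        (i, j)
        for i, j in _long_range_pairs(ss)
        if pair_distance(coords, i, j) <= 9.0
    ]
    return ToyFold(seq, ss, chain, coords, true_contacts)


def gsgs_fixture() -> tuple[ToyFold, list[ContactRecord]]:
    """Three-stranded antiparallel sheet with a five-contact design.

    Two contacts pair strands 1-2, two pair strands 2-3, and a fifth,
    deliberately erroneous contact joins strands 1 and 3, whose true
    separation in the flat sheet exceeds the 9 A contact range.  The
    erroneous record carries the lowest score and is listed last.
    """
    toy = make_toy_sheet(3, 5, 2)
    sl, ll = 5, 2
    o = sl + ll
    s1 = range(1, sl + 1)
    s2 = range(o + 1, o + sl + 1)
    s3 = range(2 * o + 1, 2 * o + sl + 1)

    def best_pairs(sa, sb, n):
        cand = [
            (i, j)
            for (i, j) in toy.true_contacts
            if i in sa and j in sb
        ]
        cand.sort(
            key=lambda p: pair_distance(toy.coords, p[0], p[1])
        )
        # spread: avoid reusing the same residue twice
        chosen, used = [], set()
        for p in cand:
            if p[0] in used or p[1] in used:
                continue
            chosen.append(p)
            used.update(p)
            if len(chosen) == n:
                break
        return chosen

    pairs12 = best_pairs(s1, s2, 2)
    pairs23 = best_pairs(s2, s3, 2)
    # erroneous contact: a strand1-strand3 pair well outside the 9 A
    # contact range (target ~13 A), so it is geometrically incompatible
    # with the four true pairings rather than a borderline case
    candidates = [
        (i, j, pair_distance(toy.coords, i, j))
        for i in list(s1)[1:-1]
        for j in list(s3)[1:-1]
    ]
    err_i, err_j, err_d = min(
        (c for c in candidates if c[2] > 9.0), key=lambda c: abs(c[2] - 13.0)
    )
    assert err_d > 9.0
    records = [
        ContactRecord(i, j, score)
        for (i, j), score in zip(
            pairs12 + pairs23, (5.0, 4.0, 3.0, 2.0)
        )
    ]
    records.append(ContactRecord(err_i, err_j, 1.0))
    return toy, records


def make_prediction(
    toyfold: ToyFold,
    n_contacts: int,
    target_precision: float,
    seed: int,
    decoy_min_dist: float = 12.0,
    min_seq_sep: int = 4,
) -> list[ContactRecord]:
    """Noisy ranked contact list with an enforced precision.

    round(n * p) contacts are drawn from the fold's true long-range
    pairs; the rest are decoys drawn from long-range pairs whose true
    distance exceeds ``decoy_min_dist`` (default 12 A, clear of the
    borderline regime).  Scores descend with the true/decoy order
    shuffled, so rank carries no information about correctness.
    """
    if not 0 < target_precision <= 1:
        raise ValueError("target_precision must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_true = int(round(n_contacts * target_precision))
    n_decoy = n_contacts - n_true
    true_pool = [p for p in toyfold.true_contacts if p[1] - p[0] >= min_seq_sep]
    decoy_pool = [
        (i, j)
        for i, j in _long_range_pairs(toyfold.ss_labels)
        if j - i >= min_seq_sep
        and pair_distance(toyfold.coords, i, j) > decoy_min_dist
    ]
    if n_true > len(true_pool) or n_decoy > len(decoy_pool):
        raise ValueError(
            f"insufficient pool: need {n_true} true of {len(true_pool)}, "
            f"{n_decoy} decoys of {len(decoy_pool)}"
        )
    chosen_true = [true_pool[k] for k in rng.choice(len(true_pool), n_true, replace=False)]
    chosen_decoy = [decoy_pool[k] for k in rng.choice(len(decoy_pool), n_decoy, replace=False)]
    pairs = chosen_true + chosen_decoy
    order = rng.permutation(len(pairs))
    scores = np.linspace(2.0, 1.0, n_contacts)
    return [
        ContactRecord(pairs[k][0], pairs[k][1], float(s))
        for k, s in zip(order, scores)
    ]


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_toy_msa(
    n_clusters: int,
    cluster_sizes,
    within_identity: float = 0.9,
    between_identity: float = 0.3,
    length: int = 80,
    seed: int = 0,
) -> MSA:
    """Gapless MSA whose effective sequence count equals n_clusters.

    Each cluster is a representative plus members mutated at disjoint
    position sets sized so every within-cluster pairwise identity stays
    at or above ``within_identity`` (> 0.8), while independently drawn
    representatives keep between-cluster identity near background
    (~1/20), far below 0.8.
    """
    if isinstance(cluster_sizes, int):
        cluster_sizes = [cluster_sizes] * n_clusters
    if len(cluster_sizes) != n_clusters:
        raise ValueError("cluster_sizes length must equal n_clusters")
    if not within_identity > 0.8 > between_identity:
        raise ValueError("need within_identity > 0.8 > between_identity")
    rng = np.random.default_rng(seed)
    m_mut = int(np.floor((1.0 - within_identity) * length / 2.0))
    records = []
    for ci, size in enumerate(cluster_sizes):
        if size < 1:
            raise ValueError("cluster sizes must be >= 1")
        if size * m_mut > length:
            raise ValueError(
                f"cluster {ci}: cannot place {size} members with {m_mut} "
                f"disjoint mutations each in length {length}"
            )
        rep = rng.choice(list(_AA20), size=length)
        positions = rng.permutation(length)
        for mi in range(size):
            row = rep.copy()
            block = positions[mi * m_mut : (mi + 1) * m_mut]
            for p in block:
                choices = [a for a in _AA20 if a != rep[p]]
                row[p] = choices[rng.integers(len(choices))]
            records.append((f"c{ci}_m{mi}", "".join(row)))
    msa = MSA(records)
    from .evaluation import n_effective

    neff = n_effective(msa)
    if abs(neff - n_clusters) > 1e-9:
        raise ValueError(
            f"inconsistent parameters: constructed N_eff {neff} != {n_clusters}"
        )
    return msa
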