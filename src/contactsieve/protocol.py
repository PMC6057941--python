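"""The full filtering pipeline.

One protocol run: (1) anneal the chain while stochastically sampling
the per-restraint weights lambda_i; (2) read off the refined contact
list (final lambda >= 0.5); (3) re-anneal with only the refined
contacts as fixed restraints (lambda = 1); (4) mark a contact "on" if
it is in the refined list and its distance in the final structure does
not violate d0 by more than the final D (<= 10 A with defaults).

The run is repeated n_repeats times with independent seeds, and the
consensus keeps contacts that are on in more than 30% of the runs.
Filtering only ever removes contacts from the selected input set.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    SecondarySegment,
    TorsionChain,
    build_torsion_chain,
    pair_distance,
    segments_from_ss,
)
from .restraints import ContactRecord, RestraintSet, select_input_contacts
from .sampler import AnnealResult, make_schedule, run_annealing

__all__ = [
    "ProtocolConfig",
    "RunOutcome",
    "FilterResult",
    "single_protocol_run",
    "consensus_filter",
    "filter_contacts",
]


@dataclass
class ProtocolConfig:
    """All protocol constants, defaulting to the published values
    where the protocol states them (quota factor, d0, D schedule,
    gamma/delta, 64 repeats, >30% consensus, 9 A TP cutoff); sampler
    sizes are this package's desk-scale calibration."""

    factor: float = 1.2
    d0: float = 7.0
    D_start: float = 150.0
    D_end: float = 3.0
    gamma: float = 0.00025
    delta: float = 0.6666
    n_repeats: int = 64
    consensus_on_fraction: float = 0.30
    lambda_on_threshold: float = 0.5
    tp_cutoff: float = 9.0
    n_steps: int = 150
    moves_per_free_dihedral: int = 8
    T_start: float = 10.0
    T_end: float = 0.1
    max_step_deg: float = 30.0
    dt: float = 1.0
    base_seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.consensus_on_fraction < 1:
            raise ValueError("consensus_on_fraction must be in (0,1)")
        for name in ("factor", "d0", "D_start", "D_end", "gamma", "delta",
                     "n_repeats", "lambda_on_threshold", "tp_cutoff",
                     "n_steps", "moves_per_free_dihedral", "T_start", "T_end",
                     "max_step_deg", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunOutcome:
    """Per-contact on/off decision of one protocol run."""

    on: np.ndarray  # bool, one per input contact
    lambdas: np.ndarray  # final annealed lambda
    chain: TorsionChain  # final refined-model torsion state
    coords_ca: np.ndarray  # final refined-model CA coordinates
    seed: int


@dataclass
class FilterResult:
    """Consensus output of the repeated protocol."""

    input_contacts: list[ContactRecord]
    on_fraction: np.ndarray
    kept: np.ndarray  # bool
    outcomes: list[RunOutcome]
    consensus_model_ca: np.ndarray
    config: ProtocolConfig
    seeds: list[int]

    @property
    def kept_contacts(self) -> list[ContactRecord]:
        return [c for c, k in zip(self.input_contacts, self.kept) if k]


def single_protocol_run(
    chain_template: TorsionChain,
    rset: RestraintSet,
    config: ProtocolConfig,
    seed: int,
) -> RunOutcome:
    """One lambda-sampling anneal plus one fixed-restraint refinement."""
    ss = np.random.SeedSequence(seed)
    seed_a, seed_b = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    schedule = make_schedule(
        config.n_steps, config.D_start, config.D_end, config.T_start, config.T_end
    )
    moves = config.moves_per_free_dihedral * max(chain_template.n_free, 1)

    work_set = RestraintSet(
        [ContactRecord(c.i, c.j, c.score, lam=1.0) for c in rset.contacts],
        d0=rset.d0,
        D=config.D_start,
    )
    stage1 = run_annealing(
        chain_template, work_set, schedule, moves, seed_a,
        sample_lambdas=True, max_step_deg=config.max_step_deg,
        dt=config.dt, gamma=config.gamma, delta=config.delta,
    )
    refined = stage1.lambdas >= config.lambda_on_threshold

    refined_set = RestraintSet(
        [
            ContactRecord(c.i, c.j, c.score, lam=1.0)
            for c, keep in zip(rset.contacts, refined)
            if keep
        ]
        or [],
        d0=rset.d0,
        D=config.D_end,
    )
    if len(refined_set):
        stage2 = run_annealing(
            chain_template, refined_set, schedule, moves, seed_b,
            sample_lambdas=False, max_step_deg=config.max_step_deg,
            dt=config.dt, gamma=config.gamma, delta=config.delta,
        )
        final_chain, final_coords = stage2.chain, stage2.coords
    else:
        final_chain, final_coords = stage1.chain, stage1.coords

    on = np.zeros(len(rset), dtype=bool)
    limit = config.d0 + config.D_end
    for q, (c, keep) in enumerate(zip(rset.contacts, refined)):
        if not keep:
            continue
        on[q] = pair_distance(final_coords, c.i, c.j) <= limit
    return RunOutcome(on, stage1.lambdas, final_chain, final_coords.ca.copy(), seed)


def consensus_filter(
    outcomes: Sequence[RunOutcome], threshold: float = 0.30
) -> tuple[np.ndarray, np.ndarray]:
    """(on_fraction, kept) across runs; kept iff fraction > threshold."""
    if not outcomes:
        raise ValueError("no outcomes to form a consensus")
    sizes = {len(o.on) for o in outcomes}
    if len(sizes) != 1:
        raise ValueError(f"mismatched contact lists across runs: sizes {sizes}")
    stack = np.vstack([o.on for o in outcomes])
    frac = stack.mean(axis=0)
    return frac, frac > threshold


def filter_contacts(
    sequence: str,
    ss_labels: str,
    ranked_contacts: Sequence[ContactRecord],
    config: Optional[ProtocolConfig] = None,
) -> FilterResult:
    """End-to-end consensus filtering of a ranked contact list.

    Builds the fixed-secondary-structure chain, selects the top
    floor(factor * N_AA) long-range contacts, executes n_repeats
    independent protocol runs (seeds base_seed + k) and applies the
    consensus rule.  Runs may execute on several threads; the result is
    identical to sequential execution.
    """
    config = config or ProtocolConfig()
    if len(sequence) != len(ss_labels):
        raise ValueError(
            f"sequence length {len(sequence)} != secondary structure "
            f"length {len(ss_labels)}"
        )
    segments = segments_from_ss(ss_labels)
    chain = build_torsion_chain(sequence, segments)
    rset = select_input_contacts(
        list(ranked_contacts), segments, len(sequence),
        factor=config.factor, d0=config.d0,
    )
    if len(rset) == 0:
        raise ValueError("no eligible contacts: every pair falls within one segment")
    for c in rset.contacts:
        if c.j > len(sequence):
            raise ValueError(f"contact ({c.i},{c.j}) beyond sequence length")

    seeds = [config.base_seed + k for k in range(config.n_repeats)]
    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            outcomes = list(
                pool.map(
                    lambda s: single_protocol_run(chain, rset, config, s), seeds
                )
            )
    else:
        outcomes = [single_protocol_run(chain, rset, config, s) for s in seeds]
    frac, kept = consensus_filter(outcomes, config.consensus_on_fraction)

    # representative model: the run whose on-set best matches the consensus
    overlap = [int(np.sum(o.on == kept)) for o in outcomes]
    model_ca = outcomes[int(np.argmax(overlap))].coords_ca
    return FilterResult(
        input_contacts=list(rset.contacts),
        on_fraction=frac,
        kept=kept,
        outcomes=outcomes,
        consensus_model_ca=model_ca,
        config=config,
        seeds=seeds,
    )
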