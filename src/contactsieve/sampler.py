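"""Simulated-annealing engine.

Structure calculation is Metropolis Monte Carlo on the free backbone
dihedrals under the clash + restraint energy, run along a schedule that
simultaneously cools the temperature T and anneals the restraint
switching cost D from 150 A down to 3 A.  After the torsion moves of
each schedule step, every restraint weight lambda_i takes one Brownian
update

    lam(t+dt) = lam(t) - gamma * dE_rest,i/dlam * dt
                + delta * sqrt(T dt) * z,    z ~ N(0, 1)

clamped to [0, 1] (gamma = 0.00025, delta = 0.6666).  Early in the
schedule D is large and every restraint is pinned on; as D falls,
restraints whose violation (d - d0)^2 exceeds the switching cost slide
to lambda = 0 and stop influencing the structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .geometry import ChainCoordinates, TorsionChain, to_coordinates
from .restraints import (
    CLASH_RMIN,
    RestraintSet,
    clash_energy,
    total_restraint_energy,
)

__all__ = [
    "AnnealSchedule",
    "AnnealResult",
    "make_schedule",
    "update_lambdas",
    "torsion_move",
    "run_annealing",
]

GAMMA_DEFAULT = 0.00025
DELTA_DEFAULT = 0.6666


@dataclass(frozen=True)
class AnnealSchedule:
    """Per-step D (switching cost, A) and T (temperature) values."""

    D_values: np.ndarray
    T_values: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.D_values)


@dataclass
class AnnealResult:
    chain: TorsionChain
    coords: ChainCoordinates
    lambdas: np.ndarray
    energy_trace: np.ndarray
    seed: int
    n_accepted: int


def make_schedule(
    n_steps: int,
    D_start: float = 150.0,
    D_end: float = 3.0,
    T_start: float = 10.0,
    T_end: float = 0.1,
) -> AnnealSchedule:
    """Geometric annealing schedules with exact endpoints."""
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    if not D_start > D_end > 0:
        raise ValueError("need D_start > D_end > 0")
    if not T_start >= T_end >= 0 or T_end <= 0:
        raise ValueError("need T_start >= T_end > 0")
    D = np.geomspace(D_start, D_end, n_steps)
    T = np.geomspace(T_start, T_end, n_steps)
    D[0], D[-1] = D_start, D_end
    T[0], T[-1] = T_start, T_end
    return AnnealSchedule(D, T)


def update_lambdas(
    lambdas,
    distances,
    D: float,
    T: float,
    dt: float = 1.0,
    gamma: float = GAMMA_DEFAULT,
    delta: float = DELTA_DEFAULT,
    rng: Optional[np.random.Generator] = None,
    d0: float = 7.0,
) -> np.ndarray:
    """One Brownian update of all restraint weights; clamped to [0, 1]."""
    lam = np.asarray(lambdas, dtype=float)
    d = np.asarray(distances, dtype=float)
    if np.any((lam < 0) | (lam > 1)):
        raise ValueError("lambda outside [0,1]")
    if rng is None:
        rng = np.random.default_rng()
    grad = np.where(d > d0, (d - d0) ** 2 - 2.0 * D**2 * lam, 0.0)
    noise = delta * np.sqrt(T * dt) * rng.standard_normal(lam.shape)
    out = np.clip(lam - gamma * grad * dt + noise, 0.0, 1.0)
    assert np.all((out >= 0) & (out <= 1))
    return out


def _free_dihedrals(chain: TorsionChain) -> list[tuple[int, bool]]:
    """(residue 0-based, is_phi) for every samplable free dihedral.

    psi of the last residue rotates nothing downstream and is skipped.
    """
    out = []
    L = len(chain)
    for k in range(L):
        if chain.fixed[k]:
            continue
        out.append((k, True))
        if k < L - 1:
            out.append((k, False))
    return out


def _flatten(coords: ChainCoordinates):
    """Atom table in kernel order (N, CA, C, CB per residue)."""
    pos, res = [], []
    idx_n, idx_ca, idx_c, idx_cb = [], [], [], []
    for i in range(len(coords)):
        idx_n.append(len(pos)); pos.append(coords.n[i]); res.append(i)
        idx_ca.append(len(pos)); pos.append(coords.ca[i]); res.append(i)
        idx_c.append(len(pos)); pos.append(coords.c[i]); res.append(i)
        if coords.sequence[i] != "G":
            idx_cb.append(len(pos)); pos.append(coords.cb[i]); res.append(i)
        else:
            idx_cb.append(-1)
    return (
        np.ascontiguousarray(pos, dtype=np.float64),
        np.asarray(res, dtype=np.int64),
        np.asarray(idx_n, dtype=np.int64),
        np.asarray(idx_ca, dtype=np.int64),
        np.asarray(idx_c, dtype=np.int64),
        np.asarray(idx_cb, dtype=np.int64),
    )


def _move_table(chain, idx_n, idx_ca, idx_c, idx_cb, n_atoms):
    moves = _free_dihedrals(chain)
    move_res = np.empty(max(len(moves), 1), dtype=np.int64)
    move_is_phi = np.zeros(max(len(moves), 1), dtype=np.bool_)
    suffix = np.full(max(len(moves), 1), n_atoms, dtype=np.int64)
    axis_a = np.zeros(max(len(moves), 1), dtype=np.int64)
    axis_b = np.zeros(max(len(moves), 1), dtype=np.int64)
    for q, (k, is_phi) in enumerate(moves):
        move_res[q] = k
        move_is_phi[q] = is_phi
        if is_phi:
            suffix[q] = idx_c[k]          # C_k, CB_k and all later residues
            axis_a[q] = idx_n[k]
            axis_b[q] = idx_ca[k]
        else:
            suffix[q] = idx_n[k + 1]      # everything past this residue
            axis_a[q] = idx_ca[k]
            axis_b[q] = idx_c[k]
    return len(moves), move_res, move_is_phi, suffix, axis_a, axis_b


def _contact_rows(rset: RestraintSet, idx_ca, idx_cb, sequence: str):
    ci = np.empty(len(rset), dtype=np.int64)
    cj = np.empty(len(rset), dtype=np.int64)
    for q, c in enumerate(rset.contacts):
        ci[q] = idx_ca[c.i - 1] if sequence[c.i - 1] == "G" else idx_cb[c.i - 1]
        cj[q] = idx_ca[c.j - 1] if sequence[c.j - 1] == "G" else idx_cb[c.j - 1]
    return ci, cj


def torsion_move(
    chain: TorsionChain,
    rset: RestraintSet,
    coords: ChainCoordinates,
    T: float,
    rng: np.random.Generator,
    max_step_deg: float = 30.0,
):
    """One Metropolis torsion move (reference implementation).

    Picks a free phi or psi uniformly, perturbs it by
    uniform(-max_step, max_step), rebuilds coordinates and accepts with
    probability min(1, exp(-dE/T)).  Returns (chain, coords, accepted).
    """
    moves = _free_dihedrals(chain)
    if not moves:
        return chain, coords, False
    k, is_phi = moves[rng.integers(len(moves))]
    delta = rng.uniform(-max_step_deg, max_step_deg)
    e_old = clash_energy(coords) + total_restraint_energy(rset, coords)
    trial = chain.copy()
    arr = trial.phi if is_phi else trial.psi
    val = (arr[k] + delta + 180.0) % 360.0 - 180.0
    arr[k] = 180.0 if val == -180.0 else val
    trial_coords = to_coordinates(trial)
    e_new = clash_energy(trial_coords) + total_restraint_energy(rset, trial_coords)
    de = e_new - e_old
    if de <= 0 or (T > 0 and rng.random() < np.exp(-min(de / T, 700.0))):
        return trial, trial_coords, True
    return chain, coords, False


def run_annealing(
    chain: TorsionChain,
    rset: RestraintSet,
    schedule: AnnealSchedule,
    moves_per_step: int,
    seed: int,
    sample_lambdas: bool = True,
    max_step_deg: float = 30.0,
    dt: float = 1.0,
    gamma: float = GAMMA_DEFAULT,
    delta: float = DELTA_DEFAULT,
    k_clash: float = 1.0,
) -> AnnealResult:
    """Run one full annealing simulation; deterministic given the seed.

    Each schedule step performs ``moves_per_step`` torsion moves, then
    (unless ``sample_lambdas`` is False, the fixed-restraint refinement
    mode) one lambda update at that step's D and T.
    """
    work = chain.copy()
    coords = to_coordinates(work)
    pos, atom_res, idx_n, idx_ca, idx_c, idx_cb = _flatten(coords)
    n_moves, move_res, move_is_phi, suffix, axis_a, axis_b = _move_table(
        work, idx_n, idx_ca, idx_c, idx_cb, pos.shape[0]
    )
    ci, cj = _contact_rows(rset, idx_ca, idx_cb, work.sequence)
    lam = rset.lambdas.astype(np.float64)
    n_steps = schedule.n_steps
    rng = np.random.default_rng(seed)
    n_total = n_steps * moves_per_step
    if n_moves > 0:
        pick = rng.integers(0, n_moves, n_total)
        dmove = rng.uniform(-max_step_deg, max_step_deg, n_total)
        uacc = rng.random(n_total)
    else:
        pick = np.zeros(n_total, dtype=np.int64)
        dmove = np.zeros(n_total)
        uacc = np.zeros(n_total)
    lam_z = rng.standard_normal((n_steps, max(len(lam), 1)))
    trace = np.zeros(n_steps)
    fixed_phi = work.phi[work.fixed].copy()
    fixed_psi = work.psi[work.fixed].copy()
    n_accept = _kernels.anneal_kernel(
        pos, atom_res, move_res, move_is_phi, suffix, axis_a, axis_b,
        ci, cj, lam, bool(sample_lambdas),
        schedule.D_values, schedule.T_values,
        rset.d0, gamma, delta, dt, CLASH_RMIN, k_clash,
        moves_per_step, pick, dmove, uacc,
        lam_z[:, : max(len(lam), 1)], work.phi, work.psi, trace,
    )
    assert np.array_equal(work.phi[work.fixed], fixed_phi)
    assert np.array_equal(work.psi[work.fixed], fixed_psi)
    assert np.all((lam >= 0) & (lam <= 1))
    final_coords = to_coordinates(work)
    return AnnealResult(work, final_coords, lam, trace, seed, int(n_accept))
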