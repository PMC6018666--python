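"""Simulated-annealing Monte Carlo refinement.

The sampler anneals between a high and a low temperature (triangular wave,
one cycle = high -> low -> high), proposing rigid-body moves of selected
domain groups and single linker-torsion moves, with Metropolis acceptance at
the instantaneous temperature.  Move amplitudes scale with T / T_high.

The expensive data terms (SAXS metainference, RDC correlation) are refreshed
every ``data_stride``-th step and held fixed in between; structural restraint
terms are evaluated at every step.  The scale nuisance lambda (flat prior on
[0.9, 1.1]) and, unless fixed, the per-point uncertainties sigma_i (Jeffreys
prior) are updated by Metropolis-within-Gibbs moves at the data stride.

The refined structure is the snapshot with the lowest metainference energy
among the high-temperature samples of the last ``selection_window`` cycles
(ties broken by the earliest step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import AtomicModel, RigidGroupPartition, apply_move, apply_torsion
from .scoring import HybridEnergyModel, metainference_energy
from scipy.spatial.transform import Rotation

__all__ = ["AnnealSchedule", "Trajectory", "run_annealing", "select_refined"]

KB_KJ_PER_MOL_K = 0.0083144621


@dataclass
class AnnealSchedule:
    """Annealing parameters: temperatures, cycling, selection, move amplitudes."""

    t_high: float = 300.0
    t_low: float = 100.0
    steps_per_half_period: int = 500
    n_cycles: int = 300
    selection_window: int = 30
    data_stride: int = 10
    seed: int = 0
    max_rotation_deg: float = 10.0
    max_translation: float = 1.5
    max_torsion_deg: float = 10.0
    lambda_step: float = 0.02
    sigma_step: float = 0.1     # log-space sigma proposal width

    def __post_init__(self):
        if not self.t_high > self.t_low > 0:
            raise ValueError("need t_high > t_low > 0")
        if not self.n_cycles >= self.selection_window >= 1:
            raise ValueError("need n_cycles >= selection_window >= 1")
        if self.data_stride < 1:
            raise ValueError("data stride must be >= 1")

    def temperature(self, step_in_cycle: int) -> float:
        half = self.steps_per_half_period
        span = self.t_high - self.t_low
        if step_in_cycle < half:
            return self.t_high - span * step_in_cycle / half
        return self.t_low + span * (step_in_cycle - half) / half


@dataclass
class Trajectory:
    """Recorded sampler states; snapshots are stored for high-T samples."""

    records: list = field(default_factory=list)
    schedule: AnnealSchedule | None = None

    def append(self, **kw):
        self.records.append(kw)

    def high_t_samples(self):
        return [r for r in self.records if r["is_high_t"]]

    def __len__(self):
        return len(self.records)


def _propose(model, partition, move_groups, schedule, rng, t_scale):
    torsions = partition.flexible
    n_moves = len(move_groups) + len(torsions)
    pick = rng.integers(n_moves)
    if pick < len(move_groups):
        group = move_groups[pick]
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(schedule.max_rotation_deg * t_scale) * rng.uniform(-1, 1)
        rot = Rotation.from_rotvec(angle * axis).as_matrix()
        trans = schedule.max_translation * t_scale * rng.uniform(-1, 1, size=3)
        return apply_move(model, partition, group, rotation=rot, translation=trans)
    residue = torsions[pick - len(move_groups)]
    delta = schedule.max_torsion_deg * t_scale * rng.uniform(-1, 1)
    return apply_torsion(model, partition, residue, delta)


def run_annealing(
    start_model: AtomicModel,
    partition: RigidGroupPartition,
    energy: HybridEnergyModel,
    schedule: AnnealSchedule,
    move_groups=None,
) -> Trajectory:
    """Anneal the model under the hybrid energy; returns the trajectory.

    ``move_groups`` names the rigid groups whose pose is sampled (default: all
    groups).  Linker torsions from the partition are always part of the move
    set.  Bit-for-bit reproducible for a given schedule seed.
    """
    partition.validate(start_model)
    if move_groups is None:
        move_groups = list(partition.groups)
    move_groups = list(move_groups)
    if len(move_groups) + len(partition.flexible) == 0:
        raise ValueError("no movable degrees of freedom")

    rng = np.random.default_rng(schedule.seed)
    model = start_model.copy()
    lam = 1.0
    has_saxs = energy.saxs_term is not None
    has_rdc = energy.rdc_exp is not None
    sigma = energy.saxs_term.sigma.copy() if has_saxs else None
    stride = schedule.data_stride

    def data_energies(m):
        e_saxs = e_rdc = 0.0
        f_raw = None
        if has_saxs:
            f_raw = energy.saxs_forward(m)
            e_saxs = metainference_energy(f_raw, energy.saxs_term, lam, sigma)
        if has_rdc:
            e_rdc = energy.rdc_energy(m)
        return e_saxs, e_rdc, f_raw

    try:
        e_struct, _ = energy.structural_energy(model)
        e_saxs, e_rdc, f_raw = data_energies(model)
    except Exception as exc:
        raise RuntimeError(f"energy evaluation failed at step 0: {exc}") from exc

    traj = Trajectory(schedule=schedule)
    period = 2 * schedule.steps_per_half_period
    step = 0
    for cycle in range(schedule.n_cycles):
        for s in range(period):
            temp = schedule.temperature(s)
            beta = 1.0 / (KB_KJ_PER_MOL_K * temp)
            t_scale = temp / schedule.t_high
            refresh = (step % stride == 0) and (has_saxs or has_rdc)

            proposal = _propose(model, partition, move_groups, schedule, rng, t_scale)
            try:
                e_struct_new, _ = energy.structural_energy(proposal)
                if refresh:
                    e_saxs_new, e_rdc_new, f_raw_new = data_energies(proposal)
                else:
                    e_saxs_new, e_rdc_new, f_raw_new = e_saxs, e_rdc, f_raw
            except Exception as exc:
                raise RuntimeError(f"energy evaluation failed at step {step}: {exc}") from exc

            delta = (e_struct_new + e_saxs_new + e_rdc_new) - (e_struct + e_saxs + e_rdc)
            accept = delta <= 0 or rng.random() < np.exp(-beta * delta)
            if accept:
                model = proposal
                e_struct, e_saxs, e_rdc, f_raw = (
                    e_struct_new, e_saxs_new, e_rdc_new, f_raw_new
                )

            # nuisance-parameter moves at the data stride, on cached forwards
            if refresh and has_saxs:
                lam, e_saxs = _lambda_move(energy, f_raw, lam, sigma, e_saxs, rng,
                                           schedule, beta)
                if not energy.saxs_term.fixed_sigma:
                    sigma, e_saxs = _sigma_moves(energy, f_raw, lam, sigma, rng,
                                                 schedule, beta)

            is_high_t = s == 0
            traj.append(
                cycle=cycle,
                step=step,
                temperature=temp,
                energy_total=e_struct + e_saxs + e_rdc,
                energy_meta=e_saxs + e_rdc,   # data-term (metainference) energy
                energy_struct=e_struct,
                energy_rdc=e_rdc,
                lam=lam,
                accepted=bool(accept),
                is_high_t=is_high_t,
                snapshot=model.copy() if is_high_t else None,
            )
            step += 1
    return traj


def _lambda_move(energy, f_raw, lam, sigma, e_saxs, rng, schedule, beta):
    lo, hi = energy.saxs_term.scale_bounds
    lam_new = lam + schedule.lambda_step * rng.uniform(-1, 1)
    if not (lo <= lam_new <= hi):
        return lam, e_saxs      # outside flat prior: reject outright
    e_new = metainference_energy(f_raw, energy.saxs_term, lam_new, sigma)
    if e_new - e_saxs <= 0 or rng.random() < np.exp(-beta * (e_new - e_saxs)):
        return lam_new, e_new
    return lam, e_saxs


def _sigma_moves(energy, f_raw, lam, sigma, rng, schedule, beta):
    """Independent per-point Metropolis moves on log sigma with a Jeffreys prior."""
    term = energy.saxs_term
    f = lam * term.base_scale * np.asarray(f_raw, dtype=float)
    m2 = (f - term.data) ** 2
    sigma_new = sigma * np.exp(schedule.sigma_step * rng.uniform(-1, 1, size=len(sigma)))
    # per-point energy incl. likelihood normalisation and Jeffreys prior (+log sigma)
    e_old = m2 / (2 * sigma ** 2) + 2 * np.log(sigma)
    e_new = m2 / (2 * sigma_new ** 2) + 2 * np.log(sigma_new)
    accept = (e_new - e_old <= 0) | (rng.random(len(sigma)) < np.exp(-beta * (e_new - e_old)))
    out = np.where(accept, sigma_new, sigma)
    e_saxs = metainference_energy(f_raw, term, lam, out)
    return out, e_saxs


def select_refined(trajectory: Trajectory, schedule: AnnealSchedule | None = None):
    """Lowest-metainference-energy high-T snapshot from the last selection window."""
    if schedule is None:
        schedule = trajectory.schedule
    samples = trajectory.high_t_samples()
    if not samples:
        raise ValueError("trajectory contains no high-temperature samples")
    last_cycle = max(r["cycle"] for r in trajectory.records)
    first_ok = last_cycle - schedule.selection_window + 1
    qualifying = [r for r in samples if r["cycle"] >= first_ok]
    if not qualifying:
        raise ValueError("no high-T samples within the selection window")
    best = min(qualifying, key=lambda r: (r["energy_meta"], r["step"]))
    return best["snapshot"]
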