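"""One-site ITC binding model: simulate, fit, and derive thermodynamics.

The cell contains the macromolecule (here RNA) at concentration M0, the
syringe the titrant (protein) at X0.  With a single class of N equivalent
sites, the bound fraction after injection i follows the closed-form root of
the binding quadratic in total concentrations (the Wiseman isotherm):

    Q_i = N * Mt_i * dH * V0 / 2 *
          [ 1 + Xr/N + Kd/(N*Mt) - sqrt((1 + Xr/N + Kd/(N*Mt))^2 - 4*Xr/N) ]

with Xr = Xt/Mt.  Per-injection heats are differences of cumulative heats
with the standard displaced-volume correction of the "overfill" cell model:
each injection displaces its own volume, and the working concentrations are

    Mt_i = M0 * (1 - dV_i/(2 V0)) / (1 + dV_i/(2 V0))
    Xt_i = X0 * (dV_i/V0) / (1 + dV_i/(2 V0))

where dV_i is the cumulative injected volume.  Units are calorie-based:
heats in µcal, dH in cal/mol, R = 1.987 cal/(mol K), T defaults to 298.15 K.

Derived quantities: dG = R T ln Kd, dS = (dH - dG) / T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationExperiment",
    "BindingFit",
    "TITRATION_PRESETS",
    "one_site_heats",
    "fit_one_site",
    "kd_from_enthalpy_entropy",
    "fold_change",
    "read_titration_csv",
    "write_titration_csv",
]

R_CAL = 1.987           # cal / (mol K)
T_DEFAULT = 298.15      # K (25 C)
CELL_VOLUME_UL = 200.0  # standard small-volume calorimeter cell


@dataclass
class TitrationExperiment:
    """An injection series: cell/syringe concentrations, volumes, heats."""

    cell_volume_ul: float
    cell_conc_uM: float          # macromolecule (RNA) in the cell
    syringe_conc_uM: float       # titrant (protein) in the syringe
    injection_volumes_ul: np.ndarray
    heats_ucal: np.ndarray | None = None
    temperature_K: float = T_DEFAULT

    def __post_init__(self):
        if self.cell_volume_ul <= 0 or self.cell_conc_uM <= 0 or self.syringe_conc_uM <= 0:
            raise ValueError("volumes and concentrations must be positive")
        self.injection_volumes_ul = np.asarray(self.injection_volumes_ul, dtype=float)
        if np.any(self.injection_volumes_ul <= 0):
            raise ValueError("injection volumes must be positive")
        if self.heats_ucal is not None:
            self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
            if not np.all(np.isfinite(self.heats_ucal)):
                raise ValueError("heats must be finite")


@dataclass
class BindingFit:
    """Fitted one-site parameters with derived state functions (calorie units)."""

    N: float
    Kd_M: float
    dH_cal_per_mol: float
    dG_cal_per_mol: float = field(init=False)
    dS_cal_per_mol_K: float = field(init=False)
    temperature_K: float = T_DEFAULT
    stderr: dict = field(default_factory=dict)
    c_value: float | None = None

    def __post_init__(self):
        if self.Kd_M <= 0:
            raise ValueError("Kd must be positive")
        self.dG_cal_per_mol = R_CAL * self.temperature_K * np.log(self.Kd_M)
        self.dS_cal_per_mol_K = (self.dH_cal_per_mol - self.dG_cal_per_mol) / self.temperature_K


#: Thermodynamic parameters of the protein/RNA titrations used as presets
#: (stoichiometry, Kd in 1e-6 M, dH in 1e4 cal/mol, dS in cal/mol/K).
TITRATION_PRESETS = {
    "RRM1+7-mer":            {"N": 1.01, "Kd_uM": 20.4,    "dH_1e4": -1.99, "dS": -45.2},
    "RRM2+7-mer":            {"N": 1.09, "Kd_uM": 6.8,     "dH_1e4": -1.64, "dS": -31.6},
    "UP1+7-mer":             {"N": 0.75, "Kd_uM": 3.4,     "dH_1e4": -3.53, "dS": -93.4},
    "UP1+17-mer(A35C)":      {"N": 1.07, "Kd_uM": 3.1,     "dH_1e4": -1.98, "dS": -41.2},
    "UP1+pri-mir-18a":       {"N": 1.35, "Kd_uM": 0.1477,  "dH_1e4": -3.52, "dS": -86.8},
    "UP1+12-mer":            {"N": 1.01, "Kd_uM": 0.0155,  "dH_1e4": -3.81, "dS": -92.0},
    "UP1+12-mer-mut1":       {"N": 1.06, "Kd_uM": 0.1541,  "dH_1e4": -2.97, "dS": -68.6},
    "UP1+12-mer-mut2":       {"N": 1.08, "Kd_uM": 0.330,   "dH_1e4": -2.45, "dS": -52.5},
    "UP1+12-mer-mut3":       {"N": 0.98, "Kd_uM": 0.00833, "dH_1e4": -4.10, "dS": -101.0},
    "UP1+10-mer":            {"N": 1.07, "Kd_uM": 0.01912, "dH_1e4": -3.94, "dS": -96.8},
    "UP1(R75E/R88A)+12-mer": {"N": 1.08, "Kd_uM": 0.0190,  "dH_1e4": -3.84, "dS": -93.5},
    "UP1(R75E/R88E)+12-mer": {"N": 1.10, "Kd_uM": 0.0401,  "dH_1e4": -3.68, "dS": -89.5},
}


def _working_concentrations(experiment: TitrationExperiment):
    """Displaced-volume-corrected total concentrations after each injection (M)."""
    v0 = experiment.cell_volume_ul
    dv = np.cumsum(experiment.injection_volumes_ul)
    m0 = experiment.cell_conc_uM * 1e-6
    x0 = experiment.syringe_conc_uM * 1e-6
    mt = m0 * (1.0 - dv / (2.0 * v0)) / (1.0 + dv / (2.0 * v0))
    xt = x0 * (dv / v0) / (1.0 + dv / (2.0 * v0))
    return mt, xt


def _cumulative_heat(N, Kd_M, dH, experiment):
    mt, xt = _working_concentrations(experiment)
    v0_l = experiment.cell_volume_ul * 1e-6
    xr = xt / mt
    term = 1.0 + xr / N + Kd_M / (N * mt)
    frac = term - np.sqrt(term ** 2 - 4.0 * xr / N)
    return N * mt * dH * v0_l / 2.0 * frac      # cal


def one_site_heats(N, Kd_M, dH_cal_per_mol, experiment: TitrationExperiment) -> np.ndarray:
    """Per-injection heats (µcal) of a one-site isotherm.

    In the stoichiometric limit (Kd -> 0) each pre-equivalence injection
    releases dH per mole of injected titrant and post-equivalence injections
    are silent; at saturation the cumulative heat tends to N * dH * (moles of
    cell macromolecule).
    """
    if N <= 0 or Kd_M < 0:
        raise ValueError("N must be positive and Kd non-negative")
    q_cum = _cumulative_heat(N, max(Kd_M, 1e-30), dH_cal_per_mol, experiment)
    dv = experiment.injection_volumes_ul
    v0 = experiment.cell_volume_ul
    q_prev = np.concatenate([[0.0], q_cum[:-1]])
    # heat displaced out of the active volume with the injected plug
    dq = q_cum - q_prev + (dv / v0) * (q_cum + q_prev) / 2.0
    return dq * 1e6     # µcal


def fit_one_site(experiment: TitrationExperiment, heat_of_dilution_mode: str = "none",
                 start=None) -> BindingFit:
    """Nonlinear least-squares fit of (N, Kd, dH) to observed injection heats.

    ``heat_of_dilution_mode``: "none" (data already corrected), or "offset"
    (a constant per-injection offset estimated from the last 3 injections is
    subtracted first).  Deterministic given the data and starting values.
    """
    if experiment.heats_ucal is None:
        raise ValueError("experiment carries no observed heats")
    heats = experiment.heats_ucal.copy()
    if len(heats) < 10:
        raise ValueError("need at least 10 informative injections")
    if heat_of_dilution_mode == "offset":
        heats = heats - np.mean(heats[-3:])
    elif heat_of_dilution_mode != "none":
        raise ValueError(f"unknown heat-of-dilution mode {heat_of_dilution_mode!r}")
    span = np.ptp(heats)
    if span < 1e-9 or span < 0.02 * np.max(np.abs(heats)):
        raise ValueError("no binding signal: flat isotherm")

    mt, xt = _working_concentrations(experiment)
    moles_cell = experiment.cell_conc_uM * 1e-6 * experiment.cell_volume_ul * 1e-6
    if start is None:
        dh0 = np.sum(heats) * 1e-6 / moles_cell
        start = (1.0, 1e-7, dh0 if abs(dh0) > 1.0 else -1e4)
    n0, kd0, dh0 = start

    def residuals(p):
        log_n, log_kd, dh = p
        return one_site_heats(np.exp(log_n), np.exp(log_kd), dh, experiment) - heats

    result = least_squares(
        residuals,
        x0=[np.log(n0), np.log(kd0), dh0],
        method="lm",
        xtol=1e-14, ftol=1e-14,
    )
    if not result.success:
        raise RuntimeError(f"one-site fit did not converge: {result.message}")
    n_fit, kd_fit = np.exp(result.x[0]), np.exp(result.x[1])
    dh_fit = result.x[2]

    # standard errors from the Jacobian (delta method for the log-parameters)
    dof = max(1, len(heats) - 3)
    s2 = 2.0 * result.cost / dof
    try:
        cov = s2 * np.linalg.inv(result.jac.T @ result.jac)
        err = np.sqrt(np.diag(cov))
        stderr = {"N": n_fit * err[0], "Kd_M": kd_fit * err[1], "dH": err[2]}
    except np.linalg.LinAlgError:
        stderr = {}

    fit = BindingFit(
        N=float(n_fit), Kd_M=float(kd_fit), dH_cal_per_mol=float(dh_fit),
        temperature_K=experiment.temperature_K, stderr=stderr,
    )
    fit.c_value = float(n_fit * experiment.cell_conc_uM * 1e-6 / kd_fit)
    if not 1.0 <= fit.c_value <= 1000.0:
        warnings.warn(
            f"c-value {fit.c_value:.3g} outside the well-determined range 1-1000; "
            "fitted Kd may be poorly constrained"
        )
    return fit


def kd_from_enthalpy_entropy(dH_cal_per_mol: float, dS_cal_per_mol_K: float,
                             temperature_K: float = T_DEFAULT) -> float:
    """Kd (M) from dG = dH - T dS and Kd = exp(dG / (R T))."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    dG = dH_cal_per_mol - temperature_K * dS_cal_per_mol_K
    return float(np.exp(dG / (R_CAL * temperature_K)))


def fold_change(Kd_a: float, Kd_b: float) -> float:
    """Affinity ratio Kd_a / Kd_b (>1 means b binds tighter)."""
    if Kd_a <= 0 or Kd_b <= 0:
        raise ValueError("dissociation constants must be positive")
    return Kd_a / Kd_b


def consistency_table(temperature_K: float = T_DEFAULT) -> pd.DataFrame:
    """Recompute Kd from (dH, dS) for every preset row and compare to the preset Kd."""
    rows = []
    for name, p in TITRATION_PRESETS.items():
        kd_calc = kd_from_enthalpy_entropy(p["dH_1e4"] * 1e4, p["dS"], temperature_K)
        rows.append({
            "interaction": name,
            "Kd_listed_uM": p["Kd_uM"],
            "Kd_from_dH_dS_uM": kd_calc * 1e6,
            "rel_dev": kd_calc * 1e6 / p["Kd_uM"] - 1.0,
        })
    return pd.DataFrame(rows)


def read_titration_csv(path, cell_volume_ul=CELL_VOLUME_UL, cell_conc_uM=None,
                       syringe_conc_uM=None, temperature_K=T_DEFAULT) -> TitrationExperiment:
    df = pd.read_csv(path, comment="#")
    return TitrationExperiment(
        cell_volume_ul=cell_volume_ul,
        cell_conc_uM=cell_conc_uM,
        syringe_conc_uM=syringe_conc_uM,
        injection_volumes_ul=df["injection_volume_uL"].to_numpy(float),
        heats_ucal=df["heat_ucal"].to_numpy(float),
        temperature_K=temperature_K,
    )


def write_titration_csv(experiment: TitrationExperiment, path) -> None:
    pd.DataFrame({
        "injection_volume_uL": experiment.injection_volumes_ul,
        "heat_ucal": experiment.heats_ucal,
    }).to_csv(path, index=False)
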