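"""Hybrid energy: Bayesian data terms plus structural restraints.

The score that drives refinement combines

* a metainference term on representative SAXS intensities -- an independent
  Gaussian likelihood per data point with a sampled per-point uncertainty
  sigma_i and an overall scale lambda carrying a flat prior on [0.9, 1.1]:

      E_meta = sum_i [ (lambda * f_i - d_i)^2 / (2 sigma_i^2) + log sigma_i ]

  (with a single replica and zero standard error of the mean this is the
  classic inferential-structure-determination limit);

* a linear-in-correlation RDC restraint (see :mod:`loopbind.rdc`);

* harmonic upper-wall structural restraints: ring-centroid interface
  distances (center 3.5 Å, k = 1000 kJ/mol), inter-domain salt-bridge
  charged-group distances (center 4 Å, k = 1000 kJ/mol), and a backbone-RMSD
  wall to a reference for secondary-structure segments (center 0 Å,
  k = 10000 kJ/mol);

* a surrogate physical term (soft-sphere repulsion between non-bonded atoms
  plus harmonic virtual bonds along each chain) that keeps chains intact and
  clash-free in place of a molecular force field.

Energies are in kJ/mol throughout.  The upper-wall convention carries no 1/2
factor: E = k (x - x0)^2 for x > x0, else 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import rdc as rdc_mod
from . import saxs as saxs_mod
from .model_core import AtomicModel, backbone_rmsd, ring_center

__all__ = [
    "MetainferenceTerm",
    "RestraintSet",
    "PhysicalTerm",
    "HybridEnergyModel",
    "upper_wall",
    "metainference_energy",
    "restraint_energy",
    "total_energy",
]

ARG_SIDE_CHAIN_N = ("NE", "NH1", "NH2")
ASP_CARBOXYLATE_O = ("OD1", "OD2")


def upper_wall(value: float, center: float, k: float) -> float:
    """One-sided harmonic wall: 0 below the center, k (value - center)^2 above."""
    if k <= 0:
        raise ValueError("force constant must be positive")
    excess = value - center
    return float(k * excess * excess) if excess > 0 else 0.0


@dataclass
class MetainferenceTerm:
    """Gaussian-likelihood-per-point data term with scale and uncertainty nuisances."""

    data: np.ndarray                    # experimental representative intensities
    sigma: np.ndarray                   # current per-point uncertainties
    scale_bounds: tuple = (0.9, 1.1)    # flat prior on lambda
    base_scale: float = 1.0             # fixed calc->exp scale, estimated once
    fixed_sigma: bool = False           # deterministic mode: never resample sigma

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        lo, hi = self.scale_bounds
        if not lo < hi:
            raise ValueError("scale prior bounds must satisfy lo < hi")


def metainference_energy(forward_values, term: MetainferenceTerm, lam: float,
                         sigma=None) -> float:
    """Negative log Gaussian likelihood (up to constants) of the data term.

    ``forward_values`` are raw forward-model values; they are multiplied by the
    term's fixed base scale and then by the sampled lambda.
    """
    lo, hi = term.scale_bounds
    if not (lo <= lam <= hi):
        raise ValueError(f"scale {lam} outside the flat prior [{lo}, {hi}]")
    sigma = term.sigma if sigma is None else np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    f = lam * term.base_scale * np.asarray(forward_values, dtype=float)
    misfit = (f - term.data) ** 2 / (2.0 * sigma ** 2)
    return float(np.sum(misfit) + np.sum(np.log(sigma)))


@dataclass
class RestraintSet:
    """The structural restraints applied during refinement.

    interface_pairs: ((chainA, resA), (chainB, resB), center Å, k) ring pairs
    salt_bridges:    ((chain, res_arg), (chain, res_asp), center Å, k)
    ss_reference:    reference model for the secondary-structure RMSD wall
    ss_selections:   selection specs (see model_core) of restrained segments
    """

    interface_pairs: list = field(default_factory=list)
    salt_bridges: list = field(default_factory=list)
    ss_reference: AtomicModel | None = None
    ss_selections: list = field(default_factory=list)
    ss_center: float = 0.0
    ss_k: float = 10000.0
    _cache: dict = field(default_factory=dict, repr=False)

    def validate(self, model: AtomicModel) -> None:
        for (ca, ra), (cb, rb), center, k in self.interface_pairs:
            if center < 0 or k <= 0:
                raise ValueError("interface restraint needs center >= 0 and k > 0")
            ring_center(model, (ca, ra))
            ring_center(model, (cb, rb))
        for (ca, ra), (cb, rb), center, k in self.salt_bridges:
            _salt_bridge_distance(model, (ca, ra), (cb, rb))


def _salt_bridge_distance(model, arg_res, asp_res) -> float:
    """Minimum distance between Arg side-chain N and Asp carboxylate O atoms."""
    def _atoms(res, names, label):
        chain, res_id = res
        mask = model.residue_mask(chain, res_id)
        if not mask.any():
            raise KeyError(f"salt-bridge residue {chain}:{res_id} not in model")
        present = [n for n in names if n in set(model.name[mask])]
        if not present:
            raise ValueError(
                f"salt-bridge residue {chain}:{res_id} has none of {names} ({label})"
            )
        return np.array([model.get_coord(chain, res_id, n) for n in present])

    n_atoms = _atoms(arg_res, ARG_SIDE_CHAIN_N, "Arg side-chain N")
    o_atoms = _atoms(asp_res, ASP_CARBOXYLATE_O, "Asp carboxylate O")
    diff = n_atoms[:, None, :] - o_atoms[None, :, :]
    return float(np.sqrt(np.sum(diff ** 2, axis=-1)).min())


def _restraint_indices(model: AtomicModel, restraints: RestraintSet):
    """Precompute atom indices for every restraint (cached per atom layout)."""
    key = (len(model), str(model.name[0]), str(model.name[-1]))
    if restraints._cache.get("key") == key:
        return restraints._cache
    from .model_core import RING_ATOMS, _matched_coords  # local to avoid cycle

    cache = {"key": key, "rings": {}, "bridges": [], "ss": []}
    for (ca, ra), (cb, rb), center, k in restraints.interface_pairs:
        for res in ((ca, ra), (cb, rb)):
            if res in cache["rings"]:
                continue
            chain, res_id = res
            mask = model.residue_mask(chain, res_id)
            res_name = model.res_name[mask][0]
            cache["rings"][res] = np.array(
                [model.atom_index(chain, res_id, a) for a in RING_ATOMS[res_name]]
            )
    for (ca, ra), (cb, rb), center, k in restraints.salt_bridges:
        mask_a = model.residue_mask(ca, ra)
        mask_b = model.residue_mask(cb, rb)
        if not mask_a.any() or not mask_b.any():
            raise KeyError(f"salt-bridge residue {ca}:{ra} or {cb}:{rb} not in model")
        n_idx = np.array([model.atom_index(ca, ra, n)
                          for n in ARG_SIDE_CHAIN_N if n in set(model.name[mask_a])],
                         dtype=int)
        o_idx = np.array([model.atom_index(cb, rb, o)
                          for o in ASP_CARBOXYLATE_O if o in set(model.name[mask_b])],
                         dtype=int)
        if len(n_idx) == 0 or len(o_idx) == 0:
            raise ValueError(
                f"salt-bridge restraint {ca}{ra}-{cb}{rb}: charged-group atoms "
                f"({ARG_SIDE_CHAIN_N} / {ASP_CARBOXYLATE_O}) missing"
            )
        cache["bridges"].append((n_idx, o_idx))
    if restraints.ss_reference is not None:
        for spec in restraints.ss_selections:
            # matched coordinate index arrays; layouts are identical per run
            xa, xb = _matched_coords(model, restraints.ss_reference, spec, True)
            from .model_core import _selection_mask, _backbone_mask
            mask = _selection_mask(model, spec) & _backbone_mask(model)
            idx = np.flatnonzero(mask)
            ref_coords = restraints.ss_reference.coord[
                _selection_mask(restraints.ss_reference, spec)
                & _backbone_mask(restraints.ss_reference)
            ]
            cache["ss"].append((idx, ref_coords))
    restraints._cache.clear()
    restraints._cache.update(cache)
    return restraints._cache


def _fast_rmsd(x, y):
    from scipy.spatial.transform import Rotation

    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(xc, yc)
    return rssd / np.sqrt(len(x))


def restraint_energy(model: AtomicModel, restraints: RestraintSet):
    """Total structural restraint energy and a per-restraint breakdown."""
    cache = _restraint_indices(model, restraints)
    breakdown = {}
    for (ca, ra), (cb, rb), center, k in restraints.interface_pairs:
        c1 = model.coord[cache["rings"][(ca, ra)]].mean(axis=0)
        c2 = model.coord[cache["rings"][(cb, rb)]].mean(axis=0)
        d = float(np.linalg.norm(c1 - c2))
        breakdown[f"interface:{ca}{ra}-{cb}{rb}"] = upper_wall(d, center, k)
    for ((ca, ra), (cb, rb), center, k), (n_idx, o_idx) in zip(
        restraints.salt_bridges, cache["bridges"]
    ):
        diff = model.coord[n_idx][:, None, :] - model.coord[o_idx][None, :, :]
        d = float(np.sqrt(np.sum(diff ** 2, axis=-1)).min())
        breakdown[f"salt_bridge:{ca}{ra}-{cb}{rb}"] = upper_wall(d, center, k)
    if restraints.ss_reference is not None:
        for spec, (idx, ref_coords) in zip(restraints.ss_selections, cache["ss"]):
            rmsd = _fast_rmsd(model.coord[idx], ref_coords)
            breakdown[f"ss_rmsd:{spec}"] = upper_wall(rmsd, restraints.ss_center,
                                                      restraints.ss_k)
    return float(sum(breakdown.values())), breakdown


@dataclass
class PhysicalTerm:
    """Surrogate physical energy: chain-bond springs + soft-sphere repulsion.

    Virtual bonds connect consecutive backbone atoms along each chain with the
    reference model's bond lengths; non-bonded atom pairs closer than
    ``clash_distance`` pay a harmonic penalty.  This stands in for a force
    field only to the extent of preventing chain breaks and interpenetration.
    """

    bond_index: np.ndarray      # (n_bonds, 2) atom indices
    bond_length: np.ndarray     # reference lengths, Å
    k_bond: float = 1000.0      # kJ/mol/Å^2
    clash_distance: float = 2.5  # Å
    k_clash: float = 100.0       # kJ/mol/Å^2
    exclusion: set = field(default_factory=set)  # frozen pairs to skip in clash term
    _excl_codes: np.ndarray | None = field(default=None, repr=False)
    _n_atoms: int = 0

    @classmethod
    def from_model(cls, model: AtomicModel, **kw) -> "PhysicalTerm":
        idx_pairs = []
        for chain in dict.fromkeys(model.chain_id):
            sel = np.flatnonzero(model.chain_id == chain)
            # consecutive atoms in file order within the chain
            for a, b in zip(sel[:-1], sel[1:]):
                idx_pairs.append((int(a), int(b)))
        bond_index = np.array(idx_pairs, dtype=int)
        lengths = np.linalg.norm(
            model.coord[bond_index[:, 0]] - model.coord[bond_index[:, 1]], axis=1
        )
        # contacts already present in the reference are intentional (bonded
        # neighbours, packed interfaces): exclude them from the clash term
        exclusion = {tuple(sorted(p)) for p in idx_pairs}
        clash_d = kw.get("clash_distance", cls.clash_distance)
        tree = cKDTree(model.coord)
        for a, b in tree.query_pairs(clash_d):
            exclusion.add((int(min(a, b)), int(max(a, b))))
        return cls(bond_index=bond_index, bond_length=lengths, exclusion=exclusion, **kw)

    def energy(self, model: AtomicModel) -> float:
        d = np.linalg.norm(
            model.coord[self.bond_index[:, 0]] - model.coord[self.bond_index[:, 1]],
            axis=1,
        )
        e_bond = self.k_bond * np.sum((d - self.bond_length) ** 2)
        n = len(model)
        if self._excl_codes is None or self._n_atoms != n:
            codes = np.fromiter((i * n + j for i, j in self.exclusion), dtype=np.int64,
                                count=len(self.exclusion))
            self._excl_codes = np.sort(codes)
            self._n_atoms = n
        tree = cKDTree(model.coord)
        pairs = tree.query_pairs(self.clash_distance, output_type="ndarray")
        e_clash = 0.0
        if len(pairs):
            codes = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
            if len(self._excl_codes):
                pos = np.minimum(np.searchsorted(self._excl_codes, codes),
                                 len(self._excl_codes) - 1)
                pairs = pairs[self._excl_codes[pos] != codes]
            if len(pairs):
                r = np.linalg.norm(model.coord[pairs[:, 0]] - model.coord[pairs[:, 1]], axis=1)
                e_clash = self.k_clash * np.sum((self.clash_distance - r) ** 2)
        return float(e_bond + e_clash)


@dataclass
class HybridEnergyModel:
    """Composition of the data terms and structural terms with their settings."""

    saxs_term: MetainferenceTerm | None = None
    saxs_q_grid: np.ndarray | None = None
    form_factors: saxs_mod.FormFactorModel | None = None
    saxs_bin_width: float | None = None
    rdc_exp: rdc_mod.RDCSet | None = None
    rdc_tensor: rdc_mod.AlignmentTensor | None = None
    rdc_slope: float = -20000.0
    restraints: RestraintSet | None = None
    physical: PhysicalTerm | None = None
    data_stride: int = 10

    # -- individual terms ------------------------------------------------

    def saxs_forward(self, model) -> np.ndarray:
        curve = saxs_mod.debye_intensity(
            model, self.saxs_q_grid, self.form_factors, bin_width=self.saxs_bin_width
        )
        return curve.I

    def saxs_energy(self, model, lam: float, sigma=None) -> float:
        return metainference_energy(self.saxs_forward(model), self.saxs_term, lam, sigma)

    def rdc_energy(self, model) -> float:
        calc = rdc_mod.back_calculate(model, self.rdc_exp, self.rdc_tensor)
        return rdc_mod.rdc_correlation_energy(calc, self.rdc_exp.D, self.rdc_slope)

    def structural_energy(self, model):
        breakdown = {}
        if self.restraints is not None:
            total, parts = restraint_energy(model, self.restraints)
            breakdown.update(parts)
        if self.physical is not None:
            breakdown["physical"] = self.physical.energy(model)
        return float(sum(breakdown.values())), breakdown


def total_energy(model: AtomicModel, energy: HybridEnergyModel, lam: float = 1.0,
                 sigma=None):
    """Full hybrid energy and its per-term breakdown (kJ/mol)."""
    breakdown = {}
    if energy.saxs_term is not None:
        breakdown["saxs_metainference"] = energy.saxs_energy(model, lam, sigma)
    if energy.rdc_exp is not None:
        breakdown["rdc_correlation"] = energy.rdc_energy(model)
    _, structural = energy.structural_energy(model)
    breakdown.update(structural)
    return float(sum(breakdown.values())), breakdown
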