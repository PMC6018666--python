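"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here, seeded and
deterministic: a toy two-domain protein / single-stranded RNA complex whose
ground truth satisfies every structural restraint exactly, noisy SAXS curves,
RDC sets from a known alignment tensor, one-site titration heats (the
published thermodynamic presets), and CSP/PRE/relaxation profiles.

The toy complex mirrors the tandem-RRM architecture: protein chain A,
residues 1-196, two compact pseudo-domains (1-90 and 108-196) joined by a
17-residue flexible linker (91-107), and a 12-nucleotide single-stranded RNA
chain B (AGUAGAUUAGCA) with one recognition site per domain.  Domains are
serpentine backbone traces (N, CA, C, O plus an amide H per residue); the
restraint-bearing groups -- Phe rings at 17/59/108/150, base rings at RNA
4/5/9/10, Arg/Asp charged atoms at 75/88 and 155/157 -- are named
pseudo-atoms placed so that all restraint centers are satisfied (restraint
energy of the truth is zero).

A single global seed expands into independent per-generator streams through
``subseed(seed, tag)`` (a CRC of the tag mixed into a SeedSequence), so
adding a generator never shifts existing streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import itc as itc_mod
from . import rdc as rdc_mod
from . import saxs as saxs_mod
from .model_core import AtomicModel, RigidGroupPartition, apply_move, backbone_rmsd
from .nmr import (PRESeries, RelaxationSeries, ShiftTable, gamma2_from_distance,
                  ratio_from_gamma2)
from .scoring import RestraintSet
from scipy.spatial.transform import Rotation

__all__ = [
    "ToyComplexSpec",
    "NoiseSpec",
    "subseed",
    "make_toy_complex",
    "simulate_saxs",
    "simulate_rdc",
    "simulate_itc",
    "simulate_nmr",
    "default_alignment_tensor",
    "T1_DELAYS_MS",
    "T1RHO_DELAYS_MS",
]

RNA_SEQUENCE = "AGUAGAUUAGCA"
T1_DELAYS_MS = (21.6, 86.4, 162.0, 248.4, 345.6, 432.0, 518.4, 669.6,
                885.6, 1144.8, 1404.0, 1782.0)
T1RHO_DELAYS_MS = (5.0, 7.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0)

DOMAIN1 = (1, 90)
LINKER = (91, 107)
DOMAIN2 = (108, 196)
PHE_SITES = (17, 59, 108, 150)          # stacked with RNA 4, 5, 9, 10
RNA_SITES = (4, 5, 9, 10)
SALT_BRIDGES = ((75, 155), (88, 157))

CA_SPACING = 3.8
RING_RADIUS = 1.4
RING_STACK = 3.4        # ring-centroid stacking distance (inside the 3.5 wall)


def subseed(seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible stream for one generator."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), zlib.crc32(tag.encode()))))


@dataclass
class NoiseSpec:
    """Gaussian noise: relative (fraction of signal) or absolute level."""

    level: float = 0.02
    relative: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("noise level must be non-negative")


@dataclass
class ToyComplexSpec:
    """Geometry of the toy tandem-domain/RNA complex and its perturbed start."""

    perturbation_rmsd: float = 8.0       # requested start-model backbone RMSD, Å
    rmsd_band: float = 0.10              # realized RMSD within +-10 % of request
    interface_gap: float = 9.0           # CA-CA distance across the salt bridges, Å
    seed: int = 0


# ---------------------------------------------------------------------------
# geometry helpers


def _snake_trace(n: int, nx: int = 5, ny: int = 5, spacing: float = CA_SPACING):
    """Serpentine CA trace through a compact grid block: n points, chain-bonded."""
    pts = np.empty((n, 3))
    per_layer = nx * ny
    for i in range(n):
        layer, rem = divmod(i, per_layer)
        row, col = divmod(rem, nx)
        if layer % 2:
            row = ny - 1 - row
        if (row + layer) % 2:
            col = nx - 1 - col
        pts[i] = (col * spacing, row * spacing, layer * spacing)
    return pts - pts.mean(axis=0)


def _perp(v):
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _hexagon(center, normal):
    e1 = _perp(normal)
    e2 = np.cross(normal / np.linalg.norm(normal), e1)
    ang = np.deg2rad(60.0 * np.arange(6))
    return center + RING_RADIUS * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)


def _amide_direction(res_id: int) -> np.ndarray:
    """Deterministic, residue-specific N-H direction (diverse orientations)."""
    rng = np.random.default_rng(10_000 + res_id)
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class _Builder:
    def __init__(self):
        self.rows = []      # (serial, name, element, res_id, res_name, chain)
        self.coords = []

    def add(self, name, element, res_id, res_name, chain, xyz):
        self.rows.append((len(self.rows) + 1, name, element, res_id, res_name, chain))
        self.coords.append(np.asarray(xyz, dtype=float))

    def build(self, ss_segments, linker):
        serial, name, element, res_id, res_name, chain = map(np.array, zip(*self.rows))
        return AtomicModel(
            serial=serial.astype(int), name=name, element=element,
            res_id=res_id.astype(int), res_name=res_name, chain_id=chain,
            coord=np.array(self.coords), ss_segments=ss_segments, linker=linker,
        )


def _protein_residue_atoms(builder, res_id, res_name, ca, t):
    p = _perp(t)
    p2 = np.cross(t, p)
    n_pos = ca - 0.5 * t + 0.3 * p
    c_pos = ca + 0.5 * t + 0.3 * p
    builder.add("N", "N", res_id, res_name, "A", n_pos)
    builder.add("CA", "C", res_id, res_name, "A", ca)
    builder.add("C", "C", res_id, res_name, "A", c_pos)
    builder.add("O", "O", res_id, res_name, "A", c_pos + 0.55 * p2)
    builder.add("H", "H", res_id, res_name, "A", n_pos + 1.02 * _amide_direction(res_id))


def _residue_names():
    names = {}
    for r in range(1, 197):
        if r in PHE_SITES:
            names[r] = "PHE"
        elif r in (75, 88):
            names[r] = "ARG"
        elif r in (155, 157):
            names[r] = "ASP"
        else:
            names[r] = "ALA"
    return names


def _rotation_candidates():
    cands = [np.eye(3)]
    axes = [np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]),
            np.array([1.0, 1.0, 0]) / np.sqrt(2), np.array([1.0, 0, 1.0]) / np.sqrt(2),
            np.array([0, 1.0, 1.0]) / np.sqrt(2)]
    for axis in axes:
        for ang in range(30, 360, 30):
            cands.append(Rotation.from_rotvec(np.deg2rad(ang) * axis).as_matrix())
    return cands


def make_toy_complex(spec: ToyComplexSpec | None = None):
    """Build (truth, perturbed start, partition, restraints, manifest).

    Deterministic per seed; the truth satisfies every restraint center
    (restraint energy 0) and the start model's backbone RMSD to truth lies
    within ``rmsd_band`` of the requested perturbation.
    """
    if spec is None:
        spec = ToyComplexSpec()
    names = _residue_names()

    # --- domain CA traces
    n1 = DOMAIN1[1] - DOMAIN1[0] + 1
    n2 = DOMAIN2[1] - DOMAIN2[0] + 1
    trace1 = _snake_trace(n1)
    trace2_local = _snake_trace(n2)

    def local_ca(trace, first, res):
        return trace[res - first]

    # --- place domain 2 so the two salt bridges can form: search rotations
    # and interface gaps for the placement with the best interdomain clearance
    # whose Arg/Asp CA-CA distances stay within pseudo-side-chain reach
    from scipy.spatial.distance import cdist

    mid1 = 0.5 * (local_ca(trace1, 1, 75) + local_ca(trace1, 1, 88))
    w = mid1 - trace1.mean(axis=0)
    w = w / np.linalg.norm(w)
    placed2 = None
    best_clearance = -np.inf
    for R2 in _rotation_candidates():
        rotated = trace2_local @ R2.T
        mid2 = 0.5 * (rotated[155 - DOMAIN2[0]] + rotated[157 - DOMAIN2[0]])
        for gap in np.arange(spec.interface_gap, spec.interface_gap + 6.1, 0.5):
            cand = rotated + (mid1 + gap * w - mid2)
            d_a = np.linalg.norm(cand[155 - DOMAIN2[0]] - local_ca(trace1, 1, 75))
            d_b = np.linalg.norm(cand[157 - DOMAIN2[0]] - local_ca(trace1, 1, 88))
            if d_a > 14.0 or d_b > 14.0:
                continue
            clearance = cdist(trace1, cand).min()
            if clearance > best_clearance:
                best_clearance = clearance
                placed2 = cand
    if placed2 is None or best_clearance < 3.5:
        raise ValueError("infeasible toy-complex spec: no domain placement "
                         "satisfies the salt bridges without overlap")

    # --- linker CA path (linear interpolation between domain ends)
    start_pt = local_ca(trace1, 1, DOMAIN1[1])
    end_pt = placed2[0]
    n_link = LINKER[1] - LINKER[0] + 1
    frac = np.arange(1, n_link + 1) / (n_link + 1)
    linker_ca = start_pt + frac[:, None] * (end_pt - start_pt)

    ca_by_res = {}
    for r in range(DOMAIN1[0], DOMAIN1[1] + 1):
        ca_by_res[r] = trace1[r - DOMAIN1[0]]
    for k, r in enumerate(range(LINKER[0], LINKER[1] + 1)):
        ca_by_res[r] = linker_ca[k]
    for r in range(DOMAIN2[0], DOMAIN2[1] + 1):
        ca_by_res[r] = placed2[r - DOMAIN2[0]]

    builder = _Builder()
    all_res = sorted(ca_by_res)
    for r in all_res:
        prev_ca = ca_by_res.get(r - 1, ca_by_res[r] - np.array([CA_SPACING, 0, 0]))
        next_ca = ca_by_res.get(r + 1, ca_by_res[r] + np.array([CA_SPACING, 0, 0]))
        t = next_ca - prev_ca
        t = t / np.linalg.norm(t)
        _protein_residue_atoms(builder, r, names[r], ca_by_res[r], t)

    centroid1 = trace1.mean(axis=0)
    centroid2 = placed2.mean(axis=0)

    # --- Phe rings point outward from their domain's centroid
    phe_centers = {}
    for r in PHE_SITES:
        centroid = centroid1 if r <= DOMAIN1[1] else centroid2
        out = ca_by_res[r] - centroid
        out = out / np.linalg.norm(out)
        center = ca_by_res[r] + 4.5 * out
        phe_centers[r] = (center, out)
        for atom_name, xyz in zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                                  _hexagon(center, out)):
            builder.add(atom_name, "C", r, "PHE", "A", xyz)

    # --- salt-bridge charged pseudo-atoms along the CA-CA connecting lines;
    # reaches split so the N-O distance lands at 3.5 Å (inside the 4 Å wall)
    for arg_res, asp_res in SALT_BRIDGES:
        vec = ca_by_res[asp_res] - ca_by_res[arg_res]
        d = np.linalg.norm(vec)
        u = vec / d
        reach_asp = min(4.0, (d - 3.5) / 2.0)
        reach_arg = d - 3.5 - reach_asp
        if reach_arg > 7.5:
            raise ValueError("infeasible toy-complex spec: salt-bridge residues "
                             "too far apart for pseudo-side-chain reach")
        nh1 = ca_by_res[arg_res] + reach_arg * u
        od1 = ca_by_res[asp_res] - reach_asp * u
        builder.add("NH1", "N", arg_res, "ARG", "A", nh1)
        builder.add("OD1", "O", asp_res, "ASP", "A", od1)
        builder.add("OD2", "O", asp_res, "ASP", "A", od1 + 1.2 * _perp(u))

    # --- RNA: base rings stacked on the Phe rings, backbone threaded through
    base_centers = {}
    for nt, phe in zip(RNA_SITES, PHE_SITES):
        center, out = phe_centers[phe]
        base_centers[nt] = (center + RING_STACK * out, out)

    anchors = {nt: base_centers[nt][0] + 2.6 * base_centers[nt][1] for nt in RNA_SITES}
    d45 = anchors[5] - anchors[4]
    for k, nt in enumerate((3, 2, 1), start=1):
        anchors[nt] = anchors[4] - k * d45
    for k, nt in enumerate((6, 7, 8), start=1):
        anchors[nt] = anchors[5] + (k / 4.0) * (anchors[9] - anchors[5])
    d910 = anchors[10] - anchors[9]
    for k, nt in enumerate((11, 12), start=1):
        anchors[nt] = anchors[10] + k * d910

    for nt in range(1, 13):
        res_name = RNA_SEQUENCE[nt - 1]
        a = anchors[nt]
        nxt = anchors.get(nt + 1, a + d910)
        e1 = nxt - a
        e1 = e1 / np.linalg.norm(e1)
        e2 = _perp(e1)
        offsets = {"P": 0.0 * e1, "O5'": 0.9 * e1 + 0.4 * e2, "C5'": 1.8 * e1,
                   "C4'": 2.7 * e1 + 0.4 * e2, "C3'": 3.6 * e1, "O3'": 4.5 * e1 + 0.4 * e2}
        elements = {"P": "P", "O5'": "O", "C5'": "C", "C4'": "C", "C3'": "C", "O3'": "O"}
        for atom_name, off in offsets.items():
            builder.add(atom_name, elements[atom_name], nt, res_name, "B", a + off)
        if nt in RNA_SITES:
            center, out = base_centers[nt]
            ring_elements = ("N", "C", "N", "C", "C", "C")
            for atom_name, el, xyz in zip(("N1", "C2", "N3", "C4", "C5", "C6"),
                                          ring_elements, _hexagon(center, out)):
                builder.add(atom_name, el, nt, res_name, "B", xyz)

    ss_segments = [("A", 5, 85), ("A", 112, 190)]
    truth = builder.build(ss_segments=ss_segments, linker=("A", *LINKER))

    # --- partition: each domain plus its bound RNA half is one rigid group
    group1 = frozenset({("A", r) for r in range(DOMAIN1[0], DOMAIN1[1] + 1)}
                       | {("B", nt) for nt in range(1, 7)})
    group2 = frozenset({("A", r) for r in range(DOMAIN2[0], DOMAIN2[1] + 1)}
                       | {("B", nt) for nt in range(7, 13)})
    flexible = [("A", r) for r in range(LINKER[0], LINKER[1] + 1)]
    order = ([("A", r) for r in range(DOMAIN1[0], DOMAIN1[1] + 1)]
             + [("B", nt) for nt in range(1, 7)]
             + flexible
             + [("A", r) for r in range(DOMAIN2[0], DOMAIN2[1] + 1)]
             + [("B", nt) for nt in range(7, 13)])
    partition = RigidGroupPartition(
        groups={"RRM1": group1, "RRM2": group2}, flexible=flexible, order=order
    )
    partition.validate(truth)

    restraints = RestraintSet(
        interface_pairs=[(("A", phe), ("B", nt), 3.5, 1000.0)
                         for phe, nt in zip(PHE_SITES, RNA_SITES)],
        salt_bridges=[(("A", a), ("A", b), 4.0, 1000.0) for a, b in SALT_BRIDGES],
        ss_reference=truth,
        ss_selections=[f"{c}:{lo}-{hi}" for c, lo, hi in ss_segments],
        ss_center=0.0,
        ss_k=10000.0,
    )
    restraints.validate(truth)

    start, realized = _perturb(truth, partition, spec)

    counts = {}
    for c in dict.fromkeys(truth.chain_id):
        counts[c] = int(np.sum(truth.chain_id == c))
    manifest = {
        "seed": spec.seed,
        "n_atoms": len(truth),
        "atoms_per_chain": counts,
        "rna_sequence": RNA_SEQUENCE,
        "domains": {"RRM1": DOMAIN1, "RRM2": DOMAIN2, "linker": LINKER},
        "requested_perturbation_rmsd": spec.perturbation_rmsd,
        "realized_perturbation_rmsd": realized,
    }
    return truth, start, partition, restraints, manifest


def _perturb(truth, partition, spec: ToyComplexSpec):
    """Rigid perturbation of the second domain group to a requested RMSD band.

    Perturbation directions are drawn until the displaced start model is
    clash-free (a physically plausible starting structure), keeping the
    realized backbone RMSD inside the requested band.
    """
    from .model_core import apply_torsion
    from .scoring import PhysicalTerm

    rng = subseed(spec.seed, "perturb")
    target = spec.perturbation_rmsd
    clash_only = PhysicalTerm.from_model(truth, k_bond=0.0)
    best = None
    for _attempt in range(40):
        deltas = rng.uniform(-30.0, 30.0, size=len(partition.flexible))

        def realize(s):
            moved = truth
            for residue, delta in zip(partition.flexible, deltas):
                moved = apply_torsion(moved, partition, residue, s * delta)
            return moved, backbone_rmsd(truth, moved)

        lo, hi = 0.0, 1.0
        moved, r = realize(hi)
        while r < target and hi < 8.0:
            hi *= 2.0
            moved, r = realize(hi)
        if r < target:
            continue
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            moved, r = realize(mid)
            if abs(r - target) <= spec.rmsd_band * target * 0.5:
                break
            if r < target:
                lo = mid
            else:
                hi = mid
        if abs(r - target) > spec.rmsd_band * target:
            continue
        clash = clash_only.energy(moved)
        if best is None or clash < best[2]:
            best = (moved, float(r), clash)
        if clash < 100.0:
            return moved, float(r)
    if best is None:
        raise ValueError("infeasible perturbation request")
    return best[0], best[1]


# ---------------------------------------------------------------------------
# forward simulators


def simulate_saxs(model, q_grid, noise: NoiseSpec | None = None,
                  form_factors=None, bin_width=None) -> saxs_mod.ScatteringCurve:
    """Debye curve of the model plus seeded Gaussian noise; sigma = noise level."""
    curve = saxs_mod.debye_intensity(model, q_grid, form_factors, bin_width=bin_width)
    if noise is None or noise.level == 0:
        return curve
    rng = subseed(noise.seed, "saxs")
    sigma = noise.level * np.abs(curve.I) if noise.relative else np.full(len(curve), noise.level)
    return saxs_mod.ScatteringCurve(q=curve.q, I=curve.I + rng.normal(size=len(curve)) * sigma,
                                    sigma=sigma)


def default_alignment_tensor(magnitude_hz: float = 10.0) -> rdc_mod.AlignmentTensor:
    """A fixed rhombic alignment tensor of typical amide-RDC magnitude."""
    return rdc_mod.AlignmentTensor.from_components(
        0.35 * magnitude_hz, -0.65 * magnitude_hz, 0.25 * magnitude_hz,
        0.15 * magnitude_hz, -0.10 * magnitude_hz,
    )


def simulate_rdc(model, tensor=None, residues=None, noise: NoiseSpec | None = None
                 ) -> rdc_mod.RDCSet:
    """Amide N-H couplings back-calculated from a known tensor, plus noise."""
    if tensor is None:
        tensor = default_alignment_tensor()
    if residues is None:
        residues = sorted({int(r) for c, r in zip(model.chain_id, model.res_id) if c == "A"})
    n = len(residues)
    rdcs = rdc_mod.RDCSet(
        chain=np.array(["A"] * n), res_id=np.array(residues),
        atom1=np.array(["N"] * n), atom2=np.array(["H"] * n),
        D=np.zeros(n), sigma=None,
    )
    rdcs.D = rdc_mod.back_calculate(model, rdcs, tensor)
    if noise is not None and noise.level > 0:
        rng = subseed(noise.seed, "rdc")
        scale = float(np.std(rdcs.D)) if noise.relative else 1.0
        sigma = noise.level * scale
        rdcs.D = rdcs.D + rng.normal(size=n) * sigma
        rdcs.sigma = np.full(n, max(sigma, 1e-6))
    return rdcs


ITC_DESIGNS = {"20x2": (20, 2.0), "26x1.5": (26, 1.5)}


def simulate_itc(preset="UP1+12-mer", design="26x1.5", noise: NoiseSpec | None = None,
                 cell_conc_uM: float = 20.0, syringe_conc_uM: float = 300.0):
    """One-site titration heats for a preset (or explicit parameter dict).

    Returns (TitrationExperiment, manifest).  Zero-noise heats equal the
    one-site forward model exactly.  Noise is Gaussian with level relative to
    the largest injection heat.
    """
    if isinstance(preset, str):
        try:
            params = itc_mod.TITRATION_PRESETS[preset]
        except KeyError:
            raise KeyError(
                f"unknown preset {preset!r}; available: {sorted(itc_mod.TITRATION_PRESETS)}"
            ) from None
        theta = {"N": params["N"], "Kd_M": params["Kd_uM"] * 1e-6,
                 "dH": params["dH_1e4"] * 1e4}
    else:
        theta = dict(preset)
    if design not in ITC_DESIGNS:
        raise KeyError(f"unknown design {design!r}; available: {sorted(ITC_DESIGNS)}")
    n_inj, vol = ITC_DESIGNS[design]
    experiment = itc_mod.TitrationExperiment(
        cell_volume_ul=itc_mod.CELL_VOLUME_UL,
        cell_conc_uM=cell_conc_uM,
        syringe_conc_uM=syringe_conc_uM,
        injection_volumes_ul=np.full(n_inj, vol),
    )
    heats = itc_mod.one_site_heats(theta["N"], theta["Kd_M"], theta["dH"], experiment)
    if noise is not None and noise.level > 0:
        rng = subseed(noise.seed, "itc")
        sigma = noise.level * np.abs(heats) if noise.relative \
            else np.full(len(heats), noise.level)
        heats = heats + rng.normal(size=len(heats)) * sigma
    experiment.heats_ucal = heats
    manifest = {"preset": preset if isinstance(preset, str) else "custom",
                "truth": theta, "design": design,
                "cell_conc_uM": cell_conc_uM, "syringe_conc_uM": syringe_conc_uM}
    return experiment, manifest


def simulate_nmr(model, label_site=("A", 66), noise: NoiseSpec | None = None,
                 t2_dia: float = 15.0, evolution_time_s: float = 0.010,
                 tau_c_s: float = 5e-9, state: str = "free"):
    """Shift tables, a PRE profile and a relaxation series for one model.

    Returns (free ShiftTable, bound ShiftTable, PRESeries, RelaxationSeries,
    manifest).  The PRE profile is computed from the model's label-site /
    amide-proton distances through the r^-6 forward model, so zero-noise
    inversion recovers the generator distances.
    """
    rng = subseed(noise.seed if noise else 0, "nmr")
    level = noise.level if noise else 0.0
    chain, label_res = label_site
    label_pos = model.get_coord(chain, label_res, "CA")

    residues = sorted({int(r) for c, r in zip(model.chain_id, model.res_id) if c == chain})
    n = len(residues)

    # ---- shift tables: interface residues move on binding
    base_h = 8.3 + 0.5 * np.sin(0.3 * np.arange(n))
    base_n = 119.0 + 4.0 * np.cos(0.2 * np.arange(n))
    interface = np.array([r in set(PHE_SITES) or min(abs(r - p) for p in PHE_SITES) <= 2
                          for r in residues])
    free = ShiftTable(res_id=np.array(residues), shift_h=base_h, shift_n=base_n,
                      state="free")
    dh = np.where(interface, 0.25, 0.0) + level * rng.normal(size=n)
    dn = np.where(interface, 1.5, 0.0) + 5.0 * level * rng.normal(size=n)
    broadened = np.array([LINKER[0] <= r <= LINKER[1] for r in residues]) & interface
    bound = ShiftTable(res_id=np.array(residues), shift_h=base_h + dh,
                       shift_n=base_n + dn, state="bound", broadened=broadened)

    # ---- PRE ratios from true label distances
    distances = np.empty(n)
    for k, r in enumerate(residues):
        try:
            pos = model.get_coord(chain, r, "H")
        except KeyError:
            pos = model.get_coord(chain, r, "N")
        distances[k] = np.linalg.norm(pos - label_pos)
    gamma2 = np.array([gamma2_from_distance(d, tau_c_s) for d in distances])
    ratios = np.array([ratio_from_gamma2(g, t2_dia, evolution_time_s) for g in gamma2])
    if level > 0:
        ratios = np.clip(ratios + level * rng.normal(size=n), 0.0, 1.2)
    pre = PRESeries(res_id=np.array(residues), ratio=ratios, label_site=label_res,
                    r2_dia=t2_dia, evolution_time_s=evolution_time_s, state=state)

    # ---- T1-style relaxation decays, two duplicated delays
    t_true = 500.0 + 150.0 * np.sin(0.1 * np.arange(n))
    delays = np.array(list(T1_DELAYS_MS) + [T1_DELAYS_MS[1], T1_DELAYS_MS[5]])
    duplicated = np.zeros(len(delays), dtype=bool)
    duplicated[-2:] = True
    intensities = np.exp(-delays[None, :] / t_true[:, None])
    if level > 0:
        intensities = np.abs(intensities * (1.0 + level * rng.normal(size=intensities.shape)))
    relax = RelaxationSeries(res_id=np.array(residues), delays_ms=delays,
                             intensities=intensities, duplicated=duplicated)

    manifest = {
        "label_site": label_site,
        "label_distances_A": distances,
        "relaxation_T_ms": t_true,
        "interface_residues": [int(r) for r, flag in zip(residues, interface) if flag],
        "broadened_residues": [int(r) for r, flag in zip(residues, broadened) if flag],
    }
    return free, bound, pre, relax, manifest
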