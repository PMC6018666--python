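"""Residual dipolar coupling analysis.

An amide N-H RDC measured in a weakly aligning medium is, to first order,

    D_i = b_i^T S b_i

where b_i is the unit N->H bond vector in the molecular frame and S the
traceless symmetric Saupe alignment tensor.  The dipolar prefactor (the
gyromagnetic constants and the N-H bond length) is folded into the fitted
tensor scale, so couplings stay in Hz and the tensor absorbs units.

Fitting is the standard linear least-squares (SVD) inversion over the five
independent tensor components; quality is reported as the Q-factor,

    Q = sqrt( sum (D_calc - D_exp)^2 / sum D_exp^2 ),

and the Pearson correlation.  The refinement restraint used by the annealing
sampler is linear in the correlation between (replica-averaged) calculated
and experimental couplings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RDCSet",
    "AlignmentTensor",
    "bond_vectors",
    "fit_tensor_svd",
    "back_calculate",
    "replica_average",
    "rdc_correlation_energy",
    "read_rdc_table",
    "write_rdc_table",
]


@dataclass
class RDCSet:
    """Measured couplings: one record per (chain, residue, atom pair)."""

    chain: np.ndarray
    res_id: np.ndarray
    atom1: np.ndarray       # e.g. "N"
    atom2: np.ndarray       # e.g. "H"
    D: np.ndarray           # Hz
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        self.res_id = np.asarray(self.res_id, dtype=int)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("uncertainties must be positive")

    def __len__(self):
        return len(self.D)

    def bonds(self):
        return list(zip(self.chain, self.res_id.tolist(), self.atom1, self.atom2))


@dataclass
class AlignmentTensor:
    """Traceless symmetric Saupe matrix with derived anisotropy parameters."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("Saupe matrix must be symmetric")
        if abs(np.trace(self.matrix)) > 1e-10 * max(1.0, np.abs(self.matrix).max()):
            raise ValueError("Saupe matrix must be traceless")

    @classmethod
    def from_components(cls, sxx, syy, sxy, sxz, syz):
        szz = -sxx - syy
        return cls(np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]]))

    @property
    def components(self):
        m = self.matrix
        return np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])

    @property
    def eigenvalues(self):
        """Eigenvalues ordered by increasing magnitude (|Axx| <= |Ayy| <= |Azz|)."""
        vals = np.linalg.eigvalsh(self.matrix)
        return vals[np.argsort(np.abs(vals))]

    @property
    def axial(self):
        """Axial component Da = Azz / 2."""
        return self.eigenvalues[2] / 2.0

    @property
    def rhombicity(self):
        axx, ayy, azz = self.eigenvalues
        return (ayy - axx) / azz * (2.0 / 3.0)


def bond_vectors(model, rdcs: RDCSet) -> np.ndarray:
    """Unit bond vectors for each RDC record, looked up in the model.

    Atom indices are cached on the RDC set per atom layout, since the same
    couplings are evaluated against many conformations during refinement.
    """
    key = (len(model), str(model.name[0]), str(model.name[-1]))
    cached = getattr(rdcs, "_bond_idx", None)
    if cached is None or cached[0] != key:
        idx = np.empty((len(rdcs), 2), dtype=int)
        missing = []
        for k, (chain, res_id, a1, a2) in enumerate(rdcs.bonds()):
            try:
                idx[k, 0] = model.atom_index(chain, res_id, a1)
                idx[k, 1] = model.atom_index(chain, res_id, a2)
            except KeyError:
                missing.append((chain, res_id, a1, a2))
        if missing:
            raise KeyError(f"bond atoms missing from model: {missing}")
        rdcs._bond_idx = (key, idx)
        cached = rdcs._bond_idx
    idx = cached[1]
    vecs = model.coord[idx[:, 1]] - model.coord[idx[:, 0]]
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def _design_matrix(b: np.ndarray) -> np.ndarray:
    x, y, z = b[:, 0], b[:, 1], b[:, 2]
    return np.column_stack([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z])


def back_calculate(model, rdcs: RDCSet, tensor: AlignmentTensor) -> np.ndarray:
    """D_calc = b^T S b per bond (Hz, with the prefactor inside S)."""
    b = bond_vectors(model, rdcs)
    return np.einsum("ni,ij,nj->n", b, tensor.matrix, b)


def fit_tensor_svd(model, rdcs: RDCSet):
    """Least-squares Saupe tensor for a model and a set of measured couplings.

    Returns (tensor, back-calculated couplings, Q-factor, Pearson r).
    Requires at least 5 bonds whose orientational design matrix has rank 5.
    """
    if len(rdcs) < 5:
        raise ValueError("under-determined tensor: need at least 5 bonds")
    b = bond_vectors(model, rdcs)
    A = _design_matrix(b)
    if np.linalg.matrix_rank(A, tol=1e-8) < 5:
        raise ValueError("under-determined tensor: design matrix rank < 5")
    comps, *_ = np.linalg.lstsq(A, rdcs.D, rcond=None)
    tensor = AlignmentTensor.from_components(*comps)
    d_calc = A @ comps
    resid = d_calc - rdcs.D
    q = float(np.sqrt(np.sum(resid ** 2) / np.sum(rdcs.D ** 2)))
    if np.std(d_calc) == 0 or np.std(rdcs.D) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(d_calc, rdcs.D)[0, 1])
    return tensor, d_calc, q, r


def replica_average(couplings_replica1, couplings_replica2, bonds1=None, bonds2=None):
    """Element-wise mean of per-bond couplings from two replicas."""
    c1 = np.asarray(couplings_replica1, dtype=float)
    c2 = np.asarray(couplings_replica2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("replicas have different numbers of bonds")
    if bonds1 is not None and bonds2 is not None and list(bonds1) != list(bonds2):
        raise ValueError("replicas carry different bond lists")
    return 0.5 * (c1 + c2)


def rdc_correlation_energy(calc_avg, exp, slope_kj_per_mol: float = -20000.0) -> float:
    """Linear-in-correlation restraint energy, E = slope * corr(calc, exp).

    With the default slope of -20000 kJ/mol the energy is minimised at
    perfect correlation, where E = -20000 kJ/mol.
    """
    calc_avg = np.asarray(calc_avg, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if len(calc_avg) < 3:
        raise ValueError("need at least 3 bonds for a correlation restraint")
    if np.std(calc_avg) == 0 or np.std(exp) == 0:
        raise ValueError("zero variance in couplings; correlation undefined")
    r = float(np.corrcoef(calc_avg, exp)[0, 1])
    return slope_kj_per_mol * r


# ---------------------------------------------------------------------------
# Table I/O: text columns "chain resid atom1 atom2 D sigma", '#' comments


def read_rdc_table(path) -> RDCSet:
    df = pd.read_csv(
        path, sep=r"\s+", comment="#",
        names=["chain", "resid", "atom1", "atom2", "D", "sigma"],
        dtype={"chain": str},
    )
    sigma = df["sigma"].to_numpy(float) if df["sigma"].notna().all() else None
    return RDCSet(
        chain=df["chain"].to_numpy(),
        res_id=df["resid"].to_numpy(int),
        atom1=df["atom1"].to_numpy(),
        atom2=df["atom2"].to_numpy(),
        D=df["D"].to_numpy(float),
        sigma=sigma,
    )


def write_rdc_table(rdcs: RDCSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# chain resid atom1 atom2 D sigma\n")
        sigma = rdcs.sigma if rdcs.sigma is not None else np.full(len(rdcs), 1.0)
        for c, r, a1, a2, d, s in zip(
            rdcs.chain, rdcs.res_id, rdcs.atom1, rdcs.atom2, rdcs.D, sigma
        ):
            fh.write(f"{c} {r} {a1} {a2} {d:.8e} {s:.6e}\n")
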