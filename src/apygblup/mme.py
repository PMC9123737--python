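"""Single-trait ssGBLUP mixed-model equations and solver.

Henderson's MME for the model y = Xb + sum_k W_k u_k + W_a a + e with
uncorrelated extra random effects (litter, optionally pen) and an additive
effect for every pedigree animal with covariance H sigma_a^2:

    [ X'X      X'W               ] [ b ]   [ X'y ]
    [ W'X  W'W + Sigma^-1 lambda ] [ u ] = [ W'y ],

where the additive block receives H^-1 * lambda_a (lambda_a =
sigma_e^2 / sigma_a^2) and each extra random effect an identity times its
own ratio.  The system is solved by preconditioned conjugate gradients with
a diagonal (Jacobi) preconditioner; convergence is declared when the
squared relative residual ||r||^2 / ||rhs||^2 falls below the tolerance
(1e-12 by default, the convention of large-scale animal-breeding solvers).

Identifiability: the first observed level of each categorical fixed effect
is constrained to zero; an intercept is always included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .apycore import HInverse

__all__ = [
    "RandomEffect",
    "ModelSpec",
    "MMESystem",
    "Solutions",
    "assemble_mme",
    "pcg_solve",
    "solve_ssgblup",
]


@dataclass(frozen=True)
class RandomEffect:
    name: str
    column: str
    variance: float

    def __post_init__(self):
        if self.variance <= 0:
            raise ValueError(f"variance of {self.name} must be > 0")


@dataclass(frozen=True)
class ModelSpec:
    """Single-trait animal model specification.

    ``fixed_effects`` are categorical columns of the phenotype table;
    ``covariates`` enter as regressions.  Variances are inputs (variance
    ratios are treated as known, as in routine genetic evaluation).
    """

    fixed_effects: tuple = ("sex",)
    covariates: tuple = ()
    random_effects: tuple = ()
    additive_variance: float = 0.20
    residual_variance: float = 0.70

    def __post_init__(self):
        if self.additive_variance <= 0 or self.residual_variance <= 0:
            raise ValueError("variances must be > 0")

    @property
    def h2(self) -> float:
        total = (self.additive_variance + self.residual_variance
                 + sum(r.variance for r in self.random_effects))
        return self.additive_variance / total

    @property
    def lambda_a(self) -> float:
        return self.residual_variance / self.additive_variance

    @classmethod
    def from_simulation(cls, config) -> "ModelSpec":
        """Model matching the synthetic generator's variance partition
        (unit phenotypic variance)."""
        randoms = []
        if config.litter_var_frac > 0:
            randoms.append(RandomEffect("litter", "litter",
                                        config.litter_var_frac))
        if config.pen_var_frac > 0:
            randoms.append(RandomEffect("pen", "pen", config.pen_var_frac))
        resid = 1.0 - config.h2 - config.litter_var_frac - config.pen_var_frac
        return cls(fixed_effects=("sex",), random_effects=tuple(randoms),
                   additive_variance=config.h2, residual_variance=resid)


@dataclass
class MMESystem:
    coefficient: sp.csr_matrix
    rhs: np.ndarray
    block_index: dict            # effect name -> (slice, labels)
    design: dict                 # effect name -> incidence matrix
    n_records: int

    @property
    def n_equations(self) -> int:
        return self.coefficient.shape[0]


@dataclass
class Solutions:
    vector: np.ndarray
    block_index: dict
    n_iter: int
    converged: bool
    meta: dict = field(default_factory=dict)

    def block(self, name: str) -> pd.Series:
        sl, labels = self.block_index[name]
        return pd.Series(self.vector[sl], index=labels)

    @property
    def b_hat(self) -> pd.Series:
        return self.block("fixed")

    @property
    def u_hat(self) -> pd.Series:
        """GEBV for every pedigree animal."""
        return self.block("additive")


def _fixed_design(records: pd.DataFrame, model: ModelSpec):
    """Intercept + dummy columns (first observed level of each categorical
    effect dropped) + covariates."""
    nrec = len(records)
    cols = [np.ones(nrec)]
    labels = ["intercept"]
    for eff in model.fixed_effects:
        levels = sorted(pd.unique(records[eff]))
        if len(levels) < 2:
            warnings.warn(f"fixed effect {eff!r} has a single observed "
                          "level; dropped (confounded with intercept)")
            continue
        for lev in levels[1:]:
            cols.append((records[eff] == lev).to_numpy(dtype=float))
            labels.append(f"{eff}:{lev}")
    for cov in model.covariates:
        cols.append(records[cov].to_numpy(dtype=float))
        labels.append(cov)
    return np.column_stack(cols), labels


def _incidence(records: pd.DataFrame, column: str, levels) -> sp.csr_matrix:
    level_pos = {lev: j for j, lev in enumerate(levels)}
    rows = np.arange(len(records))
    cols = records[column].map(level_pos).to_numpy()
    data = np.ones(len(records))
    return sp.csr_matrix((data, (rows, cols)),
                         shape=(len(records), len(levels)))


def assemble_mme(phenotypes: pd.DataFrame, model: ModelSpec,
                 h_inv: HInverse, training_mask=None) -> MMESystem:
    """Build the sparse MME from a phenotype table and H^-1.

    ``training_mask`` is a boolean mask over the phenotype rows selecting
    the records that enter the right-hand side (validation animals keep
    their equations but contribute no data).
    """
    if training_mask is None:
        training_mask = np.ones(len(phenotypes), dtype=bool)
    records = phenotypes.loc[np.asarray(training_mask)]
    if records.empty:
        raise ValueError("empty training set")
    missing = np.setdiff1d(records["animal"].to_numpy(), h_inv.ids)
    if missing.size:
        raise ValueError(f"recorded animals missing from pedigree/H: "
                         f"{missing[:5]}")
    y = records["y"].to_numpy(dtype=float)

    X, fixed_labels = _fixed_design(records, model)
    Xs = sp.csr_matrix(X)
    blocks = [("fixed", Xs, None, fixed_labels)]
    for eff in model.random_effects:
        levels = sorted(pd.unique(records[eff.column]))
        W = _incidence(records, eff.column, levels)
        lam = model.residual_variance / eff.variance
        blocks.append((eff.name, W, sp.identity(len(levels)) * lam, levels))
    animal_ids = list(h_inv.ids)
    Wa = _incidence(records, "animal", animal_ids)
    blocks.append(("additive", Wa, h_inv.matrix * model.lambda_a,
                   animal_ids))

    k = len(blocks)
    C = [[None] * k for _ in range(k)]
    rhs_parts = []
    block_index = {}
    offset = 0
    for i, (name_i, Wi, Pi, labels_i) in enumerate(blocks):
        for j, (name_j, Wj, Pj, _) in enumerate(blocks):
            if j < i:
                continue
            block = (Wi.T @ Wj).tocsr()
            if i == j and Pi is not None:
                block = (block + Pi).tocsr()
            C[i][j] = block
            if i != j:
                C[j][i] = block.T
        rhs_parts.append(Wi.T @ y)
        size = Wi.shape[1]
        block_index[name_i] = (slice(offset, offset + size), labels_i)
        offset += size
    coefficient = sp.bmat(C, format="csr")
    rhs = np.concatenate(rhs_parts)
    design = {name: W for name, W, _, _ in blocks}
    return MMESystem(coefficient, rhs, block_index, design, len(records))


def pcg_solve(system: MMESystem, tol: float = 1e-12,
              max_iter: int = 5000) -> Solutions:
    """Jacobi-preconditioned conjugate gradients on the MME.

    Stops when ||r||^2 / ||rhs||^2 <= tol.  Returns the solution with the
    iteration count; a non-converged solve is returned with a warning and
    ``converged=False``.
    """
    C = system.coefficient
    b = system.rhs
    diag = C.diagonal().copy()
    diag[diag <= 0] = 1.0
    inv_diag = 1.0 / diag

    x = np.zeros_like(b)
    r = b.copy()
    b_norm2 = float(b @ b)
    if b_norm2 == 0.0:
        return Solutions(x, system.block_index, 1, True)
    z = inv_diag * r
    p = z.copy()
    rz = float(r @ z)
    n_iter = 0
    converged = False
    while n_iter < max_iter:
        n_iter += 1
        Cp = C @ p
        alpha = rz / float(p @ Cp)
        x += alpha * p
        r -= alpha * Cp
        if float(r @ r) / b_norm2 <= tol:
            converged = True
            break
        z = inv_diag * r
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    if not converged:
        warnings.warn(f"PCG did not reach tol={tol:g} within "
                      f"{max_iter} iterations")
    return Solutions(x, system.block_index, n_iter, converged)


def solve_ssgblup(phenotypes: pd.DataFrame, model: ModelSpec,
                  h_inv: HInverse, training_mask=None,
                  tol: float = 1e-12, max_iter: int = 5000,
                  meta: dict | None = None) -> Solutions:
    """Assemble and solve the single-trait ssGBLUP MME."""
    system = assemble_mme(phenotypes, model, h_inv, training_mask)
    sol = pcg_solve(system, tol=tol, max_iter=max_iter)
    sol.meta = dict(meta or {})
    sol.meta.setdefault("n_records", system.n_records)
    return sol
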