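"""Pedigree-based BLUP baseline (animal model, no marker data).

    y = 1 mu + Z u + e,  Var(u) = A sigma2_g,  Var(e) = I sigma2_e

solved exactly from Henderson's mixed-model equations with the sparse
inverse of the numerator relationship matrix; EBVs are produced for every
pedigree member, including unphenotyped validation animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .pedigree import Pedigree, build_A_inverse
from .simulation import StudyDataset

__all__ = ["PblupFit", "solve_pblup"]


@dataclass
class PblupFit:
    mu_hat: float
    u_hat: np.ndarray  # EBV per pedigree member, pedigree order

    #: alias so evaluation code can treat PBLUP like a genomic fit
    @property
    def gebv(self) -> np.ndarray:
        return self.u_hat


def solve_pblup(
    dataset_or_pedigree,
    sigma2_g: float | None = None,
    sigma2_e: float | None = None,
    phenotype: np.ndarray | None = None,
) -> PblupFit:
    """BLUP of breeding values from phenotypes and pedigree alone.

    Accepts a :class:`~ssgp.simulation.StudyDataset` (variances taken from
    its trait architecture) or an explicit (pedigree, variances,
    phenotype-with-NaNs) triple.
    """
    if isinstance(dataset_or_pedigree, StudyDataset):
        ds = dataset_or_pedigree
        pedigree = ds.pedigree
        sigma2_g = ds.trait.sigma2_g if sigma2_g is None else sigma2_g
        sigma2_e = ds.trait.sigma2_e if sigma2_e is None else sigma2_e
        phenotype = ds.phenotype if phenotype is None else phenotype
    else:
        pedigree = dataset_or_pedigree
        if sigma2_g is None or sigma2_e is None or phenotype is None:
            raise ValueError("pedigree input requires sigma2_g, sigma2_e and phenotype")
    if not isinstance(pedigree, Pedigree):
        raise TypeError("expected a Pedigree or StudyDataset")

    N = pedigree.n
    obs = np.flatnonzero(~np.isnan(np.asarray(phenotype, dtype=float)))
    y = np.asarray(phenotype, dtype=float)[obs]
    if obs.size == 0:
        return PblupFit(mu_hat=0.0, u_hat=np.zeros(N))
    lam = sigma2_e / sigma2_g
    A_inv = build_A_inverse(pedigree)

    n = obs.size
    Z = sparse.coo_matrix((np.ones(n), (np.arange(n), obs)), shape=(n, N)).tocsr()
    ZtZ = sparse.diags(np.asarray(Z.sum(axis=0)).ravel())
    top = sparse.hstack([sparse.coo_matrix([[float(n)]]), Z.sum(axis=0)])
    bottom = sparse.hstack([Z.T @ np.ones((n, 1)), ZtZ + lam * A_inv])
    lhs = sparse.vstack([top, bottom]).tocsc()
    rhs = np.concatenate([[y.sum()], Z.T @ y])
    try:
        sol = splu(lhs).solve(rhs)
    except RuntimeError as e:
        raise np.linalg.LinAlgError(f"singular PBLUP system: {e}") from None
    if not np.all(np.isfinite(sol)):
        raise np.linalg.LinAlgError("singular PBLUP system (non-finite solution)")
    return PblupFit(mu_hat=float(sol[0]), u_hat=sol[1:])
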