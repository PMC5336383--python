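"""Age x frailty classified absorbing Markov chain via the vec-permutation model.

The cohort's state is an abundance array N with g frailty rows and omega age
columns; the population vector is vec(N), so entries are grouped in age
blocks of g frailty classes each ("frailty varies fastest").  Survival of
frailty class i is an omega x omega matrix U_i with the age-specific
survival probabilities exp(-mu(z_i, age)) on the first subdiagonal; frailty
transitions within age class j are a column-stochastic g x g matrix D_j
(the identity when frailty is fixed for life).  The joint projection matrix
on the age-block ordering is

    U_tilde = D K' U K          (K = K_{g,omega}, the vec-permutation matrix)

which reduces to K' U K for fixed frailty.  U_tilde is substochastic (the
deficit of each column sum is that state's death probability) and nilpotent
(age always advances; nobody survives the last age class), so it is the
transient matrix of an absorbing Markov chain with death absorbing.

Survival over the age interval [j, j+1) uses exp(-hazard at the interval's
start): the omega - 1 subdiagonal transitions use model ages 0..omega-2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .ggm import FrailtyDiscretization, GGMParams, gm_hazard

__all__ = [
    "AgeFrailtyModel",
    "vec_permutation_matrix",
    "survival_matrix",
    "build_projection_matrix",
]

#: Ordering convention for the joint population vector: vec of the
#: g x omega abundance array, i.e. for each age class j a contiguous block
#: of g frailty-class entries.  Every extraction operator in the package
#: assumes this ordering.
ORDERING = "age-blocks-of-frailty (vec of g x omega array)"


@dataclass(frozen=True)
class AgeFrailtyModel:
    """The transient matrix of the age x frailty chain with its block structure."""

    U_tilde: sparse.csr_matrix
    omega: int
    g: int
    ordering: str = ORDERING

    def __post_init__(self) -> None:
        n = self.omega * self.g
        if self.U_tilde.shape != (n, n):
            raise ValueError(
                f"U_tilde must be {n}x{n} for omega={self.omega}, g={self.g}"
            )

    @property
    def n_states(self) -> int:
        return self.omega * self.g


def vec_permutation_matrix(g: int, omega: int) -> sparse.csr_matrix:
    """The vec-permutation (commutation) matrix K_{g,omega}.

    Satisfies ``K @ vec(A) == vec(A.T)`` for every g x omega array A, where
    vec stacks columns.  It converts the age-block ordering (vec N) into the
    frailty-block ordering (vec N') on which the block-diagonal survival
    matrix acts.
    """
    if g < 1 or omega < 1:
        raise ValueError("g and omega must be >= 1")
    n = g * omega
    i_frail, j_age = np.meshgrid(np.arange(g), np.arange(omega), indexing="ij")
    rows = (i_frail * omega + j_age).ravel()  # position of A[i,j] in vec(A.T)
    cols = (j_age * g + i_frail).ravel()      # position of A[i,j] in vec(A)
    return sparse.csr_matrix(
        (np.ones(n), (rows, cols)), shape=(n, n)
    )


def survival_matrix(z: float, params: GGMParams, omega: int) -> sparse.csr_matrix:
    """Age-only survival matrix U_i for one frailty class.

    Subdiagonal entry (j+1, j) is exp(-mu(z, j-1)) for j = 1..omega-1
    (model ages 0..omega-2); the last age class has no outgoing survival.
    """
    if z <= 0:
        raise ValueError("frailty z must be > 0")
    if omega < 1:
        raise ValueError("omega must be >= 1")
    if omega == 1:
        return sparse.csr_matrix((1, 1))
    ages = np.arange(omega - 1, dtype=float)
    p = np.exp(-gm_hazard(ages, z, params))
    return sparse.diags(p, offsets=-1, shape=(omega, omega), format="csr")


def build_projection_matrix(
    params: GGMParams,
    frailty: FrailtyDiscretization,
    omega: int,
    D: Sequence[np.ndarray] | None = None,
) -> AgeFrailtyModel:
    """Assemble the joint projection matrix U_tilde = D K' U K.

    ``D``, if given, is a sequence of omega column-stochastic g x g frailty
    transition matrices (one per age class) for dynamic-frailty models;
    omitted, frailty is fixed for life (D = identity) and the formula
    reduces to K' U K.
    """
    g = frailty.g
    K = vec_permutation_matrix(g, omega)
    U = sparse.block_diag(
        [survival_matrix(z, params, omega) for z in frailty.z], format="csr"
    )
    U_tilde = (K.T @ U @ K).tocsr()

    if D is not None:
        if len(D) != omega:
            raise ValueError(f"need one D_j per age class: expected {omega}, got {len(D)}")
        blocks = []
        for j, Dj in enumerate(D):
            Dj = np.asarray(Dj, dtype=float)
            if Dj.shape != (g, g):
                raise ValueError(f"D[{j}] must be {g}x{g}")
            if np.any(Dj < 0) or not np.allclose(Dj.sum(axis=0), 1.0, atol=1e-10):
                raise ValueError(f"D[{j}] is not column-stochastic")
            blocks.append(sparse.csr_matrix(Dj))
        D_full = sparse.block_diag(blocks, format="csr")
        U_tilde = (D_full @ U_tilde).tocsr()

    return AgeFrailtyModel(U_tilde=U_tilde, omega=omega, g=g)
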