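"""Independent oracles used by the test suite.

These deliberately avoid the package's likelihood machinery: the REML oracle
builds the full marginal covariance V = Z G Z' + R explicitly and applies the
textbook restricted-likelihood formula; relatedness is checked by dropping
alleles down the pedigree and counting identity by descent.
"""

from __future__ import annotations

import numpy as np

from maternorm.pedigree import Pedigree
from maternorm.remlfit import DesignBundle, VarianceComponents, _residual_block


def dense_reml_m2ll(bundle: DesignBundle, vc: VarianceComponents) -> float:
    """-2 restricted logL via the explicit dense V (brute force)."""
    n, p = bundle.n, bundle.p
    W = bundle.build_W().toarray()
    X = bundle.X
    Z = W[:, p:]
    Gk = vc.genetic_matrix(bundle.effects)
    G = np.kron(Gk, bundle.A)
    R = np.zeros((n, n))
    Sig = vc.residual_matrix(bundle.n_traits)
    for name, members in bundle.patterns.items():
        B = _residual_block(Sig, members.shape[1] - 1)
        for row in members:
            R[np.ix_(row, row)] = B
    V = Z @ G @ Z.T + R
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XVX)
    bhat = np.linalg.solve(XVX, X.T @ Vi @ bundle.y)
    resid = bundle.y - X @ bhat
    return float(ldV + ldX + resid @ Vi @ resid + (n - p) * np.log(2 * np.pi))


def dense_single_trait_m2ll(X, Z, A, y, g_var, r_var) -> float:
    """-2 restricted logL of a single-trait animal model with iid residuals."""
    n, p = X.shape
    V = g_var * (Z @ A @ Z.T) + r_var * np.eye(n)
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XVX)
    bhat = np.linalg.solve(XVX, X.T @ Vi @ y)
    resid = y - X @ bhat
    return float(ldV + ldX + resid @ Vi @ resid + (n - p) * np.log(2 * np.pi))


def gene_drop_relationship(ped: Pedigree, n_rep: int, rng: np.random.Generator):
    """Monte-Carlo additive relationship matrix by allele dropping.

    Founders receive two unique alleles; offspring inherit one random allele
    from each parent (unknown parents contribute fresh unique alleles).
    Each replicate yields per-pair identity fractions; A_hat = 2 * kinship.
    Returns (A_hat, standard_error_matrix).
    """
    n = len(ped)
    a1 = np.empty((n_rep, n), dtype=np.int64)
    a2 = np.empty((n_rep, n), dtype=np.int64)
    next_allele = 0
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0:
            pick = rng.integers(0, 2, n_rep)
            a1[:, i] = np.where(pick == 0, a1[:, s], a2[:, s])
        else:
            a1[:, i] = next_allele
            next_allele += 1
        if d >= 0:
            pick = rng.integers(0, 2, n_rep)
            a2[:, i] = np.where(pick == 0, a1[:, d], a2[:, d])
        else:
            a2[:, i] = next_allele
            next_allele += 1
    A_hat = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                per_rep = 1.0 + (a1[:, i] == a2[:, i]).astype(float)
            else:
                per_rep = 0.5 * (
                    (a1[:, i] == a1[:, j]).astype(float)
                    + (a1[:, i] == a2[:, j]).astype(float)
                    + (a2[:, i] == a1[:, j]).astype(float)
                    + (a2[:, i] == a2[:, j]).astype(float)
                )
            A_hat[i, j] = A_hat[j, i] = per_rep.mean()
            se[i, j] = se[j, i] = per_rep.std(ddof=1) / np.sqrt(n_rep)
    return A_hat, se


def random_pedigree(rng: np.random.Generator, n_animals: int) -> Pedigree:
    """Random valid pedigree: each animal's parents drawn from earlier animals
    (or unknown), so a topological order always exists."""
    records = []
    ids = [f"A{k}" for k in range(n_animals)]
    for k in range(n_animals):
        sire = dam = None
        if k >= 2 and rng.random() < 0.7:
            sire = ids[int(rng.integers(0, k))]
            dam = ids[int(rng.integers(0, k))]
            if dam == sire:
                dam = None
        records.append((ids[k], sire, dam))
    return Pedigree.from_records(records)
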