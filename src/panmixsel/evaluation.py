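"""Genomic and pedigree relationship matrices, REML variance components and
BLUP prediction of additive genetic values.

The mixed model is y = X*beta + sum_k u_k + e with u_k ~ N(0, K_k sigma_k^2)
for an ordered set of relationship kernels (additive G, dominance D and
optionally their Hadamard products for epistatic covariances).  Variance
components are estimated by average-information REML with an EM-type fallback
step; predictions for non-phenotyped individuals come from the marginal
covariance (equivalent to solving the joint mixed-model equations).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .population_engine import Pedigree

__all__ = [
    "vanraden_G",
    "su_D",
    "vanraden_G_from_gram",
    "su_D_from_gram",
    "epistatic_kernels",
    "genomic_F",
    "genomic_F_from_dosage",
    "pedigree_A",
    "MixedModelFit",
    "reml_fit",
    "varcomp_frame",
    "save_kernels",
]


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def _freqs_and_mask(dosage: np.ndarray, freqs=None) -> tuple[np.ndarray, np.ndarray]:
    M = np.asarray(dosage)
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, float)
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all markers are monomorphic")
    return p, poly


def vanraden_G(dosage: np.ndarray, freqs=None) -> np.ndarray:
    """Additive genomic relationship matrix (VanRaden method 1):
    G = W W' / sum_j 2 p_j q_j with W the dosage matrix centered at 2p.
    Monomorphic markers are dropped; ``freqs`` defaults to the frequencies of
    the genotyped set itself."""
    p, poly = _freqs_and_mask(dosage, freqs)
    W = np.asarray(dosage, float)[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    return (W @ W.T) / denom


def su_D(dosage: np.ndarray, freqs=None) -> np.ndarray:
    """Dominance genomic relationship matrix (Su et al. heterozygosity
    coding): D = H H' / sum_j 2 p_j q_j (1 - 2 p_j q_j) with
    H = 1{dosage == 1} - 2pq."""
    p, poly = _freqs_and_mask(dosage, freqs)
    M = np.asarray(dosage)
    pq2 = 2.0 * p[poly] * (1.0 - p[poly])
    H = (M[:, poly] == 1).astype(float) - pq2
    denom = float(np.sum(pq2 * (1.0 - pq2)))
    return (H @ H.T) / denom


def vanraden_G_from_gram(MM: np.ndarray, Mp: np.ndarray, p: np.ndarray) -> np.ndarray:
    """VanRaden G assembled from the frequency-independent Gram matrix
    MM = M M' of the raw dosage matrix:
    W W' = MM - 2*(Mp) 1' - 2*1 (Mp)' + 4*sum(p^2) J, with Mp = M @ p.
    Monomorphic markers contribute zero to both numerator and denominator,
    so no masking is needed."""
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers are monomorphic")
    G = MM - 2.0 * Mp[:, None] - 2.0 * Mp[None, :] + 4.0 * float(p @ p)
    G /= denom
    return G


def su_D_from_gram(BB: np.ndarray, Bc: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Su et al. D assembled from the Gram matrix BB = B B' of the raw
    heterozygosity indicator matrix B = 1{dosage == 1}:
    H H' = BB - (B c) 1' - 1 (B c)' + sum(c^2) J with c = 2pq."""
    c = 2.0 * p * (1.0 - p)
    denom = float(np.sum(c * (1.0 - c)))
    if denom <= 0.0:
        raise ValueError("all markers are monomorphic")
    D = BB - Bc[:, None] - Bc[None, :] + float(c @ c)
    D /= denom
    return D


def epistatic_kernels(G: np.ndarray, D: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hadamard-product epistatic kernels (AxA, AxD housing AxD+DxA, DxD),
    each rescaled to mean diagonal 1 so variance components are comparable."""
    def scaled(K):
        return K / np.mean(np.diag(K))
    return scaled(G * G), scaled(G * D), scaled(D * D)


def genomic_F(G: np.ndarray) -> np.ndarray:
    """Genomic inbreeding: diagonal of the additive matrix minus one."""
    return np.diag(G) - 1.0


def genomic_F_from_dosage(dosage: np.ndarray, freqs=None) -> np.ndarray:
    """Genomic F computed directly from dosages (the diagonal of VanRaden G
    without forming the full matrix)."""
    p, poly = _freqs_and_mask(dosage, freqs)
    W = np.asarray(dosage, float)[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    return (W * W).sum(axis=1) / denom - 1.0


def pedigree_A(ped: Pedigree, subset_ids=None) -> tuple[np.ndarray, np.ndarray]:
    """Numerator relationship matrix by the tabular recursion, layered over
    (non-overlapping) generations.

    ``subset_ids`` is closed under ancestry automatically.  Returns (A, ids)
    with ids in processing order; the diagonal is 1 + F.
    """
    if subset_ids is None:
        need = set(int(i) for i in ped.ids)
    else:
        need = set(int(i) for i in np.asarray(subset_ids))
        frontier = list(need)
        lookup = {int(i): k for k, i in enumerate(ped.ids)}
        while frontier:
            nxt = []
            for i in frontier:
                k = lookup[i]
                for par in (int(ped.sire[k]), int(ped.dam[k])):
                    if par >= 0 and par not in need:
                        need.add(par)
                        nxt.append(par)
            frontier = nxt
    lookup = {int(i): k for k, i in enumerate(ped.ids)}
    rows = np.array(sorted(lookup[i] for i in need))
    order = rows[np.argsort(ped.generation[rows], kind="stable")]
    ids = ped.ids[order]
    pos = {int(i): k for k, i in enumerate(ids)}
    n = ids.size
    A = np.zeros((n, n))
    gens = ped.generation[order]
    start = 0
    for g in np.unique(gens):
        block = np.flatnonzero(gens == g)
        sires = ped.sire[order[block]]
        dams = ped.dam[order[block]]
        known = sires >= 0
        si = np.array([pos[int(s)] if s >= 0 else -1 for s in sires])
        di = np.array([pos[int(d)] if d >= 0 else -1 for d in dams])
        prev = np.arange(start)
        nb = block.size
        B = np.zeros((nb, start))
        if start and known.any():
            B[known] = 0.5 * (A[si[known]][:, prev] + A[di[known]][:, prev])
        rows_idx = block  # == start .. start+nb-1 after ordering
        A[np.ix_(rows_idx, prev)] = B
        A[np.ix_(prev, rows_idx)] = B.T
        # within-layer entries use parent rows already filled above
        if known.any():
            Wn = np.zeros((nb, nb))
            kn = np.flatnonzero(known)
            # A[i, j] = 0.5*(A[s_i, j] + A[d_i, j]) where j is in this layer:
            # parent rows vs this layer's columns were just written into A
            cols = rows_idx
            Wn[kn] = 0.5 * (A[si[kn]][:, cols] + A[di[kn]][:, cols])
            # recurse through whichever member of the pair has known parents
            full = np.where(known[:, None], Wn, Wn.T)
            full = 0.5 * (full + full.T)
            np.fill_diagonal(full, 0.0)
            A[np.ix_(rows_idx, rows_idx)] = full
        diag = np.ones(nb)
        if known.any():
            diag[known] = 1.0 + 0.5 * A[si[known], di[known]]
        A[rows_idx, rows_idx] = diag
        start += nb
    return A, ids


# ---------------------------------------------------------------------------
# REML / BLUP
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    """REML estimates and BLUP predictions for every kernel."""

    beta: np.ndarray
    varcomp: dict[str, float]
    predictions: dict[str, np.ndarray] = field(repr=False)
    converged: bool = True
    n_iter: int = 0
    ids_all: np.ndarray | None = None


def _reml_iterate(y, X, Ks, sigma, tol, max_iter, floor):
    n = y.size
    vary = float(np.var(y))
    converged = False
    it = 0
    # components pinned at the floor are frozen out of the update; the
    # residual (last entry) is always active
    active = np.ones(sigma.size, bool)
    for it in range(1, max_iter + 1):
        V = sigma[-1] * np.eye(n)
        for s, K in zip(sigma[:-1], Ks):
            V += s * K
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        Vi = linalg.cho_solve(cf, np.eye(n), check_finite=False)
        T = Vi @ X
        C = X.T @ T
        Ci = np.linalg.inv(C)
        P = Vi - T @ Ci @ T.T
        Py = P @ y
        KPy = [K @ Py for K in Ks] + [Py]
        trPK = [float(np.sum(P * K)) for K in Ks] + [float(np.trace(P))]
        yPKPy = [float(Py @ q) for q in KPy]
        score = 0.5 * (np.array(yPKPy) - np.array(trPK))
        # a component collapsing onto its lower bound is fixed there
        for k in range(sigma.size - 1):
            if active[k] and sigma[k] < 1e-4 * vary and score[k] < 0:
                sigma[k] = floor
                active[k] = False
        act = np.flatnonzero(active)
        new = sigma.copy()
        stepped = False
        try:
            AI = 0.5 * np.array([[KPy[a] @ (P @ KPy[b]) for b in act] for a in act])
            step = np.linalg.solve(AI, score[act])
            cand = sigma[act] + step
            if np.all(np.isfinite(cand)) and np.all(cand > -10 * floor):
                new[act] = np.maximum(cand, floor)
                stepped = True
        except np.linalg.LinAlgError:
            pass
        if not stepped:
            # EM-type multiplicative fallback: keeps components positive
            for a in act:
                ratio = yPKPy[a] / max(trPK[a], floor)
                new[a] = max(sigma[a] * min(max(ratio, 0.1), 10.0), floor)
        # small components are judged on the phenotypic-variance scale
        denom = np.maximum(np.abs(sigma[act]), 1e-3 * vary)
        delta = float(np.max(np.abs(new[act] - sigma[act]) / denom)) if act.size else 0.0
        sigma = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("REML did not converge; returning last iterate",
                      RuntimeWarning, stacklevel=3)
    return sigma, converged, it


def reml_fit(y, X, kernels: dict[str, np.ndarray], phenotyped_idx,
             var_components: dict[str, float] | None = None,
             var_init: dict[str, float] | None = None,
             jitter: float = 1e-6, tol: float = 1e-6, max_iter: int = 200
             ) -> MixedModelFit:
    """Fit the multi-kernel mixed model and predict genetic values for every
    individual covered by the kernels.

    Parameters
    ----------
    y : phenotypes of the phenotyped subset (length n_t)
    X : fixed-effect design for the phenotyped subset (n_t x p)
    kernels : ordered mapping name -> (n_all x n_all) relationship matrix over
        training plus candidates; the first kernel is the additive one used
        for selection decisions
    phenotyped_idx : positions of the phenotyped records within the kernel
        index (0..n_all-1)
    var_components : fix variance components (mapping must include
        "residual") and skip REML iterations
    jitter : ridge added to each kernel diagonal for conditioning

    Returns a :class:`MixedModelFit`; ``predictions[name]`` has length n_all.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    idx = np.asarray(phenotyped_idx, np.int64)
    names = list(kernels)
    K_all = [np.asarray(kernels[nm], float) + jitter * np.eye(len(kernels[nm]))
             for nm in names]
    Ks = [K[np.ix_(idx, idx)] for K in K_all]
    n = y.size

    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("phenotypes have zero variance")
    floor = 1e-8 * vary
    if var_components is not None:
        sigma = np.array([var_components[nm] for nm in names]
                         + [var_components["residual"]], float)
        converged, it = True, 0
    else:
        if var_init is not None and all(nm in var_init for nm in names + ["residual"]):
            sigma = np.maximum(np.array([var_init[nm] for nm in names]
                                        + [var_init["residual"]], float), floor)
        else:
            sigma = np.full(len(names) + 1, vary / (len(names) + 1))
        sigma, converged, it = _reml_iterate(y, X, Ks, sigma, tol, max_iter, floor)

    # BLUP at the final variance components (Cholesky solves only)
    V = sigma[-1] * np.eye(n)
    for s, K in zip(sigma[:-1], Ks):
        V += s * K
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    T = linalg.cho_solve(cf, X, check_finite=False)
    C = X.T @ T
    beta = np.linalg.solve(C, T.T @ y)
    Py = linalg.cho_solve(cf, y - X @ beta, check_finite=False)
    preds = {nm: s * (K[:, idx] @ Py)
             for nm, s, K in zip(names, sigma[:-1], K_all)}
    varcomp = {nm: float(s) for nm, s in zip(names, sigma[:-1])}
    varcomp["residual"] = float(sigma[-1])
    return MixedModelFit(beta=beta, varcomp=varcomp, predictions=preds,
                         converged=converged, n_iter=it)


def varcomp_frame(fits: dict, scenario: str = ""):
    """Tidy variance-component table (scenario, generation, component,
    estimate) from a mapping generation -> MixedModelFit."""
    import pandas as pd

    rows = [
        {"scenario": scenario, "generation": gen, "component": comp, "estimate": est}
        for gen, fit in fits.items() for comp, est in fit.varcomp.items()
    ]
    return pd.DataFrame(rows)


def save_kernels(path, **matrices) -> None:
    """Dump relationship matrices (and anything array-like) to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name, M in matrices.items():
            fh.create_dataset(name, data=np.asarray(M))
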