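"""Genomic relationship matrix G, blending with A22, and the
single-step inverse H^-1.

G follows VanRaden's first method: Z = M - 2p with M the 0/1/2 call
matrix and p the allele frequencies (observed in the genotyped set by
default), G = ZZ' / (2 * sum p_j (1 - p_j)).

H^-1 = A^-1 + [[0, 0], [0, (alpha*G + beta*A22)^-1 - A22^-1]], the
correction acting on the genotyped block, with mixing weights
alpha + beta = 1 (defaults 0.95 / 0.05) guarding against a singular G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

from .pedigree import RelationshipMatrixA, SparseAInverse


@dataclass
class GenomicRelationshipG:
    ids: list[str]
    values: np.ndarray
    allele_freqs: np.ndarray
    scale: float

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids
                     ).to_csv(path, sep="\t")


def compute_G(panel, freq_source: str = "observed",
              freqs: np.ndarray | None = None,
              centered_calls: np.ndarray | None = None) -> GenomicRelationshipG:
    """VanRaden method-1 genomic relationship matrix.

    ``freq_source='supplied'`` (or passing ``freqs``) uses external
    allele frequencies; otherwise frequencies observed in the panel.
    ``centered_calls`` lets QC screening pass a mean-imputed float call
    matrix; normal use requires a complete panel.
    """
    if freqs is not None:
        p = np.asarray(freqs, dtype=np.float64)
    elif freq_source == "observed":
        p = panel.allele_freq()
    else:
        raise ValueError("freq_source='supplied' requires freqs")
    scale = float(2.0 * np.sum(p * (1.0 - p)))
    if scale <= 0.0:
        raise ValueError("all SNPs monomorphic: G scale is zero")

    if centered_calls is not None:
        # QC screening path: caller supplies a (possibly float32,
        # mean-imputed) call matrix and accepts its precision
        M = np.asarray(centered_calls)
    else:
        if (panel.calls < 0).any():
            raise ValueError("panel has missing calls; impute before computing G")
        M = panel.calls.astype(np.float64)

    n = M.shape[0]
    G = np.zeros((n, n), dtype=np.float64)
    two_p = (2.0 * p).astype(M.dtype)
    chunk = 4096
    for lo in range(0, M.shape[1], chunk):
        Z = M[:, lo:lo + chunk] - two_p[lo:lo + chunk]
        G += (Z @ Z.T).astype(np.float64)
    G /= scale
    return GenomicRelationshipG(list(panel.animal_ids), G, p, scale)


def blend_G(G: GenomicRelationshipG | np.ndarray, A22: RelationshipMatrixA | np.ndarray,
            alpha: float = 0.95, beta: float = 0.05) -> np.ndarray:
    """alpha*G + beta*A22 (weights must sum to 1)."""
    if abs(alpha + beta - 1.0) > 1e-9:
        raise ValueError(f"alpha + beta must equal 1, got {alpha + beta}")
    Gv = G.values if hasattr(G, "values") else np.asarray(G)
    Av = A22.values if hasattr(A22, "values") else np.asarray(A22)
    if Gv.shape != Av.shape:
        raise ValueError("G and A22 are not conformable")
    return alpha * Gv + beta * Av


@dataclass
class HInverse:
    """A^-1 plus a dense genotyped-block correction (G_blend^-1 - A22^-1)."""

    base: SparseAInverse
    correction: np.ndarray
    genotyped_ids: list[str]
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        pos = {a: i for i, a in enumerate(self.base.ids)}
        self.genotyped_positions = np.asarray(
            [pos[a] for a in self.genotyped_ids], dtype=np.int64)

    @property
    def ids(self) -> list[str]:
        return self.base.ids

    def as_sparse(self) -> sparse.csr_matrix:
        n = len(self.base.ids)
        g = self.genotyped_positions
        rows = np.repeat(g, len(g))
        cols = np.tile(g, len(g))
        corr = sparse.coo_matrix((self.correction.ravel(), (rows, cols)),
                                 shape=(n, n))
        return (self.base.matrix + corr).tocsr()

    def matvec(self, v: np.ndarray) -> np.ndarray:
        g = self.genotyped_positions
        out = self.base.matrix @ v
        out[g] += self.correction @ v[g]
        return out

    def write_correction_tsv(self, path) -> None:
        pd.DataFrame(self.correction, index=self.genotyped_ids,
                     columns=self.genotyped_ids).to_csv(path, sep="\t")


def compute_H_inverse(A_inv: SparseAInverse, G_blend: np.ndarray,
                      A22: RelationshipMatrixA, genotyped_ids: list[str],
                      alpha: float = 0.95, beta: float = 0.05) -> HInverse:
    """Assemble H^-1 from A^-1 and the genotyped-block correction."""
    G_blend = np.asarray(G_blend, dtype=np.float64)
    try:
        cG = cho_factor(G_blend)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "blended G is singular; blend with a larger beta toward A22") from exc
    cA = cho_factor(A22.values)
    eye = np.eye(G_blend.shape[0])
    corr = cho_solve(cG, eye) - cho_solve(cA, eye)
    corr = 0.5 * (corr + corr.T)
    return HInverse(A_inv, corr, list(genotyped_ids), alpha, beta)
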