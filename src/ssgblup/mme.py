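"""Mixed-model equations for the four evaluation models.

Stage 2 of the pipeline: corrected phenotypes yc = 1*mu + Zu + e are
analysed with a per-trait overall mean as the only fixed effect. The
kinship precision K^-1 is the pedigree A^-1 for BLUP or the single-step
H^-1 for ssGBLUP; single-trait (ST) variants use scalar variance
components per trait, multi-trait (MT) variants the full G0/R0.

Missing trait records enter exactly through observation-pattern blocks:
each record contributes inv(R0[pattern, pattern]) to the coefficient
matrix, never an imputed value. Unknown ordering is [mu_1..mu_t] then
breeding values animal-major, so the kinship term is
kron(K^-1, G0^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from .grm import HInverse
from .pedigree import Pedigree, SparseAInverse

MODEL_KINDS = ("ST-BLUP", "MT-BLUP", "ST-ssGBLUP", "MT-ssGBLUP")


@dataclass
class ModelSpec:
    model_kind: str
    traits: list[str]
    G0: np.ndarray
    R0: np.ndarray
    kinship_inverse: sparse.csr_matrix  # over the pedigree ordering

    def __post_init__(self) -> None:
        self.G0 = np.atleast_2d(np.asarray(self.G0, dtype=float))
        self.R0 = np.atleast_2d(np.asarray(self.R0, dtype=float))
        t = len(self.traits)
        if self.G0.shape != (t, t) or self.R0.shape != (t, t):
            raise ValueError("variance component dimensions do not match traits")
        for name, M in (("G0", self.G0), ("R0", self.R0)):
            try:
                np.linalg.cholesky(M)
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"{name} is not positive definite") from exc


@dataclass
class EvaluationResult:
    """Per-animal, per-trait (G)EBVs plus the fitted means and solver info."""

    model_kind: str
    traits: list[str]
    animal_ids: list[str]
    ebv: np.ndarray            # (n_ped, t)
    mu: np.ndarray             # (t,)
    solver: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ebv, index=self.animal_ids, columns=self.traits)

    def tidy(self) -> pd.DataFrame:
        f = self.frame().reset_index(names="animal")
        out = f.melt(id_vars="animal", var_name="trait", value_name="value")
        out["model"] = self.model_kind
        return out

    def write_tsv(self, path) -> None:
        self.tidy().to_csv(path, sep="\t", index=False)


def _kinship_matrix(kinship) -> sparse.csr_matrix:
    if isinstance(kinship, HInverse):
        return kinship.as_sparse()
    if isinstance(kinship, SparseAInverse):
        return kinship.matrix.tocsr()
    return sparse.csr_matrix(kinship)


def build_mme(yc: pd.DataFrame, ped: Pedigree, spec: ModelSpec
              ) -> tuple[sparse.csr_matrix, np.ndarray, dict]:
    """Assemble the mixed-model equations for corrected phenotypes.

    ``yc`` has one row per animal: an ``animal`` column plus one column
    per trait (NaN = no record). Returns (coefficient matrix, rhs,
    meta) with meta describing the unknown ordering.
    """
    t = len(spec.traits)
    Y = yc[spec.traits].to_numpy(dtype=float)
    obs = np.isfinite(Y)
    rec = np.flatnonzero(obs.any(axis=1))
    apos = ped.positions(list(yc["animal"].iloc[rec]))
    n = ped.n
    nun = t + n * t

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs = np.zeros(nun)

    # per-pattern R0 sub-inverses
    codes = obs[rec] @ (1 << np.arange(t))
    winv: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for code in np.unique(codes):
        kset = np.flatnonzero((code >> np.arange(t)) & 1)
        winv[int(code)] = (kset, np.linalg.inv(spec.R0[np.ix_(kset, kset)]))

    for r, i, code in zip(rec, apos, codes):
        kset, W = winv[int(code)]
        yv = Y[r, kset]
        for a, k in enumerate(kset):
            uk = t + t * i + k
            for bb, l in enumerate(kset):
                w = W[a, bb]
                ul = t + t * i + l
                rows += [k, k, uk, uk]
                cols += [l, ul, l, ul]
                vals += [w, w, w, w]
            wy = float(W[a] @ yv)
            rhs[k] += wy
            rhs[uk] += wy

    C = sparse.coo_matrix((vals, (rows, cols)), shape=(nun, nun)).tocsr()
    G0inv = np.linalg.inv(spec.G0)
    K = sparse.kron(spec.kinship_inverse, sparse.csr_matrix(G0inv), format="csr")
    C = C + sparse.block_diag(
        [sparse.csr_matrix((t, t)), K], format="csr")
    meta = {"n_traits": t, "n_animals": n, "ordering": "mu then u animal-major"}
    return C.tocsr(), rhs, meta


def solve_mme(system: tuple, method: str = "direct", tol: float = 1e-10,
              maxiter: int = 20_000) -> tuple[np.ndarray, dict]:
    """Solve the assembled equations by sparse LU or Jacobi-preconditioned CG."""
    C, rhs = system[0], system[1]
    if method == "direct":
        try:
            lu = splu(C.tocsc())
        except RuntimeError as exc:
            raise RuntimeError(f"MME coefficient matrix is singular: {exc}") from exc
        x = lu.solve(rhs)
        info = {"method": "direct", "iterations": 1}
    elif method == "pcg":
        d = C.diagonal()
        if np.any(d <= 0):
            raise RuntimeError("MME diagonal has non-positive entries")
        M = sparse.diags(1.0 / d)
        x, flag = cg(C, rhs, rtol=tol, maxiter=maxiter, M=M)
        if flag != 0:
            res = float(np.linalg.norm(C @ x - rhs))
            raise RuntimeError(f"PCG did not converge (flag={flag}, residual={res:.3e})")
        info = {"method": "pcg", "iterations": maxiter}
    else:
        raise ValueError(f"unknown solver {method!r}")
    info["residual_norm"] = float(np.linalg.norm(C @ x - rhs))
    return x, info


def _solve_spec(yc: pd.DataFrame, ped: Pedigree, spec: ModelSpec,
                method: str = "direct") -> EvaluationResult:
    C, rhs, _ = build_mme(yc, ped, spec)
    x, info = solve_mme((C, rhs), method=method)
    t = len(spec.traits)
    mu = x[:t]
    ebv = x[t:].reshape(ped.n, t)
    return EvaluationResult(spec.model_kind, list(spec.traits), list(ped.ids),
                            ebv, mu, info)


def run_model(
    yc: pd.DataFrame,
    ped: Pedigree,
    kinship,
    varcomp,
    model_kind: str,
    traits: list[str] | None = None,
    method: str = "direct",
) -> EvaluationResult:
    """Dispatch one of the four evaluation models.

    ``kinship`` is a SparseAInverse for the BLUP variants or an HInverse
    for the ssGBLUP variants; ``varcomp`` provides G0/R0 for the traits
    (an object with .traits/.G0/.R0, e.g. a VarianceComponents summary).
    ST variants fit each trait separately with that trait's scalar
    components, which equals the MT fit with all covariances zeroed.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    if model_kind.endswith("ssGBLUP") and not isinstance(kinship, HInverse):
        raise TypeError("ssGBLUP models require an HInverse kinship")
    traits = list(traits or varcomp.traits)
    tidx = [list(varcomp.traits).index(tr) for tr in traits]
    G0 = np.asarray(varcomp.G0, dtype=float)[np.ix_(tidx, tidx)]
    R0 = np.asarray(varcomp.R0, dtype=float)[np.ix_(tidx, tidx)]
    Kinv = _kinship_matrix(kinship)

    if model_kind.startswith("ST"):
        ebv = np.zeros((ped.n, len(traits)))
        mu = np.zeros(len(traits))
        info: dict = {}
        for k, tr in enumerate(traits):
            spec = ModelSpec(model_kind, [tr], G0[[k]][:, [k]], R0[[k]][:, [k]], Kinv)
            res = _solve_spec(yc, ped, spec, method=method)
            ebv[:, k] = res.ebv[:, 0]
            mu[k] = res.mu[0]
            info[tr] = res.solver
        return EvaluationResult(model_kind, traits, list(ped.ids), ebv, mu, info)

    spec = ModelSpec(model_kind, traits, G0, R0, Kinv)
    return _solve_spec(yc, ped, spec, method=method)
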