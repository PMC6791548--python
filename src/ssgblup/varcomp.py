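"""Multi-trait Bayesian variance-component estimation (stage 1).

A Gibbs sampler for the animal model y = Xb + Zu + e with
Var(u) = G0 (x) A and Var(e) = R0 (x) I: flat priors on fixed effects,
Gaussian breeding values through the pedigree, inverse-Wishart priors
on the trait-level covariance matrices G0 (genetic) and R0 (residual).
Missing trait records are integrated out by data augmentation.

Posterior summaries report means and shortest 95% HPD intervals;
derived quantities (heritabilities, genetic/phenotypic correlations)
are computed per retained sample and then averaged, not from the
averaged components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _gibbs_kernel
from .pedigree import Pedigree, compute_A_inverse
from .phenotypes import DesignSpec, build_designs


@dataclass
class GibbsSettings:
    """Chain settings. The production-scale configuration used for the
    reference analysis is 1,100,000 cycles, 100,000 burn-in, thin 50
    (20,000 retained samples); the default here is a 1/10 desk-scale
    chain with the same retained-count arithmetic."""

    n_iter: int = 110_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter or self.thin < 1:
            raise ValueError("invalid chain settings")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class InverseWishartPrior:
    df: float
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.scale = np.asarray(self.scale, dtype=np.float64)
        try:
            np.linalg.cholesky(self.scale)
        except np.linalg.LinAlgError as exc:
            raise ValueError("prior scale matrix is not positive definite") from exc

    @property
    def mean(self) -> np.ndarray:
        t = self.scale.shape[0]
        return self.scale / (self.df - t - 1)


def default_priors(y: np.ndarray) -> tuple[InverseWishartPrior, InverseWishartPrior]:
    """Weakly informative priors: df = t + 2 and scale = diag of half the
    observed trait variances (prior mean equals the scale at this df)."""
    t = y.shape[1]
    v = np.array([np.nanvar(y[:, k]) for k in range(t)])
    v = np.where((~np.isfinite(v)) | (v <= 0), 1.0, v)
    S = np.diag(v / 2.0)
    return InverseWishartPrior(t + 2.0, S), InverseWishartPrior(t + 2.0, S.copy())


@dataclass
class PosteriorChain:
    """Retained Gibbs samples plus posterior-mean location effects."""

    traits: list[str]
    G0_samples: np.ndarray   # (m, t, t)
    R0_samples: np.ndarray
    settings: GibbsSettings
    animal_ids: list[str]
    u_mean: np.ndarray       # (n_ped, t) posterior mean breeding values
    b_hat: dict[str, np.ndarray] = field(default_factory=dict)
    designs: dict[str, DesignSpec] = field(default_factory=dict)
    #: posterior-mean residuals per record row of the input table
    #: (NaN where the trait was unobserved); rows listed in record_rows
    e_mean: np.ndarray | None = None
    record_rows: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return self.G0_samples.shape[0]

    def u_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.u_mean, index=self.animal_ids, columns=self.traits)

    def write_tsv(self, path) -> None:
        t = len(self.traits)
        iu = np.triu_indices(t)
        cols, data = [], []
        for label, samp in (("G0", self.G0_samples), ("R0", self.R0_samples)):
            for a, b in zip(*iu):
                cols.append(f"{label}[{self.traits[a]},{self.traits[b]}]")
                data.append(samp[:, a, b])
        pd.DataFrame(dict(zip(cols, data))).to_csv(path, sep="\t", index=False)


def _coefficient_arrays(designs: dict[str, DesignSpec], traits: list[str],
                        rec_rows: np.ndarray):
    """Flatten per-trait design matrices into scalar-coefficient arrays."""
    coef_trait, coef_ptr, coef_rec, coef_val, coef_xtx = [], [0], [], [], []
    names: list[tuple[str, int]] = []  # (trait, column index in DesignSpec)
    for k, tr in enumerate(traits):
        X = designs[tr].X[rec_rows]
        for c in range(X.shape[1]):
            col = X[:, c]
            nz = np.flatnonzero(col)
            xtx = float(col[nz] @ col[nz])
            if xtx <= 0.0:
                continue  # level absent from the records: not estimable
            coef_trait.append(k)
            coef_rec.append(nz.astype(np.int64))
            coef_val.append(col[nz])
            coef_ptr.append(coef_ptr[-1] + len(nz))
            coef_xtx.append(xtx)
            names.append((tr, c))
    return (
        np.asarray(coef_trait, dtype=np.int64),
        np.asarray(coef_ptr, dtype=np.int64),
        np.concatenate(coef_rec) if coef_rec else np.zeros(0, dtype=np.int64),
        np.concatenate(coef_val) if coef_val else np.zeros(0),
        np.asarray(coef_xtx),
        names,
    )


def gibbs_sample(
    table: pd.DataFrame,
    ped: Pedigree,
    designs: dict[str, DesignSpec] | None = None,
    priors: tuple[InverseWishartPrior, InverseWishartPrior] | None = None,
    settings: GibbsSettings | None = None,
    traits: list[str] | None = None,
) -> PosteriorChain:
    """Run the multi-trait Gibbs sampler on a phenotype table.

    ``table`` has one row per animal with columns ``animal``, the trait
    values (NaN = missing) and the fixed-effect columns the designs
    reference. Every phenotyped animal must be in the pedigree. The
    chain is bit-reproducible for a fixed seed.
    """
    settings = settings or GibbsSettings()
    if traits is None:
        from .phenotypes import TRAITS
        traits = [t for t in TRAITS if t in table.columns]
    if not traits:
        raise ValueError("no traits to analyse")
    designs = designs or build_designs(table, traits)

    Yfull = table[traits].to_numpy(dtype=np.float64)
    obs_full = np.isfinite(Yfull)
    rec_rows = np.flatnonzero(obs_full.any(axis=1))
    Y = np.nan_to_num(Yfull[rec_rows])
    obs = obs_full[rec_rows].astype(np.uint8)
    rec_animal = ped.positions([table["animal"].iloc[r] for r in rec_rows])
    animal_rec = np.full(ped.n, -1, dtype=np.int64)
    animal_rec[rec_animal] = np.arange(len(rec_rows))

    # observation patterns
    pat_codes = obs @ (1 << np.arange(len(traits), dtype=np.int64))
    uniq, pattern_id = np.unique(pat_codes, return_inverse=True)
    patterns = ((uniq[:, None] >> np.arange(len(traits))) & 1).astype(np.uint8)

    ct, cp, cr, cv, cx, coef_names = _coefficient_arrays(designs, traits, rec_rows)

    ainv = compute_A_inverse(ped).matrix.tocsr()
    ainv.sum_duplicates()

    if priors is None:
        priors = default_priors(Yfull)
    pg, pr = priors

    G0s, R0s, U_mean, b_mean, E_mean, status, it = _gibbs_kernel.run_chain(
        Y, obs, pattern_id.astype(np.int64), patterns, rec_animal, animal_rec,
        ct, cp, cr, cv, cx,
        ainv.indptr.astype(np.int64), ainv.indices.astype(np.int64),
        ainv.data.astype(np.float64),
        float(pg.df), pg.scale, float(pr.df), pr.scale,
        settings.n_iter, settings.burn_in, settings.thin, settings.seed,
    )
    if status != _gibbs_kernel.STATUS_OK:
        raise RuntimeError(f"Gibbs chain diverged (non-finite draw) at iteration {it}")

    b_hat: dict[str, np.ndarray] = {}
    for tr in traits:
        b_hat[tr] = np.zeros(designs[tr].X.shape[1])
    for c, (tr, col) in enumerate(coef_names):
        b_hat[tr][col] = b_mean[c]

    E_mean = np.where(obs.astype(bool), E_mean, np.nan)
    return PosteriorChain(list(traits), G0s, R0s, settings, list(ped.ids),
                          U_mean, b_hat, designs, E_mean, rec_rows)


def single_trait_mode(
    table: pd.DataFrame,
    ped: Pedigree,
    designs: dict[str, DesignSpec] | None = None,
    priors=None,
    settings: GibbsSettings | None = None,
    traits: list[str] | None = None,
) -> dict[str, PosteriorChain]:
    """Per-trait chains with genetic and residual covariances fixed at zero."""
    settings = settings or GibbsSettings()
    if traits is None:
        from .phenotypes import TRAITS
        traits = [t for t in TRAITS if t in table.columns]
    chains: dict[str, PosteriorChain] = {}
    for k, tr in enumerate(traits):
        if not np.isfinite(table[tr].to_numpy(dtype=float)).any():
            raise ValueError(f"trait {tr!r} has no records")
        st_settings = GibbsSettings(settings.n_iter, settings.burn_in,
                                    settings.thin, settings.seed + k)
        st_priors = None
        if priors is not None:
            pg, pr = priors
            st_priors = (
                InverseWishartPrior(3.0, pg.scale[[k]][:, [k]]),
                InverseWishartPrior(3.0, pr.scale[[k]][:, [k]]),
            )
        chains[tr] = gibbs_sample(table, ped, designs, st_priors,
                                  st_settings, traits=[tr])
    return chains


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples for an HPD interval")
    k = max(1, int(np.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential-scale-reduction diagnostic for a scalar chain."""
    x = np.asarray(x, dtype=float)
    half = len(x) // 2
    a, b = x[:half], x[half:2 * half]
    m = 2
    n = half
    means = np.array([a.mean(), b.mean()])
    vars_ = np.array([a.var(ddof=1), b.var(ddof=1)])
    W = vars_.mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


@dataclass
class VarianceComponents:
    """Trait-level covariance summaries (posterior means and HPDs)."""

    traits: list[str]
    G0: np.ndarray
    R0: np.ndarray
    h2: np.ndarray
    genetic_corr: np.ndarray
    residual_corr: np.ndarray
    phenotypic_corr: np.ndarray
    hpd: dict[str, tuple[float, float]] = field(default_factory=dict)
    diagnostics: dict[str, float] = field(default_factory=dict)

    @property
    def sigma_a2(self) -> np.ndarray:
        return np.diag(self.G0)

    @property
    def sigma_e2(self) -> np.ndarray:
        return np.diag(self.R0)

    @property
    def sigma_p2(self) -> np.ndarray:
        return self.sigma_a2 + self.sigma_e2

    @classmethod
    def from_components(cls, traits: list[str], G0: np.ndarray, R0: np.ndarray
                        ) -> "VarianceComponents":
        """Deterministic bookkeeping from given covariance matrices:
        sigma_p2 = sigma_a2 + sigma_e2 and h2 = sigma_a2 / sigma_p2."""
        G0 = np.atleast_2d(np.asarray(G0, dtype=float))
        R0 = np.atleast_2d(np.asarray(R0, dtype=float))
        sa2, se2 = np.diag(G0), np.diag(R0)
        h2 = sa2 / (sa2 + se2)
        d = np.sqrt(np.diag(G0))
        gc = G0 / np.outer(d, d)
        dr = np.sqrt(np.diag(R0))
        rc = R0 / np.outer(dr, dr)
        P = G0 + R0
        dp = np.sqrt(np.diag(P))
        pc = P / np.outer(dp, dp)
        return cls(list(traits), G0, R0, h2, gc, rc, pc)

    def to_dict(self) -> dict:
        t = self.traits
        out = {
            "traits": t,
            "G0": self.G0.tolist(),
            "R0": self.R0.tolist(),
            "sigma_a2": dict(zip(t, self.sigma_a2.tolist())),
            "sigma_e2": dict(zip(t, self.sigma_e2.tolist())),
            "sigma_p2": dict(zip(t, self.sigma_p2.tolist())),
            "h2": dict(zip(t, self.h2.tolist())),
            "genetic_corr": self.genetic_corr.tolist(),
            "phenotypic_corr": self.phenotypic_corr.tolist(),
            "hpd": {k: list(v) for k, v in self.hpd.items()},
        }
        return out


def summarize_chain(chain: PosteriorChain, hpd_mass: float = 0.95
                    ) -> VarianceComponents:
    """Posterior means and HPD intervals; derived quantities per sample."""
    m = chain.n_retained
    if m < 2:
        raise ValueError("need at least 2 retained samples")
    G = chain.G0_samples
    R = chain.R0_samples
    t = len(chain.traits)

    sa2 = np.einsum("mkk->mk", G)
    se2 = np.einsum("mkk->mk", R)
    h2_s = sa2 / (sa2 + se2)
    dG = np.sqrt(sa2)
    gc_s = G / (dG[:, :, None] * dG[:, None, :])
    dR = np.sqrt(se2)
    rc_s = R / (dR[:, :, None] * dR[:, None, :])
    P = G + R
    dP = np.sqrt(np.einsum("mkk->mk", P))
    pc_s = P / (dP[:, :, None] * dP[:, None, :])

    hpd: dict[str, tuple[float, float]] = {}
    for k, tr in enumerate(chain.traits):
        hpd[f"sigma_a2[{tr}]"] = hpd_interval(sa2[:, k], hpd_mass)
        hpd[f"sigma_e2[{tr}]"] = hpd_interval(se2[:, k], hpd_mass)
        hpd[f"sigma_p2[{tr}]"] = hpd_interval(sa2[:, k] + se2[:, k], hpd_mass)
        hpd[f"h2[{tr}]"] = hpd_interval(h2_s[:, k], hpd_mass)
        for j in range(k + 1, t):
            pair = f"{tr},{chain.traits[j]}"
            hpd[f"rG[{pair}]"] = hpd_interval(gc_s[:, k, j], hpd_mass)
            hpd[f"rP[{pair}]"] = hpd_interval(pc_s[:, k, j], hpd_mass)

    sign, logdet = np.linalg.slogdet(G)
    diagnostics = {"split_rhat_logdetG0": split_rhat(logdet)}

    return VarianceComponents(
        list(chain.traits), G.mean(axis=0), R.mean(axis=0),
        h2_s.mean(axis=0), gc_s.mean(axis=0), rc_s.mean(axis=0),
        pc_s.mean(axis=0), hpd, diagnostics,
    )
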