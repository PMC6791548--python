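"""Synthetic pedigree / genotype / phenotype generator.

The generator emulates the structure of a national beef-cattle
progeny-test population: a multi-generation pedigree with paternal
half-sib families, a genotyped subset concentrated in the most recent
generations, yearling weight recorded on every tested animal, and
carcass traits only on a ~2.6x smaller slaughtered subset (marbling
score further thinned, mirroring the exclusion of records scored before
the current 9-point grading system).

Default trait-level covariance truths are the published multi-trait
estimates for the five traits (BT, CW, EMA, MS, YW): genetic variances
(5.66, 460.32, 29.38, 1.59, 273.81), residual variances (5.54, 721.79,
35.52, 0.91, 761.44), the genetic correlation matrix (e.g. rG(CW,YW) =
0.76) and residual covariances derived as phenotypic minus genetic
covariance; both matrices are positive definite.

Genotypes are gene-dropped down the pedigree at independent SNPs
(no linkage disequilibrium): founders are drawn under Hardy-Weinberg
equilibrium at per-SNP allele frequencies, descendants inherit one
allele from each parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree, inbreeding
from .phenotypes import TRAITS

# --- published multi-trait covariance truths (trait order bt, cw, ema, ms, yw)

TRUE_SIGMA_A2 = np.array([5.66, 460.32, 29.38, 1.59, 273.81])
TRUE_SIGMA_E2 = np.array([5.54, 721.79, 35.52, 0.91, 761.44])

_RG = np.array([
    [1.00, 0.14, -0.14, -0.06, -0.01],
    [0.14, 1.00, 0.56, 0.17, 0.76],
    [-0.14, 0.56, 1.00, 0.29, 0.34],
    [-0.06, 0.17, 0.29, 1.00, -0.16],
    [-0.01, 0.76, 0.34, -0.16, 1.00],
])
_RP = np.array([
    [1.00, 0.28, 0.01, 0.07, 0.18],
    [0.28, 1.00, 0.57, 0.10, 0.70],
    [0.01, 0.57, 1.00, 0.21, 0.36],
    [0.07, 0.10, 0.21, 1.00, 0.01],
    [0.18, 0.70, 0.36, 0.01, 1.00],
])

_sa = np.sqrt(TRUE_SIGMA_A2)
_sp = np.sqrt(TRUE_SIGMA_A2 + TRUE_SIGMA_E2)
TRUE_G0 = _RG * np.outer(_sa, _sa)
#: residual covariance = phenotypic covariance - genetic covariance
TRUE_R0 = _RP * np.outer(_sp, _sp) - TRUE_G0

TRAIT_MEANS = {"bt": 8.71, "cw": 343.96, "ema": 78.90, "ms": 3.33, "yw": 342.06}


def _sub(M: np.ndarray, idx: list[int]) -> np.ndarray:
    return M[np.ix_(idx, idx)]


def trait_truths(traits: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(G0, R0) truth matrices restricted to the given traits."""
    idx = [TRAITS.index(t) for t in traits]
    return _sub(TRUE_G0, idx).copy(), _sub(TRUE_R0, idx).copy()


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic population."""

    n_founders: int = 200
    n_generations: int = 5
    n_sires_per_gen: int = 40
    n_offspring_per_gen: int = 700
    n_snps: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    traits: list[str] = field(default_factory=lambda: list(TRAITS))
    G0_true: np.ndarray | None = None
    R0_true: np.ndarray | None = None
    #: fraction of animals with carcass records (~1/2.6 of YW records)
    carcass_fraction: float = 1.0 / 2.6
    #: fraction of carcass animals retaining a marbling score (3,991/5,824)
    ms_fraction: float = 0.685
    #: number of contemporary-group levels per factor
    n_cg_yw: int = 25
    n_cg_carcass: int = 20
    n_birth_place: int = 12
    #: fixed-effect SD as a multiple of the trait phenotypic SD
    fixed_effect_scale: float = 1.0
    #: generations whose animals are genotyped (most recent ones)
    genotyped_generations: int = 2
    #: "polygenic": breeding values by pedigree recursion, independent of
    #: the simulated markers (the exact model the Gibbs sampler assumes);
    #: "genomic": breeding values are sums of marker effects, so realized
    #: genomic relationships carry Mendelian-sampling information and
    #: single-step evaluation has a genuine edge over pedigree BLUP
    genetic_architecture: str = "polygenic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G0_true is None or self.R0_true is None:
            g, r = trait_truths(self.traits)
            if self.G0_true is None:
                self.G0_true = g
            if self.R0_true is None:
                self.R0_true = r
        self.G0_true = np.atleast_2d(np.asarray(self.G0_true, dtype=float))
        self.R0_true = np.atleast_2d(np.asarray(self.R0_true, dtype=float))
        t = len(self.traits)
        if self.G0_true.shape != (t, t) or self.R0_true.shape != (t, t):
            raise ValueError("truth matrices do not match trait list")
        for name, M in (("G0_true", self.G0_true), ("R0_true", self.R0_true)):
            try:
                np.linalg.cholesky(M)
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"{name} is not positive definite") from exc
        if self.n_founders < 1:
            raise ValueError("need at least one founder")


def simulate_pedigree(cfg: SimulationConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Discrete-generation random mating with paternal half-sib families.

    Each generation samples a limited set of sires (progeny-test
    structure) and one dam per offspring from the previous generation.
    Returns the sorted pedigree and a per-animal metadata frame with
    sex and generation.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[tuple[str, str | None, str | None]] = []
    sex: dict[str, str] = {}
    gen_of: dict[str, int] = {}

    founders = [f"F{i:05d}" for i in range(cfg.n_founders)]
    for i, a in enumerate(founders):
        records.append((a, None, None))
        sex[a] = "M" if i < cfg.n_founders // 2 else "F"
        gen_of[a] = 0
    prev = founders
    for g in range(1, cfg.n_generations):
        males = [a for a in prev if sex[a] == "M"]
        females = [a for a in prev if sex[a] == "F"]
        sires = list(rng.choice(males, size=min(cfg.n_sires_per_gen, len(males)),
                                replace=False))
        cur = []
        for j in range(cfg.n_offspring_per_gen):
            a = f"G{g}_{j:05d}"
            s = sires[int(rng.integers(len(sires)))]
            d = females[int(rng.integers(len(females)))]
            records.append((a, s, d))
            sex[a] = "M" if rng.random() < 0.5 else "F"
            gen_of[a] = g
            cur.append(a)
        prev = cur
    ped = Pedigree.from_records(records)
    meta = pd.DataFrame({
        "animal": ped.ids,
        "sex": [sex[a] for a in ped.ids],
        "generation": [gen_of[a] for a in ped.ids],
    })
    return ped, meta


def gene_drop(ped: Pedigree, cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Gene-drop all animals: founder haplotypes under HWE at per-SNP
    frequencies, descendants inherit one allele from each parent
    (independent SNPs). Returns (calls for the whole pedigree, p)."""
    rng = np.random.default_rng(cfg.seed + 1)
    n, m = ped.n, cfg.n_snps
    p = rng.uniform(cfg.maf_low, cfg.maf_high, size=m)
    h1 = np.zeros((n, m), dtype=np.int8)
    h2 = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN:
            h1[i] = rng.random(m) < p
        else:
            pick = rng.random(m) < 0.5
            h1[i] = np.where(pick, h1[s], h2[s])
        if d == UNKNOWN:
            h2[i] = rng.random(m) < p
        else:
            pick = rng.random(m) < 0.5
            h2[i] = np.where(pick, h1[d], h2[d])
    return (h1 + h2).astype(np.int8), p


def _panel_from_calls(ped: Pedigree, calls: np.ndarray, genotyped_ids: list[str]):
    from .qc import GenotypePanel

    m = calls.shape[1]
    rows = ped.positions(genotyped_ids)
    snp_ids = [f"snp{j:06d}" for j in range(m)]
    chrom = np.asarray([str(1 + j % 29) for j in range(m)], dtype=object)
    pos = np.arange(1, m + 1, dtype=np.int64) * 1000
    return GenotypePanel(list(genotyped_ids), snp_ids, chrom, pos, calls[rows])


def default_genotyped_ids(ped: Pedigree, cfg: SimulationConfig) -> list[str]:
    gmax = int(ped.generation.max())
    cut = gmax - cfg.genotyped_generations + 1
    return [a for a, g in zip(ped.ids, ped.generation) if g >= cut]


def simulate_genotypes(ped: Pedigree, cfg: SimulationConfig,
                       genotyped_ids: list[str] | None = None):
    """Gene-drop genotypes for the whole pedigree; return a panel of the
    genotyped subset (default: the most recent generations)."""
    calls, _ = gene_drop(ped, cfg)
    if genotyped_ids is None:
        genotyped_ids = default_genotyped_ids(ped, cfg)
    return _panel_from_calls(ped, calls, genotyped_ids)


def simulate_breeding_values(ped: Pedigree, G0: np.ndarray, rng) -> np.ndarray:
    """u by pedigree recursion: u_i = 0.5(u_s + u_d) + m_i with
    Mendelian-sampling covariance 0.5(1 - (F_s + F_d)/2) G0; founders
    and unknown-parent contributions carry the full share of variance."""
    F, _ = inbreeding(ped)
    t = G0.shape[0]
    n = ped.n
    Lg = np.linalg.cholesky(G0)
    U = np.zeros((n, t))
    z = rng.standard_normal((n, t))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        pa = np.zeros(t)
        # each known parent contributes half its breeding value; the
        # Mendelian-sampling variance shrinks with parental inbreeding
        if s != UNKNOWN and d != UNKNOWN:
            pa = 0.5 * (U[s] + U[d])
            w = 0.5 * (1.0 - 0.5 * (F[s] + F[d]))
        elif s != UNKNOWN or d != UNKNOWN:
            par = s if s != UNKNOWN else d
            pa = 0.5 * U[par]
            w = 0.75 - 0.25 * F[par]
        else:
            w = 1.0
        U[i] = pa + np.sqrt(w) * (Lg @ z[i])
    return U


def genomic_breeding_values(calls: np.ndarray, p: np.ndarray, G0: np.ndarray,
                            rng) -> np.ndarray:
    """u as a sum of marker effects: u = Z a with Z the centered calls and
    per-SNP effect vectors a_j ~ MVN(0, G0 / (2 sum p(1-p))), so founder
    genetic covariance is G0 in expectation and realized genomic
    relationships carry the Mendelian-sampling signal."""
    m = calls.shape[1]
    scale = 2.0 * np.sum(p * (1.0 - p))
    La = np.linalg.cholesky(np.atleast_2d(G0) / scale)
    a = rng.standard_normal((m, La.shape[0])) @ La.T
    Z = calls.astype(np.float64) - 2.0 * p
    return Z @ a


def simulate_phenotypes(ped: Pedigree, cfg: SimulationConfig,
                        meta: pd.DataFrame | None = None,
                        calls: np.ndarray | None = None,
                        founder_freqs: np.ndarray | None = None) -> pd.DataFrame:
    """Phenotype table y = fixed effects + u + e with the configured
    missing-data pattern (YW on everyone, carcass traits on a subset,
    MS further thinned).

    Under the "genomic" architecture the full-pedigree call matrix (and
    founder allele frequencies) must be supplied or is re-derived by
    gene dropping with the config seed."""
    rng = np.random.default_rng(cfg.seed + 2)
    traits = cfg.traits
    t = len(traits)
    n = ped.n
    if cfg.genetic_architecture == "genomic":
        if calls is None:
            calls, founder_freqs = gene_drop(ped, cfg)
        U = genomic_breeding_values(calls, founder_freqs, cfg.G0_true, rng)
    elif cfg.genetic_architecture == "polygenic":
        U = simulate_breeding_values(ped, cfg.G0_true, rng)
    else:
        raise ValueError(
            f"unknown genetic architecture {cfg.genetic_architecture!r}")
    E = rng.multivariate_normal(np.zeros(t), cfg.R0_true, size=n,
                                method="cholesky")

    sp = np.sqrt(np.diag(cfg.G0_true) + np.diag(cfg.R0_true))
    cg_yw = rng.integers(cfg.n_cg_yw, size=n)
    cg_carc = rng.integers(cfg.n_cg_carcass, size=n)
    bp = rng.integers(cfg.n_birth_place, size=n)
    eff_yw = rng.normal(0, 1, cfg.n_cg_yw)
    eff_carc = rng.normal(0, 1, cfg.n_cg_carcass)
    eff_bp = rng.normal(0, 0.5, cfg.n_birth_place)
    slaughter_age = rng.normal(730.0, 25.0, size=n)
    age_slope = 0.3  # per-day effect, scaled by trait SD below

    table = pd.DataFrame({
        "animal": ped.ids,
        "cg_yw": [f"yw{v}" for v in cg_yw],
        "cg_carcass": [f"cc{v}" for v in cg_carc],
        "birth_place": [f"bp{v}" for v in bp],
        "slaughter_age": slaughter_age,
    })
    if meta is not None:
        table = table.merge(meta[["animal", "sex", "generation"]], on="animal")

    has_carcass = rng.random(n) < cfg.carcass_fraction
    has_ms = has_carcass & (rng.random(n) < cfg.ms_fraction)
    scale = cfg.fixed_effect_scale
    for k, tr in enumerate(traits):
        factor_eff = eff_bp[bp] * sp[k] * scale
        if tr == "yw":
            factor_eff = factor_eff + eff_yw[cg_yw] * sp[k] * scale
        else:
            factor_eff = factor_eff + eff_carc[cg_carc] * sp[k] * scale
        y = TRAIT_MEANS.get(tr, 0.0) + factor_eff + U[:, k] + E[:, k]
        if tr in ("cw", "ema", "ms"):
            y = y + age_slope * (sp[k] / sp.max()) * (slaughter_age - 730.0)
        if tr == "yw":
            mask = np.ones(n, dtype=bool)
        elif tr == "ms":
            mask = has_ms
        else:
            mask = has_carcass
        table[tr] = np.where(mask, y, np.nan)

    # keep the true breeding values available for validation studies
    for k, tr in enumerate(traits):
        table[f"tbv_{tr}"] = U[:, k]
    return table


def simulate_dataset(cfg: SimulationConfig):
    """Convenience wrapper: pedigree, metadata, genotype panel, phenotypes.

    A single gene drop feeds both the genotype panel and (under the
    genomic architecture) the breeding values, so the panel really does
    tag the simulated causal variation."""
    ped, meta = simulate_pedigree(cfg)
    calls, p = gene_drop(ped, cfg)
    panel = _panel_from_calls(ped, calls, default_genotyped_ids(ped, cfg))
    table = simulate_phenotypes(ped, cfg, meta, calls=calls, founder_freqs=p)
    return ped, meta, panel, table


# ---------------------------------------------------------------------------
# QC fixture engineered to the published filter counts
# ---------------------------------------------------------------------------

@dataclass
class QCFixtureSpec:
    """Removal counts for the engineered QC panel (defaults are the
    published category counts: 45,304 SNPs over 1,679 animals reduced
    to 34,479 SNPs and 1,541 animals)."""

    n_snps: int = 45_304
    n_unknown_pos: int = 302
    n_sex_chrom: int = 1_150
    n_low_call_rate: int = 2_677
    n_low_maf: int = 6_684
    n_mendel_snps: int = 12
    n_keep_animals: int = 1_541
    n_high_missing: int = 73
    n_no_phenotype: int = 15
    n_conflict: int = 11
    n_deviation: int = 39
    n_child_pairs: int = 50  # genotyped parent-child pairs among keepers
    seed: int = 2024

    def __post_init__(self) -> None:
        snp_removed = (self.n_unknown_pos + self.n_sex_chrom +
                       self.n_low_call_rate + self.n_low_maf + self.n_mendel_snps)
        if snp_removed >= self.n_snps:
            raise ValueError("SNP removal counts exceed the panel size")
        if self.n_child_pairs + self.n_deviation + 1 > self.n_keep_animals:
            raise ValueError("animal counts inconsistent")

    @property
    def n_animals(self) -> int:
        return (self.n_keep_animals + self.n_high_missing + self.n_no_phenotype
                + self.n_conflict + self.n_deviation)

    @property
    def n_snps_after(self) -> int:
        return (self.n_snps - self.n_unknown_pos - self.n_sex_chrom
                - self.n_low_call_rate - self.n_low_maf - self.n_mendel_snps)


def make_qc_fixture(spec: QCFixtureSpec | None = None):
    """Engineer a (panel, pedigree, phenotypes) triple whose QC cascade
    removes exactly the published per-category counts.

    Every removal category is disjoint by construction at its stage:
    high-missing animals carry 15% missing calls; conflict animals are
    progeny of genotyped keepers with opposing homozygotes injected at
    2% of SNPs; deviation animals are pedigree full sibs of keepers with
    mirrored (2 - g) genotypes so the genomic relationship contradicts
    the pedigree one; Mendelian-error SNPs are 12 markers with an
    opposing homozygote planted in one surviving parent-child pair.
    """
    from .qc import MISSING, GenotypePanel

    spec = spec or QCFixtureSpec()
    rng = np.random.default_rng(spec.seed)
    m = spec.n_snps

    # --- marker map and SNP category layout
    j0 = 0
    idx_unknown = np.arange(j0, j0 + spec.n_unknown_pos); j0 += spec.n_unknown_pos
    idx_sex = np.arange(j0, j0 + spec.n_sex_chrom); j0 += spec.n_sex_chrom
    idx_lowcr = np.arange(j0, j0 + spec.n_low_call_rate); j0 += spec.n_low_call_rate
    idx_lowmaf = np.arange(j0, j0 + spec.n_low_maf); j0 += spec.n_low_maf
    idx_mendel = np.arange(j0, j0 + spec.n_mendel_snps); j0 += spec.n_mendel_snps

    chrom = np.asarray([str(1 + j % 29) for j in range(m)], dtype=object)
    pos = np.arange(1, m + 1, dtype=np.int64) * 100
    chrom[idx_unknown] = "0"
    pos[idx_unknown] = -1
    chrom[idx_sex] = "X"

    p = rng.uniform(0.1, 0.5, size=m)
    p[idx_lowmaf] = 0.002

    # --- animals
    keepers = [f"K{i:05d}" for i in range(spec.n_keep_animals)]
    base = keepers[: spec.n_keep_animals - spec.n_child_pairs]
    children = keepers[spec.n_keep_animals - spec.n_child_pairs:]
    high_missing = [f"HM{i:03d}" for i in range(spec.n_high_missing)]
    no_pheno = [f"NP{i:03d}" for i in range(spec.n_no_phenotype)]
    conflict = [f"CF{i:03d}" for i in range(spec.n_conflict)]
    deviation = [f"DV{i:03d}" for i in range(spec.n_deviation)]

    # pedigree: base keepers and extras are children of ungenotyped founders;
    # keeper children descend from base keepers; deviation animals are full
    # sibs of base keepers not otherwise used as parents.
    n_pairs = spec.n_child_pairs
    child_parents = base[:n_pairs]
    conflict_parents = base[n_pairs: n_pairs + spec.n_conflict]
    dev_sibs = base[n_pairs + spec.n_conflict:
                    n_pairs + spec.n_conflict + spec.n_deviation]

    records: list[tuple[str, str | None, str | None]] = []
    founder_count = 0

    def founder() -> str:
        nonlocal founder_count
        a = f"U{founder_count:05d}"
        founder_count += 1
        records.append((a, None, None))
        return a

    dev_parents: dict[str, tuple[str, str]] = {}
    for a in base:
        s, d = founder(), founder()
        records.append((a, s, d))
        if a in dev_sibs:
            dev_parents[a] = (s, d)
    for a, par in zip(children, child_parents):
        records.append((a, par, founder()))
    for a, par in zip(conflict, conflict_parents):
        records.append((a, par, founder()))
    for a, sib in zip(deviation, dev_sibs):
        s, d = dev_parents[sib]
        records.append((a, s, d))
    for a in high_missing + no_pheno:
        records.append((a, founder(), founder()))
    ped = Pedigree.from_records(records)

    # --- genotypes
    animals = keepers + high_missing + no_pheno + conflict + deviation
    row = {a: i for i, a in enumerate(animals)}
    n = len(animals)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)

    def drop_from(parent_row: int, child_row: int) -> None:
        """One allele from the parent, the other from the base frequency."""
        g = calls[parent_row]
        a1 = np.where(g == 1, rng.integers(0, 2, size=m).astype(np.int8),
                      (g // 2).astype(np.int8))
        a2 = (rng.random(m) < p).astype(np.int8)
        calls[child_row] = a1 + a2

    for a, par in zip(children, child_parents):
        drop_from(row[par], row[a])
    for a, par in zip(conflict, conflict_parents):
        drop_from(row[par], row[a])
        # plant opposing homozygotes at 2% of SNPs where the parent is homozygous
        g = calls[row[par]]
        hom = np.flatnonzero(g != 1)
        sel = rng.choice(hom, size=int(0.02 * m), replace=False)
        calls[row[a], sel] = 2 - g[sel]
    for a, sib in zip(deviation, dev_sibs):
        calls[row[a]] = 2 - calls[row[sib]]  # mirrored genotypes

    # Mendelian-error SNPs: opposing homozygotes in one surviving pair
    pair_parent, pair_child = row[child_parents[0]], row[children[0]]
    calls[pair_parent, idx_mendel] = 0
    calls[pair_child, idx_mendel] = 2

    # missingness: low-call-rate SNPs missing in 5% of keepers ...
    n_miss = max(1, int(round(0.05 * spec.n_keep_animals)))
    keep_rows = np.asarray([row[a] for a in keepers])
    for j in idx_lowcr:
        miss_rows = rng.choice(keep_rows, size=n_miss, replace=False)
        calls[miss_rows, j] = MISSING
    # ... and high-missing animals missing at 15% of all SNPs
    for a in high_missing:
        sel = rng.random(m) < 0.15
        calls[row[a], sel] = MISSING

    snp_ids = [f"fx{j:06d}" for j in range(m)]
    panel = GenotypePanel(animals, snp_ids, chrom, pos, calls)

    pheno = pd.DataFrame({"animal": animals})
    yw = rng.normal(342.0, 32.0, size=n)
    pheno["yw"] = yw
    pheno.loc[pheno["animal"].isin(no_pheno), "yw"] = np.nan
    for tr in ("bt", "cw", "ema", "ms"):
        pheno[tr] = np.nan
    return panel, ped, pheno
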