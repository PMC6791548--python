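"""Genotype panel handling and quality-control cascade.

The cascade mirrors a routine SNP-chip cleaning protocol for a
progeny-test cattle population: animal-level exclusions first
(missingness, phenotype availability, parent-progeny genotype
conflicts, pedigree-genomic deviations), then SNP-level exclusions
(unknown position, sex chromosomes, call rate, minor allele frequency,
Mendelian errors). Counts at every stage are local to that stage, so
the per-category removal numbers reconcile sequentially.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree, extract_A22

MISSING = -1  # missing genotype call

SEX_CHROMOSOMES = {"X", "Y", "XY", "MT", "30", "31", "32", "33"}
UNKNOWN_CHROM = "0"
UNKNOWN_POS = -1


@dataclass
class GenotypePanel:
    """Animals x SNPs genotype calls (0/1/2, MISSING=-1) plus marker map."""

    animal_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray  # str per SNP; "0" = unknown
    pos: np.ndarray    # int per SNP; -1 = unknown
    calls: np.ndarray  # int8 (n_animals, n_snps)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("calls shape inconsistent with ids")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def select_snps(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            list(self.animal_ids),
            [self.snp_ids[j] for j in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.snp_ids[j] for j in keep],
            self.chrom[keep].copy(), self.pos[keep].copy(),
            self.calls[:, keep].copy(),
        )

    def select_animals(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        rows = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypePanel(
            [self.animal_ids[i] for i in rows],
            list(self.snp_ids), self.chrom.copy(), self.pos.copy(),
            self.calls[rows].copy(),
        )

    def allele_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (missing ignored)."""
        obs = self.calls >= 0
        n_called = obs.sum(axis=0)
        tot = np.where(self.calls >= 0, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, tot / (2.0 * n_called), np.nan)

    def write_tsv(self, calls_path, map_path) -> None:
        df = pd.DataFrame(self.calls, index=self.animal_ids, columns=self.snp_ids)
        df = df.where(df >= 0, other=pd.NA)
        df.to_csv(calls_path, sep="\t", index_label="animal", na_rep="NA")
        pd.DataFrame({"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos}
                     ).to_csv(map_path, sep="\t", index=False)


def read_panel_tsv(calls_path, map_path) -> GenotypePanel:
    df = pd.read_csv(calls_path, sep="\t", index_col=0)
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    m = pd.read_csv(map_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    m = m.set_index("snp_id").loc[list(df.columns)]
    return GenotypePanel(
        [str(a) for a in df.index], [str(s) for s in df.columns],
        m["chrom"].fillna(UNKNOWN_CHROM).to_numpy(dtype=object),
        m["pos"].fillna(UNKNOWN_POS).to_numpy(dtype=np.int64),
        calls,
    )


def read_panel_plink(raw_path, bim_path) -> GenotypePanel:
    """Read a PLINK .raw (additive recode) plus .bim marker map."""
    raw = pd.read_csv(raw_path, sep=r"\s+")
    meta_cols = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
                 if c in raw.columns]
    geno = raw.drop(columns=meta_cols)
    snp_ids = [c.rsplit("_", 1)[0] for c in geno.columns]
    calls = geno.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp_id": str})
    bim = bim.set_index("snp_id").loc[snp_ids]
    return GenotypePanel(
        [str(a) for a in raw["IID"]], snp_ids,
        bim["chrom"].to_numpy(dtype=object),
        bim["pos"].to_numpy(dtype=np.int64),
        calls,
    )


@dataclass
class QCReport:
    """Ordered record of a filter cascade, per axis (snp or animal)."""

    axis: str
    n_before: int
    steps: list[tuple[str, int, list[str]]] = field(default_factory=list)

    @property
    def n_after(self) -> int:
        return self.n_before - sum(n for _, n, _ in self.steps)

    def add(self, name: str, removed_ids: list[str]) -> None:
        self.steps.append((name, len(removed_ids), list(removed_ids)))

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "steps": [{"filter": n, "n_removed": k, "ids_removed": ids}
                      for n, k, ids in self.steps],
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def intersect_panels(panel_a: GenotypePanel, panel_b: GenotypePanel) -> GenotypePanel:
    """Union of animals over the intersection of SNP ids (chip merging).

    Marker metadata is taken from ``panel_a`` where the maps disagree.
    """
    overlap = set(panel_a.animal_ids) & set(panel_b.animal_ids)
    if overlap:
        raise ValueError(f"panels share animal ids: {sorted(overlap)[:5]}")
    common = [s for s in panel_a.snp_ids if s in set(panel_b.snp_ids)]
    if not common:
        import warnings
        warnings.warn("panels share no SNP ids; merged panel has no markers")
    ia = {s: j for j, s in enumerate(panel_a.snp_ids)}
    ib = {s: j for j, s in enumerate(panel_b.snp_ids)}
    ja = np.asarray([ia[s] for s in common], dtype=np.int64)
    jb = np.asarray([ib[s] for s in common], dtype=np.int64)
    calls = np.vstack([panel_a.calls[:, ja], panel_b.calls[:, jb]]) if common else \
        np.zeros((panel_a.n_animals + panel_b.n_animals, 0), dtype=np.int8)
    return GenotypePanel(
        list(panel_a.animal_ids) + list(panel_b.animal_ids),
        common, panel_a.chrom[ja].copy(), panel_a.pos[ja].copy(), calls,
    )


def _genotyped_parent_pairs(panel: GenotypePanel, ped: Pedigree) -> list[tuple[int, int]]:
    """(parent_row, offspring_row) pairs where both are in the panel."""
    row = {a: i for i, a in enumerate(panel.animal_ids)}
    pairs = []
    for a, i in row.items():
        p = ped.index.get(a)
        if p is None:
            continue
        for par in (ped.sire[p], ped.dam[p]):
            if par != UNKNOWN and ped.ids[par] in row:
                pairs.append((row[ped.ids[par]], i))
    return pairs


def _opposing_homozygote_counts(calls: np.ndarray, pairs) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (n_opposing, n_both_called) over all SNPs."""
    n_opp = np.zeros(len(pairs), dtype=np.int64)
    n_called = np.zeros(len(pairs), dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        gi, gj = calls[i], calls[j]
        both = (gi >= 0) & (gj >= 0)
        n_called[k] = both.sum()
        n_opp[k] = np.count_nonzero(both & (((gi == 0) & (gj == 2)) |
                                            ((gi == 2) & (gj == 0))))
    return n_opp, n_called


def apply_snp_filters(
    panel: GenotypePanel,
    ped: Pedigree,
    call_rate_min: float = 0.98,
    maf_min: float = 0.01,
) -> tuple[GenotypePanel, QCReport]:
    """SNP cascade: unknown position, sex chromosomes, call rate, MAF,
    Mendelian error (any genotyped parent-offspring pair with opposing
    homozygotes at the SNP).

    Thresholds are strict (``< threshold`` removed), ties retained.
    Call rate and MAF are computed on the animals present in ``panel``
    and on SNPs surviving the earlier stages.
    """
    for thr in (call_rate_min, maf_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must be in [0, 1]")
    report = QCReport("snp", panel.n_snps)
    cur = panel

    unknown = (cur.pos == UNKNOWN_POS) | (np.asarray(cur.chrom) == UNKNOWN_CHROM)
    report.add("unknown_position", [cur.snp_ids[j] for j in np.flatnonzero(unknown)])
    cur = cur.select_snps(~unknown)

    sex = np.isin(np.asarray(cur.chrom, dtype=object), list(SEX_CHROMOSOMES))
    report.add("sex_chromosome", [cur.snp_ids[j] for j in np.flatnonzero(sex)])
    cur = cur.select_snps(~sex)

    call_rate = (cur.calls >= 0).mean(axis=0)
    low_cr = call_rate < call_rate_min
    report.add("call_rate", [cur.snp_ids[j] for j in np.flatnonzero(low_cr)])
    cur = cur.select_snps(~low_cr)

    p = cur.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    low_maf = maf < maf_min
    report.add("maf", [cur.snp_ids[j] for j in np.flatnonzero(low_maf)])
    cur = cur.select_snps(~low_maf)

    pairs = _genotyped_parent_pairs(cur, ped)
    mendel = np.zeros(cur.n_snps, dtype=bool)
    for i, j in pairs:
        gi, gj = cur.calls[i], cur.calls[j]
        mendel |= ((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))
    report.add("mendelian_error", [cur.snp_ids[j] for j in np.flatnonzero(mendel)])
    cur = cur.select_snps(~mendel)

    return cur, report


def provisional_G(panel: GenotypePanel) -> np.ndarray:
    """VanRaden-style G with missing calls mean-imputed (QC screening only)."""
    from .grm import compute_G

    calls = panel.calls.astype(np.float32)
    p = panel.allele_freq()
    miss = calls < 0
    calls = np.where(miss, (2.0 * p)[None, :].astype(np.float32), calls)
    return compute_G(
        GenotypePanel(panel.animal_ids, panel.snp_ids, panel.chrom, panel.pos,
                      np.clip(np.round(calls), 0, 2).astype(np.int8)),
        freqs=p, centered_calls=calls,
    ).values


def apply_animal_filters(
    panel: GenotypePanel,
    ped: Pedigree,
    phenotypes: pd.DataFrame | None,
    trait_columns: list[str] | None = None,
    missing_max: float = 0.10,
    conflict_rate_max: float = 0.01,
    dev_threshold: float = 0.5,
) -> tuple[GenotypePanel, QCReport]:
    """Animal cascade: genotype missingness, phenotype availability,
    parent-progeny conflicts, pedigree-genomic deviations.

    A conflict is a genotyped parent-offspring pair whose genome-wide
    opposing-homozygote rate exceeds ``conflict_rate_max``; a deviation
    is a pair with |G_ij - A22_ij| > ``dev_threshold`` under a
    provisional (mean-imputed) G on the current survivors. In a flagged
    pair the pedigree-later animal (the progeny / the younger recruit)
    is removed.
    """
    report = QCReport("animal", panel.n_animals)
    cur = panel

    miss_frac = (cur.calls < 0).mean(axis=1)
    high = miss_frac > missing_max
    report.add("genotype_missingness", [cur.animal_ids[i] for i in np.flatnonzero(high)])
    cur = cur.select_animals(~high)

    if phenotypes is not None:
        cols = trait_columns or [c for c in ("bt", "cw", "ema", "ms", "yw")
                                 if c in phenotypes.columns]
        has = phenotypes.set_index("animal")[cols].notna().any(axis=1)
        no_pheno = np.asarray([not bool(has.get(a, False)) for a in cur.animal_ids])
    else:
        no_pheno = np.zeros(cur.n_animals, dtype=bool)
    report.add("no_phenotype", [cur.animal_ids[i] for i in np.flatnonzero(no_pheno)])
    cur = cur.select_animals(~no_pheno)

    pairs = _genotyped_parent_pairs(cur, ped)
    n_opp, n_called = _opposing_homozygote_counts(cur.calls, pairs)
    flagged = np.zeros(cur.n_animals, dtype=bool)
    order = {a: ped.index[a] for a in cur.animal_ids}
    for k, (i, j) in enumerate(pairs):
        if n_called[k] > 0 and n_opp[k] / n_called[k] > conflict_rate_max:
            later = i if order[cur.animal_ids[i]] > order[cur.animal_ids[j]] else j
            flagged[later] = True
    report.add("parent_progeny_conflict",
               [cur.animal_ids[i] for i in np.flatnonzero(flagged)])
    cur = cur.select_animals(~flagged)

    G = provisional_G(cur)
    A22 = extract_A22(ped, cur.animal_ids).values
    dev = np.abs(G - A22)
    np.fill_diagonal(dev, 0.0)
    exceed = dev > dev_threshold
    # in a flagged pair, remove the animal that deviates against more
    # relatives (the likelier mislabelled sample); pedigree order breaks ties
    n_exceed = exceed.sum(axis=1)
    flagged = np.zeros(cur.n_animals, dtype=bool)
    ii, jj = np.nonzero(np.triu(exceed, k=1))
    for i, j in zip(ii, jj):
        if n_exceed[i] != n_exceed[j]:
            flagged[i if n_exceed[i] > n_exceed[j] else j] = True
        else:
            flagged[i if order[cur.animal_ids[i]] > order[cur.animal_ids[j]] else j] = True
    report.add("pedigree_genomic_deviation",
               [cur.animal_ids[i] for i in np.flatnonzero(flagged)])
    cur = cur.select_animals(~flagged)

    return cur, report


def impute_missing(panel: GenotypePanel, seed: int | None = 0,
                   deterministic: bool = False) -> GenotypePanel:
    """Fill missing calls from observed allele frequencies.

    Stochastic mode draws Binomial(2, p_j); deterministic mode rounds
    2*p_j. Raises if any SNP has no observed calls.
    """
    calls = panel.calls.copy()
    miss = calls < 0
    if not miss.any():
        return panel
    p = panel.allele_freq()
    dead = np.isnan(p)
    if dead.any():
        raise ValueError(
            f"{int(dead.sum())} SNPs have zero observed calls; filter them first")
    rows, cols = np.nonzero(miss)
    if deterministic:
        fill = np.round(2.0 * p[cols])
    else:
        rng = np.random.default_rng(seed)
        fill = rng.binomial(2, p[cols])
    calls[rows, cols] = fill.astype(np.int8)
    return GenotypePanel(list(panel.animal_ids), list(panel.snp_ids),
                         panel.chrom.copy(), panel.pos.copy(), calls)
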