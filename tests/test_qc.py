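"""Genotype panel merging, the QC filter cascade, and imputation."""

import numpy as np
import pytest

from ssgblup.pedigree import Pedigree
from ssgblup.qc import (MISSING, GenotypePanel, apply_animal_filters,
                        apply_snp_filters, impute_missing, intersect_panels,
                        read_panel_tsv)


def make_panel(ids, calls, chrom=None, pos=None, prefix="s"):
    calls = np.asarray(calls, dtype=np.int8)
    m = calls.shape[1]
    return GenotypePanel(
        list(ids), [f"{prefix}{j}" for j in range(m)],
        np.asarray(chrom if chrom is not None else ["1"] * m, dtype=object),
        np.asarray(pos if pos is not None else np.arange(1, m + 1)), calls)


@pytest.fixture
def founder_ped():
    return Pedigree.from_records([(a, None, None) for a in "ABCDEF"])


class TestIntersectPanels:
    def test_identical_marker_sets(self):
        a = make_panel(["A", "B"], [[0, 1, 2], [2, 1, 0]])
        b = make_panel(["C"], [[1, 1, 1]])
        merged = intersect_panels(a, b)
        assert merged.snp_ids == a.snp_ids
        assert merged.animal_ids == ["A", "B", "C"]

    def test_disjoint_markers_warn(self):
        a = make_panel(["A"], [[0, 1]], prefix="x")
        b = make_panel(["B"], [[1, 2]], prefix="y")
        with pytest.warns(UserWarning, match="no SNP ids"):
            merged = intersect_panels(a, b)
        assert merged.n_snps == 0

    def test_partial_overlap(self):
        rng = np.random.default_rng(0)
        a = GenotypePanel(["A1", "A2"], [f"m{j}" for j in range(10)],
                          np.asarray(["1"] * 10, dtype=object), np.arange(10),
                          rng.integers(0, 3, (2, 10)).astype(np.int8))
        shared = [f"m{j}" for j in (1, 3, 5, 7, 9)]
        b_ids = shared + ["q1", "q2", "q3"]
        b = GenotypePanel(["B1"], b_ids, np.asarray(["1"] * 8, dtype=object),
                          np.arange(8), rng.integers(0, 3, (1, 8)).astype(np.int8))
        merged = intersect_panels(a, b)
        assert merged.snp_ids == shared
        assert merged.n_animals == 3
        # calls follow each animal's original panel
        ja = [a.snp_ids.index(s) for s in shared]
        assert (merged.calls[0] == a.calls[0, ja]).all()

    def test_overlapping_animals_error(self):
        a = make_panel(["A"], [[0]])
        b = make_panel(["A"], [[1]])
        with pytest.raises(ValueError, match="share animal ids"):
            intersect_panels(a, b)


class TestSnpFilters:
    def test_clean_panel_unchanged(self, founder_ped):
        panel = make_panel(list("ABCDEF"), np.tile([0, 1, 2], (6, 4))[:, :4].T.T)
        # MAF 0.5, autosomal, known positions, complete
        panel = make_panel(list("ABCDEF"), [[0, 1, 2, 1]] * 3 + [[2, 1, 0, 1]] * 3)
        out, rep = apply_snp_filters(panel, founder_ped)
        assert out.n_snps == panel.n_snps
        assert all(k == 0 for _, k, _ in rep.steps)

    def test_maf_boundary_is_strict(self, founder_ped):
        # 6 animals, 12 alleles: one copy -> MAF 1/12 > 0.01; engineered
        # frequencies exactly at the threshold must be retained
        calls = np.zeros((6, 1), dtype=np.int8)
        calls[0, 0] = 1  # MAF = 1/12
        panel = make_panel(list("ABCDEF"), calls)
        out, _ = apply_snp_filters(panel, founder_ped, maf_min=1.0 / 12.0)
        assert out.n_snps == 1  # "lower than" is strict: tie retained

    def test_cascade_stage_order_and_counts(self, founder_ped):
        # columns: unknown-position, sex-chromosome, low-call-rate,
        # low-MAF, and two clean SNPs (animals x snps)
        calls = np.array([
            [0, 1, MISSING, 0, 1, 2],
            [1, 1, 1, 0, 1, 0],
            [2, 1, 2, 0, 0, 1],
            [0, 1, 1, 0, 2, 2],
            [1, 1, 0, 0, 1, 0],
            [2, 1, 2, 1, 0, 1],
        ], dtype=np.int8)
        chrom = ["0", "X", "1", "1", "1", "1"]
        pos = [-1, 5, 10, 15, 20, 25]
        panel = make_panel(list("ABCDEF"), calls, chrom=chrom, pos=pos)
        out, rep = apply_snp_filters(panel, founder_ped, call_rate_min=0.9,
                                     maf_min=0.2)
        names = [n for n, _, _ in rep.steps]
        assert names == ["unknown_position", "sex_chromosome", "call_rate",
                         "maf", "mendelian_error"]
        assert [k for _, k, _ in rep.steps] == [1, 1, 1, 1, 0]
        assert rep.n_after == rep.n_before - sum(k for _, k, _ in rep.steps)
        assert out.n_snps == rep.n_after == 2

    def test_threshold_validation(self, founder_ped):
        panel = make_panel(list("ABCDEF"), np.ones((6, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            apply_snp_filters(panel, founder_ped, call_rate_min=1.5)


class TestAnimalFilters:
    def test_clean_panel_unchanged(self, founder_ped):
        import pandas as pd
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.5, (6, 50)).astype(np.int8)
        panel = make_panel(list("ABCDEF"), calls)
        pheno = pd.DataFrame({"animal": list("ABCDEF"), "yw": 300.0})
        out, rep = apply_animal_filters(panel, founder_ped, pheno)
        assert out.n_animals == 6
        assert all(k == 0 for _, k, _ in rep.steps)

    def test_opposing_homozygote_offspring_flagged(self):
        import pandas as pd
        ped = Pedigree.from_records([("S", None, None), ("D", None, None),
                                     ("O", "S", "D")])
        rng = np.random.default_rng(2)
        m = 200
        sire = rng.binomial(2, 0.5, m).astype(np.int8)
        child = np.where(sire == 1, 1, sire).astype(np.int8)
        # make the child opposing-homozygous at 20% of SNPs
        hom = np.flatnonzero(sire != 1)
        bad = hom[: int(0.2 * m)]
        child[bad] = 2 - sire[bad]
        panel = make_panel(["S", "O"], np.vstack([sire, child]))
        pheno = pd.DataFrame({"animal": ["S", "O"], "yw": 300.0})
        out, rep = apply_animal_filters(panel, ped, pheno)
        removed = dict((n, ids) for n, _, ids in rep.steps)
        assert removed["parent_progeny_conflict"] == ["O"]

    def test_reordering_animals_permutes_not_changes(self, founder_ped):
        import pandas as pd
        rng = np.random.default_rng(3)
        calls = rng.binomial(2, 0.4, (6, 60)).astype(np.int8)
        calls[2, :30] = MISSING  # >10% missing for animal C
        pheno = pd.DataFrame({"animal": list("ABCDEF"), "yw": 300.0})
        pheno.loc[pheno.animal == "E", "yw"] = np.nan
        removed_sets = []
        for perm in ([0, 1, 2, 3, 4, 5], [5, 3, 1, 0, 2, 4]):
            panel = make_panel([list("ABCDEF")[i] for i in perm], calls[perm])
            _, rep = apply_animal_filters(panel, founder_ped, pheno)
            removed_sets.append(frozenset(i for _, _, ids in rep.steps for i in ids))
        assert removed_sets[0] == removed_sets[1] == {"C", "E"}


class TestImputeMissing:
    def test_no_missing_identity(self):
        panel = make_panel(["A", "B"], [[0, 1], [2, 1]])
        out = impute_missing(panel, seed=0)
        assert (out.calls == panel.calls).all()

    def test_fixed_frequency_one(self):
        calls = np.full((5, 3), 2, dtype=np.int8)
        calls[0, 0] = MISSING
        out = impute_missing(make_panel(list("ABCDE"), calls), seed=0)
        assert out.calls[0, 0] == 2

    def test_binomial_mean_at_half(self):
        rng = np.random.default_rng(4)
        calls = rng.binomial(2, 0.5, (100, 100)).astype(np.int8)
        miss = rng.random((100, 100)) < 0.10
        calls_m = np.where(miss, MISSING, calls).astype(np.int8)
        out = impute_missing(make_panel([f"a{i}" for i in range(100)], calls_m),
                             seed=7)
        imputed = out.calls[miss]
        assert 0.94 <= imputed.mean() <= 1.06

    def test_zero_called_snp_errors(self):
        calls = np.full((3, 2), MISSING, dtype=np.int8)
        calls[:, 1] = 1
        with pytest.raises(ValueError, match="zero observed"):
            impute_missing(make_panel(["A", "B", "C"], calls), seed=0)

    def test_deterministic_mode(self):
        calls = np.array([[2, 2], [2, 2], [MISSING, 0]], dtype=np.int8)
        out = impute_missing(make_panel(["A", "B", "C"], calls),
                             deterministic=True)
        assert out.calls[2, 0] == 2


def test_panel_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    calls = rng.integers(0, 3, (4, 6)).astype(np.int8)
    calls[1, 2] = MISSING
    panel = make_panel(["w", "x", "y", "z"], calls)
    panel.write_tsv(tmp_path / "g.tsv", tmp_path / "m.tsv")
    back = read_panel_tsv(tmp_path / "g.tsv", tmp_path / "m.tsv")
    assert back.animal_ids == panel.animal_ids
    assert back.snp_ids == panel.snp_ids
    assert (back.calls == panel.calls).all()
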