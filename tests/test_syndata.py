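"""Population simulator: pedigree structure, meiosis, genetic values,
variance calibration and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genopred import syndata
from genopred.syndata import (
    InvalidDesignError,
    MarkerMap,
    QTLSpec,
    TraitParams,
    assign_architecture,
    build_pedigree,
    compute_genetic_values,
    drop_genes,
    evenly_spaced_map,
    meiosis,
    simulate_founders,
    simulate_population,
)


class TestPedigree:
    @pytest.mark.parametrize(
        "sires,dams,prog,expected_total,expected_progeny",
        [
            (20, 10, 15, 3220, 3000),  # the full study design
            (1, 1, 1, 3, 1),
            (2, 2, 2, 14, 8),
        ],
    )
    def test_counts(self, sires, dams, prog, expected_total, expected_progeny):
        ped = build_pedigree(sires, dams, prog)
        assert len(ped) == expected_total
        assert (ped["generation"] == "progeny").sum() == expected_progeny

    def test_minimal_pedigree_links(self):
        ped = build_pedigree(1, 1, 1)
        child = ped[ped["generation"] == "progeny"].iloc[0]
        assert child["sire"] == 1 and child["dam"] == 2

    def test_structure_invariants(self):
        ped = build_pedigree(3, 2, 4)
        ids = ped["id"].to_numpy()
        assert np.all(np.diff(ids) > 0)
        founders = ped[ped["generation"] == "founder"]
        assert (founders[["sire", "dam"]] == 0).all().all()
        prog = ped[ped["generation"] == "progeny"]
        founder_ids = set(founders["id"])
        assert set(prog["sire"]) <= founder_ids
        assert set(prog["dam"]) <= founder_ids
        # each dam mated to exactly one sire, family sizes constant
        fam = prog.groupby("dam")["sire"].nunique()
        assert (fam == 1).all()
        assert (prog.groupby("dam").size() == 4).all()

    @given(s=st.integers(1, 5), d=st.integers(1, 5), p=st.integers(1, 5))
    @settings(max_examples=20, deadline=None)
    def test_count_formula(self, s, d, p):
        assert len(build_pedigree(s, d, p)) == s + s * d + s * d * p

    def test_invalid_counts(self):
        with pytest.raises(InvalidDesignError):
            build_pedigree(0, 10, 15)


class TestMap:
    def test_default_panel(self):
        m = evenly_spaced_map()
        assert m.n_snps == 1998
        assert list(m.chromosomes) == [1, 2, 3, 4, 5]
        for c in m.chromosomes:
            pos = m.position[m.snps_on(c)]
            assert np.all(np.diff(pos) > 0)
            assert pos.min() >= 0 and pos.max() <= 1.0
        # genome-wide even spacing
        gpos = m.position + (m.chromosome - 1) * 1.0
        assert np.allclose(np.diff(gpos), 5.0 / 1998)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            MarkerMap(chromosome=np.array([1, 1]), position=np.array([0.5, 0.2]))


class TestFounders:
    def test_forced_frequency_half(self):
        m = evenly_spaced_map(10, 1)
        haps = simulate_founders(m, 0.5, 0.5, 500, seed=0)
        freq = haps.mean(axis=(0, 1))
        assert np.all(np.abs(freq - 0.5) < 3 * np.sqrt(0.25 / 1000))

    def test_binomial_error_bound(self):
        m = evenly_spaced_map(1, 1)
        haps = simulate_founders(m, 0.2, 0.2, 1000, seed=3)
        freq = haps.mean()
        assert abs(freq - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 2000)

    def test_determinism(self):
        m = evenly_spaced_map(50, 2)
        h1 = simulate_founders(m, 0.1, 0.5, 20, seed=42)
        h2 = simulate_founders(m, 0.1, 0.5, 20, seed=42)
        assert np.array_equal(h1, h2)

    def test_bad_maf_bounds(self):
        m = evenly_spaced_map(10, 1)
        for lo, hi in [(0.0, 0.5), (0.3, 0.2), (0.1, 0.6)]:
            with pytest.raises(InvalidDesignError):
                simulate_founders(m, lo, hi, 5, seed=0)


class TestMeiosis:
    def test_zero_length_chromosome_intact(self):
        m = MarkerMap(chromosome=np.ones(5, dtype=int),
                      position=np.zeros(5), chrom_length=0.0)
        rng = np.random.default_rng(0)
        parent = np.array([[1, 1, 0, 0, 1], [0, 0, 1, 1, 0]], dtype=np.uint8)
        for _ in range(20):
            g = meiosis(parent, m, rng)
            assert np.array_equal(g, parent[0]) or np.array_equal(g, parent[1])

    def test_inheritance_closure(self):
        """Every progeny allele is a copy of a parental allele."""
        m = evenly_spaced_map(40, 2)
        ped = build_pedigree(2, 2, 3)
        founders = simulate_founders(m, 0.1, 0.5, 6, seed=1)
        haps = drop_genes(ped, founders, m, seed=2)
        row_of = {int(i): r for r, i in enumerate(ped["id"])}
        for r in np.flatnonzero((ped["generation"] == "progeny").to_numpy()):
            sr = row_of[int(ped["sire"].iloc[r])]
            dr = row_of[int(ped["dam"].iloc[r])]
            for slot, pr in ((0, sr), (1, dr)):
                ok = (haps[r, slot] == haps[pr, 0]) | (haps[r, slot] == haps[pr, 1])
                assert ok.all()

    def test_haldane_end_to_end_recombination(self):
        """Recombination fraction across 1 Morgan approaches the Haldane
        map-function value (1 - e^-2)/2."""
        m = MarkerMap(chromosome=np.array([1, 1]),
                      position=np.array([0.0, 1.0]), chrom_length=1.0)
        rng = np.random.default_rng(12345)
        parent = np.array([[1, 1], [0, 0]], dtype=np.uint8)  # doubly het
        n = 20_000
        rec = 0
        for _ in range(n):
            g = meiosis(parent, m, rng)
            rec += int(g[0] != g[1])
        expected = 0.5 * (1.0 - np.exp(-2.0))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec / n - expected) < 3 * se

    def test_mendelian_consistency(self):
        pop = simulate_population(n_sires=3, n_dams_per_sire=2,
                                  n_progeny_per_dam=4, n_snps=100,
                                  n_phenotyped_per_family=2, seed=5)
        assert syndata.mendelian_error_count(pop) == 0

    def test_allele_frequency_drift_bounded(self):
        pop = simulate_population(n_sires=10, n_dams_per_sire=5,
                                  n_progeny_per_dam=10, n_snps=200,
                                  n_phenotyped_per_family=5, seed=9)
        founder = ~pop.is_progeny
        f0 = pop.genotypes[founder].mean(axis=0) / 2
        f1 = pop.genotypes[pop.is_progeny].mean(axis=0) / 2
        n_prog = pop.is_progeny.sum()
        se = np.sqrt(np.maximum(f0 * (1 - f0), 1e-6) / (2 * n_prog))
        # cosegregation inflates drift above the i.i.d. binomial SE; 5 SEs
        # of the founder frequency still bounds it on this design
        assert np.all(np.abs(f1 - f0) < 5 * np.maximum(se, 0.05))


class TestArchitecture:
    def test_default_preset(self):
        m = evenly_spaced_map(1000, 5)
        qtl = assign_architecture(m)
        assert len(qtl) == 8
        assert sum(q.action == "additive" for q in qtl) == 5
        assert sum(q.action == "imprinted" for q in qtl) == 1
        assert sum(q.action == "epistatic_pair" for q in qtl) == 2
        chroms = sorted({int(m.chromosome[q.snp_index]) for q in qtl})
        assert chroms == [1, 2, 3, 4, 5]
        major = max(qtl, key=lambda q: abs(q.effect))
        assert m.chromosome[major.snp_index] == 1
        assert abs(major.effect) == pytest.approx(4.0)
        phases = {q.linkage_phase for q in qtl if q.action == "additive"}
        assert {"coupling", "repulsion"} <= phases

    def test_empty_custom_spec(self):
        m = evenly_spaced_map(100, 5)
        qtl = assign_architecture(m, preset=[])
        assert qtl == []
        haps = simulate_founders(m, 0.2, 0.5, 10, seed=0)
        tbv_a, tbv_t = compute_genetic_values(haps, qtl)
        assert np.all(tbv_t == 0) and np.all(tbv_a == 0)

    def test_unpaired_epistatic_rejected(self):
        m = evenly_spaced_map(100, 5)
        with pytest.raises((InvalidDesignError, ValueError)):
            assign_architecture(
                m, preset=[QTLSpec(3, "epistatic_pair", 1.0, partner_index=90),
                           QTLSpec(90, "additive", 1.0)])

    def test_off_map_rejected(self):
        m = evenly_spaced_map(100, 5)
        with pytest.raises(InvalidDesignError):
            assign_architecture(m, preset=[QTLSpec(100, "additive", 1.0)])


class TestGeneticValues:
    def test_additive_homozygote_difference(self):
        # dosage 2 vs dosage 0 differ by exactly 2a
        haps = np.zeros((3, 2, 1), dtype=np.uint8)
        haps[1, 0, 0] = 1  # het
        haps[2, :, 0] = 1  # hom alt
        _, tbv = compute_genetic_values(haps, [QTLSpec(0, "additive", 1.7)])
        assert tbv[2] - tbv[0] == pytest.approx(2 * 1.7)
        assert tbv[1] == pytest.approx(0.0)

    def test_imprinted_ordered_heterozygotes(self):
        """Enumerate all 4 ordered genotypes: only the paternal allele
        matters under paternal expression."""
        haps = np.array(
            [[[0], [0]], [[0], [1]], [[1], [0]], [[1], [1]]], dtype=np.uint8)
        e = 0.9
        _, tbv = compute_genetic_values(
            haps, [QTLSpec(0, "imprinted", e)])
        assert tbv == pytest.approx([-e, -e, +e, +e])
        # maternal expression flips the ordered heterozygotes
        _, tbv_m = compute_genetic_values(
            haps, [QTLSpec(0, "imprinted", e, imprint_origin="maternal")])
        assert tbv_m == pytest.approx([-e, +e, -e, +e])

    def test_epistatic_product_counted_once(self):
        rng = np.random.default_rng(0)
        haps = (rng.random((50, 2, 2)) < 0.4).astype(np.uint8)
        gamma = 1.3
        qtl = [QTLSpec(0, "epistatic_pair", gamma, partner_index=1),
               QTLSpec(1, "epistatic_pair", gamma, partner_index=0)]
        _, tbv = compute_genetic_values(haps, qtl)
        dos = haps.sum(axis=1)
        expected = gamma * (dos[:, 0] - 1.0) * (dos[:, 1] - 1.0)
        assert tbv == pytest.approx(expected)


class TestTraitAndPhenotypes:
    def test_trait_param_consistency(self):
        t = TraitParams()
        assert t.h2 == pytest.approx(0.3, abs=5e-4)
        with pytest.raises(InvalidDesignError):
            TraitParams(h2=0.5)

    def test_default_design_split(self):
        pop = simulate_population(n_snps=200, seed=0)
        assert pop.n_individuals == 3220
        assert pop.is_phenotyped.sum() == 2000
        assert pop.is_validation.sum() == 1000

    def test_variance_calibration_exact(self):
        pop = simulate_population(n_sires=4, n_dams_per_sire=3,
                                  n_progeny_per_dam=5, n_snps=150,
                                  n_phenotyped_per_family=3, seed=2)
        v = np.var(pop.tbv_additive[pop.is_progeny])
        assert v == pytest.approx(26.35, abs=1e-9)

    def test_noiseless_limit(self):
        pop = simulate_population(
            n_sires=2, n_dams_per_sire=2, n_progeny_per_dam=4, n_snps=100,
            n_phenotyped_per_family=2,
            trait=TraitParams(mu=5.0, sigma2_a=10.0, sigma2_e=1e-12), seed=3)
        obs = pop.is_phenotyped
        assert pop.phenotype[obs] == pytest.approx(
            5.0 + pop.tbv_total[obs], abs=1e-4)

    def test_phenotype_model_identity(self):
        pop = simulate_population(n_sires=3, n_dams_per_sire=2,
                                  n_progeny_per_dam=4, n_snps=100,
                                  n_phenotyped_per_family=2, seed=4)
        obs = pop.is_phenotyped
        assert pop.phenotype[obs] == pytest.approx(
            pop.trait.mu + pop.tbv_total[obs] + pop.residual[obs])

    def test_no_additive_qtl_rejected(self):
        m = evenly_spaced_map(100, 5)
        ped = build_pedigree(2, 2, 3)
        founders = simulate_founders(m, 0.2, 0.5, 6, seed=0)
        haps = drop_genes(ped, founders, m, seed=0)
        pop = syndata.SimulatedPopulation(haplotypes=haps, pedigree=ped,
                                          marker_map=m, qtl=[])
        with pytest.raises(InvalidDesignError, match="zero additive"):
            syndata.scale_and_phenotype(pop, TraitParams(), 2, seed=0)


class TestDeterminismAndIO:
    def test_byte_identical_outputs(self, tmp_path):
        kw = dict(n_sires=2, n_dams_per_sire=2, n_progeny_per_dam=4,
                  n_snps=60, n_phenotyped_per_family=2, seed=77)
        p1 = syndata.write_population(simulate_population(**kw),
                                      tmp_path / "a")
        p2 = syndata.write_population(simulate_population(**kw),
                                      tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_genotype_heterozygosity_consistency(self):
        pop = simulate_population(n_sires=2, n_dams_per_sire=2,
                                  n_progeny_per_dam=3, n_snps=80,
                                  n_phenotyped_per_family=2, seed=8)
        X = pop.genotypes
        W = pop.heterozygosity
        assert np.array_equal(X, pop.haplotypes.sum(axis=1))
        assert np.array_equal(W == 1, X == 1)
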