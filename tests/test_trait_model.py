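"""Gene effects, constrained epistasis tables, Kempthorne partition oracle,
genotypic values and fixed-heritability phenotypes."""
import numpy as np
import pytest

from panmixsel.trait_model import (EPISTASIS_TYPES, GeneEffects,
                                   TraitArchitecture, assign_epistatic_pairs,
                                   build_architecture, derive_gene_effects,
                                   genotypic_value, kempthorne_decompose,
                                   pair_variance_terms, phenotype, sample_I22,
                                   solve_epistatic_effects)

# F2 phenotypic ratios (out of 16) that define the classical types
F2_RATIOS = {
    "complementary": (9, 7),
    "duplicate": (15, 1),
    "dominant": (12, 3, 1),
    "recessive": (9, 3, 4),
    "dominant_and_recessive": (13, 3),
    "duplicate_cumulative": (9, 6, 1),
    "non_epistatic_interaction": (9, 3, 3, 1),
}


class TestGeneEffects:
    def test_single_gene_solution(self):
        eff = derive_gene_effects(1.1, 2.9, 1, dominance_degrees=[0.5])
        assert eff.m[0] == pytest.approx(2.0)
        assert eff.a[0] == pytest.approx(0.9)
        assert eff.d[0] == pytest.approx(0.45)

    def test_sums_exact_for_default_partition(self):
        eff = derive_gene_effects(1.1, 2.9, 1000, seed=0)
        assert np.sum(eff.m + eff.a) == pytest.approx(2.9)
        assert np.sum(eff.m - eff.a) == pytest.approx(1.1)
        assert eff.a.sum() == pytest.approx(0.9)
        assert 0.55 < eff.degree.mean() < 0.65  # Uniform(0, 1.2)

    def test_geometric_allocation_keeps_sums(self):
        eff = derive_gene_effects(1.1, 2.9, 50, seed=0, allocation="geometric")
        assert np.sum(eff.m + eff.a) == pytest.approx(2.9)
        assert eff.a[0] > eff.a[-1]

    def test_zero_degree_means_no_dominance(self):
        eff = derive_gene_effects(0.0, 2.0, 4, dominance_degrees=np.zeros(4))
        assert np.all(eff.d == 0)

    def test_errors(self):
        with pytest.raises(ValueError):
            derive_gene_effects(1.1, 2.9, 0)
        with pytest.raises(ValueError):
            derive_gene_effects(2.9, 1.1, 10)


class TestEpistaticPairs:
    def test_half_of_1000_genes_gives_250_pairs(self):
        pairs = assign_epistatic_pairs(np.arange(1000), 0.5, seed=1)
        assert len(pairs) == 250
        flat = [g for (i, j, _) in pairs for g in (i, j)]
        assert len(set(flat)) == 500  # disjoint pairs

    def test_zero_fraction(self):
        assert assign_epistatic_pairs(np.arange(10), 0.0) == []

    def test_seed_determinism(self):
        a = assign_epistatic_pairs(np.arange(100), 0.5, seed=42)
        b = assign_epistatic_pairs(np.arange(100), 0.5, seed=42)
        assert a == b

    def test_odd_count_warns_and_drops(self):
        with pytest.warns(RuntimeWarning):
            pairs = assign_epistatic_pairs(np.arange(10), 0.5, seed=2)
        assert len(pairs) == 2

    def test_fixed_type_policy(self):
        pairs = assign_epistatic_pairs(np.arange(20), 1.0, "duplicate", seed=3)
        assert all(t == "duplicate" for (_, _, t) in pairs)


class TestPartitions:
    def test_partitions_cover_nine_genotypes_once(self):
        for name, classes in EPISTASIS_TYPES.items():
            cells = [c for cls in classes for c in cls]
            assert len(cells) == 9 and len(set(cells)) == 9, name

    def test_f2_ratios(self):
        """Class probabilities in an F2 (both loci segregating 1:2:1) match
        the classical ratios the types are named after."""
        f2 = {0: 0.25, 1: 0.5, 2: 0.25}
        for name, classes in EPISTASIS_TYPES.items():
            probs = sorted((sum(f2[x] * f2[y] for (x, y) in cls)
                            for cls in classes), reverse=True)
            expect = sorted((r / 16 for r in F2_RATIOS[name]), reverse=True)
            assert probs == pytest.approx(expect), name


class TestSolver:
    @pytest.mark.parametrize("type_name", list(EPISTASIS_TYPES))
    def test_class_equality_and_count(self, type_name):
        m1, a1, d1 = 1.0, 0.4, 0.2
        m2, a2, d2 = 0.8, 0.3, 0.15
        I22 = 0.37
        I = solve_epistatic_effects(m1, a1, d1, m2, a2, d2, type_name, I22)
        alpha1, alpha2 = np.array([-a1, d1, a1]), np.array([-a2, d2, a2])
        G = m1 + m2 + alpha1[:, None] + alpha2[None, :] + I
        classes = EPISTASIS_TYPES[type_name]
        values = []
        for cls in classes:
            vals = [G[x, y] for (x, y) in cls]
            assert np.ptp(vals) < 1e-12  # constant within class
            values.append(vals[0])
        assert len(np.unique(np.round(values, 12))) == len(classes)
        assert G[2, 2] == pytest.approx(m1 + m2 + a1 + a2 + I22)

    def test_complementary_anchor(self):
        m1, a1, d1, m2, a2, d2 = 1.0, 0.4, 0.2, 0.8, 0.3, 0.15
        I = solve_epistatic_effects(m1, a1, d1, m2, a2, d2, "complementary", 0.1)
        assert I[0, 0] == 0.0  # anchored reference genotype
        G00 = m1 + m2 - a1 - a2 + I[0, 0]
        assert G00 == pytest.approx(m1 + m2 - a1 - a2)

    def test_unknown_type(self):
        with pytest.raises(ValueError):
            solve_epistatic_effects(1, 0.1, 0, 1, 0.1, 0, "triplicate", 0.0)


class TestSampleI22:
    def test_zero_variance_is_degenerate(self):
        assert sample_I22(1.5, 0.0, 0.0, 0.0, seed=0) == 0.0

    def test_monte_carlo_variance(self):
        k, sa, sd = 1.5, 0.8, 0.3
        draws = np.array([0.0])
        rng = np.random.default_rng(11)
        draws = np.array([sample_I22(k, sa, sd, 0.0, rng) for _ in range(100_000)])
        assert draws.var() == pytest.approx(k * (sa + sd), rel=0.02)

    def test_negative_variance_clamped(self):
        with pytest.warns(RuntimeWarning):
            assert sample_I22(1.0, 0.1, 0.1, -0.2, seed=0) == 0.0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            sample_I22(0.0, 1.0, 0.0, 0.0)

    def test_pair_variance_terms_zero_covariance(self):
        eff = derive_gene_effects(1.1, 2.9, 4, seed=0)
        sa, sd, sad = pair_variance_terms(eff, 0, 1, np.full(4, 0.4))
        assert sa > 0 and sd >= 0 and sad == 0.0


def _brute_force_partition(G, p_i, p_j):
    """Independent oracle: incremental weighted least squares over the nine
    genotypes with HWE x HWE weights, using raw (uncentered) regressors."""
    x = np.repeat(np.arange(3.0), 3)
    y = np.tile(np.arange(3.0), 3)
    hx, hy = (x == 1).astype(float), (y == 1).astype(float)
    wi = np.array([(1 - p_i) ** 2, 2 * p_i * (1 - p_i), p_i ** 2])
    wj = np.array([(1 - p_j) ** 2, 2 * p_j * (1 - p_j), p_j ** 2])
    w = (wi[:, None] * wj[None, :]).ravel()
    g = np.asarray(G, float).ravel()
    sw = np.sqrt(w)

    def rss(cols):
        Xd = np.column_stack([np.ones(9)] + cols) * sw[:, None]
        coef, *_ = np.linalg.lstsq(Xd, g * sw, rcond=None)
        r = g * sw - Xd @ coef
        return float(r @ r)

    terms = {
        "additive": [x, y],
        "dominance": [hx, hy],
        "axa": [x * y],
        "axd": [x * hy, hx * y],
        "dxd": [hx * hy],
    }
    cols, comps, prev = [], {}, rss([])
    for name, cc in terms.items():
        cols.extend(cc)
        cur = rss(cols)
        comps[name] = prev - cur
        prev = cur
    comps["total"] = rss([]) - prev
    return comps


class TestKempthorne:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_regression(self, seed):
        rng = np.random.default_rng(seed)
        p_i, p_j = rng.uniform(0.05, 0.95, 2)
        G = rng.normal(0.0, 1.0, (3, 3))
        comps, _ = kempthorne_decompose(G, p_i, p_j)
        oracle = _brute_force_partition(G, p_i, p_j)
        assert comps.additive == pytest.approx(oracle["additive"], abs=1e-10)
        assert comps.dominance == pytest.approx(oracle["dominance"], abs=1e-10)
        assert comps.axa == pytest.approx(oracle["axa"], abs=1e-10)
        assert comps.axd == pytest.approx(oracle["axd"], abs=1e-10)
        assert comps.dxd == pytest.approx(oracle["dxd"], abs=1e-10)
        total = (comps.additive + comps.dominance + comps.axa
                 + comps.axd + comps.dxd)
        assert total == pytest.approx(comps.total, abs=1e-10)

    def test_no_epistatic_effects_no_epistatic_variance(self):
        alpha1, alpha2 = np.array([-0.4, 0.1, 0.4]), np.array([-0.2, 0.0, 0.2])
        G = 1.0 + alpha1[:, None] + alpha2[None, :]
        comps, _ = kempthorne_decompose(G, 0.3, 0.7)
        assert comps.axa == pytest.approx(0.0, abs=1e-14)
        assert comps.axd == pytest.approx(0.0, abs=1e-14)
        assert comps.dxd == pytest.approx(0.0, abs=1e-14)

    def test_single_locus_collapse(self):
        # locus j invariant: p=0.5, d=0 gives sigma_A^2 = a^2/2
        a = 0.6
        G = np.tile(np.array([-a, 0.0, a])[:, None], (1, 3))
        comps, _ = kempthorne_decompose(G, 0.5, 1.0)
        assert comps.additive == pytest.approx(a * a / 2)
        assert comps.dominance == pytest.approx(0.0, abs=1e-14)
        assert comps.total == pytest.approx(comps.additive)

    def test_degenerate_frequency(self):
        comps, _ = kempthorne_decompose(np.ones((3, 3)), 0.0, 0.5)
        assert comps.total == pytest.approx(0.0)


class TestGenotypicValue:
    def test_all_heterozygote_without_epistasis(self):
        eff = derive_gene_effects(1.1, 2.9, 5, dominance_degrees=np.full(5, 0.5))
        arch = TraitArchitecture(eff, [], 1.1, 2.9, 1.0, 3.5, 0.3)
        fav = np.ones((1, 5))  # dosage 1 everywhere
        g = genotypic_value(fav, arch)
        assert g[0] == pytest.approx(np.sum(eff.m + eff.d))

    def test_double_homozygote_with_pair(self, toy_arch):
        pair = toy_arch.pairs[0]
        eff = toy_arch.effects
        fav = np.full((1, toy_arch.n_qtl), 2)  # all favorable
        fav[0, pair.i] = 0  # unfavorable homozygote (u = 2)
        fav[0, pair.j] = 0
        g = genotypic_value(fav, toy_arch)
        # remove the other loci and pairs to isolate the target pair
        base_rest = sum(eff.m[k] - eff.a[k] for k in range(toy_arch.n_qtl)
                        if k not in (pair.i, pair.j))
        other = sum(p.I[0, 0] for p in toy_arch.pairs if p is not pair)
        expected = (base_rest + other + eff.m[pair.i] + eff.m[pair.j]
                    + eff.a[pair.i] + eff.a[pair.j] + pair.I[2, 2])
        assert g[0] == pytest.approx(expected)

    def test_population_mean_within_interval(self, toy_map, toy_founders, toy_arch):
        g = genotypic_value(toy_founders.dosage(toy_map.qtl_cols), toy_arch)
        i_bound = sum(np.abs(p.I).max() for p in toy_arch.pairs)
        assert toy_arch.g_min - i_bound <= g.mean() <= toy_arch.g_max + i_bound


class TestPhenotype:
    def test_realized_heritability(self):
        rng = np.random.default_rng(5)
        g = rng.normal(2.0, 0.12, 4000)
        y, var_e = phenotype(g, 0.30, -10.0, 10.0, seed=6)
        h2_hat = g.var() / y.var()
        assert h2_hat == pytest.approx(0.30, abs=0.02)
        assert var_e == pytest.approx(g.var() * 0.7 / 0.3)

    def test_h2_one_returns_genotypes(self):
        g = np.array([1.5, 2.0, 2.5])
        y, var_e = phenotype(g, 1.0 - 1e-12, 1.0, 3.5, seed=0)
        assert np.allclose(y, g, atol=1e-4)

    def test_bounds_enforced(self):
        rng = np.random.default_rng(7)
        g = rng.normal(2.0, 0.5, 1000)
        with pytest.warns(RuntimeWarning):
            y, _ = phenotype(g, 0.3, 1.0, 3.5, seed=8)
        assert y.min() >= 1.0 and y.max() <= 3.5

    def test_zero_variance_needs_fallback(self):
        g = np.full(10, 2.0)
        with pytest.raises(ValueError):
            phenotype(g, 0.3, 1.0, 3.5, seed=0)
        with pytest.warns(RuntimeWarning):
            y, var_e = phenotype(g, 0.3, 1.0, 3.5, seed=0, fallback_error_var=0.01)
        assert var_e == 0.01


class TestArchitecture:
    def test_yaml_roundtrip(self, toy_arch, tmp_path):
        path = tmp_path / "arch.yaml"
        toy_arch.to_yaml(path)
        back = TraitArchitecture.from_yaml(path)
        assert np.allclose(back.effects.m, toy_arch.effects.m)
        assert np.allclose(back.effects.d, toy_arch.effects.d)
        assert len(back.pairs) == len(toy_arch.pairs)
        for p, q in zip(back.pairs, toy_arch.pairs):
            assert (p.i, p.j, p.type_name) == (q.i, q.j, q.type_name)
            assert np.allclose(p.I, q.I)

    def test_bounds_invariant_enforced(self):
        eff = GeneEffects(m=np.array([2.0]), a=np.array([0.5]),
                          d=np.array([0.0]), degree=np.array([0.0]))
        with pytest.raises(ValueError):
            TraitArchitecture(eff, [], 1.1, 2.9, 1.0, 3.5, 0.3)

    def test_epistatic_variance_share_is_small(self, toy_map, toy_founders):
        """Across the default architecture with epistasis the epistatic
        variances are a minor share of the genotypic variance."""
        fav = toy_founders.dosage(toy_map.qtl_cols).mean(axis=0) / 2.0
        arch = build_architecture(toy_map.n_qtl, gen0_fav_freq=fav,
                                  epistasis_fraction=0.5, seed=33)
        p_unfav = 1.0 - fav
        epi = tot = 0.0
        for pair in arch.pairs:
            comps, _ = kempthorne_decompose(pair.genotypic_table(arch.effects),
                                            p_unfav[pair.i], p_unfav[pair.j])
            epi += comps.axa + comps.axd + comps.dxd
            tot += comps.total
        g = genotypic_value(toy_founders.dosage(toy_map.qtl_cols), arch)
        assert epi / g.var() < 0.10
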