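"""QTL mapping: normalization, forward selection, fine mapping, FDR."""

import numpy as np
import pandas as pd
import pytest

from remergence import (
    CrossSimParams,
    GenomeModel,
    GenotypeMatrix,
    PhenotypePanel,
    VariantLocus,
    append_pseudo_genotypes,
    fine_map_qtn,
    forward_select,
    normalize_phenotypes,
    permutation_fdr,
    simulate_f6_cross,
    variance_explained,
)


def _panel(values, plates=None):
    n = len(values)
    return PhenotypePanel(
        pd.DataFrame(
            {
                "progeny": [f"p{i}" for i in range(n)],
                "replicate": 0,
                "plate": plates if plates is not None else 0,
                "row": 0,
                "col": np.arange(n) % 4,
                "colony_size": values,
            }
        )
    )


def _sim_design(n=500, n_markers=300, qtns=(), seed=0, noise_sd=1.0,
                plate_effect_sd=0.0):
    cp = CrossSimParams(
        n_progeny=n, n_markers=n_markers, qtns=tuple(qtns), noise_sd=noise_sd,
        plate_effect_sd=plate_effect_sd,
    )
    mat, phen, truth = simulate_f6_cross(
        cp, GenomeModel.yeast(0.25), np.random.default_rng(seed)
    )
    panel = PhenotypePanel(phen)
    y = normalize_phenotypes(panel).reindex(mat.strains).to_numpy()
    design = append_pseudo_genotypes(mat, panel)
    return mat, design, y, truth


class TestNormalizePhenotypes:
    def test_zscore_properties(self):
        y = normalize_phenotypes(_panel([1.0, 2.0, 3.0, 7.0]))
        assert y.mean() == pytest.approx(0.0, abs=1e-12)
        assert y.std(ddof=0) == pytest.approx(1.0)

    def test_replicate_mean_first(self):
        panel = PhenotypePanel(
            pd.DataFrame(
                {
                    "progeny": ["a", "a", "b", "b"],
                    "colony_size": [1.0, 3.0, 5.0, 9.0],
                }
            )
        )
        means = panel.progeny_means()
        assert means["a"] == 2.0 and means["b"] == 7.0

    def test_affine_invariance(self, rng):
        raw = rng.normal(10, 3, 50)
        a = normalize_phenotypes(_panel(raw))
        b = normalize_phenotypes(_panel(4.2 * raw - 17.0))
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            normalize_phenotypes(_panel([2.0, 2.0, 2.0]))


class TestPseudoGenotypes:
    def _tiny_matrix(self, n):
        loci = [VariantLocus("chrI", p + 1, "A", "G") for p in range(3)]
        calls = (np.arange(3 * n).reshape(n, 3) % 2).astype(np.int8)
        return GenotypeMatrix.from_loci([f"p{i}" for i in range(n)], loci, calls)

    def test_single_plate_contributes_nothing(self):
        m = self._tiny_matrix(6)
        design = append_pseudo_genotypes(m, _panel(np.arange(6.0)))
        assert not any(n.startswith("plate") for n in design.names)

    def test_two_plates_one_indicator(self):
        m = self._tiny_matrix(6)
        design = append_pseudo_genotypes(
            m, _panel(np.arange(6.0), plates=[0, 0, 0, 1, 1, 1])
        )
        assert sum(n.startswith("plate") for n in design.names) == 1
        assert not design.is_genetic[-1]

    def test_plate_effect_absorbed_no_spurious_qtl(self):
        """A strong planted plate artifact is captured by the
        pseudo-genotypes and produces no genetic QTL at p_retain."""
        _, design, y, _ = _sim_design(
            n=400, n_markers=200, qtns=(), seed=3, noise_sd=0.5,
            plate_effect_sd=2.0,
        )
        model = forward_select(design, y)
        assert model.n_qtls == 0
        assert (~model.terms["is_genetic"]).any()  # plate term was selected

    def test_pseudo_never_reported_as_qtl(self):
        _, design, y, _ = _sim_design(
            n=300, n_markers=100, qtns=((50, 0.8),), seed=4, plate_effect_sd=1.0
        )
        model = forward_select(design, y)
        assert (model.genetic_terms["marker_index"] >= 0).all()


class TestForwardSelection:
    def test_null_rarely_selects(self):
        """Pure-noise phenotypes: no genetic term retained in >= 95% of
        seeds at the default thresholds."""
        zero = 0
        n_seeds = 20
        for seed in range(n_seeds):
            _, design, _, _ = _sim_design(n=300, n_markers=150, qtns=(), seed=seed)
            y = np.random.default_rng(1000 + seed).normal(size=design.n_obs)
            if forward_select(design, y).n_qtls == 0:
                zero += 1
        assert zero >= int(0.95 * n_seeds)

    def test_recovers_single_planted_qtn(self):
        """One planted 0.5 SD effect at n=1125 is retained (possibly as a
        perfectly linked neighbor)."""
        mat, design, y, truth = _sim_design(
            n=1125, n_markers=400, qtns=((123, 0.5),), seed=7
        )
        model = forward_select(design, y)
        assert model.n_qtls >= 1
        g_true = mat.calls[:, 123].astype(float)
        best_r2 = max(
            np.corrcoef(g_true, mat.calls[:, int(mk)].astype(float))[0, 1] ** 2
            for mk in model.genetic_terms["marker_index"]
        )
        assert best_r2 > 0.95

    def test_recovers_three_additive_qtns(self):
        """Three planted additive effects (0.4/0.3/0.2 SD) are all
        recovered with effects within 3 SE.  The panel is sized so the
        smallest effect has power at p_retain = 1e-5."""
        n = 3000
        mat, design, y, truth = _sim_design(
            n=n, n_markers=400, qtns=((60, 0.4), (200, 0.3), (340, 0.2)),
            seed=11,
        )
        model = forward_select(design, y)
        planted = {60: 0.4, 200: 0.3, 340: 0.2}
        # raw progeny-level phenotype: genetic variance a^2 q(1-q) per QTN
        # plus replicate-averaged noise (duplicates halve the variance)
        raw_sd = np.sqrt(0.5 + sum(e**2 * 0.25 for e in planted.values()))
        found = {}
        for _, row in model.genetic_terms.iterrows():
            g = mat.calls[:, int(row["marker_index"])].astype(float)
            for mk, eff in planted.items():
                if np.corrcoef(g, mat.calls[:, mk].astype(float))[0, 1] ** 2 > 0.9:
                    found[mk] = row["effect"]
        assert set(found) == set(planted)
        se = 2.0 / np.sqrt(n)  # conservative SE of a 0/1-covariate effect
        for mk, eff in planted.items():
            assert abs(found[mk] - eff / raw_sd) < 3 * se

    def test_deterministic(self):
        _, design, y, _ = _sim_design(n=200, n_markers=80, qtns=((30, 0.7),), seed=2)
        a = forward_select(design, y)
        b = forward_select(design, y)
        assert a.terms.equals(b.terms)


class TestVarianceExplained:
    def test_noise_free_single_qtn_explains_everything(self):
        _, design, y, _ = _sim_design(
            n=200, n_markers=50, qtns=((25, 1.0),), seed=5, noise_sd=1e-12
        )
        model = forward_select(design, y)
        assert model.terms["variance_explained"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_matches_closed_form(self):
        """Effect a over duplicate-averaged unit noise explains
        a^2 q (1-q) / (a^2 q (1-q) + 1/2) of the progeny-level variance
        (q = allele frequency ~ 0.5; duplicates halve the noise)."""
        a = 0.5
        mat, design, y, _ = _sim_design(
            n=2000, n_markers=60, qtns=((30, a),), seed=6
        )
        model = forward_select(design, y)
        q = mat.calls[:, 30].mean()
        v = a**2 * q * (1 - q)
        expected = v / (v + 0.5)
        got = model.genetic_terms["variance_explained"].sum()
        assert got == pytest.approx(expected, abs=0.03)

    def test_null_model_zero(self):
        _, design, y, _ = _sim_design(n=200, n_markers=50, qtns=(), seed=9)
        model = forward_select(design, y)
        assert model.terms["variance_explained"].sum() <= 0.1
        assert (model.terms["variance_explained"] >= 0).all()


class TestFineMapping:
    def _direct_design(self, g, y, names=None):
        n, p = g.shape
        loci = [VariantLocus("chrI", 10 * (j + 1), "A", "G") for j in range(p)]
        mat = GenotypeMatrix.from_loci(
            [f"p{i}" for i in range(n)], loci, g.astype(np.int8)
        )
        panel = _panel(y)
        design = append_pseudo_genotypes(mat, panel)
        return mat, design

    def test_single_candidate_resolved(self, rng):
        g = rng.integers(0, 2, size=(300, 1))
        y = 0.8 * g[:, 0] + rng.normal(size=300)
        y = (y - y.mean()) / y.std()
        mat, design = self._direct_design(g, y)
        model = forward_select(design, y)
        prof = fine_map_qtn(model, 0, mat, y, design)
        assert prof.resolved and prof.best_marker == 0

    def test_perfect_ld_unresolved(self, rng):
        g0 = rng.integers(0, 2, size=300)
        g = np.column_stack([g0, g0])  # perfect linkage
        y = 0.8 * g0 + rng.normal(size=300)
        y = (y - y.mean()) / y.std()
        mat, design = self._direct_design(g, y)
        model = forward_select(design, y)
        qtl = int(model.genetic_terms["marker_index"].iloc[0])
        prof = fine_map_qtn(model, qtl, mat, y, design)
        assert not prof.resolved
        assert prof.best_marker is None

    def test_planted_variant_wins_against_partial_ld(self):
        """Causal variant flanked by r^2 ~ 0.9 neighbors: top QTN score at
        the planted variant in >= 90% of seeds (n = 2000 progeny)."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(300 + seed)
            n = 2000
            causal = rng.integers(0, 2, size=n)
            neighbors = []
            for _ in range(2):
                nb = causal.copy()
                flip = rng.random(n) < 0.05  # r^2 ~ 0.81-0.9
                nb[flip] = 1 - nb[flip]
                neighbors.append(nb)
            g = np.column_stack([neighbors[0], causal, neighbors[1]])
            y = 0.5 * causal + rng.normal(size=n)
            y = (y - y.mean()) / y.std()
            mat, design = self._direct_design(g, y)
            model = forward_select(design, y)
            if model.n_qtls == 0:
                continue
            qtl = int(model.genetic_terms["marker_index"].iloc[0])
            prof = fine_map_qtn(model, qtl, mat, y, design, r2_min=0.5)
            if prof.scores[prof.candidates == 1][0] == prof.scores.max():
                hits += 1
        assert hits >= int(0.9 * n_seeds)


class TestPermutationFdr:
    def test_strong_qtns_low_fdr(self):
        """Three strong planted effects: empirical FDR below 10% at the
        default thresholds."""
        _, design, y, _ = _sim_design(
            n=600, n_markers=200, qtns=((40, 0.5), (100, 0.45), (160, 0.4)),
            seed=13,
        )
        fdr = permutation_fdr(design, y, n_perms=12, rng=np.random.default_rng(0))
        assert not fdr.degenerate
        assert fdr.fdr < 0.10

    def test_null_flagged_degenerate(self):
        _, design, _, _ = _sim_design(n=200, n_markers=80, qtns=(), seed=17)
        y = np.random.default_rng(5).normal(size=design.n_obs)
        fdr = permutation_fdr(design, y, n_perms=10, rng=np.random.default_rng(1))
        if fdr.n_real == 0:
            assert fdr.degenerate and fdr.fdr == 1.0

    def test_stable_under_more_permutations(self):
        _, design, y, _ = _sim_design(
            n=400, n_markers=120, qtns=((60, 0.6),), seed=19
        )
        a = permutation_fdr(design, y, n_perms=10, rng=np.random.default_rng(2))
        b = permutation_fdr(design, y, n_perms=20, rng=np.random.default_rng(3))
        assert abs(a.fdr - b.fdr) < 0.3

    def test_min_permutations_enforced(self):
        _, design, y, _ = _sim_design(n=100, n_markers=30, qtns=(), seed=23)
        with pytest.raises(ValueError):
            permutation_fdr(design, y, n_perms=5)
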