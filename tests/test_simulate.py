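"""Forward simulators: mutations, meiosis, admixture, balancing, neutral
placement and the inbred cross."""

import collections

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from remergence import (
    AdmixtureParams,
    BalancingParams,
    CrossSimParams,
    GenomeModel,
    MutationModel,
    PhyloTree,
    build_admixed_population,
    generate_random_mutations,
    overlay_balanced_polymorphisms,
    place_neutral_variants_on_tree,
    simulate_f6_cross,
    simulate_meiosis,
)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class TestRandomMutations:
    def test_zero_is_empty(self, rng):
        assert generate_random_mutations(0, rng=rng) == []

    def test_too_many_errors(self, rng):
        g = GenomeModel(names=("c1",), lengths=(10,))
        with pytest.raises(ValueError):
            generate_random_mutations(11, g, rng=rng)

    def test_tstv_calibration(self, rng):
        """At kappa = 3 the transition fraction is 0.75 (tolerance 0.005
        at n = 1e5, ~3.6 binomial SE)."""
        events = generate_random_mutations(100_000, rng=rng)
        ts = np.mean([(e.ref_allele, e.alt_allele) in TRANSITIONS for e in events])
        assert ts == pytest.approx(0.75, abs=0.005)
        assert all(e.is_transition == ((e.ref_allele, e.alt_allele) in TRANSITIONS)
                   for e in events[:1000])

    def test_chromosome_occupancy_proportional_to_length(self, rng):
        genome = GenomeModel.yeast()
        events = generate_random_mutations(50_000, genome, rng=rng)
        counts = collections.Counter(e.chromosome for e in events)
        observed = np.array([counts[c] for c in genome.names])
        expected = 50_000 * np.array(genome.lengths) / genome.total_length
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=genome.n_chromosomes - 1)
        assert p > 0.01

    def test_sites_unique_within_lineage(self, rng):
        g = GenomeModel(names=("c1",), lengths=(500,))
        events = generate_random_mutations(400, g, rng=rng)
        pos = [(e.chromosome, e.position) for e in events]
        assert len(set(pos)) == len(pos)


class TestMeiosis:
    def _variants(self, genome, positions, chrom="chrI"):
        return pd.DataFrame(
            {
                "chrom": pd.Categorical(
                    [chrom] * len(positions), categories=list(genome.names),
                    ordered=True,
                ),
                "pos": np.array(positions),
            }
        )

    def test_identical_parents_identity(self, rng):
        g = GenomeModel.yeast(0.01)
        v = self._variants(g, [10, 50, 90, 200])
        p = np.array([0, 1, 0, 1], dtype=np.int8)
        child, bp = simulate_meiosis(p, p, v, g, rng)
        assert np.array_equal(child, p)
        assert len(bp) == 16

    def test_two_segment_mosaic_all_patterns(self):
        """On one chromosome with 4 markers, the child is a two-segment
        mosaic; every breakpoint interval is reachable over seeds."""
        g = GenomeModel(names=("c1",), lengths=(100,))
        v = self._variants(g, [10, 30, 60, 90], chrom="c1")
        pa = np.zeros(4, dtype=np.int8)
        pb = np.ones(4, dtype=np.int8)
        seen = set()
        for seed in range(300):
            child, _ = simulate_meiosis(pa, pb, v, g, np.random.default_rng(seed))
            seen.add(tuple(child.tolist()))
        expected = set()
        for cut in range(5):  # breakpoint before marker `cut`
            for first in (0, 1):
                expected.add(tuple([first] * cut + [1 - first] * (4 - cut)))
        assert seen <= expected
        # every 2-segment pattern with a breakpoint strictly inside is seen
        interior = {p for p in expected if len(set(p)) == 2}
        assert interior <= seen

    def test_every_call_from_a_parent(self, rng):
        g = GenomeModel.yeast(0.01)
        pos = np.sort(rng.choice(2000, size=30, replace=False) + 1)
        v = self._variants(g, pos)
        pa = rng.integers(0, 2, 30).astype(np.int8)
        pb = rng.integers(0, 2, 30).astype(np.int8)
        child, _ = simulate_meiosis(pa, pb, v, g, rng)
        assert ((child == pa) | (child == pb)).all()


class TestAdmixedPopulation:
    def test_counts_and_strains(self, small_population):
        pop = small_population
        assert pop.matrix.n_strains == 15
        assert len(pop.events) == 5 * 600 + 15 * 200

    def test_founders_only_no_homoplasy_when_sites_distinct(self, small_genome):
        params = AdmixtureParams(
            n_founders=5, muts_per_founder=50, n_mosaics=0, muts_per_strain_post=0
        )
        pop = build_admixed_population(
            params, small_genome, rng=np.random.default_rng(0)
        )
        counts = pop.true_emergence_counts()
        sites = pop.events["site"]
        if sites.is_unique:
            assert pop.true_homoplasy_count() == 0
        assert (counts >= 1).all()

    def test_truth_log_recounts_homoplasy(self, small_population):
        """True homoplasy equals a brute-force recount of sites with >= 2
        independent origination records."""
        pop = small_population
        tally = collections.Counter(pop.events["site"])
        brute = sum(1 for c in tally.values() if c >= 2)
        assert pop.true_homoplasy_count() == brute

    def test_conservation_alt_calls_equal_event_propagations(self, small_population):
        pop = small_population
        assert int((pop.matrix.calls == 1).sum()) == int(pop.events["carriers"].sum())

    def test_seeded_determinism(self, small_genome):
        params = AdmixtureParams(muts_per_founder=200, muts_per_strain_post=50)
        a = build_admixed_population(params, small_genome, rng=np.random.default_rng(5))
        b = build_admixed_population(params, small_genome, rng=np.random.default_rng(5))
        assert a.matrix == b.matrix
        assert a.events.equals(b.events)

    def test_mosaics_need_two_founders(self):
        with pytest.raises(ValueError):
            AdmixtureParams(n_founders=1, n_mosaics=2)


class TestBalancingOverlay:
    def test_zero_fraction_unchanged(self, small_population, rng):
        out = overlay_balanced_polymorphisms(
            small_population, BalancingParams(0.0, 0.5), rng=rng
        )
        assert out is small_population

    def test_count_is_round_f_times_events(self, small_population, rng):
        out = overlay_balanced_polymorphisms(
            small_population, BalancingParams(0.1, 0.5), rng=rng
        )
        n_total = len(small_population.events)
        assert int(out.balanced.sum()) == round(0.1 * n_total)
        assert out.matrix.n_loci == small_population.matrix.n_loci + round(0.1 * n_total)

    def test_mean_carriers_matches_binomial(self, small_population, rng):
        """MAF = 2^-5 with 15 strains: mean alt carriers per balanced locus
        is 15/32 within 3 SE."""
        maf = 2.0**-5
        out = overlay_balanced_polymorphisms(
            small_population, BalancingParams(0.5, maf), rng=rng
        )
        n_bal = int(out.balanced.sum())
        carriers = out.matrix.alt_counts()[out.balanced]
        se = np.sqrt(15 * maf * (1 - maf) / n_bal)
        assert abs(carriers.mean() - 15 * maf) < 3 * se

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            BalancingParams(-0.1, 0.5)
        with pytest.raises(ValueError):
            BalancingParams(0.1, 0.7)
        with pytest.raises(ValueError):
            BalancingParams(0.1, 0.0)


class TestNeutralPlacement:
    def test_terminal_branch_single_leaf(self, small_genome, rng):
        t = PhyloTree.from_newick("(A:1,(B:0.0001,C:0.0001):0.0001);")
        pop = place_neutral_variants_on_tree(t, 200, small_genome, rng)
        # nearly all mass on A's branch
        on_a = (pop.matrix.calls[pop.matrix.strains.index("A")] == 1)
        single = pop.matrix.alt_counts() == 1
        assert (on_a & single).mean() > 0.9
        for j in np.flatnonzero(on_a):
            assert pop.matrix.alt_counts()[j] == 1

    def test_internal_branch_propagates_to_clade(self, small_genome, rng):
        t = PhyloTree.from_newick("((A:0.0001,B:0.0001):1,(C:0.0001,D:0.0001):0.0001);")
        pop = place_neutral_variants_on_tree(t, 100, small_genome, rng)
        idx = [pop.matrix.strains.index(s) for s in ("A", "B")]
        both_ab = (pop.matrix.calls[idx] == 1).all(axis=0)
        assert both_ab.mean() > 0.9

    def test_branch_counts_proportional_to_length(self, small_population, rng):
        from remergence import neighbor_joining, snp_distance_matrix

        tree = neighbor_joining(snp_distance_matrix(small_population.matrix))
        lengths, desc = tree.edge_descendants()
        pop = place_neutral_variants_on_tree(tree, 10_000, rng=rng)
        counts = collections.Counter(pop.events["lineage"])
        observed = np.array([counts[f"branch{i}"] for i in range(len(lengths))])
        keep = lengths > 0
        expected = 10_000 * lengths / lengths.sum()
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2.sf(chi2, df=keep.sum() - 1) > 0.01

    def test_zero_length_tree_errors(self, small_genome, rng):
        t = PhyloTree.from_newick("(A:0,(B:0,C:0):0);")
        with pytest.raises(ValueError, match="branch length"):
            place_neutral_variants_on_tree(t, 10, small_genome, rng)

    def test_truth_marks_single_emergence(self, small_genome, rng):
        t = PhyloTree.from_newick("(A:1,(B:1,C:1):1);")
        pop = place_neutral_variants_on_tree(t, 50, small_genome, rng)
        assert (pop.true_emergence_counts() == 1).all()


class TestCrossSimulation:
    def test_no_qtns_no_noise_constant_phenotype(self, rng):
        cp = CrossSimParams(
            n_progeny=20, n_markers=40, qtns=(), noise_sd=0.0, plate_effect_sd=0.0
        )
        _, phen, _ = simulate_f6_cross(cp, GenomeModel.yeast(0.01), rng)
        assert phen["colony_size"].nunique() == 1

    def test_single_qtn_exact_separation(self, rng):
        cp = CrossSimParams(
            n_progeny=40, n_markers=40, qtns=((7, 1.0),), noise_sd=0.0,
            plate_effect_sd=0.0,
        )
        mat, phen, _ = simulate_f6_cross(cp, GenomeModel.yeast(0.01), rng)
        means = phen.groupby("progeny", sort=False)["colony_size"].mean()
        g = pd.Series(mat.calls[:, 7], index=mat.strains)
        vals = sorted(means.groupby(g).mean())
        assert vals[1] - vals[0] == pytest.approx(1.0)

    def test_replicates_share_genotype_plates_assigned(self, rng):
        cp = CrossSimParams(n_progeny=30, n_markers=20, n_replicates=3,
                            plate_shape=(4, 6))
        _, phen, _ = simulate_f6_cross(cp, GenomeModel.yeast(0.01), rng)
        assert (phen.groupby("progeny").size() == 3).all()
        assert phen["plate"].nunique() == int(np.ceil(90 / 24))

    def test_linkage_decay(self):
        """Correlation between marker genotypes decreases with distance."""
        cp = CrossSimParams(n_progeny=1000, n_markers=300, qtns=())
        mat, _, _ = simulate_f6_cross(
            cp, GenomeModel.yeast(0.5), np.random.default_rng(21)
        )
        g = mat.calls.astype(float)
        v = mat.variants
        r2_near, r2_far = [], []
        chrom = v["chrom"].cat.codes.to_numpy()
        pos = v["pos"].to_numpy()
        for j in range(mat.n_loci - 1):
            for k in (j + 1, j + 8):
                if k >= mat.n_loci or chrom[j] != chrom[k]:
                    continue
                r = np.corrcoef(g[:, j], g[:, k])[0, 1]
                d = pos[k] - pos[j]
                (r2_near if d < 50_000 else r2_far).append(r**2)
        assert np.mean(r2_near) > np.mean(r2_far)
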