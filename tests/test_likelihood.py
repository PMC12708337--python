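import numpy as np
import pytest

from mitocongruence.alignment import Alignment
from mitocongruence.experiments import (
    enumerated_site_loglik,
    jc_site_loglik_closed_form,
)
from mitocongruence.likelihood import (
    AlignmentData,
    LikelihoodEngine,
    optimize_parameters,
    site_log_likelihoods,
)
from mitocongruence.model import ModelParams, jc_params
from mitocongruence.simulate import simulate_alignment
from mitocongruence.tree import PhyloTree, sample_species_tree

PARAMS = ModelParams(
    r_ac_at=1.0, r_ag=4.0, r_cg_gt=1.5, r_ct=8.0,
    freqs=np.array([0.35, 0.25, 0.15, 0.25]),
    alpha=0.6, pinv=0.15, ncat=4,
)


class TestPruningCorrectness:
    @pytest.mark.parametrize("n_taxa,nsites", [(4, 20), (5, 10), (6, 6)])
    def test_matches_exhaustive_enumeration(self, n_taxa, nsites):
        """Pruning equals the sum over all internal-state assignments."""
        tree = sample_species_tree(n_taxa, seed=n_taxa)
        aln = simulate_alignment(tree, PARAMS, nsites, seed=n_taxa + 50)
        mine = site_log_likelihoods(tree, aln, PARAMS).values
        ref = enumerated_site_loglik(tree, aln, PARAMS)
        assert np.abs(mine - ref).max() < 1e-8

    def test_handles_ambiguity_and_gaps(self):
        tree = PhyloTree.from_newick(
            "(a:0.1,b:0.2,(c:0.15,d:0.3):0.1);"
        )
        aln = Alignment.from_sequences(
            {"a": "ARN-", "b": "ACGT", "c": "AC-T", "d": "WCGT"}
        )
        mine = site_log_likelihoods(tree, aln, PARAMS).values
        ref = enumerated_site_loglik(tree, aln, PARAMS)
        assert np.abs(mine - ref).max() < 1e-8

    def test_jc_collapse_matches_closed_form(self):
        tree = sample_species_tree(6, seed=2)
        jc = jc_params(ncat=1)
        aln = simulate_alignment(tree, jc, 150, seed=3)
        mine = site_log_likelihoods(tree, aln, jc).values
        ref = jc_site_loglik_closed_form(tree, aln)
        assert np.abs(mine - ref).max() < 1e-8

    def test_tn93_collapse_matches_closed_form(self):
        """With AC=CG (all transversions equal) the engine reduces to
        TN93, whose transition probabilities have a closed form."""
        pi = np.array([0.35, 0.25, 0.15, 0.25])
        kappa_r, kappa_y, beta = 6.0, 9.0, 1.2
        params = ModelParams(
            r_ac_at=beta, r_ag=kappa_r, r_cg_gt=beta, r_ct=kappa_y,
            freqs=pi, alpha=1.0, pinv=0.0, ncat=1,
        )
        tree = PhyloTree.from_newick(
            "(a:0.12,b:0.27,(c:0.08,d:0.33):0.14);"
        )
        aln = simulate_alignment(tree, params, 80, seed=4)

        # independent TN93 P(t): spectral form with rate classes
        pa, pc, pg, pt = pi
        pr, py = pa + pg, pc + pt
        mu = 2 * (
            kappa_r * pa * pg + kappa_y * pc * pt + beta * pr * py
        )

        def p_tn93(t):
            s = t / mu
            e2 = np.exp(-beta * s)
            er = np.exp(-s * (pr * kappa_r + py * beta))
            ey = np.exp(-s * (py * kappa_y + pr * beta))
            p = np.empty((4, 4))
            for i, (fi, ri, ei, group) in enumerate(
                [(pa, pr, er, "R"), (pc, py, ey, "Y"),
                 (pg, pr, er, "R"), (pt, py, ey, "Y")]
            ):
                for j, (fj, rj, ej, gj) in enumerate(
                    [(pa, pr, er, "R"), (pc, py, ey, "Y"),
                     (pg, pr, er, "R"), (pt, py, ey, "Y")]
                ):
                    if group == gj:
                        if i == j:
                            p[i, j] = (
                                fj + fj * (1 - rj) / rj * e2
                                + (rj - fj) / rj * ej
                            )
                        else:
                            p[i, j] = (
                                fj + fj * (1 - rj) / rj * e2
                                - fj / rj * ej
                            )
                    else:
                        p[i, j] = fj * (1 - e2)
            return p

        # brute-force likelihood with the closed-form matrices
        masks = aln.masks()
        bits = np.array([1, 2, 4, 8], dtype=np.uint8)
        row = {t_: i for i, t_ in enumerate(aln.taxa)}
        nodes = list(tree.postorder())
        internal = [n for n in nodes if not n.is_leaf()]
        iidx = {id(n): j for j, n in enumerate(internal)}
        import itertools

        ref = np.zeros(aln.n_sites)
        for site in range(aln.n_sites):
            total = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                prob = pi[assign[iidx[id(tree.root)]]]
                for n in nodes:
                    if n is tree.root:
                        continue
                    pmat = p_tn93(n.length)
                    ps = assign[iidx[id(n.parent)]]
                    if n.is_leaf():
                        compat = (masks[row[n.name], site] & bits) > 0
                        prob *= pmat[ps][compat].sum()
                    else:
                        prob *= pmat[ps, assign[iidx[id(n)]]]
                total += prob
            ref[site] = np.log(total)
        mine = site_log_likelihoods(tree, aln, params).values
        assert np.abs(mine - ref).max() < 1e-8


class TestInvariances:
    def test_root_relocation(self):
        tree = sample_species_tree(7, seed=5)
        aln = simulate_alignment(tree, PARAMS, 120, seed=6)
        base = site_log_likelihoods(tree, aln, PARAMS).values
        dt = tree.to_dendropy()
        internal = [
            n for n in dt.preorder_node_iter()
            if not n.is_leaf() and n is not dt.seed_node
        ]
        dt.reroot_at_node(internal[0], update_bipartitions=False)
        rerooted = PhyloTree.from_dendropy(dt)
        moved = site_log_likelihoods(rerooted, aln, PARAMS).values
        assert np.abs(base - moved).max() < 1e-10

    def test_taxon_order_invariance(self):
        tree = sample_species_tree(6, seed=7)
        aln = simulate_alignment(tree, PARAMS, 100, seed=8)
        shuffled = aln.subset_taxa(list(reversed(aln.taxa)))
        a = site_log_likelihoods(tree, aln, PARAMS).values
        b = site_log_likelihoods(tree, shuffled, PARAMS).values
        assert np.abs(a - b).max() < 1e-10

    def test_zero_lengths_identical_sequences(self):
        tree = PhyloTree.from_newick("(a:0,b:0,(c:0,d:0):0);")
        aln = Alignment.from_sequences(
            {"a": "ACGT", "b": "ACGT", "c": "ACGT", "d": "ACGT"}
        )
        params = ModelParams(
            freqs=np.array([0.4, 0.3, 0.2, 0.1]), ncat=1
        )
        vals = site_log_likelihoods(tree, aln, params).values
        expected = np.log([0.4, 0.3, 0.2, 0.1])
        assert np.allclose(vals, expected, atol=1e-10)

    def test_total_is_sum_of_sites(self):
        tree = sample_species_tree(6, seed=9)
        aln = simulate_alignment(tree, PARAMS, 200, seed=10)
        sll = site_log_likelihoods(tree, aln, PARAMS)
        engine = LikelihoodEngine(tree, AlignmentData(aln), PARAMS)
        assert sll.total == pytest.approx(
            engine.log_likelihood(), abs=1e-8
        )

    def test_label_mismatch_names_offenders(self):
        tree = sample_species_tree(5, seed=1)
        aln = simulate_alignment(tree, PARAMS, 10, seed=1)
        bad = Alignment(
            ["zz" + t for t in aln.taxa], aln.matrix
        )
        with pytest.raises(ValueError, match="zzt"):
            LikelihoodEngine(tree, AlignmentData(bad), PARAMS)


class TestOptimization:
    def test_monotone_trace_and_fixed_point(self, tree6, mito_model):
        aln = simulate_alignment(tree6, mito_model, 800, seed=20)
        fit = optimize_parameters(
            tree6, aln, max_rounds=25, optimize_rates=False
        )
        assert all(
            b - a > -1e-6 for a, b in zip(fit.trace, fit.trace[1:])
        )
        again = optimize_parameters(
            fit.tree, aln, init=fit.params, max_rounds=3,
            optimize_rates=False,
        )
        assert abs(again.loglik - fit.loglik) < 1e-2
        assert again.loglik >= fit.loglik - 1e-8

    def test_parameter_recovery(self):
        """Gamma shape and invariant fraction recovered from data
        simulated under known values (averaged over seeds)."""
        true = ModelParams(
            r_ac_at=1.0, r_ag=5.0, r_cg_gt=1.0, r_ct=7.0,
            freqs=np.array([0.3, 0.25, 0.2, 0.25]),
            alpha=0.5, pinv=0.2, ncat=4,
        )
        alphas, pinvs = [], []
        for s in range(6):
            tree = sample_species_tree(10, seed=200 + s)
            aln = simulate_alignment(tree, true, 12000, seed=300 + s)
            fit = optimize_parameters(
                tree, aln,
                init=true.with_(alpha=1.0, pinv=0.05,
                                freqs=aln.empirical_frequencies()),
                max_rounds=12, optimize_rates=True,
            )
            alphas.append(fit.params.alpha)
            pinvs.append(fit.params.pinv)
        assert abs(np.mean(alphas) - 0.5) < 0.15
        assert abs(np.mean(pinvs) - 0.2) < 0.08
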