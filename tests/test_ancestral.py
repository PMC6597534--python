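"""Brownian-motion ancestral state reconstruction."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from probrain import ancestral, pcm, synthetic
from probrain.ancestral import ml_ancestral_states, node_change_summary, reconstruct_traits
from probrain.treedata import parse_newick, write_newick


def brute_force_states(tree, tip_values):
    """Numeric maximization of the joint BM likelihood over internal states.

    The ML internal states minimize the branch-weighted sum of squared
    changes; this oracle solves that program with a generic optimizer.
    """
    tips = {tree.labels[v]: float(tip_values[tree.labels[v]]) for v in tree.tips}
    internal = tree.internal_nodes
    idx = {v: i for i, v in enumerate(internal)}

    def objective(a):
        s = 0.0
        for v in range(1, tree.n_nodes):
            p = tree.parent[v]
            xv = a[idx[v]] if v in idx else tips[tree.labels[v]]
            s += (xv - a[idx[p]]) ** 2 / max(tree.blen[v], 1e-8)
        return s

    a0 = np.full(len(internal), np.mean(list(tips.values())))
    res = optimize.minimize(objective, a0, method="BFGS", options={"gtol": 1e-12})
    return {v: res.x[idx[v]] for v in internal}


class TestMLAncestralStates:
    def test_two_tip_symmetric_mean(self):
        t = parse_newick("(A:1,B:1):0;")
        st = ml_ancestral_states(t, {"A": 2.0, "B": 4.0})
        assert st.root_estimate == pytest.approx(3.0, abs=1e-12)

    def test_constant_field(self):
        t = synthetic.random_tree(10, seed=4)
        st = ml_ancestral_states(t, {lab: 7.5 for lab in t.tip_labels})
        np.testing.assert_allclose(st.estimates, 7.5, atol=1e-9)
        assert st.sigma2 == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(st.variances, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_joint_likelihood_oracle_six_tips(self, seed):
        t = synthetic.random_tree(6, seed=seed)
        yv = synthetic.simulate_traits(t, pcm.EvoModel("BM"), 0.0, seed=seed)
        st = ml_ancestral_states(t, yv)
        oracle = brute_force_states(t, yv)
        for v, e in zip(st.node_ids, st.estimates):
            assert e == pytest.approx(oracle[int(v)], abs=1e-6)

    def test_root_equals_gls_phylogenetic_mean(self, fx, eq_table):
        tree = fx.specimen_tree
        df = eq_table.df.set_index("specimen_id")
        vals = df.loc[tree.tip_labels, "eq"].astype(float)
        st = ml_ancestral_states(tree, vals)
        C = pcm.phylo_covariance(tree, pcm.EvoModel("BM"), tree.tip_labels).matrix
        w = np.linalg.solve(C, np.ones(len(vals)))
        gls_mean = float(w @ vals.to_numpy()) / float(w.sum())
        assert st.root_estimate == pytest.approx(gls_mean, abs=1e-10)

    def test_affine_equivariance(self):
        t = synthetic.random_tree(12, seed=9)
        yv = synthetic.simulate_traits(t, pcm.EvoModel("BM"), 1.0, seed=9)
        base = ml_ancestral_states(t, yv)
        shifted = ml_ancestral_states(t, 3.0 * yv - 5.0)
        np.testing.assert_allclose(shifted.estimates, 3.0 * base.estimates - 5.0, atol=1e-9)

    def test_missing_tip_value_rejected(self):
        t = parse_newick("(A:1,B:1):0;")
        with pytest.raises(ValueError, match="missing"):
            ml_ancestral_states(t, {"A": 1.0})

    def test_interval_coverage_simulated_histories(self):
        """95% intervals cover the true simulated internal states at close to
        nominal rate (50-tip tree, 200 recorded Brownian histories)."""
        t = synthetic.random_tree(50, seed=42)
        hits = total = 0
        for rep in range(200):
            yv, internal = synthetic.simulate_bm_recursive(t, 1.0, 0.0, seed=rep)
            st = ml_ancestral_states(t, yv)
            for v, lo, hi in zip(st.node_ids, st.ci_low, st.ci_high):
                total += 1
                hits += lo <= internal[int(v)] <= hi
        assert 0.90 <= hits / total <= 0.99

    def test_matches_phytools_fastanc(self):
        """Estimates equal phytools::fastAnc to 1e-8; variances agree after
        accounting for its (n-1) vs our ML (n) rate denominator."""
        t = synthetic.random_tree(8, seed=3)
        yv = synthetic.simulate_traits(t, pcm.EvoModel("BM"), 2.0, seed=11)
        st = ml_ancestral_states(t, yv)
        r_script = textwrap.dedent("""
            suppressMessages(library(phytools))
            tr <- read.tree(text=%r)
            vals <- c(%s)
            x <- setNames(vals, c(%s))
            fa <- fastAnc(tr, x, vars=TRUE)
            for (i in seq_along(fa$ace)) {
              node <- as.integer(names(fa$ace)[i])
              tips <- paste(sort(extract.clade(tr, node)$tip.label), collapse=",")
              cat(sprintf("%%s %%.12f %%.12f\\n", tips, fa$ace[i], fa$var[i]))
            }
        """) % (
            write_newick(t),
            ",".join(f"{float(v)!r}" for v in yv.to_numpy()),
            ",".join(f"'{k}'" for k in yv.index),
        )
        out = subprocess.run(["Rscript", "-e", r_script], capture_output=True, text=True, check=True)
        r_states = {}
        for line in out.stdout.splitlines():
            tips, est, var = line.split()
            r_states[tips] = (float(est), float(var))
        n = t.n_tips
        for v, est, var in zip(st.node_ids, st.estimates, st.variances):
            key = ",".join(sorted(t.labels[u] for u in t.clade_tips(int(v))))
            r_est, r_var = r_states[key]
            assert est == pytest.approx(r_est, abs=1e-8)
            assert var * n / (n - 1) == pytest.approx(r_var, rel=1e-8)


class TestReconstructTraits:
    def test_constant_tips_reconstruct_constant(self, fx):
        tree = synthetic.random_tree(8, seed=1)
        df = pd.DataFrame({
            "specimen_id": tree.tip_labels,
            "taxon": tree.tip_labels,
            "endocast_cm3": np.nan,
            "brain_g": 4000.0,
            "body_g": 3e6,
            "eq": 1.5,
            "group": "proboscidean",
        })
        from probrain.treedata import SpecimenTable

        states = reconstruct_traits(tree, SpecimenTable(df))
        np.testing.assert_allclose(states["eq"].estimates, 1.5, atol=1e-9)
        np.testing.assert_allclose(states["brain"].linear_estimates, 4000.0, rtol=1e-9)

    def test_fixture_named_nodes(self, fx, eq_table):
        states = reconstruct_traits(fx.specimen_tree, eq_table)
        eq = states["eq"]
        assert eq.estimate_at("Proboscidea") == pytest.approx(0.24, abs=0.05)
        assert eq.estimate_at("Elephantimorpha") == pytest.approx(0.73, abs=0.15)
        assert states["brain"].scale == "log10" and eq.scale == "linear"


class TestNodeChangeSummary:
    def _states(self, tree, mapping):
        order = tree.internal_nodes
        mk = lambda vals, scale: ancestral.AncestralStates(
            trait="x", scale=scale,
            node_ids=np.array(order),
            node_labels=[tree.labels[v] for v in order],
            estimates=np.array([vals[v] for v in order]),
            variances=np.zeros(len(order)),
            ci_low=np.zeros(len(order)), ci_high=np.zeros(len(order)),
            sigma2=0.0,
        )
        return {k: mk(v, s) for k, (v, s) in mapping.items()}

    def test_hand_arithmetic(self):
        t = parse_newick("((A:1,B:1)inner:1,(C:1,D:1)other:1)root:0;")
        ids = {t.node_by_label(lab): lab for lab in ["root", "inner", "other"]}
        root, inner, other = sorted(ids, key=lambda v: ["root", "inner", "other"].index(ids[v]))
        states = self._states(t, {
            "eq": ({root: 1.0, inner: 2.0, other: 1.1}, "linear"),
            "body": ({root: 6.0, inner: 6.1, other: 6.5}, "log10"),
            "brain": ({root: 3.0, inner: 3.5, other: 3.2}, "log10"),
        })
        out = node_change_summary(states, t).set_index("child_clade")
        assert out.loc["inner", "eq_ratio"] == pytest.approx(2.0)
        assert out.loc["inner", "body_ratio"] == pytest.approx(10 ** 0.1)
        assert bool(out.loc["inner", "pulse"]) is True
        assert bool(out.loc["other", "pulse"]) is False

    def test_constant_states_no_pulses(self):
        t = parse_newick("((A:1,B:1)inner:1,C:2)root:0;")
        vals = {v: 1.0 for v in t.internal_nodes}
        states = self._states(t, {
            "eq": (vals, "linear"), "body": (vals, "log10"), "brain": (vals, "log10"),
        })
        out = node_change_summary(states, t)
        assert (out["eq_ratio"] == 1.0).all()
        assert not out["pulse"].any()

    def test_fixture_pulse_edges_include_both_increases(self, fx, eq_table):
        states = reconstruct_traits(fx.specimen_tree, eq_table)
        out = node_change_summary(states, fx.specimen_tree)
        pulses = set(out.loc[out["pulse"], "child_clade"])
        assert {"Elephantimorpha", "Elephantoidea"} <= pulses
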