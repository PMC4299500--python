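"""Tests of replication in an independent cohort and the shuffled null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dcnet import stats as st
from dcnet.model import DifferentialCoexpression
from dcnet.network import DCNetwork
from dcnet.replication import (
    connectivity_preserving_null,
    control_correlation_replication,
    exclude_age_associated,
    relaxed_direction,
    replication_fraction,
)
from dcnet.simulate import generate_paired_groups


class TestRelaxedDirection:
    def test_cases(self):
        assert relaxed_direction(0.001, 0.5) == "GOC"
        assert relaxed_direction(0.5, 0.001) == "LOC"
        assert relaxed_direction(0.3, 0.3) == "LOC"  # tie falls to "otherwise"

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            relaxed_direction(float("nan"), 0.5)


@pytest.fixture(scope="module")
def discovery():
    """Fitted discovery network plus matrices and shared-structure truth."""
    ds, truth = generate_paired_groups(
        120, 100, 100, frac_goc=0.04, frac_loc=0.04, effect_delta_r=0.6,
        seed=11, structure_seed=10,
    )
    res = DifferentialCoexpression.from_dataset(ds).fit(target_fdr=0.01, seed=11)
    return ds, truth, res


@pytest.fixture(scope="module")
def independent():
    """Independent cohort regenerated from the same planted structure."""
    ds, _ = generate_paired_groups(
        120, 60, 60, frac_goc=0.04, frac_loc=0.04, effect_delta_r=0.6,
        seed=12, structure_seed=10,
    )
    return ds.group_matrix("case"), ds.group_matrix("control")


class TestReplicationFraction:
    def test_self_replication_is_one(self, discovery):
        ds, _, res = discovery
        out = replication_fraction(
            res.network, ds.group_matrix("case"), ds.group_matrix("control"),
            q_rep=3.84,
        )
        assert out.fraction == 1.0
        assert out.n_replicated == out.n_eligible == len(res.network)

    def test_same_distribution_null_rate(self, rng):
        """Independent case/control drawn from one distribution: replication
        ~ chi^2(1) tail at q_rep halved by direction matching."""
        genes = [f"R{k:05d}" for k in range(120)]
        pairs = []
        used = set()
        while len(pairs) < 300:
            a, b = rng.choice(genes, 2, replace=False)
            key = tuple(sorted((a, b)))
            if key not in used:
                used.add(key)
                pairs.append(
                    {"gene_i": key[0], "gene_j": key[1],
                     "direction": "GOC" if rng.random() < 0.5 else "LOC", "q": 30.0}
                )
        net = DCNetwork(pd.DataFrame(pairs))
        cols_c = [f"c{k}" for k in range(150)]
        cols_t = [f"t{k}" for k in range(150)]
        case = pd.DataFrame(rng.standard_normal((120, 150)), index=genes, columns=cols_c)
        ctrl = pd.DataFrame(rng.standard_normal((120, 150)), index=genes, columns=cols_t)
        out = replication_fraction(net, case, ctrl, q_rep=3.84)
        expected = 0.5 * st.chi2_p(3.84)
        assert out.fraction == pytest.approx(expected, abs=0.035)

    def test_planted_structure_replicates_above_null(self, discovery, independent):
        _, _, res = discovery
        indep_case, indep_ctrl = independent
        out = connectivity_preserving_null(
            res.network, indep_case, indep_ctrl, n_shuffles=100, seed=5
        )
        assert out.fraction > out.null_fractions.mean()
        assert out.empirical_p <= 0.05

    def test_no_eligible_pairs_errors(self, discovery):
        _, _, res = discovery
        empty = pd.DataFrame(
            np.zeros((2, 10)), index=["x1", "x2"],
            columns=[f"s{k}" for k in range(10)],
        )
        with pytest.raises(ValueError):
            replication_fraction(res.network, empty, empty)


class TestConnectivityPreservingNull:
    def test_empirical_p_floor(self, discovery, independent):
        """Observed above every null fraction: p = 1/(n_shuffles + 1)."""
        _, _, res = discovery
        indep_case, indep_ctrl = independent
        out = connectivity_preserving_null(
            res.network, indep_case, indep_ctrl, n_shuffles=200, seed=6
        )
        if (out.null_fractions < out.fraction).all():
            assert out.empirical_p == pytest.approx(1.0 / 201)
        assert 0.0 < out.empirical_p <= 1.0

    def test_zero_shuffles_errors(self, discovery, independent):
        _, _, res = discovery
        with pytest.raises(ValueError):
            connectivity_preserving_null(res.network, *independent, n_shuffles=0)

    def test_shuffle_preserves_degree_multiset(self, discovery, independent):
        """Gene-label shuffling is an isomorphism: degree multiset invariant."""
        _, _, res = discovery
        indep_case, _ = independent
        restricted = res.network.restrict_genes(set(indep_case.index))
        universe = sorted(restricted.genes)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(universe))
        relabel = {universe[k]: universe[perm[k]] for k in range(len(universe))}
        shuffled = DCNetwork(
            restricted.pairs.assign(
                gene_i=restricted.pairs["gene_i"].map(relabel),
                gene_j=restricted.pairs["gene_j"].map(relabel),
            )
        )
        assert sorted(shuffled.degrees().to_numpy()) == sorted(
            restricted.degrees().to_numpy()
        )
        assert len(shuffled) == len(restricted)

    def test_restrict_then_replicate_commutes(self, discovery, independent):
        _, _, res = discovery
        indep_case, indep_ctrl = independent
        subset = sorted(res.network.genes)[: len(res.network.genes) // 2]
        case_sub = indep_case.loc[indep_case.index.intersection(subset)]
        ctrl_sub = indep_ctrl.loc[indep_ctrl.index.intersection(subset)]
        a = replication_fraction(
            res.network.restrict_genes(subset), indep_case, indep_ctrl
        )
        b = replication_fraction(res.network, case_sub, ctrl_sub)
        assert a.fraction == b.fraction and a.n_eligible == b.n_eligible


class TestControlCorrelationReplication:
    def test_collinear_data_full_replication(self, rng):
        genes = [f"g{k}" for k in range(6)]
        base = rng.standard_normal(30)
        ctrl = pd.DataFrame(
            np.vstack([base * (k + 1) for k in range(6)]), index=genes,
            columns=[f"s{k}" for k in range(30)],
        )
        pairs = pd.DataFrame(
            {"gene_i": ["g0", "g1", "g2"], "gene_j": ["g3", "g4", "g5"],
             "direction": ["LOC"] * 3, "q": [30.0] * 3}
        )
        out = control_correlation_replication(pairs, ctrl, n_shuffles=10, seed=0)
        assert out["frac_nominal"] == 1.0
        assert out["frac_bonferroni"] == 1.0

    def test_null_nominal_rate_near_alpha(self, rng):
        genes = [f"g{k}" for k in range(80)]
        ctrl = pd.DataFrame(
            rng.standard_normal((80, 100)), index=genes,
            columns=[f"s{k}" for k in range(100)],
        )
        used, rows = set(), []
        while len(rows) < 300:
            a, b = rng.choice(genes, 2, replace=False)
            key = tuple(sorted((a, b)))
            if key not in used:
                used.add(key)
                rows.append({"gene_i": key[0], "gene_j": key[1],
                             "direction": "LOC", "q": 10.0})
        out = control_correlation_replication(
            pd.DataFrame(rows), ctrl, alpha=0.05, n_shuffles=20, seed=1
        )
        assert out["frac_nominal"] == pytest.approx(0.05, abs=0.04)

    def test_planted_loc_pairs_beat_shuffled_null(self, discovery, independent):
        _, truth, res = discovery
        _, indep_ctrl = independent
        loc = res.network.subset(res.network.pairs["direction"] == "LOC")
        out = control_correlation_replication(loc, indep_ctrl, n_shuffles=50, seed=2)
        assert out["frac_nominal"] > out["null_frac_nominal"]
        assert out["two_proportion_p"] < 0.01


class TestAgeExclusion:
    def test_null_aging_removes_chi2_tail(self, discovery, rng):
        _, _, res = discovery
        genes = sorted(res.network.genes)
        elder = pd.DataFrame(rng.standard_normal((len(genes), 56)), index=genes,
                             columns=[f"e{k}" for k in range(56)])
        adult = pd.DataFrame(rng.standard_normal((len(genes), 53)), index=genes,
                             columns=[f"a{k}" for k in range(53)])
        _, removed = exclude_age_associated(res.network, elder, adult, q_age=2.71)
        assert removed == pytest.approx(st.chi2_p(2.71), abs=0.05)

    def test_infinite_cutoff_identity(self, discovery, rng):
        _, _, res = discovery
        genes = sorted(res.network.genes)
        elder = pd.DataFrame(rng.standard_normal((len(genes), 30)), index=genes,
                             columns=[f"e{k}" for k in range(30)])
        adult = pd.DataFrame(rng.standard_normal((len(genes), 30)), index=genes,
                             columns=[f"a{k}" for k in range(30)])
        filtered, removed = exclude_age_associated(
            res.network, elder, adult, q_age=float("inf")
        )
        assert removed == 0.0
        assert filtered.pair_keys() == res.network.pair_keys()

    def test_age_associated_pair_removed(self, rng):
        """A pair with elder/adult correlation difference 0.6 is excluded."""
        genes = ["gA", "gB"]
        n = 55
        z = rng.standard_normal(n)
        elder = pd.DataFrame(
            [z + 0.7 * rng.standard_normal(n), z + 0.7 * rng.standard_normal(n)],
            index=genes, columns=[f"e{k}" for k in range(n)],
        )
        adult = pd.DataFrame(rng.standard_normal((2, n)), index=genes,
                             columns=[f"a{k}" for k in range(n)])
        net = DCNetwork(pd.DataFrame(
            {"gene_i": ["gA"], "gene_j": ["gB"], "direction": ["GOC"], "q": [30.0]}
        ))
        filtered, removed = exclude_age_associated(net, elder, adult, q_age=2.71)
        assert removed == 1.0 and len(filtered) == 0

    def test_partition_conservation(self, discovery, rng):
        _, _, res = discovery
        genes = sorted(res.network.genes)
        elder = pd.DataFrame(rng.standard_normal((len(genes), 40)), index=genes,
                             columns=[f"e{k}" for k in range(40)])
        adult = pd.DataFrame(rng.standard_normal((len(genes), 40)), index=genes,
                             columns=[f"a{k}" for k in range(40)])
        filtered, removed = exclude_age_associated(res.network, elder, adult)
        n_removed = round(removed * len(res.network))
        assert len(filtered) + n_removed == len(res.network)
        assert filtered.pair_keys() <= res.network.pair_keys()
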