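import numpy as np
import pandas as pd
import pytest

from ecoassembly import (
    AssemblyModel,
    CommunityMatrix,
    NullConfig,
    Phylogeny,
    RemovalTarget,
    beta_mntd,
    decision_rules,
    simulate_regime,
    simulate_traits,
    simulate_tree,
    SyntheticScenario,
    targets_from_taxonomy,
)
from ecoassembly.removal import remove_and_recompute
from conftest import random_instance


CFG = NullConfig(n_reps=10, seed=0)


class TestDecisionRules:
    @pytest.mark.parametrize(
        "ses,ses_i,rc,rc_i,expected",
        [
            (2.6, 1.1, np.nan, np.nan, "heterogeneous_selection"),
            (2.6, 2.7, np.nan, np.nan, "drift"),  # removal did not flip
            (-2.4, -1.0, np.nan, np.nan, "homogeneous_selection"),
            (-2.4, -2.1, np.nan, np.nan, "drift"),  # -2.1 is not > -2
            (0.2, 0.3, 0.97, 0.40, "dispersal_limitation"),
            (0.2, 0.3, 0.97, 0.96, "drift"),  # still significant after removal
            (0.2, 0.3, -0.97, -0.40, "homogenizing_dispersal"),
            (0.2, 0.3, 0.40, np.nan, "drift"),
            (0.2, 2.5, 0.97, np.nan, "drift"),  # SES leaves the band on removal
        ],
    )
    def test_five_rules(self, ses, ses_i, rc, rc_i, expected):
        label, _ = decision_rules(ses, ses_i, rc, rc_i, CFG)
        assert label == expected

    def test_paper_literal_swaps_dispersal_labels(self):
        cfg = NullConfig(n_reps=10, seed=0, rule_labels="paper-literal")
        label, _ = decision_rules(0.2, 0.3, 0.97, 0.40, cfg)
        assert label == "homogenizing_dispersal"
        label, _ = decision_rules(0.2, 0.3, -0.97, -0.40, cfg)
        assert label == "dispersal_limitation"

    def test_missing_rc_in_band_is_error(self):
        with pytest.raises(RuntimeError, match="RC missing"):
            decision_rules(0.2, 0.3, np.nan, np.nan, CFG)

    def test_masking_flag(self):
        _, masking = decision_rules(1.0, 2.5, 0.2, np.nan, CFG)
        assert masking
        _, masking = decision_rules(1.0, 1.2, 0.2, np.nan, CFG)
        assert not masking


class TestRemoveAndRecompute:
    def _fitted(self, seed=21, n_sites=5, n_taxa=12):
        comm, tree = random_instance(seed, n_sites=n_sites, n_taxa=n_taxa, total=80)
        model = AssemblyModel(comm, tree)
        return model.fit(n_reps=100, seed=3)

    def test_noop_target_absent_from_pair(self):
        """A taxon absent from both sites of a pair leaves that pair's
        metrics exactly unchanged and falls to the drift rule."""
        res = self._fitted()
        comm = res.model.community
        # find a (taxon, pair) combination with zero abundance at both ends
        found = False
        for taxon in comm.taxon_ids:
            col = comm.data[taxon]
            absent = [s for s in comm.site_ids if col[s] == 0]
            if len(absent) >= 2:
                outcomes = remove_and_recompute(res, RemovalTarget(taxon, (taxon,)))
                mask = outcomes["site_a"].isin(absent) & outcomes["site_b"].isin(absent)
                sub = outcomes[mask & (outcomes["status"] == "ok")]
                if len(sub):
                    found = True
                    pm = res.pair_metrics.set_index(["site_a", "site_b"])
                    for row in sub.itertuples(index=False):
                        ref = pm.loc[(row.site_a, row.site_b)]
                        assert row.ses_minus_i == ref["ses"]
                        assert row.rc_minus_i == ref["rc"] or (
                            np.isnan(row.rc_minus_i) and np.isnan(ref["rc"])
                        )
                        assert row.attributed_process == "drift"
        assert found, "fixture produced no absent-taxon pair; adjust seed"

    def test_singleton_toy_beta_mntd_after_removal(self):
        # sites {A,B} vs {A,C}: removing A leaves singletons B vs C
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        D = tree.cophenetic(["A", "B", "C"]).to_numpy()
        ck = np.array([1.0, 1.0, 0.0])
        cm = np.array([1.0, 0.0, 1.0])
        ck[0] = cm[0] = 0.0
        assert beta_mntd(ck, cm, D) == pytest.approx(D[1, 2])

    def test_oracle_from_scratch_on_filtered_table(self):
        """Masked removal equals a full re-run on the taxon-filtered table
        sharing the original tree (unpruned pool) and the same seed."""
        comm, tree = random_instance(33, n_sites=6, n_taxa=20, total=120)
        model = AssemblyModel(comm, tree)
        res = model.fit(n_reps=120, seed=11)
        target_taxon = comm.taxon_ids[0]
        target = RemovalTarget(target_taxon, (target_taxon,))
        outcomes = remove_and_recompute(res, target)

        reduced = comm.drop_taxa([target_taxon])
        # share the fitted model's pool: its aligned tree, unpruned
        scratch = AssemblyModel(reduced, res.model.tree, prune_tree=False).fit(
            n_reps=120, seed=11
        )
        ref = scratch.pair_metrics.set_index(["site_a", "site_b"])
        present_sites = set(comm.data.index[comm.data[target_taxon] > 0])
        checked_ses = checked_rc = 0
        for row in outcomes.itertuples(index=False):
            if row.status != "ok":
                continue
            if not ({row.site_a, row.site_b} & present_sites):
                continue  # identity removal is checked separately
            r = ref.loc[(row.site_a, row.site_b)]
            assert row.ses_minus_i == pytest.approx(r["ses"], abs=1e-12)
            checked_ses += 1
            if not np.isnan(row.rc_minus_i):
                assert row.rc_minus_i == pytest.approx(r["rc"], abs=1e-12)
                checked_rc += 1
        assert checked_ses > 0

    def test_group_removal_equals_joint_mask(self):
        comm, tree = random_instance(8, n_sites=4, n_taxa=10, total=60)
        model = AssemblyModel(comm, tree)
        res = model.fit(n_reps=80, seed=2)
        members = tuple(comm.taxon_ids[:3])
        group = remove_and_recompute(res, RemovalTarget("grp", members))
        reduced = comm.drop_taxa(members)
        scratch = AssemblyModel(reduced, res.model.tree, prune_tree=False).fit(
            n_reps=80, seed=2
        )
        ref = scratch.pair_metrics.set_index(["site_a", "site_b"])
        present = comm.data[list(members)].sum(axis=1) > 0
        for row in group.itertuples(index=False):
            if row.status != "ok":
                continue
            if not (present[row.site_a] or present[row.site_b]):
                continue
            assert row.ses_minus_i == pytest.approx(
                ref.loc[(row.site_a, row.site_b), "ses"], abs=1e-12
            )

    def test_unknown_member_taxon_rejected(self):
        res = self._fitted()
        with pytest.raises(KeyError, match="nope"):
            remove_and_recompute(res, RemovalTarget("bad", ("nope",)))

    def test_removal_emptying_site_is_inapplicable(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):2);")
        data = pd.DataFrame(
            [[5, 0, 0, 0], [0, 3, 2, 0], [1, 1, 1, 1]],
            index=["s1", "s2", "s3"],
            columns=["A", "B", "C", "D"],
        )
        model = AssemblyModel(CommunityMatrix(data), tree)
        res = model.fit(n_reps=60, seed=1)
        outcomes = remove_and_recompute(res, RemovalTarget("A", ("A",)))
        s1_rows = outcomes[
            (outcomes["site_a"] == "s1") | (outcomes["site_b"] == "s1")
        ]
        assert (s1_rows["status"] == "inapplicable").all()


class TestAttributeTaxa:
    def test_rows_sum_to_one(self):
        comm, tree = random_instance(40, n_sites=5, n_taxa=12, total=90)
        res = AssemblyModel(comm, tree).fit(n_reps=80, seed=5)
        table = res.attribute_taxa()
        from ecoassembly import PROCESSES

        ok = table[table["n_evaluable"] > 0]
        assert len(ok) > 0
        np.testing.assert_allclose(ok[list(PROCESSES)].sum(axis=1), 1.0, atol=1e-9)
        assert ((ok[list(PROCESSES)] >= 0) & (ok[list(PROCESSES)] <= 1)).all().all()

    def test_taxonomy_group_targets(self):
        comm, tree = random_instance(40, n_sites=4, n_taxa=10, total=60)
        half = comm.n_taxa // 2
        tax = pd.DataFrame(
            {"phylum": ["P1"] * half + ["P2"] * (comm.n_taxa - half)},
            index=comm.taxon_ids,
        )
        targets = targets_from_taxonomy(tax, "phylum", comm.taxon_ids)
        assert [t.target_id for t in targets] == ["P1", "P2"]
        assert len(targets[0].member_taxa) == half

    def test_zero_evaluable_flagged_not_zeros(self, star_tree):
        # on a star tree every pair is degenerate -> nothing evaluable
        data = pd.DataFrame(
            [[2, 1, 0, 0], [0, 1, 2, 1]], index=["s1", "s2"],
            columns=["A", "B", "C", "D"],
        )
        res = AssemblyModel(CommunityMatrix(data), star_tree).fit(n_reps=40, seed=0)
        table = res.attribute_taxa(targets=[RemovalTarget("A", ("A",))])
        assert table.loc[0, "n_evaluable"] == 0
        assert np.isnan(table.loc[0, "heterogeneous_selection"])

    def test_divergence_monotonicity(self):
        """Inflating the divergent taxon's trait displacement never lowers
        its heterogeneous-selection attribution (three effect sizes).

        Effect sizes are expressed in niche widths and kept within the
        coexistence regime: once the displacement far exceeds the niche
        width the taxon forms monocultures at the top of the gradient,
        its removal empties those sites, and the affected pairs become
        inapplicable by design -- the invariant's premise (the taxon
        participates in mixed communities) no longer holds.
        """
        tree = simulate_tree(30, seed=14)
        traits = simulate_traits(tree, 1.0, seed=14)
        coph = tree.cophenetic(sorted(tree.tip_labels))
        causal = coph.to_numpy().mean(axis=1).argmax()
        causal_taxon = coph.index[causal]
        width = 0.3 * traits.std()  # the scenario's default niche width
        fractions = []
        evaluable = []
        for delta in (0.5, 1.0, 2.0):
            t = traits.copy()
            t[causal_taxon] = traits.max() + delta * width
            sc = SyntheticScenario(
                "heterogeneous_selection", n_taxa=30, n_sites=8,
                total_per_site=400, seed=14,
            )
            comm, _, _ = simulate_regime(sc, tree, t)
            if causal_taxon not in comm.taxon_ids:
                pytest.fail("causal taxon absent from simulated table")
            res = AssemblyModel(comm, tree).fit(n_reps=200, seed=14)
            tab = res.attribute_taxa(
                targets=[RemovalTarget(causal_taxon, (causal_taxon,))]
            )
            fractions.append(float(tab.loc[0, "heterogeneous_selection"]))
            evaluable.append(int(tab.loc[0, "n_evaluable"]))
        # premise: the taxon coexists at every effect size (no pair lost)
        assert len(set(evaluable)) == 1
        assert fractions == sorted(fractions)
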