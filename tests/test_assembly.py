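import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly import (
    CommunityTable,
    Metacommunity,
    NullModelConfig,
    Process,
    SampleMetadata,
    ValidationError,
    beta_mntd,
    bnti_matrix,
    classify_pair,
    classify_pairs,
    process_fractions,
    rc_bray,
    rc_bray_matrix,
)
from ecoassembly.assembly import PairProcessRecord
from ecoassembly.io import align_inputs, tip_distance_matrix
from conftest import random_tree_and_counts


def beta_mntd_double_loop(x, y, dist, abundance_weighted=True):
    """Literal double-loop transcription of the definition."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    in_x, in_y = np.flatnonzero(x > 0), np.flatnonzero(y > 0)
    if abundance_weighted:
        wx, wy = x[in_x] / x[in_x].sum(), y[in_y] / y[in_y].sum()
    else:
        wx = np.full(len(in_x), 1 / len(in_x))
        wy = np.full(len(in_y), 1 / len(in_y))
    total = 0.0
    for w, i in zip(wx, in_x):
        total += w * min(dist[i, j] for j in in_y)
    for w, j in zip(wy, in_y):
        total += w * min(dist[j, i] for i in in_x)
    return 0.5 * total


class TestBetaMNTD:
    def test_two_tip_disjoint_value(self, cherry_tree):
        d = tip_distance_matrix(cherry_tree, ["A", "B"])
        assert beta_mntd([1, 0], [0, 1], d) == pytest.approx(2.0)

    def test_identical_communities_zero(self, four_tip_tree):
        d = tip_distance_matrix(four_tip_tree, list("ABCD"))
        assert beta_mntd([1, 2, 3, 4], [1, 2, 3, 4], d) == pytest.approx(0.0)

    @pytest.mark.parametrize("weighted", [True, False])
    @pytest.mark.parametrize("trial", range(8))
    def test_matches_double_loop_oracle(self, trial, weighted):
        rng = np.random.default_rng(200 + trial)
        tree, table = random_tree_and_counts(rng, rng.integers(4, 10), 2)
        d = tip_distance_matrix(tree, table.taxon_ids)
        x, y = table.counts
        got = beta_mntd(x, y, d, abundance_weighted=weighted)
        want = beta_mntd_double_loop(x, y, d, abundance_weighted=weighted)
        assert got == pytest.approx(want, abs=1e-12)

    def test_symmetric_in_communities(self):
        rng = np.random.default_rng(31)
        tree, table = random_tree_and_counts(rng, 7, 2)
        d = tip_distance_matrix(tree, table.taxon_ids)
        x, y = table.counts
        assert beta_mntd(x, y, d) == pytest.approx(beta_mntd(y, x, d))

    def test_adding_shared_taxon_never_increases(self, four_tip_tree):
        d = tip_distance_matrix(four_tip_tree, list("ABCD"))
        base = beta_mntd([5, 0, 0, 0], [0, 5, 0, 0], d)
        # add taxon C with equal relative abundance to both communities
        shared = beta_mntd([5, 0, 5, 0], [0, 5, 5, 0], d)
        assert shared <= base + 1e-12

    def test_empty_community_rejected(self, cherry_tree):
        d = tip_distance_matrix(cherry_tree, ["A", "B"])
        with pytest.raises(ValidationError):
            beta_mntd([0, 0], [1, 0], d)


class TestBntiMatrix:
    def test_star_tree_degenerate_null_is_error(self):
        labels = ["A", "B", "C", "D"]
        star = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        table = CommunityTable(
            pd.DataFrame(
                [[1, 2, 0, 0], [0, 0, 3, 4]], index=["a", "b"], columns=labels
            )
        )
        with pytest.raises(ValidationError, match="degenerate"):
            bnti_matrix(table, star, NullModelConfig(n_null=19, seed=0))

    def test_identical_membership_degenerate_can_fall_through(self):
        rng = np.random.default_rng(1)
        tree, table = random_tree_and_counts(rng, 6, 2)
        same = CommunityTable(
            pd.DataFrame(
                [[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]],
                index=["a", "b"],
                columns=table.taxon_ids,
            )
        )
        out = bnti_matrix(
            same, tree, NullModelConfig(n_null=19, seed=0), on_degenerate="zero"
        )
        assert out.iloc[0, 1] == 0.0

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        tree, table = random_tree_and_counts(rng, 8, 4)
        cfg = NullModelConfig(n_null=49, seed=77)
        b1 = bnti_matrix(table, tree, cfg, on_degenerate="zero")
        b2 = bnti_matrix(table, tree, cfg, on_degenerate="zero")
        pd.testing.assert_frame_equal(b1, b2)

    def test_null_generated_data_rarely_significant(self):
        """Tip-shuffled data is a draw from the null: |betaNTI| <= 2 mostly."""
        from ecoassembly import ScenarioConfig, simulate_scenario

        cfg = ScenarioConfig(
            n_taxa=40, n_groups=2, reps_per_group=3, depth=800, seed=5
        )
        truth = simulate_scenario(cfg)
        rng = np.random.default_rng(0)
        hits = total = 0
        for s in range(10):
            tips = list(truth.tree.tips())
            names = [t.name for t in tips]
            rng.shuffle(names)
            for t, n in zip(tips, names):
                t.name = n
            b = bnti_matrix(
                truth.table, truth.tree, NullModelConfig(n_null=99, seed=s)
            ).to_numpy()
            iu = np.triu_indices(b.shape[0], 1)
            hits += (np.abs(b[iu]) <= 2).sum()
            total += len(iu[0])
        assert hits / total >= 0.9


def plackett_luce_subset_prob(subset, weights):
    """P(drawing exactly `subset` by sequential weighted sampling w/o repl.)."""
    total = 0.0
    for order in itertools.permutations(subset):
        prob, remaining = 1.0, weights.sum()
        for item in order:
            prob *= weights[item] / remaining
            remaining -= weights[item]
        total += prob
    return total


def multinomial_pmf(counts, probs):
    from math import factorial

    n = sum(counts)
    p = factorial(n)
    for c in counts:
        p //= factorial(c)
    out = float(p)
    for c, q in zip(counts, probs):
        out *= q**c
    return out


def enumerate_null_communities(richness, depth, occupancy, relab):
    """All null assemblies with their probabilities (tiny pools only)."""
    pool = np.flatnonzero(occupancy > 0)
    out = []
    for subset in itertools.combinations(pool, richness):
        p_subset = plackett_luce_subset_prob(subset, occupancy)
        extra = depth - richness
        q = relab[list(subset)]
        q = q / q.sum()
        for alloc in itertools.product(range(extra + 1), repeat=richness):
            if sum(alloc) != extra:
                continue
            counts = np.zeros(len(occupancy))
            for i, t in enumerate(subset):
                counts[t] = 1 + alloc[i]
            out.append((counts, p_subset * multinomial_pmf(alloc, q)))
    return out


def rc_exact(x, y, occupancy, relab):
    """Exhaustively enumerated Raup-Crick value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    obs = np.abs(x - y).sum() / (x + y).sum()
    nulls_x = enumerate_null_communities(
        int((x > 0).sum()), int(x.sum()), occupancy, relab
    )
    nulls_y = enumerate_null_communities(
        int((y > 0).sum()), int(y.sum()), occupancy, relab
    )
    frac = 0.0
    for cx, px in nulls_x:
        for cy, py in nulls_y:
            bc = np.abs(cx - cy).sum() / (cx + cy).sum()
            if np.isclose(bc, obs, atol=1e-12):
                frac += 0.5 * px * py
            elif bc < obs:
                frac += px * py
    return (frac - 0.5) * 2


class TestRcBray:
    def test_single_taxon_pool_all_ties_gives_zero(self):
        meta = Metacommunity(
            occupancy=np.array([1.0]), relative_abundance=np.array([1.0])
        )
        cfg = NullModelConfig(n_null=99, seed=0)
        assert rc_bray([4], [6], meta, cfg) == pytest.approx(0.0)

    def test_observed_above_all_nulls_gives_one(self):
        # uniform pool: nulls are near-even, the observed pair is extreme
        occupancy = np.array([1.0, 1.0, 1.0])
        relab = np.array([1 / 3, 1 / 3, 1 / 3])
        meta = Metacommunity(occupancy=occupancy, relative_abundance=relab)
        cfg = NullModelConfig(n_null=199, seed=1)
        val = rc_bray([34, 33, 33], [98, 1, 1], meta, cfg)
        assert val == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(4))
    def test_monte_carlo_matches_enumeration(self, trial):
        rng = np.random.default_rng(300 + trial)
        occupancy = rng.uniform(0.2, 1.0, size=3)
        relab = rng.dirichlet(np.ones(3))
        meta = Metacommunity(occupancy=occupancy, relative_abundance=relab)
        x = np.array([2, 1, 0])
        y = np.array([1, 0, rng.integers(1, 3)])
        exact = rc_exact(x, y, occupancy, relab)
        n_null = 2000
        mc = rc_bray(x, y, meta, NullModelConfig(n_null=n_null, seed=trial))
        f_exact = exact / 2 + 0.5
        se = 2 * np.sqrt(max(f_exact * (1 - f_exact), 1e-4) / n_null)
        assert abs(mc - exact) <= 3 * se

    def test_matrix_and_pairwise_agree_in_distribution(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 12, size=(4, 5))
        counts[:, 0] += 1
        table = CommunityTable(
            pd.DataFrame(
                counts,
                index=[f"s{i}" for i in range(4)],
                columns=[f"T{i}" for i in range(5)],
            )
        )
        meta = Metacommunity.from_table(table)
        mat = rc_bray_matrix(table, NullModelConfig(n_null=999, seed=3), meta=meta)
        pair = rc_bray(
            counts[0], counts[1], meta, NullModelConfig(n_null=999, seed=4)
        )
        # same null model, independent streams: values should be close
        assert abs(mat.iloc[0, 1] - pair) < 0.2

    def test_richness_exceeding_pool_rejected(self):
        meta = Metacommunity(
            occupancy=np.array([1.0, 0.0]), relative_abundance=np.array([1.0, 0.0])
        )
        with pytest.raises(ValidationError, match="richness"):
            rc_bray([1, 1], [2, 0], meta, NullModelConfig(n_null=9, seed=0))


class TestClassifyPair:
    cfg = NullModelConfig(n_null=9, seed=0)

    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (2.5, None, Process.VARIABLE_SELECTION),
            (-2.5, None, Process.HOMOGENEOUS_SELECTION),
            (0.5, 0.97, Process.DISPERSAL_LIMITATION),
            (0.5, -0.97, Process.HOMOGENIZING_DISPERSAL),
            (0.5, 0.2, Process.UNDOMINATED),
            (2.0, 0.0, Process.UNDOMINATED),  # boundary betaNTI not significant
            (-2.0, 0.95, Process.UNDOMINATED),  # boundary RC not significant
            (0.0, -0.95, Process.UNDOMINATED),
        ],
    )
    def test_threshold_rules(self, bnti, rc, expected):
        assert classify_pair(bnti, rc, self.cfg) is expected

    def test_rc_with_significant_bnti_is_contract_error(self):
        with pytest.raises(ValueError, match="absent"):
            classify_pair(3.0, 0.5, self.cfg)

    def test_missing_rc_with_nonsignificant_bnti_is_error(self):
        with pytest.raises(ValueError, match="required"):
            classify_pair(0.5, None, self.cfg)


def _records(processes, scopes):
    return [
        PairProcessRecord(
            sample_a=f"a{i}",
            sample_b=f"b{i}",
            comparison_scope=s,
            beta_mntd_obs=0.0,
            bnti=0.0,
            rc_bray=0.0,
            process=p,
        )
        for i, (p, s) in enumerate(zip(processes, scopes))
    ]


class TestProcessFractions:
    def test_printed_within_source_split(self):
        procs = [Process.HOMOGENIZING_DISPERSAL] * 11 + [
            Process.HOMOGENEOUS_SELECTION
        ] * 7
        recs = _records(procs, ["within_group"] * 18)
        summary = process_fractions(recs, scope="within")
        assert summary.dispersal_total * 100 == pytest.approx(61.11, abs=0.01)
        assert summary.selection_total * 100 == pytest.approx(38.89, abs=0.01)

    def test_single_process_is_total(self):
        recs = _records([Process.UNDOMINATED] * 5, ["between_group"] * 5)
        s = process_fractions(recs, scope="between")
        assert s.fractions[Process.UNDOMINATED] == pytest.approx(1.0)
        assert sum(s.fractions.values()) == pytest.approx(1.0)

    def test_design_pair_counts(self):
        from ecoassembly import ScenarioConfig, simulate_scenario

        cfg = ScenarioConfig(n_taxa=20, depth=400, seed=0)
        truth = simulate_scenario(cfg)
        ids = truth.table.sample_ids
        groups = truth.metadata.groups_for(ids)
        n_within = sum(
            1
            for i in range(18)
            for j in range(i + 1, 18)
            if groups[i] == groups[j]
        )
        assert n_within == 6 * comb(3, 2) == 18
        assert comb(18, 2) - n_within == 135

    def test_per_group_denominators(self):
        # 2 groups x 2 reps: 2 within + 4 between = 6 pairs
        ids = ["g1_a", "g1_b", "g2_a", "g2_b"]
        meta = SampleMetadata(
            pd.DataFrame(
                {"group": ["g1", "g1", "g2", "g2"]},
                index=pd.Index(ids, name="sample_id"),
            )
        )
        recs = []
        pairs = list(itertools.combinations(ids, 2))
        for a, b in pairs:
            scope = "within_group" if a[:2] == b[:2] else "between_group"
            recs.append(
                PairProcessRecord(a, b, scope, 0.0, 0.0, 0.0, Process.UNDOMINATED)
            )
        per = process_fractions(recs, meta, scope="per_group")
        assert per["g1"].n_pairs == 5  # 1 within + 4 between
        per_between = process_fractions(
            recs, meta, scope="per_group", include_within_pairs=False
        )
        assert per_between["g1"].n_pairs == 4

    def test_empty_scope_rejected(self):
        recs = _records([Process.UNDOMINATED], ["between_group"])
        with pytest.raises(ValidationError):
            process_fractions(recs, scope="within")


class TestClassifyPairsEndToEnd:
    def test_records_cover_all_pairs_and_contract(self):
        from ecoassembly import ScenarioConfig, simulate_scenario

        cfg = ScenarioConfig(
            n_taxa=30, n_groups=3, reps_per_group=2, depth=600, seed=8
        )
        truth = simulate_scenario(cfg)
        bundle = align_inputs(truth.table, truth.tree, truth.metadata)
        recs = classify_pairs(bundle, NullModelConfig(n_null=49, seed=2))
        assert len(recs) == comb(6, 2)
        for r in recs:
            if abs(r.bnti) > 2:
                assert r.rc_bray is None
            else:
                assert r.rc_bray is not None and -1 <= r.rc_bray <= 1
            assert r.process in Process
        within = process_fractions(recs, scope="within")
        between = process_fractions(recs, scope="between")
        assert within.n_pairs + between.n_pairs == len(recs)
        assert sum(within.fractions.values()) == pytest.approx(1.0)
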