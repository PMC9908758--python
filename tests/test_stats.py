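"""Permutation 2x2 RM-ANOVA, cluster filter, post-hoc tests, correlation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from evtopo import (
    CONDITIONS,
    CurrentDensityMap,
    build_source_space,
    pearson_correlation,
    perm_rm_anova_2x2,
    posthoc_paired,
    spatial_cluster_filter,
)
from evtopo.stats import (
    cell_matrix,
    nodewise_anova,
    rm_anova_2x2_f,
)


def _table_from_matrix(Y):
    rows = []
    for s, row in enumerate(Y):
        for c, val in zip(CONDITIONS, row):
            congruency, synchrony = c.split("-")
            rows.append(
                {
                    "subject": f"S{s:02d}",
                    "congruency": congruency,
                    "synchrony": synchrony,
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def anova_oracle(Y):
    """Textbook two-way repeated-measures decomposition (plain loops)."""
    n = Y.shape[0]
    grand = Y.mean()
    subj_mean = Y.mean(axis=1)
    # factor level means: A = congruency (cols 0,1 vs 2,3), B = synchrony
    A = [Y[:, :2].mean(), Y[:, 2:].mean()]
    B = [Y[:, [0, 2]].mean(), Y[:, [1, 3]].mean()]
    cellm = Y.mean(axis=0)
    out = {}
    for effect in ("congruency", "synchrony", "interaction"):
        if effect == "congruency":
            ss_eff = 2 * n * sum((a - grand) ** 2 for a in A)
            lv = lambda s, j: Y[s, :2].mean() if j == 0 else Y[s, 2:].mean()  # noqa: E731
            lm = A
        elif effect == "synchrony":
            ss_eff = 2 * n * sum((b - grand) ** 2 for b in B)
            lv = lambda s, j: Y[s, [0, 2]].mean() if j == 0 else Y[s, [1, 3]].mean()  # noqa: E731
            lm = B
        else:
            ss_eff = n * sum(
                (cellm[k] - A[k // 2] - B[k % 2] + grand) ** 2 for k in range(4)
            )
        if effect != "interaction":
            ss_err = 0.0
            for s in range(n):
                for j in range(2):
                    ss_err += 2 * (lv(s, j) - subj_mean[s] - lm[j] + grand) ** 2
        else:
            ss_err = 0.0
            for s in range(n):
                for k in range(4):
                    resid = (
                        Y[s, k]
                        - cellm[k]
                        - (Y[s, : 2].mean() if k < 2 else Y[s, 2:].mean())
                        - (Y[s, [0, 2]].mean() if k % 2 == 0 else Y[s, [1, 3]].mean())
                        + subj_mean[s]
                        + (A[k // 2] + B[k % 2] - grand)
                    )
                    ss_err += resid**2
        F = ss_eff / (ss_err / (n - 1))
        eta = ss_eff / (ss_eff + ss_err)
        out[effect] = (F, eta)
    return out


class TestRmAnovaF:
    def test_matches_textbook_oracle(self, rng):
        for _ in range(25):
            Y = rng.standard_normal((4, 4)) * 2 + 5
            got = rm_anova_2x2_f(Y)
            want = anova_oracle(Y)
            for eff in got:
                assert got[eff][0] == pytest.approx(want[eff][0], rel=1e-10)
                assert got[eff][1] == pytest.approx(want[eff][1], rel=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        Y = rng.standard_normal((8, 4)) + 3
        df = _table_from_matrix(Y)
        res = pingouin.rm_anova(
            data=df, dv="value", within=["congruency", "synchrony"],
            subject="subject", detailed=True,
        )
        got = rm_anova_2x2_f(Y)
        for _, row in res.iterrows():
            name = {
                "congruency": "congruency",
                "synchrony": "synchrony",
                "congruency * synchrony": "interaction",
            }[row["Source"]]
            assert got[name][0] == pytest.approx(row["F"], rel=1e-8)

    def test_constant_within_subject_gives_zero_f(self):
        Y = np.tile(np.array([[1.0], [2.0], [5.0], [9.0]]), (1, 4))
        got = rm_anova_2x2_f(Y)
        for eff in got:
            assert got[eff][0] == 0.0

    def test_invariant_to_per_subject_constants(self, rng):
        """Within-subject contrasts cancel subject means, so per-subject
        offsets leave F unchanged (to fp rounding of the shifted sums)."""
        Y = rng.standard_normal((6, 4))
        shifted = Y + rng.standard_normal((6, 1)) * 100
        a, b = rm_anova_2x2_f(Y), rm_anova_2x2_f(shifted)
        for eff in a:
            assert a[eff][0] == pytest.approx(b[eff][0], rel=1e-9)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            rm_anova_2x2_f(rng.standard_normal((2, 4)))


class TestPermAnova:
    def test_p_floor_and_determinism(self, rng):
        df = _table_from_matrix(rng.standard_normal((6, 4)))
        a = perm_rm_anova_2x2(df, "value", n_permutations=99, seed=3)
        b = perm_rm_anova_2x2(df, "value", n_permutations=99, seed=3)
        for eff in a.effects:
            assert a[eff]["p"] == b[eff]["p"]
            assert a[eff]["p"] >= 1.0 / 100.0

    def test_strong_effect_detected_at_floor(self, rng):
        Y = rng.standard_normal((10, 4)) * 0.1
        Y[:, :2] += 5.0  # congruency effect
        df = _table_from_matrix(Y)
        res = perm_rm_anova_2x2(df, "value", n_permutations=199, seed=0)
        assert res["congruency"]["p"] == pytest.approx(1.0 / 200.0)
        assert res["congruency"]["eta2p"] > 0.9

    def test_incomplete_design_rejected(self, rng):
        df = _table_from_matrix(rng.standard_normal((4, 4)))
        df = df[~((df.subject == "S00") & (df.synchrony == "asynchronous"))]
        with pytest.raises(ValueError, match="no complete subjects|missing"):
            perm_rm_anova_2x2(df.dropna(), "value", 99, 0)

    def test_power_for_planted_effect(self, rng):
        """A standardized congruency shift of 1.2 SD at n = 10 is detected
        in at least 80% of replicate studies."""
        hits = 0
        reps = 200
        for _ in range(reps):
            Y = rng.standard_normal((10, 4))
            Y[:, :2] += 1.2
            df = _table_from_matrix(Y)
            res = perm_rm_anova_2x2(df, "value", n_permutations=199, seed=int(rng.integers(2**31)))
            hits += res["congruency"]["p"] <= 0.05
        assert hits / reps >= 0.8

    def test_listwise_missing_exclusion(self, rng):
        Y = rng.standard_normal((10, 4))
        df = _table_from_matrix(Y)
        df.loc[df.subject.isin(["S00", "S01"]), "value"] = np.nan
        subjects, mat = cell_matrix(df, "value")
        assert len(subjects) == 8 and mat.shape == (8, 4)


class TestNodewise:
    def _maps(self, data, space):
        density = {}
        for s in range(data.shape[0]):
            for k, c in enumerate(CONDITIONS):
                density[(f"S{s:02d}", c)] = data[s, :, k]
        return CurrentDensityMap(density=density, space=space, window_ms=(0, 10))

    def test_identical_conditions_give_zero_f(self, rng):
        space = build_source_space(10.0, 5.0)
        base = rng.random((4, space.n_nodes))
        data = np.repeat(base[:, :, None], 4, axis=2)
        res = nodewise_anova(self._maps(data, space), n_permutations=49, seed=0)
        for eff in res:
            np.testing.assert_array_equal(res[eff]["F"], 0.0)

    def test_shared_schedule_determinism(self, rng):
        space = build_source_space(10.0, 5.0)
        data = rng.random((5, space.n_nodes, 4))
        m = self._maps(data, space)
        a = nodewise_anova(m, n_permutations=99, seed=11)
        b = nodewise_anova(m, n_permutations=99, seed=11)
        for eff in a:
            np.testing.assert_array_equal(a[eff]["p"], b[eff]["p"])

    def test_planted_single_node_attains_minimum_p(self, rng):
        """The node carrying a planted congruency effect has the smallest
        p over nodes in >= 95% of 100 replicates (small space)."""
        space = build_source_space(10.0, 5.0)  # 33 nodes
        target = 7
        wins = 0
        for _ in range(100):
            data = rng.random((10, space.n_nodes, 4))
            data[:, target, :2] += 2.5
            res = nodewise_anova(
                self._maps(data, space), n_permutations=199, seed=int(rng.integers(2**31))
            )
            p = res["congruency"]["p"]
            wins += p[target] == p.min()
        assert wins >= 95

    def test_nodewise_agrees_with_scalar_anova(self, rng):
        space = build_source_space(10.0, 5.0)
        data = rng.random((6, space.n_nodes, 4))
        res = nodewise_anova(self._maps(data, space), n_permutations=99, seed=5)
        node = 3
        from evtopo.stats import rm_anova_2x2_f

        obs = rm_anova_2x2_f(data[:, node, :])
        for eff in res:
            assert res[eff]["F"][node] == pytest.approx(obs[eff][0], rel=1e-10)


class TestClusterFilter:
    def test_retains_37_but_not_12_at_min_size_17(self):
        """Two contiguous sub-threshold components of 37 and 12 nodes: only
        the 37-node one survives the 17-node spatial criterion."""
        space = build_source_space(40.0, 8.0, connectivity=26)
        order = np.lexsort((space.nodes[:, 2], space.nodes[:, 1], space.nodes[:, 0]))
        pmap = np.ones(space.n_nodes)
        left = [i for i in order if space.nodes[i, 0] < 0][:37]
        right = [i for i in order[::-1] if space.nodes[i, 0] > 16][:12]
        pmap[left] = 0.01
        pmap[right] = 0.01
        res = spatial_cluster_filter(pmap, np.ones_like(pmap), space, 0.05, 17)
        sizes = sorted(c["size"] for c in res.clusters)
        assert sizes == [12, 37]
        assert [c["size"] for c in res.retained()] == [37]

    def test_no_subthreshold_nodes_gives_empty(self):
        space = build_source_space(10.0, 5.0)
        res = spatial_cluster_filter(
            np.ones(space.n_nodes), np.ones(space.n_nodes), space
        )
        assert res.clusters == [] and res.retained() == []

    def test_components_match_bruteforce_flood_fill(self, rng):
        """Random p-maps: component memberships equal a BFS flood fill."""
        space = build_source_space(20.0, 5.0, connectivity=6)
        for _ in range(20):
            pmap = rng.random(space.n_nodes)
            res = spatial_cluster_filter(pmap, pmap, space, threshold_p=0.3, min_size=1)
            # oracle: BFS over sub-threshold nodes
            sub = set(np.flatnonzero(pmap < 0.3))
            seen = set()
            comps = set()
            for start in sorted(sub):
                if start in seen:
                    continue
                comp = {start}
                queue = [start]
                while queue:
                    u = queue.pop()
                    for v in space.neighbors(u):
                        if v in sub and v not in comp:
                            comp.add(int(v))
                            queue.append(int(v))
                seen |= comp
                comps.add(frozenset(comp))
            got = {frozenset(c["nodes"]) for c in res.clusters}
            assert got == comps


class TestPosthocAndCorrelation:
    def test_identical_pairs_give_zero(self, rng):
        Y = np.tile(rng.standard_normal((6, 1)), (1, 4))
        df = _table_from_matrix(Y)
        res = posthoc_paired(df, "value", [(CONDITIONS[0], CONDITIONS[1])])
        assert res.loc[0, "t"] == 0.0 and res.loc[0, "d"] == 0.0

    def test_matches_paired_t_oracle(self):
        """4-pair hand case against the textbook paired-t formula."""
        a = np.array([3.0, 5.0, 4.0, 6.0])
        b = np.array([2.0, 4.5, 4.0, 5.0])
        Y = np.column_stack([a, b, np.zeros(4), np.zeros(4)])
        df = _table_from_matrix(Y)
        res = posthoc_paired(df, "value", [(CONDITIONS[0], CONDITIONS[1])])
        diff = a - b
        t_oracle = diff.mean() / (diff.std(ddof=1) / np.sqrt(4))
        t_scipy, p_scipy = scipy.stats.ttest_rel(a, b)
        assert res.loc[0, "t"] == pytest.approx(t_oracle, rel=1e-10)
        assert res.loc[0, "t"] == pytest.approx(t_scipy, rel=1e-10)
        assert res.loc[0, "p"] == pytest.approx(p_scipy, rel=1e-10)
        assert res.loc[0, "d"] == pytest.approx(diff.mean() / diff.std(ddof=1), rel=1e-10)

    def test_pair_order_antisymmetry(self, rng):
        df = _table_from_matrix(rng.standard_normal((5, 4)))
        ab = posthoc_paired(df, "value", [(CONDITIONS[2], CONDITIONS[3])])
        ba = posthoc_paired(df, "value", [(CONDITIONS[3], CONDITIONS[2])])
        assert ab.loc[0, "t"] == -ba.loc[0, "t"]
        assert ab.loc[0, "d"] == -ba.loc[0, "d"]
        assert ab.loc[0, "p"] == ba.loc[0, "p"]

    def test_correlation_closed_forms(self, rng):
        x = rng.standard_normal(10)
        r, _ = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0, abs=1e-12)
        r, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_correlation_matches_oracle(self, rng):
        for _ in range(100):
            x, y = rng.standard_normal((2, 10))
            r, p = pearson_correlation(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            r_oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert r == pytest.approx(r_oracle, rel=1e-12, abs=1e-14)

    def test_correlation_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(5), rng.standard_normal(5))
        with pytest.raises(ValueError):
            pearson_correlation(np.arange(2), np.arange(2))
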