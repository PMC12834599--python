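import numpy as np
import pandas as pd
import pytest

from connstats import (
    merge_networks,
    pair_enrichment,
    run_nla,
    welch_t,
    westfall_young_adjust,
    whole_network_enrichment,
)
from connstats.edges import edge_pairs, n_edges
from connstats.parcellation import DEFAULT_MERGE_SPEC, NetworkAssignment


def _wy_enumeration_oracle(observed, null, two_sided=True):
    """Literal step-down maxT with explicit loops (independent oracle)."""
    obs = np.abs(observed) if two_sided else np.array(observed, float)
    nul = np.abs(null) if two_sided else np.array(null, float)
    m = len(obs)
    order = sorted(range(m), key=lambda j: (-obs[j], j))
    q = []
    for r in range(m):
        hits = 0
        for b in range(nul.shape[0]):
            mx = max(nul[b, order[s]] for s in range(r, m))
            if mx >= obs[order[r]]:
                hits += 1
        q.append(hits / nul.shape[0])
    for r in range(1, m):
        q[r] = max(q[r], q[r - 1])
    out = np.empty(m)
    for r, j in enumerate(order):
        out[j] = q[r]
    return out


class TestMergeNetworks:
    def test_identity_spec_unchanged(self, small_parcellation):
        _, assignment = small_parcellation
        ident = {l: l for l in set(assignment.labels)}
        merged = merge_networks(assignment, ident)
        assert np.array_equal(merged.labels, assignment.labels)

    def test_five_motor_labels_collapse_to_sm(self, small_parcellation):
        _, assignment = small_parcellation
        merged = merge_networks(assignment, DEFAULT_MERGE_SPEC)
        motor = {
            "premotor",
            "somatomotor hand",
            "somatomotor mouth",
            "somatomotor foot",
            "somato-cognitive action",
        }
        was_motor = np.isin(assignment.labels.astype(str), list(motor))
        assert (merged.labels[was_motor] == "SM").all()
        assert "SAL" not in merged.labels and "SAL/PMN" in merged.labels

    def test_parcel_counts_conserved(self, small_parcellation):
        _, assignment = small_parcellation
        merged = merge_networks(assignment)
        assert len(merged.labels) == len(assignment.labels)
        raw_counts = pd.Series(assignment.labels).value_counts()
        merged_counts = pd.Series(merged.labels).value_counts()
        for raw, tgt in DEFAULT_MERGE_SPEC.items():
            if raw in raw_counts:
                assert merged_counts[tgt] >= raw_counts[raw]
        assert merged_counts.sum() == raw_counts.sum()

    def test_unmapped_label_rejected(self, small_parcellation):
        _, assignment = small_parcellation
        with pytest.raises(ValueError, match="unmapped"):
            merge_networks(assignment, {"premotor": "SM"})


class TestWelch:
    def test_hand_arithmetic_toy(self):
        # A={1,2,3}: mean 2, var 1; B={0,0,0,1}: mean 1/4, var 1/4
        expected = (2 - 0.25) / np.sqrt(1 / 3 + 0.25 / 4)
        assert welch_t([1, 2, 3], [0, 0, 0, 1]) == pytest.approx(expected)

    def test_identical_groups_zero_and_antisymmetry(self, rng):
        a = rng.standard_normal(10)
        assert welch_t(a, a) == pytest.approx(0.0)
        b = rng.standard_normal(8)
        assert welch_t(a, b) == pytest.approx(-welch_t(b, a))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t([1.0], [1, 2, 3])
        with pytest.raises(ValueError, match="zero pooled variance"):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestPairEnrichment:
    def _toy(self):
        # 9 parcels, 3 networks of 3 -> 6 unordered pairs, all with >= 3 edges
        networks = np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3, dtype=object)
        rng = np.random.default_rng(0)
        t = rng.standard_normal(n_edges(9))
        return networks, t

    def test_all_equal_statistics_zero(self):
        networks, _ = self._toy()
        res = pair_enrichment(np.full(n_edges(9), 1.3), networks)
        assert np.allclose(res["welch_t"], 0.0)

    def test_matches_bruteforce_set_enumeration(self):
        networks, t = self._toy()
        res = pair_enrichment(t, networks)
        ii, jj = edge_pairs(9)
        for row in res.itertuples():
            edges = [
                k
                for k in range(len(t))
                if {networks[ii[k]], networks[jj[k]]} == {row.network_a, row.network_b}
                or (
                    row.network_a == row.network_b
                    and networks[ii[k]] == networks[jj[k]] == row.network_a
                )
            ]
            assert len(edges) == row.n_edges
            assert row.welch_t == pytest.approx(welch_t(t[edges], t))

    def test_pair_count_and_partition(self):
        networks, t = self._toy()
        res = pair_enrichment(t, networks)
        assert len(res) == 3 * 4 // 2  # K(K+1)/2
        assert res["n_edges"].sum() == n_edges(9)

    def test_label_permutation_equivariance(self):
        networks, t = self._toy()
        res = pair_enrichment(t, networks)
        swap = {"A": "C", "B": "B", "C": "A"}
        res2 = pair_enrichment(t, np.array([swap[x] for x in networks], dtype=object))
        for row in res.itertuples():
            a, b = sorted((swap[row.network_a], swap[row.network_b]))
            match = res2[(res2["network_a"] == a) & (res2["network_b"] == b)]
            assert match["welch_t"].iloc[0] == pytest.approx(row.welch_t)

    def test_sum_to_connectome_consistency(self):
        networks, t = self._toy()
        res = pair_enrichment(t, networks)
        ii, jj = edge_pairs(9)
        means = []
        for row in res.itertuples():
            sel = np.array(
                [
                    sorted((networks[ii[k]], networks[jj[k]]))
                    == sorted((row.network_a, row.network_b))
                    for k in range(len(t))
                ]
            )
            means.append(t[sel].mean())
        weighted = np.average(means, weights=res["n_edges"])
        assert weighted == pytest.approx(t.mean(), abs=1e-12)

    def test_undefined_small_pair_excluded(self):
        # one isolated network with a single parcel: its within-pair has 0 edges
        networks = np.array(["A", "A", "A", "B"], dtype=object)
        t = np.arange(n_edges(4), dtype=float)
        res = pair_enrichment(t, networks)
        bb = res[(res["network_a"] == "B") & (res["network_b"] == "B")]
        assert bb.empty  # no within-B edges exist at all
        ab = res[(res["network_a"] == "A") & (res["network_b"] == "B")]
        assert len(ab) == 1 and np.isfinite(ab["welch_t"].iloc[0])


class TestWholeNetworkEnrichment:
    def test_all_equal_zero_and_full_coverage_zero(self):
        networks = np.array(["A"] * 3 + ["B"] * 3, dtype=object)
        res = whole_network_enrichment(np.full(n_edges(6), 2.0), networks)
        assert np.allclose(res["welch_t"], 0.0)
        res_all = whole_network_enrichment(
            np.arange(n_edges(6), dtype=float), np.array(["A"] * 6, dtype=object)
        )
        assert res_all["welch_t"].iloc[0] == 0.0

    def test_planted_inflation_gives_positive_statistic(self, rng):
        networks = np.array(["hot"] * 4 + ["cold"] * 8, dtype=object)
        ii, jj = edge_pairs(12)
        t = rng.standard_normal(n_edges(12)) * 0.1
        incident = (networks[ii] == "hot") | (networks[jj] == "hot")
        t[incident] += np.sign(t[incident] + 1e-12) * 3.0  # inflate |t|
        res = whole_network_enrichment(t, networks)
        hot = res[res["network"] == "hot"]["welch_t"].iloc[0]
        cold = res[res["network"] == "cold"]["welch_t"].iloc[0]
        assert hot > 0
        assert hot > cold

    def test_within_edge_set_option(self):
        networks = np.array(["A"] * 3 + ["B"] * 3, dtype=object)
        t = np.arange(n_edges(6), dtype=float)
        inc = whole_network_enrichment(t, networks, edge_set="incident")
        wit = whole_network_enrichment(t, networks, edge_set="within")
        assert (inc["n_edges"] > wit["n_edges"]).all()
        assert (wit["n_edges"] == 3).all()


class TestWestfallYoung:
    def test_single_hypothesis_reduces_to_bootstrap_p(self):
        null = np.array([[0.5], [1.5], [2.5], [3.5]])
        assert westfall_young_adjust(np.array([2.0]), null)[0] == pytest.approx(2 / 4)

    def test_two_hypothesis_toy_matches_enumeration(self):
        obs = np.array([2.0, -1.0])
        null = np.array([[1.5, 0.5], [2.5, 1.2], [0.3, -0.4], [1.9, 3.0]])
        got = westfall_young_adjust(obs, null)
        want = _wy_enumeration_oracle(obs, null)
        assert np.allclose(got, want)

    def test_random_fixtures_match_enumeration(self, rng):
        for _ in range(10):
            m, B = rng.integers(2, 6), rng.integers(2, 9)
            obs = rng.standard_normal(m)
            null = rng.standard_normal((B, m))
            assert np.allclose(
                westfall_young_adjust(obs, null),
                _wy_enumeration_oracle(obs, null),
            )
            got = westfall_young_adjust(obs, null, alternative="greater")
            want = _wy_enumeration_oracle(obs, null, two_sided=False)
            assert np.allclose(got, want)

    def test_adjusted_dominates_raw(self, rng):
        m, B = 8, 40
        obs = rng.standard_normal(m)
        null = rng.standard_normal((B, m))
        adjusted = westfall_young_adjust(obs, null)
        raw = (np.abs(null) >= np.abs(obs)[None, :]).mean(axis=0)
        assert (adjusted >= raw - 1e-12).all()

    def test_nan_hypotheses_excluded(self, rng):
        obs = np.array([2.0, np.nan, 0.5])
        null = rng.standard_normal((20, 3))
        adj = westfall_young_adjust(obs, null)
        assert np.isnan(adj[1]) and np.isfinite(adj[0]) and np.isfinite(adj[2])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            westfall_young_adjust(np.zeros(3), np.zeros((5, 2)))


class TestRunNLA:
    def test_requires_null(self, small_parcellation):
        _, assignment = small_parcellation
        t = np.zeros(n_edges(len(assignment.labels)))
        with pytest.raises(ValueError, match="bootstrap null"):
            run_nla((t, None), merge_networks(assignment))

    def test_null_exchangeability(self, null_cohort_data, small_parcellation):
        # treating one null replicate as "observed" must give well-behaved
        # (roughly uniform) adjusted p-values
        from connstats import EdgewiseMarginalModel

        _, design, Y = null_cohort_data
        _, assignment = small_parcellation
        model = EdgewiseMarginalModel(B=120, random_state=5).fit(design, Y)
        merged = merge_networks(assignment)
        ps = []
        for b in range(0, 120, 10):
            res = run_nla((model.null_t_[b], np.delete(model.null_t_, b, axis=0)),
                          merged)
            ps.extend(res.pairs["p_fwer"].dropna())
        ps = np.array(ps)
        assert ps.min() >= 0 and ps.max() <= 1
        # under exchangeability adjusted p should rarely be tiny
        assert (ps < 0.05).mean() < 0.15

    def test_planted_block_detected_and_reported(self, small_parcellation):
        from connstats import (
            EdgewiseMarginalModel,
            build_design,
            default_truth,
            gen_cohort,
            gen_fc_data,
        )

        _, assignment = small_parcellation
        cohort = gen_cohort(600, n_sites=15, prevalence_stim=0.3, seed=77)
        Y, _ = gen_fc_data(cohort, assignment, default_truth(), seed=78)
        design = build_design(cohort, ["age_months", "fd_mean"], "stimulant")
        model = EdgewiseMarginalModel(B=200, random_state=79).fit(design, Y)
        merged = merge_networks(assignment)
        res = run_nla(model, merged)
        sig = {
            (r.network_a, r.network_b) for r in res.significant_pairs().itertuples()
        }
        assert ("SM", "SM") in sig
        assert ("SAL/PMN", "SM") in sig
        assert (res.pairs["p_fwer"].dropna() >= res.pairs["p_raw"].dropna() - 1e-12).all()
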