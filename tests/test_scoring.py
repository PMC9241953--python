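"""Normalization chain, classification rule, and phase sorting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pullcall import (
    CountTable,
    DETable,
    MixtureFit,
    NotConvergedError,
    PhaseAnnotation,
    ValidationError,
    bait_normalize,
    classify,
    length_normalize,
    merge_and_log2,
    phase_sort,
)


def make_table(counts: dict, lengths: dict, bait="BAIT") -> CountTable:
    frame = pd.DataFrame(counts)
    frame.index.name = "protein_id"
    frame.columns.name = "assay_id"
    return CountTable(counts=frame, bait_id=bait).attach_lengths(lengths)


def simple_fit(means=(-6.0, -2.0), weights=(0.8, 0.2), variances=(1.0, 1.0), converged=True):
    return MixtureFit(
        k=len(means), weights=weights, means=means, variances=variances,
        log_likelihood=-1.0, n_obs=50, n_iter=3, converged=converged, seed=0,
    )


class TestLengthNormalize:
    def test_elementwise_division(self, toy_table):
        values = length_normalize(toy_table)
        assert values.loc["P1", "a1"] == pytest.approx(10 / 200)
        assert values.loc["P2", "a1"] == 0.0
        # every cell equals brute-force division
        for p in toy_table.proteins:
            for a in toy_table.assays:
                assert values.loc[p, a] == pytest.approx(
                    toy_table.counts.loc[p, a] / toy_table.lengths[p], abs=1e-15
                )

    def test_missing_length_listed(self):
        table = make_table(
            {"a1": {"BAIT": 10, "P1": 2, "P9": 3}}, {"BAIT": 100, "P1": 50}
        )
        with pytest.raises(ValidationError, match="P9"):
            length_normalize(table)

    def test_no_lengths_attached(self):
        frame = pd.DataFrame({"a1": {"BAIT": 5}})
        with pytest.raises(ValidationError, match="length"):
            length_normalize(CountTable(counts=frame, bait_id="BAIT"))

    def test_pseudocount_applied_before_length(self, toy_table):
        values = length_normalize(toy_table, pseudocount=1.0)
        assert values.loc["P2", "a1"] == pytest.approx(1 / 300)


class TestBaitNormalize:
    def test_bait_maps_to_one_everywhere(self, toy_table):
        values = bait_normalize(length_normalize(toy_table), "BAIT")
        assert np.allclose(values.loc["BAIT"], 1.0)

    def test_per_assay_division(self):
        # same prey raw value, assay-specific bait values -> assay-specific results
        table = make_table(
            {"a1": {"B": 50, "P": 10}, "a2": {"B": 25, "P": 10}, "a3": {"B": 100, "P": 10}},
            {"B": 100, "P": 100}, bait="B",
        )
        values = bait_normalize(length_normalize(table), "B")
        assert values.loc["P"].tolist() == pytest.approx([10 / 50, 10 / 25, 10 / 100])

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_matches_brute_force_on_random_tables(self, data):
        n_prot = data.draw(st.integers(2, 8))
        n_assay = data.draw(st.integers(1, 4))
        counts = data.draw(
            st.lists(
                st.lists(st.integers(0, 500), min_size=n_assay, max_size=n_assay),
                min_size=n_prot, max_size=n_prot,
            )
        )
        lengths = data.draw(
            st.lists(st.integers(50, 3000), min_size=n_prot, max_size=n_prot)
        )
        counts[0] = [max(c, 1) for c in counts[0]]  # row 0 is the bait
        ids = [f"P{i}" for i in range(n_prot)]
        table = make_table(
            {f"a{j}": {ids[i]: counts[i][j] for i in range(n_prot)} for j in range(n_assay)},
            dict(zip(ids, lengths)), bait="P0",
        )
        values = bait_normalize(length_normalize(table), "P0")
        for i in range(n_prot):
            for j in range(n_assay):
                expected = (counts[i][j] / lengths[i]) / (counts[0][j] / lengths[0])
                assert values.loc[ids[i], f"a{j}"] == pytest.approx(expected, abs=1e-12)

    def test_scale_free_when_bait_scales_with_assay(self):
        """Multiplying every count of one assay by a constant leaves that
        assay's bait-normalized values unchanged."""
        base = {"a1": {"B": 50, "P1": 10, "P2": 4}, "a2": {"B": 40, "P1": 8, "P2": 2}}
        lengths = {"B": 500, "P1": 200, "P2": 100}
        scaled = {"a1": {k: v * 7 for k, v in base["a1"].items()}, "a2": base["a2"]}
        v1 = bait_normalize(length_normalize(make_table(base, lengths, "B")), "B")
        v2 = bait_normalize(length_normalize(make_table(scaled, lengths, "B")), "B")
        pd.testing.assert_frame_equal(v1, v2)


class TestMergeAndLog2:
    def test_pooling_and_exclusions(self, toy_table):
        values = bait_normalize(length_normalize(toy_table), "BAIT")
        obs = merge_and_log2(values, "BAIT", min_observations=1)
        # bookkeeping identity: (P-1) preys x A assays - zero cells
        n_zero = sum(1 for _, _, r in obs.excluded if r == "zero-count")
        assert len(obs.entries) == 4 * 3 - n_zero
        assert n_zero == 3
        assert sum(1 for _, _, r in obs.excluded if r == "bait") == 3
        assert "BAIT" not in set(obs.entries["protein_id"])

    def test_log2_arithmetic(self):
        table = make_table(
            {"a1": {"B": 40, "P": 10}}, {"B": 100, "P": 100}, bait="B"
        )
        values = bait_normalize(length_normalize(table), "B")
        obs = merge_and_log2(values, "B", min_observations=1)
        assert obs.entries["log2_value"].iloc[0] == pytest.approx(np.log2(0.25))

    def test_min_observation_guard(self, toy_table):
        values = bait_normalize(length_normalize(toy_table), "BAIT")
        with pytest.raises(ValidationError, match="unfittable"):
            merge_and_log2(values, "BAIT", min_observations=50)


class TestClassify:
    def _setup(self, counts):
        lengths = {pid: 100 for pid in counts["a1"]}
        table = make_table(counts, lengths, bait="B")
        values = bait_normalize(length_normalize(table), "B")
        obs = merge_and_log2(values, "B", min_observations=1)
        return table, obs

    def test_threshold_boundaries_hand_derived(self):
        """Six-protein toy table: the strict posterior rule and the count
        floor jointly decide membership, including the count==4 and
        posterior==0.5 boundary cases."""
        table, obs = self._setup(
            {
                "a1": {"B": 100, "Phit": 30, "Plow": 1, "Pfew": 2, "Pzero": 0, "Pmid": 4},
                "a2": {"B": 100, "Phit": 28, "Plow": 1, "Pfew": 2, "Pzero": 0, "Pmid": 4},
            }
        )
        # symmetric fit: posterior is exactly 0.5 at the midpoint -4.0
        fit = simple_fit(means=(-6.0, -2.0), weights=(0.5, 0.5))
        # Pmid at log2(4/100 / 1) = log2(0.04) = -4.644: high posterior? no:
        # place the midpoint at Pmid's score to probe the strict inequality
        fit_mid = simple_fit(
            means=(-6.0, -6.0 + 2 * (np.log2(0.04) + 6.0)), weights=(0.5, 0.5)
        )
        calls = {c.protein_id: c for c in classify(obs, fit_mid, table)}
        # Phit: posterior ~1, total 58 -> in
        assert calls["Phit"].is_interactor
        # Pfew: total 4 < 5 -> out regardless of posterior
        assert not calls["Pfew"].is_interactor
        # Pmid: sits exactly at the component midpoint -> posterior == 0.5,
        # strict rule excludes it despite total 8 >= 5
        assert calls["Pmid"].posterior == pytest.approx(0.5, abs=1e-9)
        assert not calls["Pmid"].is_interactor
        # Plow: low posterior -> out; Pzero: never observed -> posterior 0
        assert not calls["Plow"].is_interactor
        assert calls["Pzero"].posterior == 0.0
        assert np.isnan(calls["Pzero"].mean_log2_score)
        assert not calls["Pzero"].is_interactor
        # bait reported flagged, verdict true, sentinel posterior
        assert calls["B"].is_bait and calls["B"].is_interactor and calls["B"].posterior == 1.0

    def test_count_filter_dominates_high_posterior(self):
        table, obs = self._setup(
            {"a1": {"B": 100, "P": 2}, "a2": {"B": 100, "P": 2}}
        )
        fit = simple_fit(means=(-9.0, np.log2(0.02)))
        calls = {c.protein_id: c for c in classify(obs, fit, table)}
        assert calls["P"].posterior > 0.9
        assert not calls["P"].is_interactor  # total 4 < 5

    def test_mean_log2_is_arithmetic_mean_of_observed_assays(self):
        table, obs = self._setup({"a1": {"B": 100, "P": 8}, "a2": {"B": 50, "P": 0}})
        calls = {c.protein_id: c for c in classify(obs, simple_fit(), table)}
        # only assay a1 observed -> mean equals that single log2 value
        assert calls["P"].mean_log2_score == pytest.approx(np.log2(0.08))

    def test_requires_converged_fit(self, toy_table):
        values = bait_normalize(length_normalize(toy_table), "BAIT")
        obs = merge_and_log2(values, "BAIT", min_observations=1)
        with pytest.raises(NotConvergedError):
            classify(obs, simple_fit(converged=False), toy_table)

    @settings(max_examples=25, deadline=None)
    @given(
        pt=st.floats(0.05, 0.95), ct=st.integers(0, 20),
        dp=st.floats(0.0, 0.04), dc=st.integers(0, 10), seed=st.integers(0, 50),
    )
    def test_monotone_in_thresholds(self, pt, ct, dp, dc, seed):
        """Raising either threshold never turns a negative verdict positive."""
        rng = np.random.default_rng(seed)
        counts = {
            a: {"B": 100, **{f"P{i}": int(rng.integers(0, 30)) for i in range(6)}}
            for a in ("a1", "a2")
        }
        table, obs = self._setup(counts)
        fit = simple_fit()
        loose = {c.protein_id for c in classify(obs, fit, table, pt, ct) if c.is_interactor}
        strict = {
            c.protein_id
            for c in classify(obs, fit, table, min(pt + dp, 0.99), ct + dc)
            if c.is_interactor
        }
        assert strict <= loose

    def test_any_assay_count_mode(self):
        table, obs = self._setup(
            {"a1": {"B": 100, "P": 4}, "a2": {"B": 100, "P": 3}}
        )
        fit = simple_fit(means=(-9.0, -4.7))
        total = {c.protein_id: c for c in classify(obs, fit, table, count_mode="total")}
        per = {c.protein_id: c for c in classify(obs, fit, table, count_mode="any_assay")}
        assert total["P"].is_interactor       # 4 + 3 = 7 >= 5
        assert not per["P"].is_interactor     # no single assay reaches 5


class TestPhaseSort:
    def _de(self, rows):
        return DETable(
            frame=pd.DataFrame(rows, columns=["transcript_id", "log2_change", "adjusted_p"])
        )

    def _ann(self, mapping):
        return PhaseAnnotation(phases=pd.Series(mapping))

    def test_strict_lfc_boundary_and_partition(self):
        de = self._de(
            [
                ("t_g1", 1.6, 0.01),
                ("t_exact", 1.5, 0.01),     # exactly 1.5 -> excluded (strict >)
                ("t_down", -2.0, 0.01),
                ("t_ns", 3.0, 0.5),         # fails padj <= 0.1
                ("t_na", 2.0, None),        # missing padj -> excluded
            ]
        )
        ann = self._ann({"t_g1": "G1", "t_exact": "G1", "t_ns": "SMC"})
        groups = phase_sort(de, ann)
        assert groups["G1"] == ["t_g1"]
        assert groups["SMC"] == []
        assert groups["NONCYCLICAL"] == ["t_down"]  # unannotated fallback

    def test_padj_filter_optional(self):
        de = self._de([("t1", 2.0, 0.9), ("t2", -1.0, 0.001)])
        groups = phase_sort(de, self._ann({"t1": "SMC"}), padj_threshold=None)
        assert groups["SMC"] == ["t1"]

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_partition_property(self, data):
        """Groups are disjoint and their union is exactly the retained set."""
        n = data.draw(st.integers(1, 25))
        lfc = data.draw(st.lists(st.floats(-4, 4), min_size=n, max_size=n))
        padj = data.draw(st.lists(st.floats(0, 1), min_size=n, max_size=n))
        phase_idx = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
        ids = [f"t{i}" for i in range(n)]
        de = self._de(list(zip(ids, lfc, padj)))
        ann = self._ann(
            {
                tid: ("G1", "SMC", "NONCYCLICAL")[k]
                for tid, k in zip(ids, phase_idx) if k < 3  # k == 3 -> unannotated
            }
        )
        groups = phase_sort(de, ann)
        retained = {
            tid for tid, fc, p in zip(ids, lfc, padj) if abs(fc) > 1.5 and p <= 0.1
        }
        members = [t for g in groups.values() for t in g]
        assert len(members) == len(set(members))
        assert set(members) == retained
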