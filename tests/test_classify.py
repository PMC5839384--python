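import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormtx.classify import (
    ContrastCallSet,
    classify_diet_response,
    classify_temperature_response,
    intersect_across_diets,
)


def call_set(up_25v15=(), down_25v15=(), up_25v20=(), down_25v20=(), up_20v15=(),
             down_20v15=(), diet="ecoli"):
    return ContrastCallSet(
        diet=diet,
        calls={
            "25v15": (set(up_25v15), set(down_25v15)),
            "25v20": (set(up_25v20), set(down_25v20)),
            "20v15": (set(up_20v15), set(down_20v15)),
        },
    )


class TestTemperatureDefinitions:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            # up at 25 vs both others, quiet at 20v15 -> exclusively hot
            (dict(up_25v15={"g"}, up_25v20={"g"}), "exclusively_hot"),
            # up only against 15 -> really a 15-degC down-shift
            (dict(up_25v15={"g"}), "false_hot"),
            # up at 15 vs both others, quiet at 25v20 -> exclusively cold
            (dict(down_25v15={"g"}, down_20v15={"g"}), "exclusively_cold"),
            # up at 15 only vs 25 -> really a 25-degC down-shift
            (dict(down_25v15={"g"}), "false_cold"),
        ],
    )
    def test_single_gene_patterns(self, kwargs, expected):
        cls = classify_temperature_response(call_set(**kwargs))
        assert cls.labels.get("g") == expected

    def test_quiet_gene_is_other(self):
        cls = classify_temperature_response(call_set(up_25v15={"x"}))
        assert "g" not in cls.labels

    def test_hot_candidate_significant_at_20v15_drops_to_other(self):
        """The 184-to-183 rule: any 20v15 significance disqualifies."""
        cls = classify_temperature_response(
            call_set(up_25v15={"g"}, up_25v20={"g"}, up_20v15={"g"})
        )
        assert "g" not in cls.labels  # not exclusively_hot, not false_hot
        assert "g" in cls.both_hot_candidates

    def test_contradictory_calls_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            call_set(up_25v15={"g"}, down_25v15={"g"})


def _ids(prefix, n):
    return {f"{prefix}{i}" for i in range(n)}


class TestPublishedCardinalities:
    def test_ecoli_hot_side_partition(self):
        """571 up at 25v15 with 184 also up at 25v20, one 20v15-significant,
        reproduce the published 183/387 split."""
        up_25v15 = _ids("g", 571)
        up_25v20 = _ids("g", 184)  # subset of up_25v15
        up_20v15 = {"g0"}  # the single excluded candidate
        cls = classify_temperature_response(
            call_set(up_25v15=up_25v15, up_25v20=up_25v20, up_20v15=up_20v15)
        )
        counts = cls.counts()
        assert counts["exclusively_hot"] == 183
        assert counts["false_hot"] == 387
        assert len(cls.both_hot_candidates) == 184

    def test_bsubtilis_hot_side_partition(self):
        cls = classify_temperature_response(
            call_set(up_25v15=_ids("g", 919), up_25v20=_ids("g", 161))
        )
        assert cls.counts()["false_hot"] == 758

    def test_ecoli_cold_side_partition(self):
        """665 up at 15v25, 35 also up at 15v20, 6 significant at 25v20:
        reproduce the published 29/630 split."""
        up_15v25 = _ids("g", 665)
        up_15v20 = _ids("g", 35)
        sig_25v20 = {f"g{i}" for i in range(6)}  # 6 of the 35 move at 20 vs 25
        cls = classify_temperature_response(
            call_set(down_25v15=up_15v25, down_20v15=up_15v20, down_25v20=sig_25v20)
        )
        counts = cls.counts()
        assert counts["exclusively_cold"] == 29
        assert counts["false_cold"] == 630


class TestInvariants:
    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 50))
    @settings(max_examples=30, deadline=None)
    def test_up_set_partitions_into_candidates_plus_false_hot(self, n_up, n_both, n_sig):
        n_both = min(n_both, n_up)
        cls = classify_temperature_response(
            call_set(
                up_25v15=_ids("g", n_up),
                up_25v20=_ids("g", n_both),
                up_20v15={f"g{i}" for i in range(min(n_sig, n_up))},
            )
        )
        assert len(cls.both_hot_candidates) + cls.counts()["false_hot"] == n_up
        assert cls.genes("exclusively_hot").isdisjoint(cls.genes("false_hot"))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(100)]
        up1 = set(rng.choice(genes, 40, replace=False))
        up2 = set(rng.choice(sorted(up1), 15, replace=False))
        mapping = {g: f"x{i}" for i, g in enumerate(rng.permutation(genes))}
        cls = classify_temperature_response(call_set(up_25v15=up1, up_25v20=up2))
        cls_m = classify_temperature_response(
            call_set(up_25v15={mapping[g] for g in up1}, up_25v20={mapping[g] for g in up2})
        )
        assert {mapping[g]: l for g, l in cls.labels.items()} == cls_m.labels


class TestDietResponse:
    def test_requires_all_three_temperatures(self):
        calls = {15: ({"g"}, set()), 20: ({"g"}, set()), 25: (set(), set())}
        labels = classify_diet_response(calls)
        assert labels["g"] == "none"

    def test_consistent_gene_labelled(self):
        calls = {t: ({"g"}, {"h"}) for t in (15, 20, 25)}
        labels = classify_diet_response(calls)
        assert labels["g"] == "ecoli_up"
        assert labels["h"] == "bsubtilis_up"

    def test_missing_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            classify_diet_response({15: (set(), set()), 20: (set(), set())})

    def test_published_diet_set_sizes(self):
        """Fixture sized to reproduce the published 68 / 173 diet partition."""
        ec = _ids("e", 68)
        bs = _ids("b", 173)
        calls = {t: (ec | _ids(f"extra{t}_", 9), bs) for t in (15, 20, 25)}
        labels = classify_diet_response(calls)
        assert (labels == "ecoli_up").sum() == 68
        assert (labels == "bsubtilis_up").sum() == 173


class TestCrossDiet:
    def _cls(self, diet, genes):
        return classify_temperature_response(
            call_set(up_25v15=set(genes), up_25v20=set(genes), diet=diet)
        )

    def test_disjoint_sets_empty_intersection(self):
        a = self._cls("ecoli", {"g1", "g2"})
        b = self._cls("bsubtilis", {"g3"})
        common, n1, n2 = intersect_across_diets(a, b, "exclusively_hot")
        assert common == set() and (n1, n2) == (2, 1)

    def test_identical_sets_full_intersection(self):
        a = self._cls("ecoli", {"g1", "g2", "g3"})
        b = self._cls("bsubtilis", {"g1", "g2", "g3"})
        common, n1, n2 = intersect_across_diets(a, b, "exclusively_hot")
        assert len(common) == n1 == n2 == 3

    def test_unknown_label_rejected(self):
        a = self._cls("ecoli", {"g1"})
        with pytest.raises(ValueError, match="label"):
            intersect_across_diets(a, a, "lukewarm")
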