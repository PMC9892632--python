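import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import (
    oracle_item_cf,
    oracle_item_sim,
    oracle_user_cf,
    oracle_user_sim,
)
from soothe.collaborative import (
    InteractionError,
    build_cooccurrence_matrix,
    build_interaction_store,
    build_item_similarity_matrix,
    build_user_similarity_matrix,
    item_cf_score,
    item_similarity,
    top_k_neighbors,
    user_cf_score,
    user_similarity,
)

records_strategy = st.lists(
    st.tuples(
        st.sampled_from([f"u{i}" for i in range(6)]),
        st.sampled_from([f"i{j}" for j in range(8)]),
    ),
    min_size=1,
    max_size=50,
)


class TestInteractionStore:
    def test_inverted_index(self):
        store = build_interaction_store([("u1", "a"), ("u1", "b"), ("u2", "b")])
        assert store.audience("b") == {"u1", "u2"}
        assert store.liked("u1") == {"a", "b"}

    def test_duplicates_stored_once(self):
        store = build_interaction_store([("u1", "a"), ("u1", "a")])
        assert store.liked("u1") == {"a"}
        assert store.rating("u1", "a") == 1.0

    def test_malformed_records_counted_not_raised(self):
        store = build_interaction_store([("u1", "a"), ("", "b"), ("u2", None)])
        assert store.n_rejected == 2
        assert store.users == ("u1",)

    def test_out_of_range_rating_rejected(self):
        store = build_interaction_store([("u1", "a", 9.0), ("u1", "b", 4.5)])
        assert store.n_rejected == 1
        assert store.rating("u1", "b") == 4.5

    @given(records_strategy)
    def test_forward_and_inverted_maps_consistent(self, records):
        store = build_interaction_store(records)
        for u, items in store.user_items.items():
            for y in items:
                assert u in store.item_users[y]
        for y, users in store.item_users.items():
            for u in users:
                assert y in store.user_items[u]
        assert set(store.ratings) == {
            (u, y) for u, items in store.user_items.items() for y in items
        }


class TestUserSimilarity:
    def test_identical_sets_unpenalized(self, eight_user_store):
        assert user_similarity("u1", "u3", eight_user_store) == 1.0

    def test_two_of_three_overlap(self):
        store = build_interaction_store(
            [("u", y) for y in "abc"] + [("v", y) for y in "bcd"]
        )
        assert user_similarity("u", "v", store) == pytest.approx(2 / 3)

    def test_penalty_neutral_at_audience_nine(self):
        # every co-liked item has audience exactly 9: 1/log10(10) = 1,
        # so the penalized similarity equals the unpenalized one.
        records = [("u", y) for y in "ab"] + [("v", y) for y in "ab"]
        records += [(f"w{i}", y) for i in range(7) for y in "ab"]
        store = build_interaction_store(records)
        assert len(store.audience("a")) == 9
        pen = user_similarity("u", "v", store, penalized=True)
        unpen = user_similarity("u", "v", store, penalized=False)
        assert pen == unpen == 1.0

    def test_empty_history_zero(self):
        store = build_interaction_store([("u", "a")])
        store.user_items["v"] = frozenset()  # patient with no history yet
        assert user_similarity("u", "v", store) == 0.0
        with pytest.raises(InteractionError, match="ghost"):
            user_similarity("u", "ghost", store)

    def test_literal_non_sqrt_variant(self):
        store = build_interaction_store(
            [("u", y) for y in "abc"] + [("v", y) for y in "bcd"]
        )
        assert user_similarity(
            "u", "v", store, sqrt_denominator=False
        ) == pytest.approx(2 / 9)

    def test_symmetry_and_oracle_on_fixture(self, eight_user_store):
        likes = {u: set(s) for u, s in eight_user_store.user_items.items()}
        for penalized in (False, True):
            for u in eight_user_store.users:
                for v in eight_user_store.users:
                    if u == v:
                        continue
                    z = user_similarity(u, v, eight_user_store, penalized=penalized)
                    assert z == user_similarity(
                        v, u, eight_user_store, penalized=penalized
                    )
                    assert z == oracle_user_sim(likes, u, v, penalized=penalized)
                    # cosine form is bounded by 1; the penalized form only
                    # once co-liked audiences reach 9 (penalty factor <= 1)
                    assert z >= 0.0
                    if not penalized:
                        assert z <= 1.0

    def test_popularity_growth_never_raises_penalized_sim(self, eight_user_store):
        base = user_similarity("u1", "u3", eight_user_store, penalized=True)
        bigger = build_interaction_store(
            list(eight_user_store.ratings) + [(f"extra{i}", "b") for i in range(5)]
        )
        grown = user_similarity("u1", "u3", bigger, penalized=True)
        assert grown <= base


class TestItemSimilarity:
    def test_identical_audiences_penalized_one(self, eight_user_store):
        store = build_interaction_store(
            [("u1", "a"), ("u1", "b"), ("u2", "a"), ("u2", "b")]
        )
        assert item_similarity("a", "b", store, penalized=True) == 1.0

    def test_asymmetric_and_symmetric_forms(self):
        store = build_interaction_store(
            [("u1", "h"), ("u2", "h"), ("u2", "y"), ("u3", "y"), ("u4", "y")]
        )
        assert item_similarity("h", "y", store, penalized=False) == 0.5
        assert item_similarity("h", "y", store, penalized=True) == pytest.approx(
            1 / math.sqrt(6)
        )

    def test_zero_audience_track(self, eight_user_store):
        assert item_similarity("a", "missing", eight_user_store) == 0.0

    def test_matrix_symmetric_and_matches_oracle(self, eight_user_store):
        likes = {u: set(s) for u, s in eight_user_store.user_items.items()}
        sims = build_item_similarity_matrix(eight_user_store, penalized=True)
        assert np.array_equal(sims.values, sims.values.T)
        for h in sims.labels:
            for y in sims.labels:
                if h != y:
                    assert sims.sim(h, y) == oracle_item_sim(
                        likes, h, y, penalized=True
                    )
                    assert 0.0 <= sims.sim(h, y) <= 1.0


class TestCooccurrence:
    def test_single_user_pair(self):
        store = build_interaction_store([("u", "a"), ("u", "b")])
        sims = build_cooccurrence_matrix(store)
        assert sims.sim("a", "b") == 1.0

    def test_disjoint_audiences_zero(self):
        store = build_interaction_store([("u", "a"), ("v", "b")])
        sims = build_cooccurrence_matrix(store)
        assert sims.sim("a", "b") == 0.0

    def test_equals_direct_pairwise_exactly(self, eight_user_store):
        direct = build_item_similarity_matrix(eight_user_store, penalized=True)
        via_counts = build_cooccurrence_matrix(eight_user_store)
        assert direct.labels == via_counts.labels
        assert direct.values.tolist() == via_counts.values.tolist()

    @given(records_strategy)
    def test_paths_agree_on_random_stores(self, records):
        store = build_interaction_store(records)
        direct = build_item_similarity_matrix(store, penalized=True)
        via_counts = build_cooccurrence_matrix(store)
        assert direct.values.tolist() == via_counts.values.tolist()


class TestNeighborhoods:
    def test_k_larger_than_population(self, eight_user_store):
        sims = build_user_similarity_matrix(eight_user_store)
        hood = top_k_neighbors("u1", sims, 100)
        assert len(hood.neighbors) == 7
        assert "u1" not in hood.ids

    def test_tie_break_ascending_id(self):
        store = build_interaction_store(
            [("u", "a"), ("v1", "a"), ("v2", "a")]
        )
        sims = build_user_similarity_matrix(store)
        hood = top_k_neighbors("u", sims, 1)
        assert hood.ids == ("v1",)

    def test_matches_full_sort_oracle(self, eight_user_store):
        sims = build_user_similarity_matrix(eight_user_store)
        hood = top_k_neighbors("u5", sims, 3)
        ranked = sorted(
            ((v, sims.sim("u5", v)) for v in sims.labels if v != "u5"),
            key=lambda t: (-t[1], t[0]),
        )
        assert list(hood.neighbors) == ranked[:3]

    def test_invalid_k(self, eight_user_store):
        sims = build_user_similarity_matrix(eight_user_store)
        with pytest.raises(ValueError):
            top_k_neighbors("u1", sims, 0)


class TestCfScores:
    def test_no_neighbor_liked_track(self):
        store = build_interaction_store(
            [("u", "a"), ("v", "a"), ("v", "b"), ("w", "c")]
        )
        sims = build_user_similarity_matrix(store)
        assert user_cf_score("w", "b", store, sims, 1) == 0.0

    def test_single_neighbor_contribution(self):
        store = build_interaction_store(
            [("u", "a"), ("u", "b"), ("v", "a"), ("v", "c"), ("v", "y")]
        )
        sims = build_user_similarity_matrix(store, penalized=False)
        z = user_similarity("u", "v", store)
        assert user_cf_score("u", "y", store, sims, 1) == z * 1.0

    def test_user_cf_matches_bruteforce(self, eight_user_store):
        likes = {u: set(s) for u, s in eight_user_store.user_items.items()}
        sims = build_user_similarity_matrix(eight_user_store, penalized=True)
        for u in eight_user_store.users:
            for y in eight_user_store.items:
                got = user_cf_score(u, y, eight_user_store, sims, 3)
                want = oracle_user_cf(likes, dict(eight_user_store.ratings), u, y, 3)
                assert got == want
                assert got >= 0.0

    def test_item_cf_matches_bruteforce(self, eight_user_store):
        likes = {u: set(s) for u, s in eight_user_store.user_items.items()}
        items = list(eight_user_store.items)
        sims = build_item_similarity_matrix(eight_user_store, penalized=True)
        for u in eight_user_store.users:
            for y in items:
                got = item_cf_score(u, y, eight_user_store, sims, 2)
                want = oracle_item_cf(
                    likes, dict(eight_user_store.ratings), items, u, y, 2
                )
                assert got == want

    def test_score_monotone_in_rating(self):
        base = [("u", "a"), ("v", "a"), ("v", "y", 1.0)]
        raised = [("u", "a"), ("v", "a"), ("v", "y", 5.0)]
        s1 = build_interaction_store(base)
        s2 = build_interaction_store(raised)
        sims1 = build_user_similarity_matrix(s1, penalized=False)
        sims2 = build_user_similarity_matrix(s2, penalized=False)
        assert user_cf_score("u", "y", s2, sims2, 2) >= user_cf_score(
            "u", "y", s1, sims1, 2
        )

    def test_unknown_user_raises_with_id(self, eight_user_store):
        sims = build_user_similarity_matrix(eight_user_store)
        with pytest.raises(InteractionError, match="ghost"):
            user_cf_score("ghost", "a", eight_user_store, sims, 2)
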