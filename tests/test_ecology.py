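"""Jaccard metrics, aggregate media, resampling schemes, correlations."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mento.ecology import (
    EcologicalProfile,
    aggregate_minenv,
    binned_similarity_curve,
    containment_test,
    fastidiousness_correlates,
    growth_on_aggregate,
    jaccard,
    mean_pair_score,
    read_minenv_table,
    read_profile,
    split_half_environment_distance,
    write_profile,
)
from mento.errors import PreconditionError, UnknownIdentifierError
from mento.synthetic import CommunitySpec, generate_community

sets_st = st.sets(st.integers(min_value=0, max_value=8), max_size=6)


class TestJaccard:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ({"a", "b"}, {"b", "c"}, 1 / 3),
            ({"a", "b"}, {"a", "b"}, 1.0),
            ({"a"}, {"b"}, 0.0),
            (set(), set(), 1.0),
            (set(), {"a"}, 0.0),
        ],
    )
    def test_known_values(self, s1, s2, expected):
        assert jaccard(s1, s2) == pytest.approx(expected)

    @given(s1=sets_st, s2=sets_st)
    def test_symmetric_and_bounded(self, s1, s2):
        assert jaccard(s1, s2) == jaccard(s2, s1)
        assert 0.0 <= jaccard(s1, s2) <= 1.0

    @given(s1=sets_st, s2=sets_st, s3=sets_st)
    def test_jaccard_distance_triangle_inequality(self, s1, s2, s3):
        d12 = 1 - jaccard(s1, s2)
        d23 = 1 - jaccard(s2, s3)
        d13 = 1 - jaccard(s1, s3)
        assert d13 <= d12 + d23 + 1e-12


class TestAggregate:
    def test_union_semantics(self):
        assert aggregate_minenv([{"a", "b"}, {"b", "c"}]) == {"a", "b", "c"}

    def test_singleton_identity(self):
        assert aggregate_minenv([{"x", "y"}]) == {"x", "y"}

    def test_all_empty_gives_empty(self):
        assert aggregate_minenv([set(), set()]) == frozenset()

    def test_empty_list_rejected(self):
        with pytest.raises(PreconditionError):
            aggregate_minenv([])


def _four_org_profile():
    """Organisms 1,2 co-distributed; 3,4 co-distributed elsewhere."""
    return EcologicalProfile(
        organisms=["o1", "o2", "o3", "o4"],
        environments=["e1", "e2"],
        presence=np.array([[1, 0], [1, 0], [0, 1], [0, 1]]),
    )


class TestBinnedSimilarityCurve:
    def test_hand_enumerable_extremes(self):
        # co-distributed pairs share everything, others share nothing:
        # nearest bin ratio 1, farthest bin ratio 0, perfect rank order
        profile = _four_org_profile()
        minenvs = {
            "o1": frozenset({"a", "b"}),
            "o2": frozenset({"a", "b"}),
            "o3": frozenset({"c", "d"}),
            "o4": frozenset({"c", "d"}),
        }
        curve = binned_similarity_curve(
            minenvs, profile, n_bins=2, thresholds=[50.0], min_pairs_per_bin=1
        )
        assert curve.pair_counts.tolist() == [2, 4]
        assert curve.ratio[0, 0] == 1.0
        assert curve.ratio[1, 0] == 0.0
        rho, p = curve.spearman[50.0]
        assert rho == pytest.approx(1.0)

    def test_identical_organisms_fill_one_bin(self):
        profile = EcologicalProfile(
            organisms=["a", "b", "c"],
            environments=["e"],
            presence=np.ones((3, 1)),
        )
        minenvs = {o: frozenset({"x"}) for o in "abc"}
        curve = binned_similarity_curve(
            minenvs, profile, n_bins=4, thresholds=[100.0], min_pairs_per_bin=1
        )
        assert curve.pair_counts.tolist() == [3, 0, 0, 0]
        assert curve.ratio[0, 0] == 1.0
        assert curve.spearman[100.0] is None  # a single bin has no trend

    def test_underfilled_bins_flagged_and_correlation_absent(self):
        profile = _four_org_profile()
        minenvs = {o: frozenset({"x"}) for o in profile.organisms}
        curve = binned_similarity_curve(
            minenvs, profile, n_bins=2, thresholds=[50.0], min_pairs_per_bin=99
        )
        assert curve.flagged.all()
        assert curve.spearman[50.0] is None

    def test_fewer_than_two_shared_organisms_rejected(self):
        profile = _four_org_profile()
        with pytest.raises(PreconditionError):
            binned_similarity_curve({"o1": frozenset({"a"})}, profile)


class TestSplitHalf:
    def test_identical_minenvs_give_zero_within_distance(self):
        rng_profile = EcologicalProfile(
            organisms=[f"m{i}" for i in range(4)] + [f"r{i}" for i in range(4)],
            environments=["focal", "other"],
            presence=np.array([[1, 0]] * 4 + [[0, 1]] * 4),
        )
        minenvs = {f"m{i}": frozenset({"a", "b"}) for i in range(4)}
        minenvs |= {f"r{i}": frozenset({chr(99 + i)}) for i in range(4)}
        res = split_half_environment_distance(
            minenvs, rng_profile, "focal", n_trials=5, group_size=2, seed=0
        )
        assert res.within_mean == 0.0
        assert res.random_mean > 0.0

    def test_single_trial_is_reproducible(self):
        models, profile, _ = generate_community(CommunitySpec(seed=3))
        minenvs = {
            o: frozenset(m.exchange_metabolite_ids) for o, m in models.items()
        }
        env = profile.environments[0]
        a = split_half_environment_distance(
            minenvs, profile, env, n_trials=1, group_size=2, seed=7
        )
        b = split_half_environment_distance(
            minenvs, profile, env, n_trials=1, group_size=2, seed=7
        )
        assert a.per_trial.equals(b.per_trial)

    def test_too_few_members_names_the_environment(self):
        profile = _four_org_profile()
        minenvs = {o: frozenset({"x"}) for o in profile.organisms}
        with pytest.raises(PreconditionError, match="e1"):
            split_half_environment_distance(
                minenvs, profile, "e1", group_size=5
            )


class TestGrowthOnAggregate:
    @pytest.fixture()
    def community(self):
        models, profile, _ = generate_community(
            CommunitySpec(n_organisms=16, n_environments=3, coupling=1.0, seed=21)
        )
        from mento.core import unique_minenv

        minenvs = {o: unique_minenv(m).minenv for o, m in models.items()}
        return models, profile, minenvs

    def test_minenv_subset_of_aggregate_guarantees_growth(self, community):
        models, profile, minenvs = community
        env = profile.environments[0]
        res = growth_on_aggregate(
            models, minenvs, profile, env, n_trials=4, seed=2
        )
        # reconstruct each trial's aggregate from the builder bookkeeping:
        # every tested organism whose own MINENV fits the aggregate grew
        for trial, group in res.per_trial.groupby("trial"):
            tested_in = group[group.group == "inside"].organism
            members = set(profile.members_of(env))
            builders = members & set(minenvs) - set(tested_in)
            aggregate = aggregate_minenv(minenvs[o] for o in builders)
            for o in tested_in:
                if minenvs[o] <= aggregate:
                    assert group[group.organism == o].grows.all()

    def test_two_member_environment_splits_one_and_one(self):
        models, _, _ = generate_community(
            CommunitySpec(n_organisms=4, n_environments=2, seed=33)
        )
        orgs = sorted(models)
        minenvs = {
            o: frozenset(m.exchange_metabolite_ids) for o, m in models.items()
        }
        profile = EcologicalProfile(
            organisms=orgs,
            environments=["pair", "rest"],
            presence=np.array([[1, 0], [1, 0], [0, 1], [0, 1]]),
        )
        res = growth_on_aggregate(
            models, minenvs, profile, "pair", holdout_fraction=0.5, n_trials=2, seed=0
        )
        inside = res.per_trial[res.per_trial.group == "inside"]
        assert (inside.groupby("trial").size() == 1).all()

    def test_reproducible_given_seed(self, community):
        models, profile, minenvs = community
        env = profile.environments[1]
        a = growth_on_aggregate(models, minenvs, profile, env, n_trials=3, seed=9)
        b = growth_on_aggregate(models, minenvs, profile, env, n_trials=3, seed=9)
        assert a.per_trial.equals(b.per_trial)


class TestContainment:
    def test_shared_single_medium_is_always_contained(self):
        profile = _four_org_profile()
        media = {o: frozenset({"m1", "m2"}) for o in profile.organisms}
        res = containment_test(media, profile, "e1", n_trials=3, seed=0)
        assert res.inside_fraction == 1.0
        assert res.outside_fraction == 1.0

    def test_private_compound_blocks_containment(self):
        profile = EcologicalProfile(
            organisms=["a", "b", "c", "z"],
            environments=["e1", "e2"],
            presence=np.array([[1, 0], [1, 0], [1, 0], [0, 1]]),
        )
        media = {
            "a": frozenset({"x"}),
            "b": frozenset({"x"}),
            "c": frozenset({"x", "private"}),
            "z": frozenset({"x"}),
        }
        res = containment_test(media, profile, "e1", n_trials=20, seed=1)
        inside = res.per_trial[res.per_trial.group == "inside"]
        got = inside[inside.organism == "c"]
        assert not got.empty and not got.grows.any()


class TestCorrelates:
    def test_self_correlation_is_one(self):
        sizes = {f"o{i}": float(i) for i in range(10)}
        rho, p, n = fastidiousness_correlates(sizes, sizes)
        assert rho == pytest.approx(1.0)
        assert n == 10

    def test_anti_correlation_is_minus_one(self):
        sizes = {f"o{i}": float(i) for i in range(10)}
        neg = {k: -v for k, v in sizes.items()}
        rho, _, _ = fastidiousness_correlates(sizes, neg)
        assert rho == pytest.approx(-1.0)

    def test_independent_covariate_is_null(self):
        rng = np.random.default_rng(0)
        sizes = {f"o{i}": float(rng.integers(5, 40)) for i in range(1000)}
        cov = {f"o{i}": float(rng.normal()) for i in range(1000)}
        rho, p, n = fastidiousness_correlates(sizes, cov)
        assert abs(rho) < 0.1 and p > 0.05

    def test_insufficient_overlap_rejected(self):
        with pytest.raises(PreconditionError):
            fastidiousness_correlates({"a": 1, "b": 2}, {"a": 1.0, "b": 2.0})


class TestMeanPairScore:
    def test_mean_over_all_pairings(self):
        scores = {("a", "b"): 1.0, ("a", "c"): 3.0, ("b", "c"): 10.0}
        assert mean_pair_score("a", scores) == 2.0

    def test_single_pair_returns_that_score(self):
        assert mean_pair_score("b", {("a", "b"): 4.5}) == 4.5

    def test_absent_organism_raises(self):
        with pytest.raises(UnknownIdentifierError):
            mean_pair_score("zz", {("a", "b"): 1.0})


class TestTableIO:
    def test_profile_round_trip(self, tmp_path):
        profile = _four_org_profile()
        path = tmp_path / "profile.tsv"
        write_profile(profile, path)
        back = read_profile(path)
        assert back.organisms == profile.organisms
        assert back.environments == profile.environments
        assert np.array_equal(back.presence, profile.presence)

    def test_minenv_table_round_trip(self, tmp_path, conversion_toy):
        from mento.core import critical_metabolites, unique_minenv, write_results_table

        res = unique_minenv(conversion_toy)
        critical_metabolites(conversion_toy, res)
        path = tmp_path / "minenvs.tsv"
        write_results_table({conversion_toy.id: res}, path)
        sizes, sets_ = read_minenv_table(path)
        assert sizes[conversion_toy.id] == res.minimal_size
        assert sets_[conversion_toy.id] == res.minenv

    def test_profile_without_header_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("\n")
        with pytest.raises((PreconditionError, Exception)):
            read_profile(path)


class TestCouplingRecovery:
    """The generative claim: nutrient-co-occurrence coupling is detectable."""

    def test_fully_coupled_community_shows_positive_trend(self):
        from mento.core import unique_minenv

        models, profile, _ = generate_community(CommunitySpec(coupling=1.0, seed=11))
        minenvs = {o: unique_minenv(m).minenv for o, m in models.items()}
        curve = binned_similarity_curve(
            minenvs, profile, n_bins=10, thresholds=[30.0], min_pairs_per_bin=10
        )
        rho, p = curve.spearman[30.0]
        assert rho > 0 and p < 0.05

    def test_split_half_within_smaller_than_random_when_coupled(self):
        from mento.core import unique_minenv

        models, profile, _ = generate_community(CommunitySpec(coupling=1.0, seed=11))
        minenvs = {o: unique_minenv(m).minenv for o, m in models.items()}
        within, rand = [], []
        for env in profile.environments:
            members = [o for o in profile.members_of(env) if o in minenvs]
            if len(members) >= 6:
                r = split_half_environment_distance(
                    minenvs, profile, env, n_trials=20, group_size=3, seed=5
                )
                within.append(r.within_mean)
                rand.append(r.random_mean)
        t, p = stats.ttest_rel(within, rand, alternative="less")
        assert p < 0.05
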