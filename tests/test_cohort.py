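import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from phedas.cohort import CensorWindow, aggregate, censor_visits, match_controls
from phedas.errors import ConfigError


def _subjects(rows):
    return pd.DataFrame(rows, columns=["subject_id", "sex", "is_case", "diagnosis_age"])


def _visits(rows):
    return pd.DataFrame(rows, columns=["subject_id", "age_at_visit", "phecode"])


class TestCensorWindow:
    def test_reversed_bounds_rejected(self):
        with pytest.raises(ConfigError):
            CensorWindow("age_interval", 10.0, 5.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            CensorWindow("middle_censor", 0.0, 5.0)


class TestCensorVisits:
    def test_left_censor_hand_trace(self):
        subjects = _subjects([("c1", "male", 1, 70.0)])
        visits = _visits([("c1", a, "296.2") for a in (63.0, 67.0, 69.0, 71.0)])
        kept = censor_visits(visits, subjects, CensorWindow("left_censor", 0.0, 5.0))
        assert sorted(kept["age_at_visit"]) == [67.0, 69.0]

    def test_age_interval_closed_below(self):
        subjects = _subjects([("s", "male", 1, np.nan)])
        visits = _visits([("s", 7.0, "296.2"), ("s", 6.9, "296.2")])
        kept = censor_visits(
            visits, subjects, CensorWindow("age_interval", 7.0, float("inf"))
        )
        assert list(kept["age_at_visit"]) == [7.0]

    def test_right_censor_includes_year_zero(self):
        subjects = _subjects([("c1", "male", 1, 50.0)])
        visits = _visits([("c1", 50.0, "296.2"), ("c1", 56.0, "296.2")])
        kept = censor_visits(visits, subjects, CensorWindow("right_censor", 0.0, 5.0))
        assert list(kept["age_at_visit"]) == [50.0]

    def test_missing_diagnosis_age_names_subjects(self):
        subjects = _subjects([("c1", "male", 1, np.nan)])
        visits = _visits([("c1", 50.0, "296.2")])
        with pytest.raises(ConfigError, match="c1"):
            censor_visits(visits, subjects, CensorWindow("left_censor", 0.0, 5.0))

    @pytest.mark.parametrize(
        "window",
        [
            CensorWindow("age_interval", 7.0, 60.0),
            CensorWindow("left_censor", 0.0, 5.0),
            CensorWindow("right_censor", 0.0, 5.0),
        ],
    )
    def test_censoring_shrinks_and_is_idempotent(self, window):
        rng = np.random.default_rng(7)
        subjects = _subjects([(f"s{i}", "male", 1, 50.0) for i in range(20)])
        visits = _visits(
            [(f"s{i}", a, "296.2") for i in range(20) for a in rng.uniform(0, 100, 5)]
        )
        once = censor_visits(visits, subjects, window)
        assert len(once) <= len(visits)
        twice = censor_visits(once, subjects, window)
        pd.testing.assert_frame_equal(once, twice)


class TestMatchControls:
    def _pool(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return _subjects(
            [
                (f"p{i}", rng.choice(["male", "female"]), 0, float(rng.uniform(20, 80)))
                for i in range(n)
            ]
        )

    def test_sexes_match_exactly(self):
        cases = _subjects([("c1", "male", 1, 40.0), ("c2", "female", 1, 60.0)])
        controls = match_controls(cases, self._pool(10), ratio=1, seed=1)
        assert len(controls) == 2
        sex_of = dict(zip(controls["matched_case"], controls["sex"]))
        assert sex_of == {"c1": "male", "c2": "female"}

    def test_exhausted_stratum_warns_and_returns_fewer(self):
        cases = _subjects([("c1", "male", 1, 40.0)])
        pool = _subjects([("p1", "male", 0, 41.0), ("p2", "male", 0, 39.0)])
        with pytest.warns(UserWarning, match="exhausted"):
            controls = match_controls(cases, pool, ratio=3, seed=1)
        assert len(controls) == 2

    def test_same_seed_same_controls(self):
        cases = _subjects(
            [(f"c{i}", "female", 1, 50.0 + i) for i in range(5)]
        )
        pool = self._pool(40, seed=3)
        a = match_controls(cases, pool, ratio=2, seed=11)
        b = match_controls(cases, pool, ratio=2, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_exclusion_carriers_removed_from_pool(self):
        cases = _subjects([("c1", "male", 1, 40.0)])
        pool = _subjects([("p1", "male", 0, 40.0), ("p2", "male", 0, 45.0)])
        controls = match_controls(
            cases, pool, ratio=1, exclusions={"296.2"}, seed=0,
            pool_phecodes={"p1": {"296.2"}},
        )
        assert list(controls["subject_id"]) == ["p2"]

    def test_controls_inherit_case_reference_age(self):
        cases = _subjects([("c1", "male", 1, 72.5)])
        pool = _subjects([("p1", "male", 0, np.nan)])
        controls = match_controls(cases, pool, ratio=1, seed=0)
        assert controls.loc[0, "diagnosis_age"] == 72.5

    def test_matched_ages_beat_random_draw(self):
        rng = np.random.default_rng(5)
        cases = _subjects(
            [(f"c{i}", "male", 1, float(rng.uniform(30, 70))) for i in range(30)]
        )
        pool = _subjects(
            [(f"p{i}", "male", 0, float(rng.uniform(20, 80))) for i in range(300)]
        )
        matched = match_controls(cases, pool, ratio=1, seed=2)
        matched_diff = (
            matched.set_index("matched_case")["diagnosis_age"]
            - cases.set_index("subject_id")["diagnosis_age"]
        ).abs().mean()
        # mean |age gap| for random same-size draws, averaged over 200 sims
        diffs = []
        for _ in range(200):
            draw = pool.sample(len(cases), random_state=rng.integers(2**31)).reset_index(drop=True)
            diffs.append((draw["diagnosis_age"].values - cases["diagnosis_age"].values))
        random_diff = np.abs(np.concatenate(diffs)).mean()
        assert matched_diff <= random_diff

    def test_overlapping_pool_rejected(self):
        cases = _subjects([("c1", "male", 1, 40.0)])
        with pytest.raises(ConfigError):
            match_controls(cases, cases, ratio=1, seed=0)


class TestAggregate:
    def test_binary_count_duration_direct_definitions(self):
        subjects = _subjects([("s1", "female", 1, np.nan)])
        visits = _visits([("s1", 40.0, "296.2"), ("s1", 42.5, "296.2")])
        for measure, expected in [("binary", 1), ("count", 2), ("duration", 2.5)]:
            m = aggregate(visits, subjects, measure=measure)
            assert m.loc["s1", "296.2"] == expected

    def test_no_occurrences_give_zero(self):
        subjects = _subjects([("s1", "male", 0, 55.0)])
        visits = _visits([])
        for measure in ("binary", "count", "duration"):
            m = aggregate(visits, subjects, measure=measure, phecodes=["296.2"])
            assert m.loc["s1", "296.2"] == 0

    def test_full_matrix_matches_brute_force_tally(self, hand_visits, toy_map):
        from phedas.vocab import map_visits

        mapped, _ = map_visits(hand_visits, toy_map)
        subjects = _subjects(
            [("a", "female", 1, np.nan), ("b", "male", 0, np.nan), ("c", "female", 0, np.nan)]
        )
        counts = aggregate(mapped, subjects, measure="count")
        # brute force: a has 296.21+311 -> 296.2 twice, 331.0 -> 290.11 once
        assert counts.loc["a", "296.2"] == 2 and counts.loc["a", "290.11"] == 1
        assert counts.loc["b", "290.11"] == 2 and counts.loc["b", "296.2"] == 0
        assert counts.loc["c", "296.2"] == 1 and counts.loc["c", "290.11"] == 0
        dur = aggregate(mapped, subjects, measure="duration")
        assert dur.loc["a", "296.2"] == pytest.approx(2.5)
        assert dur.loc["b", "290.11"] == pytest.approx(0.5)
        assert dur.loc["c", "296.2"] == 0.0

    def test_age_is_mean_visit_age_with_reference_fallback(self):
        subjects = _subjects([("s1", "male", 1, 60.0), ("s2", "male", 0, 45.0)])
        visits = _visits([("s1", 40.0, "296.2"), ("s1", 50.0, "296.2")])
        m = aggregate(visits, subjects, measure="binary")
        assert m.loc["s1", "age"] == 45.0
        assert m.loc["s2", "age"] == 45.0  # fallback to reference age

    def test_sex_coding_and_unknown_dropped(self):
        subjects = _subjects(
            [("s1", "female", 1, 50.0), ("s2", "male", 0, 50.0), ("s3", "?", 0, 50.0)]
        )
        with pytest.warns(UserWarning, match="unknown sex"):
            m = aggregate(_visits([]), subjects, measure="binary", phecodes=["296.2"])
        assert list(m.index) == ["s1", "s2"]
        assert m.loc["s1", "sex"] == 1 and m.loc["s2", "sex"] == 0

    def test_unknown_measure_rejected(self):
        with pytest.raises(ConfigError):
            aggregate(_visits([]), _subjects([("s", "male", 0, 1.0)]), measure="median")

    @given(
        ages=st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False), min_size=0, max_size=8
        )
    )
    @settings(derandomize=True, max_examples=40)
    def test_measure_consistency_invariants(self, ages):
        """binary=1 iff count>=1; duration>0 implies count>=2."""
        subjects = _subjects([("s1", "male", 1, 50.0)])
        visits = _visits([("s1", a, "296.2") for a in ages])
        b = aggregate(visits, subjects, "binary", phecodes=["296.2"]).loc["s1", "296.2"]
        c = aggregate(visits, subjects, "count", phecodes=["296.2"]).loc["s1", "296.2"]
        d = aggregate(visits, subjects, "duration", phecodes=["296.2"]).loc["s1", "296.2"]
        assert (b == 1) == (c >= 1)
        assert c == len(ages)
        if d > 0:
            assert c >= 2
        assert d >= 0
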