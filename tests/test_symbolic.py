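"""SAX/EWD abstraction, abstract temporal relations and TIRP mining."""

from itertools import combinations

import numpy as np
import pytest

from trendsieve.symbolic import (
    SymbolInterval,
    SymbolicError,
    TIRPFeaturizer,
    canonical_order,
    ewd_discretize,
    find_instances,
    mine_tirps,
    relation,
    sax_breakpoints,
    sax_discretize,
    tirp_matrix,
)
from trendsieve.windowing import WindowGrid


def _grid(m, width=2.0):
    return WindowGrid(m * width, width, allowed_widths=None)


class TestSax:
    def test_breakpoints_are_normal_quartiles(self):
        bp = sax_breakpoints(4)
        assert bp == pytest.approx([-0.6745, 0.0, 0.6745], abs=1e-4)

    def test_breakpoints_reject_tiny_alphabet(self):
        with pytest.raises(SymbolicError):
            sax_breakpoints(1)

    def test_symbols_and_merging(self):
        # normalized means [-1, -1, 2]: two low windows merge, high stands
        out = sax_discretize([-1.0, -1.0, 2.0], "x", _grid(3), 4, mu=0.0, sd=1.0)
        assert [(iv.symbol, iv.start, iv.end) for iv in out] == [
            (1, 0.0, 4.0),
            (4, 4.0, 6.0),
        ]

    def test_constant_series_is_single_middle_interval(self):
        out = sax_discretize([5.0] * 6, "x", _grid(6), 4)
        assert len(out) == 1
        assert out[0].symbol == 2  # middle symbol for zero spread
        assert (out[0].start, out[0].end) == (0.0, 12.0)

    def test_bin_occupancy_on_standard_normal(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(10_000)
        symbols = np.digitize(z, sax_breakpoints(4)) + 1
        freqs = np.bincount(symbols, minlength=5)[1:] / z.size
        assert np.all(np.abs(freqs - 0.25) < 0.02)


class TestEwd:
    def test_equal_width_bins(self):
        out = ewd_discretize([0.0, 2.5, 4.5, 6.5], "x", _grid(4), 4)
        assert [iv.symbol for iv in out] == [1, 2, 3, 4]

    def test_max_value_in_closed_top_bin(self):
        out = ewd_discretize([0.0, 8.0], "x", _grid(2), 4)
        assert out[-1].symbol == 4

    def test_degenerate_range_maps_to_middle(self):
        out = ewd_discretize([3.0, 3.0], "x", _grid(2), 4)
        assert len(out) == 1 and out[0].symbol == 2

    def test_disagrees_with_sax_on_skewed_data(self):
        # heavy right skew: quantile bins and equal-width bins differ
        vals = [0.0, 0.1, 0.2, 10.0]
        sax = sax_discretize(vals, "x", _grid(4), 4)
        ewd = ewd_discretize(vals, "x", _grid(4), 4)
        assert [iv.symbol for iv in sax] != [iv.symbol for iv in ewd]


class TestRelation:
    def test_before(self):
        a = SymbolInterval("x", 1, 0.0, 2.0)
        b = SymbolInterval("x", 2, 5.0, 7.0)
        assert relation(a, b, 0.0) == "before"

    def test_contains(self):
        a = SymbolInterval("x", 1, 0.0, 10.0)
        b = SymbolInterval("x", 2, 2.0, 5.0)
        assert relation(a, b) == "contains"

    def test_overlaps(self):
        a = SymbolInterval("x", 1, 0.0, 4.0)
        b = SymbolInterval("x", 2, 2.0, 6.0)
        assert relation(a, b) == "overlaps"

    def test_meets_folds_into_overlaps_at_zero_epsilon(self):
        a = SymbolInterval("x", 1, 0.0, 2.0)
        b = SymbolInterval("x", 2, 2.0, 4.0)
        assert relation(a, b, 0.0) == "overlaps"

    def test_epsilon_relaxes_before(self):
        a = SymbolInterval("x", 1, 0.0, 2.0)
        b = SymbolInterval("x", 2, 2.5, 4.0)
        assert relation(a, b, 0.0) == "before"
        assert relation(a, b, 1.0) == "overlaps"

    def test_non_canonical_order_rejected(self):
        a = SymbolInterval("x", 1, 3.0, 4.0)
        b = SymbolInterval("x", 2, 0.0, 2.0)
        with pytest.raises(SymbolicError):
            relation(a, b)


def _iv(ch, sym, s, e):
    return SymbolInterval(ch, sym, float(s), float(e))


def enumerate_tirps_oracle(database, min_support, k_max, epsilon=0.0):
    """Brute-force enumeration of every symbol/relation combination."""
    counts = {}
    for ivs in database:
        ivs = canonical_order(ivs)
        seen = set()
        for k in range(2, k_max + 1):
            for comb in combinations(range(len(ivs)), k):
                key = (
                    tuple((ivs[i].channel, ivs[i].symbol) for i in comb),
                    tuple(
                        relation(ivs[comb[i]], ivs[comb[j]], epsilon)
                        for j in range(1, k)
                        for i in range(j)
                    ),
                )
                seen.add(key)
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    n = len(database)
    return {
        key: c / n for key, c in counts.items() if c / n + 1e-12 >= min_support
    }


class TestMineTirps:
    def test_unanimous_pattern(self):
        db = [
            [_iv("a", 1, 0, 2), _iv("b", 1, 5, 7)],
            [_iv("a", 1, 1, 3), _iv("b", 1, 8, 9)],
        ]
        out = mine_tirps(db, min_support=0.6, k_max=2)
        assert len(out) == 1
        t = out[0]
        assert t.symbols == (("a", 1), ("b", 1))
        assert t.relations == ("before",)
        assert t.support == 1.0

    def test_below_threshold_not_frequent(self):
        db = [
            [_iv("a", 1, 0, 2), _iv("b", 1, 5, 7)],
            [_iv("a", 1, 0, 2)],
        ]
        assert mine_tirps(db, min_support=0.6, k_max=2) == []

    def test_empty_database(self):
        assert mine_tirps([], 0.6, 3) == []

    def test_anti_monotone_supports(self):
        rng = np.random.default_rng(3)
        db = _random_db(rng, n_patients=6, n_intervals=6)
        out = mine_tirps(db, min_support=0.4, k_max=3)
        by_key = {(t.symbols, t.relations): t.support for t in out}
        for t in out:
            if t.size == 3:
                parent = (t.symbols[:2], t.relations[:1])
                assert t.support <= by_key[parent] + 1e-12

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        db = _random_db(rng)
        mined = {
            ((t.symbols), (t.relations)): t.support
            for t in mine_tirps(db, min_support=0.5, k_max=3)
        }
        oracle = enumerate_tirps_oracle(db, min_support=0.5, k_max=3)
        assert mined == oracle


def _random_db(rng, n_patients=5, n_intervals=6, n_channels=3, alphabet=3):
    db = []
    for _ in range(n_patients):
        ivs = []
        for _ in range(int(rng.integers(1, n_intervals + 1))):
            s = float(rng.integers(0, 20))
            e = s + float(rng.integers(1, 8))
            ch = f"c{rng.integers(n_channels)}"
            ivs.append(_iv(ch, int(rng.integers(1, alphabet + 1)), s, e))
        db.append(canonical_order(ivs))
    return db


class TestTirpMatrix:
    def _ab_tirp(self):
        db = [[_iv("a", 1, 0, 2), _iv("b", 1, 5, 7)]]
        return mine_tirps(db, 0.5, 2)[0]

    def test_span_duration(self):
        t = self._ab_tirp()
        db = [[_iv("a", 1, 0, 2), _iv("b", 1, 5, 7)]]
        X = tirp_matrix(db, [t])
        assert X.iloc[0, 0] == 7.0  # last end (7) minus first start (0)

    def test_absent_pattern_is_zero(self):
        t = self._ab_tirp()
        X = tirp_matrix([[_iv("a", 1, 0, 2)]], [t])
        assert X.iloc[0, 0] == 0.0

    def test_mean_over_instances(self):
        t = self._ab_tirp()
        db = [
            [_iv("a", 1, 0, 2), _iv("b", 1, 4, 6), _iv("b", 1, 5, 8)]
        ]  # spans 6 and 8
        X = tirp_matrix(db, [t])
        assert X.iloc[0, 0] == 7.0

    def test_empty_frequent_set_rejected(self):
        with pytest.raises(SymbolicError):
            tirp_matrix([[]], [])


class TestFindInstances:
    def test_all_instances_found(self):
        t = TestTirpMatrix()._ab_tirp()
        ivs = [_iv("a", 1, 0, 2), _iv("b", 1, 4, 6), _iv("b", 1, 5, 8)]
        inst = find_instances(ivs, t)
        assert len(inst) == 2

    def test_unknown_symbol_gives_no_instances(self):
        t = TestTirpMatrix()._ab_tirp()
        assert find_instances([_iv("z", 9, 0, 1)], t) == []


class TestTIRPFeaturizer:
    def test_fast_transform_matches_reference_matcher(self, small_cohort):
        recs = small_cohort.records[:25]
        f = TIRPFeaturizer().fit(recs)
        if not f.tirps_:
            pytest.skip("no frequent patterns in this draw")
        X_fast = f.transform(recs[:8])
        grid = f._grid()
        db = []
        for r in recs[:8]:
            d = {}
            for ch in f.channels_:
                wm = f._window_means(r, ch, grid)
                if wm is not None:
                    d[ch] = wm
            db.append(f._discretize_patient(d, grid))
        X_ref = tirp_matrix(db, f.tirps_, f.epsilon)
        assert np.allclose(X_fast.to_numpy(), X_ref.to_numpy())

    def test_training_statistics_applied_to_test_patients(self, small_cohort):
        train = small_cohort.records[:30]
        test = small_cohort.records[30:40]
        f = TIRPFeaturizer().fit(train)
        X = f.transform(test)
        assert X.shape[0] == 10
        assert (X.to_numpy() >= 0).all()  # durations are nonnegative

    def test_json_serialization(self, small_cohort):
        f = TIRPFeaturizer().fit(small_cohort.records[:25])
        payload = f.tirps_to_json()
        for entry in payload:
            assert set(entry) == {"symbols", "relations", "support"}
            assert 0 < entry["support"] <= 1

    def test_invalid_settings_rejected(self):
        with pytest.raises(SymbolicError):
            TIRPFeaturizer(alphabet=1).fit([])
        with pytest.raises(SymbolicError):
            TIRPFeaturizer(discretizer="kmeans").fit([])
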