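import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hexitope.contact_analysis import (
    ContactSeries,
    aggregate_residue_level,
    interaction_probability,
    min_residue_distance,
    pair_contact_series,
)
from hexitope.errors import HexitopeError
from hexitope import synthetic_data as synth
from tests.conftest import brute_force_min_distance


def test_min_distance_closed_form():
    a = [[0.0, 0.0, 0.0]]
    b = [[0.0, 0.0, 1.5], [0.0, 0.0, 4.0]]
    assert min_residue_distance(a, b) == pytest.approx(1.5)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_min_distance_symmetric(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
    assert min_residue_distance(a, b) == pytest.approx(min_residue_distance(b, a))


def test_accelerated_equals_exhaustive_on_random_pairs():
    """KD-tree minimum distances agree with the O(n*m) brute-force oracle."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        a = rng.uniform(-20, 20, size=(rng.integers(1, 30), 3))
        b = rng.uniform(-20, 20, size=(rng.integers(1, 30), 3))
        assert min_residue_distance(a, b, method="kdtree") == pytest.approx(
            brute_force_min_distance(a, b)
        )
        assert min_residue_distance(a, b, method="brute") == pytest.approx(
            brute_force_min_distance(a, b)
        )


def _single_pair_series(toy_complex, fraction, n_frames, seed=1, threshold=2.0):
    pair = toy_complex.contact_pairs[0]
    schedule = synth.ContactSchedule(fractions={pair: fraction}, seed=seed)
    traj, truth = synth.simulate_contact_trajectory(toy_complex, schedule, n_frames)
    series = pair_contact_series(traj, toy_complex.topology, [pair], threshold=threshold)
    return pair, series, truth[pair]


def test_contact_strictly_below_threshold(toy_complex):
    """A pair held exactly at the threshold distance is never a contact."""
    pair, series, _ = _single_pair_series(
        toy_complex, fraction=1.0, n_frames=20, threshold=1.5
    )
    # generator places contacts at exactly 1.5 Å; with threshold 1.5 the
    # strict < comparison classifies every frame as non-contact
    assert not series.indicator.any()
    _, series2, _ = _single_pair_series(toy_complex, 1.0, 20, threshold=2.0)
    assert series2.indicator.all()


def test_all_true_gives_exactly_100(toy_complex):
    pair, series, _ = _single_pair_series(toy_complex, 1.0, 100)
    table = interaction_probability(series)
    assert table.pair_probability[pair] == 100.0


def test_all_false_gives_zero(toy_complex):
    pair, series, _ = _single_pair_series(toy_complex, 0.0, 100)
    table = interaction_probability(series)
    assert table.pair_probability[pair] == 0.0


def test_probability_equals_independent_recount(toy_complex):
    """Pipeline probabilities match an explicit per-frame distance recount."""
    pairs = toy_complex.contact_pairs[:4]
    schedule = synth.ContactSchedule(
        fractions={p: f for p, f in zip(pairs, (0.1, 0.4, 0.7, 0.95))}, seed=11
    )
    traj, _ = synth.simulate_contact_trajectory(toy_complex, schedule, n_frames=300)
    series = pair_contact_series(traj, toy_complex.topology, pairs, threshold=2.0)
    table = interaction_probability(series)
    topo = toy_complex.topology
    for pair in pairs:
        (ent_a, num_a), (ent_b, num_b) = pair
        sa = topo.atom_slice(topo.find(ent_a, num_a).key)
        sb = topo.atom_slice(topo.find(ent_b, num_b).key)
        count = 0
        for f in range(traj.n_frames):
            d = brute_force_min_distance(
                traj.frames[f, sa[0]:sa[1]], traj.frames[f, sb[0]:sb[1]]
            )
            count += d < 2.0
        assert table.pair_probability[pair] == pytest.approx(100.0 * count / traj.n_frames)


def test_probability_monotone_in_threshold(toy_complex):
    pair = toy_complex.contact_pairs[0]
    schedule = synth.ContactSchedule(fractions={pair: 0.5}, seed=5)
    traj, _ = synth.simulate_contact_trajectory(
        toy_complex, schedule, n_frames=200, contact_distance=1.7, apart_distance=3.0
    )
    counts = []
    for threshold in (3.5, 2.0, 1.5):
        s = pair_contact_series(traj, toy_complex.topology, [pair], threshold=threshold)
        counts.append(int(s.indicator.sum()))
    assert counts[0] >= counts[1] >= counts[2]


def _series_from_indicator(indicator, pairs):
    return ContactSeries(pairs=pairs, indicator=np.asarray(indicator), threshold=2.0)


def test_residue_union_of_disjoint_pairs():
    """30% and 20% contacts in disjoint frame sets union to 50%."""
    n = 100
    row1 = np.zeros(n, bool); row1[:30] = True
    row2 = np.zeros(n, bool); row2[30:50] = True
    pairs = [(("P1", 54), ("AB1-HC", 30)), (("P1", 54), ("AB1-HC", 55))]
    series = _series_from_indicator([row1, row2], pairs)
    agg = aggregate_residue_level(series, "P1")
    assert agg[("P1", 54)] == pytest.approx(50.0)
    table = interaction_probability(series)
    assert table.residue_probability[(("P1", 54), "AB1")] == pytest.approx(50.0)


def test_residue_with_single_pair_equals_pair_value():
    rng = np.random.default_rng(0)
    row = rng.random(200) < 0.37
    pairs = [(("P2", 56), ("AB1-HC", 104))]
    series = _series_from_indicator([row], pairs)
    table = interaction_probability(series)
    assert table.residue_probability[(("P2", 56), "AB1")] == pytest.approx(
        table.pair_probability[pairs[0]]
    )


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_residue_value_bounds_pair_values(seed):
    """The frame-union residue probability never drops below any pair value."""
    rng = np.random.default_rng(seed)
    n_pairs, n = rng.integers(2, 6), 80
    pairs = [(("P1", 54), ("AB1-HC", 10 + i)) for i in range(n_pairs)]
    series = _series_from_indicator(rng.random((n_pairs, n)) < 0.4, pairs)
    table = interaction_probability(series)
    residue = table.residue_probability[(("P1", 54), "AB1")]
    assert all(residue >= table.pair_probability[p] - 1e-9 for p in pairs)


@pytest.mark.parametrize("p", [0.05, 0.5, 0.82, 0.98])
def test_bernoulli_rate_recovery(p):
    """Estimates at n=5000 fall within 3 binomial SE in >=99% of replicates."""
    n = 5000
    se3 = 3.0 * np.sqrt(p * (1 - p) / n)
    hits = 0
    reps = 100
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        row = rng.random(n) < p
        series = _series_from_indicator([row], [(("P1", 54), ("AB1-HC", 30))])
        est = interaction_probability(series).pair_probability[series.pairs[0]] / 100.0
        hits += abs(est - p) <= se3
    assert hits >= 0.99 * reps


def test_zero_frames_and_unknown_residue_errors(toy_complex):
    empty = _series_from_indicator(np.empty((1, 0), bool), [(("P1", 54), ("AB1-HC", 30))])
    with pytest.raises(HexitopeError):
        interaction_probability(empty)
    pair = (("P1", 999), ("AB1-HC", 30))
    schedule = synth.ContactSchedule(fractions={toy_complex.contact_pairs[0]: 1.0}, seed=0)
    traj, _ = synth.simulate_contact_trajectory(toy_complex, schedule, 2)
    with pytest.raises(HexitopeError):
        pair_contact_series(traj, toy_complex.topology, [pair])
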