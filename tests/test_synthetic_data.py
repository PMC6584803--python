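import numpy as np
import pytest

from hexitope.contact_analysis import interaction_probability, pair_contact_series
from hexitope.errors import ConfigurationError, HexitopeError
from hexitope import synthetic_data as synth
from tests.conftest import brute_force_min_distance


def test_generators_are_seed_deterministic():
    c = synth.build_toy_complex()
    sch = synth.ContactSchedule(fractions={c.contact_pairs[0]: 0.5}, seed=99)
    t1, _ = synth.simulate_contact_trajectory(c, sch, 50)
    t2, _ = synth.simulate_contact_trajectory(c, sch, 50)
    np.testing.assert_array_equal(t1.frames, t2.frames)
    p1, l1 = synth.generate_pose_set(n=6, n_correct=2, seed=5)
    p2, l2 = synth.generate_pose_set(n=6, n_correct=2, seed=5)
    assert l1 == l2
    for a, b in zip(p1, p2):
        np.testing.assert_array_equal(a.coords, b.coords)
    r1 = synth.simulate_current_traces(seed=8)[0].current
    r2 = synth.simulate_current_traces(seed=8)[0].current
    np.testing.assert_array_equal(r1, r2)


def test_default_complex_ground_truth_by_brute_force(toy_complex):
    """Brute-force geometry recovers exactly the designed contact map."""
    topo = toy_complex.topology
    coords = toy_complex.coords
    threshold = 2.0
    observed: dict[str, set[str]] = {ab: set() for ab in topo.antibodies()}
    for protomer in topo.protomers:
        for res_p in topo.residues_of_entity(protomer):
            sp = topo.atom_slice(res_p.key)
            for ab in topo.antibodies():
                for res_a in topo.residues_of_entity(ab):
                    sa = topo.atom_slice(res_a.key)
                    d = brute_force_min_distance(coords[sp[0]:sp[1]], coords[sa[0]:sa[1]])
                    if d < threshold:
                        observed[ab].add(protomer)
    assert observed == {
        "AB1": {"P1", "P2", "P3", "P4"},
        "AB2": {"P4", "P5", "P6", "P1"},
    }


def test_channel_only_and_trimer_variants():
    channel = synth.build_toy_complex(n_antibodies=0)
    assert channel.topology.antibodies() == []
    assert len(channel.topology.chains) == 6
    trimer = synth.build_toy_complex(n_protomers=3, n_antibodies=1,
                                     contact_map={"AB1": ["P1", "P2"]})
    assert trimer.topology.protomers == ["P1", "P2", "P3"]
    assert {p for (p, _), _ in trimer.contact_pairs} == {"P1", "P2"}


def test_contact_map_unknown_protomer_errors():
    with pytest.raises(ConfigurationError, match="absent protomer"):
        synth.build_toy_complex(contact_map={"AB1": ["P7"]})


def test_scheduled_fraction_one_measures_100(toy_complex):
    pair = toy_complex.contact_pairs[2]
    sch = synth.ContactSchedule(fractions={pair: 1.0}, seed=0)
    traj, _ = synth.simulate_contact_trajectory(toy_complex, sch, 40)
    series = pair_contact_series(traj, toy_complex.topology, [pair])
    assert interaction_probability(series).pair_probability[pair] == 100.0


def test_realized_fraction_tracks_target(toy_complex):
    pair = toy_complex.contact_pairs[0]
    sch = synth.ContactSchedule(fractions={pair: 0.82}, seed=1)
    traj, truth = synth.simulate_contact_trajectory(toy_complex, sch, 5000)
    realized = truth[pair].mean()
    se3 = 3 * np.sqrt(0.82 * 0.18 / 5000)
    assert abs(realized - 0.82) <= se3
    # the geometric measurement agrees with the drawn truth exactly
    series = pair_contact_series(traj, toy_complex.topology, [pair])
    np.testing.assert_array_equal(series.indicator[0], truth[pair])


def test_markov_model_unbiased_with_inflated_variance(toy_complex):
    """Dwell-correlated contacts keep the stationary mean but raise the
    variance of the fraction estimate relative to independent draws."""
    p, n, reps = 0.5, 400, 60
    est_b, est_m = [], []
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        est_b.append(float(np.mean(synth._draw_indicator(p, n, "bernoulli", 1, rng))))
        rng = np.random.default_rng(seed)
        est_m.append(
            float(np.mean(synth._draw_indicator(p, n, "two_state_markov", 25, rng)))
        )
    assert np.mean(est_m) == pytest.approx(p, abs=0.1)
    assert np.var(est_m) > 2 * np.var(est_b)


def test_mobile_residue_in_two_pairs_rejected(toy_complex):
    pair1 = toy_complex.contact_pairs[0]
    pair2 = ((("P2", 54)), pair1[1])
    sch = synth.ContactSchedule(fractions={pair1: 0.5, pair2: 0.5}, seed=0)
    with pytest.raises(HexitopeError, match="mobile"):
        synth.simulate_contact_trajectory(toy_complex, sch, 5)


def test_schedule_validation():
    with pytest.raises(HexitopeError):
        synth.ContactSchedule(fractions={(("P1", 54), ("AB1-HC", 30)): 1.5})
    with pytest.raises(HexitopeError):
        synth.ContactSchedule(fractions={}, model="brownian")


def test_invalid_frame_and_pose_counts(toy_complex):
    sch = synth.ContactSchedule(fractions={toy_complex.contact_pairs[0]: 0.5})
    with pytest.raises(HexitopeError):
        synth.simulate_contact_trajectory(toy_complex, sch, 0)
    with pytest.raises(HexitopeError):
        synth.generate_pose_set(n=5, n_correct=6)


def test_bundled_tables_shapes_and_values(bundled):
    assert len(bundled["family_motifs"]) == 20
    assert len(bundled["residual_conductance"]) == 10
    ch = bundled["channel_contacts"]
    leu56_p2 = ch[(ch.protomer == "P2") & (ch.number == 56)]
    assert leu56_p2.probability_pct.item() == 100
    ab = bundled["antibody_contacts"]
    thr182 = ab[(ab.chain == "LC") & (ab.number == 182)]
    assert thr182.probability_pct.item() == 98
    cond = bundled["residual_conductance"]
    assert cond.set_index("isoform").residual_pct["hCx26"] == 16.8


def test_pose_set_extreme_counts():
    poses, labels = synth.generate_pose_set(n=4, n_correct=0, seed=1)
    assert not any(labels)
    poses, labels = synth.generate_pose_set(n=4, n_correct=4, seed=1)
    assert all(labels)
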