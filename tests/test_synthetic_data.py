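"""The cohort generator: sizes, event statistics, epochs, and fixture I/O."""

import numpy as np
import pandas as pd
import pytest

from ticsupp import synthetic_data as sd
from ticsupp.timefreq import ERSPGrid, compute_ersp


def test_default_cohort_sizes():
    cohort = sd.generate_cohort(sd.CohortConfig(seed=0))
    counts = cohort.subjects.group.value_counts()
    assert counts["TDC"] == 37
    assert counts["CTD"] == 39


def test_cohort_is_deterministic_for_fixed_seed():
    a = sd.generate_cohort(sd.CohortConfig(seed=7))
    b = sd.generate_cohort(sd.CohortConfig(seed=7))
    pd.testing.assert_frame_equal(a.subjects, b.subjects)
    pd.testing.assert_frame_equal(a.events, b.events)
    c = sd.generate_cohort(sd.CohortConfig(seed=8))
    assert not a.events.equals(c.events)


def test_zero_rate_excludes_every_subject():
    config = sd.CohortConfig(
        n_per_group={"TDC": 5, "CTD": 5},
        event_rate={(g, c): 0.0 for g in sd.GROUPS for c in sd.CONDITIONS},
        seed=0,
    )
    cohort = sd.generate_cohort(config)
    assert cohort.subjects.excluded.all()
    assert cohort.events.empty


def test_event_count_mean_matches_renewal_target():
    """1000 subjects at 17.9/min for 5 min: mean count within 2 SE of 89.5."""
    config = sd.CohortConfig(
        n_per_group={"TDC": 1000},
        event_rate={("TDC", c): 17.9 for c in sd.CONDITIONS},
        rate_dispersion={"TDC": 0.0},
        condition_noise=0.0,
        suppression_kappa=0.0,
        block_duration_min=(5.0, 5.0),
        min_events=0,
        seed=11,
    )
    cohort = sd.generate_cohort(config)
    counts = (
        cohort.events[cohort.events.condition == "NoSupp"]
        .groupby("subject_id")
        .size()
        .reindex(cohort.subjects.subject_id, fill_value=0)
    )
    se = counts.std() / np.sqrt(len(counts))
    assert abs(counts.mean() - 89.5) < 2 * se


def test_event_series_invariants(small_cohort):
    refractory = small_cohort.config.refractory_s
    for (sid, cond), grp in small_cohort.events.groupby(["subject_id", "condition"]):
        times = grp.event_time_s.to_numpy()
        assert np.all(np.diff(times) >= refractory)
        assert times[0] >= 0
        assert times[-1] <= grp.block_duration_s.iloc[0]


def test_rates_converge_to_configured_group_means():
    """Across a large simulated group, mean events/min approaches the target."""
    config = sd.CohortConfig(
        n_per_group={"CTD": 400},
        event_rate={("CTD", c): r for c, r in
                    zip(sd.CONDITIONS, (3.6, 2.3, 1.9))},
        block_duration_min=(6.0, 6.0),
        min_events=0,
        seed=3,
    )
    cohort = sd.generate_cohort(config)
    for cond, target in zip(sd.CONDITIONS, (3.6, 2.3, 1.9)):
        counts = (
            cohort.events[cohort.events.condition == cond]
            .groupby("subject_id")
            .size()
            .reindex(cohort.subjects.subject_id, fill_value=0)
        )
        rate = counts.mean() / 6.0
        assert rate == pytest.approx(target, rel=0.15)


def _subject(group="TDC", ability=0.0):
    return {"subject_id": "S0", "group": group, "latent_ability": ability}


def test_early_events_are_dropped():
    config = sd.CohortConfig(min_events=0, sampling_rate=125.0, effect_spec=[], seed=0)
    events = {"NoSupp": sd.EventSeries("NoSupp", np.array([2.0, 300.0]), 360.0)}
    ic = sd.simulate_ic_epochs(_subject(), events, config, rng=np.random.default_rng(0))
    assert ic.epochs["NoSupp"].shape == (1, int(5 * 125))


def test_all_early_events_raise():
    config = sd.CohortConfig(min_events=0, effect_spec=[], seed=0)
    events = {"NoSupp": sd.EventSeries("NoSupp", np.array([1.0, 3.0]), 360.0)}
    with pytest.raises(ValueError, match="retained"):
        sd.simulate_ic_epochs(_subject(), events, config, rng=np.random.default_rng(0))


def test_flat_effect_spec_gives_flat_ersp():
    """With all injected amplitudes at 0 dB the epochs are stationary."""
    spec = sd.EffectSpec(band_hz=(4.0, 8.0), window_s=(-3.0, 0.0), amplitude_db={})
    config = sd.CohortConfig(
        min_events=0, sampling_rate=125.0, effect_spec=[spec], seed=0
    )
    events = {
        "NoSupp": sd.EventSeries("NoSupp", np.linspace(10, 590, 40), 600.0)
    }
    ic = sd.simulate_ic_epochs(_subject(), events, config, rng=np.random.default_rng(2))
    tensor = compute_ersp(ic.epochs["NoSupp"], 125.0, ERSPGrid.regular(25, 200))
    grid = tensor.grid
    band = tensor.values[np.ix_((grid.freqs_hz >= 4) & (grid.freqs_hz <= 8),
                                (grid.times_s >= -3.0) & (grid.times_s <= 0.0))]
    assert abs(band.mean()) < 0.5  # nothing was injected in the band/window


def test_injected_theta_burst_recovered_via_ersp():
    """A +3 dB suppression-condition theta burst appears in the ERSP contrast."""
    spec = sd.EffectSpec(
        band_hz=(4.0, 8.0),
        window_s=(-3.0, 0.0),
        amplitude_db={("TDC", "Supp_Vrb"): 3.0},
    )
    config = sd.CohortConfig(
        min_events=0, sampling_rate=125.0, effect_spec=[spec],
        coupling_beta=0.0, seed=0,
    )
    times = np.linspace(10, 590, 40)
    events = {
        c: sd.EventSeries(c, times, 600.0) for c in ("NoSupp", "Supp_Vrb")
    }
    ic = sd.simulate_ic_epochs(_subject(), events, config, rng=np.random.default_rng(5))
    grid = ERSPGrid.regular(25, 200)
    e_no = compute_ersp(ic.epochs["NoSupp"], 125.0, grid)
    e_supp = compute_ersp(ic.epochs["Supp_Vrb"], 125.0, grid)
    contrast = e_supp.values - e_no.values
    fi = np.argmin(np.abs(grid.freqs_hz - np.sqrt(32.0)))
    ti = np.argmin(np.abs(grid.times_s + 1.5))
    assert contrast[fi, ti] == pytest.approx(3.0, abs=1.0)
    # outside the injected band the mean contrast stays near zero
    far = contrast[grid.freqs_hz > 20.0, :]
    assert abs(far.mean()) < 0.5


def test_ability_scales_injected_amplitude():
    config = sd.CohortConfig(min_events=0, seed=0)
    spec = config.effect_spec[0]
    db = spec.amplitude_db[("TDC", "Supp_Vrb")]
    # with coupling_beta = 0.5, ability +1 scales the injected dB by 1.5
    assert db * (1.0 + config.coupling_beta * 1.0) == pytest.approx(1.5 * db)


def test_coupling_zero_gives_uncorrelated_summaries():
    pairs = sd.simulate_summary_pairs(4000, rho=0.0, seed=0)
    r = np.corrcoef(pairs.delta_summary, pairs.suppression_score)[0, 1]
    assert abs(r) < 0.05


def test_summary_pairs_hit_target_correlation():
    pairs = sd.simulate_summary_pairs(20000, rho=0.5, seed=1)
    r = np.corrcoef(pairs.delta_summary, pairs.suppression_score)[0, 1]
    assert r == pytest.approx(0.5, abs=0.03)


def test_fixture_roundtrip(tmp_path, small_cohort, small_ic_data):
    sd.write_fixture(small_cohort, small_ic_data, tmp_path / "fx")
    cohort2, ics2 = sd.read_fixture(tmp_path / "fx")
    pd.testing.assert_frame_equal(small_cohort.subjects, cohort2.subjects)
    pd.testing.assert_frame_equal(small_cohort.events, cohort2.events)
    assert cohort2.config == small_cohort.config
    by_key = {(ic.subject_id, ic.ic_id): ic for ic in ics2}
    assert len(by_key) == len(small_ic_data)
    for ic in small_ic_data:
        other = by_key[(ic.subject_id, ic.ic_id)]
        np.testing.assert_array_equal(ic.dipole_xyz, other.dipole_xyz)
        assert ic.centroid_index == other.centroid_index
        for cond, eps in ic.epochs.items():
            np.testing.assert_array_equal(eps, other.epochs[cond])


def test_fixture_roundtrip_empty_cohort(tmp_path):
    config = sd.CohortConfig(n_per_group={"TDC": 1}, seed=0)
    empty = sd.CohortTable(
        subjects=pd.DataFrame(
            columns=[
                "subject_id", "group", "age", "sex", "drug", "puts",
                "latent_ability", "excluded",
            ]
        ),
        events=pd.DataFrame(
            columns=["subject_id", "condition", "event_time_s", "block_duration_s"]
        ),
        config=config,
    )
    sd.write_fixture(empty, [], tmp_path / "fx")
    cohort2, ics2 = sd.read_fixture(tmp_path / "fx")
    assert cohort2.subjects.empty
    assert ics2 == []


def test_fixture_reports_all_event_series(tmp_path):
    config = sd.CohortConfig(
        n_per_group={"TDC": 2},
        event_rate={("TDC", c): 8.0 for c in sd.CONDITIONS},
        min_events=0,
        seed=4,
    )
    cohort = sd.generate_cohort(config)
    sd.write_fixture(cohort, [], tmp_path / "fx")
    cohort2, _ = sd.read_fixture(tmp_path / "fx")
    n_series = cohort2.events.groupby(["subject_id", "condition"]).ngroups
    assert n_series == 2 * 3


def test_fixture_layout_version_mismatch(tmp_path, small_cohort):
    import h5py

    sd.write_fixture(small_cohort, [], tmp_path / "fx")
    with h5py.File(tmp_path / "fx" / "ic_epochs.h5", "a") as h5:
        h5.attrs["layout_version"] = "999"
    with pytest.raises(ValueError, match="layout version"):
        sd.read_fixture(tmp_path / "fx")


def test_missing_fixture_file(tmp_path):
    with pytest.raises(FileNotFoundError):
        sd.read_fixture(tmp_path / "nope")


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_per_group": {"TDC": 0, "CTD": 5}},
        {"event_rate": {("TDC", "NoSupp"): -1.0}},
        {"block_duration_min": (0.0, 5.0)},
        {"min_events": -1},
    ],
)
def test_invalid_config_raises(kwargs):
    with pytest.raises(ValueError):
        sd.CohortConfig(**kwargs)


def test_event_series_validation():
    with pytest.raises(ValueError, match="increasing"):
        sd.EventSeries("NoSupp", np.array([2.0, 1.0]), 300.0)
    with pytest.raises(ValueError, match="within"):
        sd.EventSeries("NoSupp", np.array([2.0, 400.0]), 300.0)
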