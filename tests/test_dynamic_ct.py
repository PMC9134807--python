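"""Kymographs, lifetimes, regimes, power-law fits and C-factors."""

import itertools

import numpy as np
import pytest

from circuitop.contact_mapping import ContactMap, ContactTrajectory
from circuitop.dynamic_ct import (
    DEFAULT_REGIMES,
    LifetimeTable,
    RegimeSpec,
    build_kymograph,
    c_factor,
    cumulative_contact_time,
    filtered_topology_trajectory,
    fit_power_law,
    fit_power_law_density,
    fit_power_law_mle,
    lifetime_table,
    regime_mask,
    run_lifetimes,
)
from circuitop.synthetic_data import sample_truncated_power_law

from conftest import oracle_census, random_contact_map


def traj_from_rows(rows: dict, n_frames: int, N: int, delta_t=5.0) -> ContactTrajectory:
    maps = []
    for f in range(n_frames):
        contacts = frozenset(p for p, row in rows.items() if row[f])
        maps.append(ContactMap(N=N, contacts=contacts))
    return ContactTrajectory(maps=tuple(maps), delta_t=delta_t)


class TestKymograph:
    def test_no_contacts_gives_zero_rows(self):
        traj = ContactTrajectory(
            maps=tuple(ContactMap(N=10, contacts=frozenset()) for _ in range(5))
        )
        kymo = build_kymograph(traj)
        assert kymo.presence.shape == (0, 5)

    def test_single_pair_presence_count(self):
        rows = {(1, 6): [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]}
        kymo = build_kymograph(traj_from_rows(rows, 10, 10))
        assert kymo.pairs == ((1, 6),)
        assert kymo.presence.sum() == 5

    def test_random_schedule_reconstructed(self, rng):
        pairs = [(int(i), int(i) + 5) for i in range(1, 51)]
        rows = {p: rng.integers(0, 2, size=40) for p in pairs}
        kymo = build_kymograph(traj_from_rows(rows, 40, 60))
        active = sorted(p for p in pairs if rows[p].any())
        assert list(kymo.pairs) == active
        for r, p in enumerate(kymo.pairs):
            assert np.array_equal(kymo.presence[r], rows[p].astype(np.uint8))


class TestRunLifetimes:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([1, 1, 1, 0, 0, 1, 1], [15.0, 10.0]),
            ([1] * 8, [40.0]),
            ([0, 0, 0], []),
        ],
    )
    def test_examples(self, row, expected):
        assert run_lifetimes(row, 5.0) == expected

    def test_matches_rle_oracle(self, rng):
        row = rng.integers(0, 2, size=200)
        oracle = [
            5.0 * len(list(g)) for k, g in itertools.groupby(row) if k == 1
        ]
        assert sorted(run_lifetimes(row, 5.0)) == sorted(oracle)

    def test_gap_tolerance_merges_runs(self):
        row = [1, 1, 0, 1, 1, 0, 0, 1]
        assert run_lifetimes(row, 1.0, gap_tolerance=1) == [4.0, 1.0]

    def test_invalid_delta_t(self):
        with pytest.raises(ValueError):
            run_lifetimes([1, 0], 0.0)

    def test_conservation_of_presence(self, rng):
        for _ in range(10):
            row = rng.integers(0, 2, size=100)
            assert sum(run_lifetimes(row, 5.0)) == pytest.approx(5.0 * row.sum())


class TestLifetimeTable:
    def test_single_run_max_equals_cumulative(self):
        rows = {(1, 8): [0, 1, 1, 1, 0, 0]}
        table = lifetime_table(build_kymograph(traj_from_rows(rows, 6, 10)))
        assert table.max_lifetime[0] == table.cumulative_time[0] == 15.0

    def test_two_runs(self):
        rows = {(1, 8): [1, 1, 1, 0, 0, 1, 1]}
        table = lifetime_table(build_kymograph(traj_from_rows(rows, 7, 10)))
        assert table.max_lifetime[0] == 15.0
        assert table.cumulative_time[0] == 25.0

    def test_row_conservation(self, rng):
        pairs = [(int(i), int(i) + 4) for i in range(1, 21)]
        rows = {p: rng.integers(0, 2, size=50) for p in pairs}
        kymo = build_kymograph(traj_from_rows(rows, 50, 30))
        table = lifetime_table(kymo)
        for r, runs in enumerate(table.runs):
            assert sum(runs) / kymo.delta_t == kymo.presence[r].sum()
        total = sum(sum(r) for r in table.runs) / kymo.delta_t
        assert total == kymo.presence.sum()


class TestPowerLawFit:
    def test_exact_tau_minus_two_density(self):
        tau = np.logspace(0.2, 3.0, 15)
        fit = fit_power_law_density(tau, 4.2 * tau**-2.0)
        assert fit.gamma == pytest.approx(2.0, abs=1e-12)
        assert fit.A == pytest.approx(4.2)
        assert fit.r_squared == pytest.approx(1.0)

    def test_sampled_recovery(self):
        rng = np.random.default_rng(42)
        tau = sample_truncated_power_law(rng, 1.5, 5.0, 2000.0, 10_000)
        assert fit_power_law(tau).gamma == pytest.approx(1.5, abs=0.1)

    def test_mle_recovery(self):
        rng = np.random.default_rng(43)
        tau = sample_truncated_power_law(rng, 1.5, 5.0, 2000.0, 10_000)
        assert fit_power_law_mle(tau).gamma == pytest.approx(1.5, abs=0.1)

    def test_replicate_stability(self):
        fits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tau = sample_truncated_power_law(rng, 1.5, 5.0, 2000.0, 10_000)
            g = fit_power_law(tau).gamma
            assert g == pytest.approx(1.5, abs=0.15)
            fits.append(g)
        assert np.mean(fits) == pytest.approx(1.5, abs=0.05)

    def test_identical_lifetimes_fit_error(self):
        with pytest.raises(ValueError):
            fit_power_law([10.0] * 50)

    def test_window_restricts_data(self):
        rng = np.random.default_rng(7)
        tau = sample_truncated_power_law(rng, 1.5, 5.0, 2000.0, 5000)
        fit = fit_power_law(tau, window=(10.0, 1000.0))
        assert fit.fit_window[0] >= 10.0 and fit.fit_window[1] <= 1000.0


class TestRegimes:
    def make_table(self, maxima):
        pairs = tuple((k + 1, k + 10) for k in range(len(maxima)))
        runs = tuple((m,) for m in maxima)
        return LifetimeTable(pairs=pairs, runs=runs, delta_t=5.0, N=40)

    def test_middle_regime_selection(self):
        table = self.make_table([100.0, 1000.0, 3000.0])  # 0.1, 1, 3 us
        assert regime_mask(table, DEFAULT_REGIMES["middle"]) == {(2, 11)}

    def test_full_interval_is_identity(self):
        table = self.make_table([10.0, 600.0, 5000.0])
        assert regime_mask(table, RegimeSpec("all", 0.0, float("inf"))) == set(table.pairs)

    def test_boundary_value_goes_to_upper_regime(self):
        table = self.make_table([500.0])  # exactly 0.5 us
        assert regime_mask(table, DEFAULT_REGIMES["middle"]) == {(1, 10)}
        assert regime_mask(table, DEFAULT_REGIMES["short"]) == set()

    def test_default_regimes_partition_pairs(self, rng):
        table = self.make_table(list(rng.uniform(1, 4000, size=30)))
        masks = [regime_mask(table, r) for r in DEFAULT_REGIMES.values()]
        assert set().union(*masks) == set(table.pairs)
        for a, b in itertools.combinations(masks, 2):
            assert not (a & b)


class TestFilteredTopology:
    def test_full_mask_is_identity(self, rng):
        maps = tuple(random_contact_map(rng, N=50, m=12) for _ in range(4))
        traj = ContactTrajectory(maps=maps, delta_t=5.0)
        all_pairs = set().union(*(m.contacts for m in maps))
        filtered = filtered_topology_trajectory(traj, all_pairs)
        for f, cmap in zip(filtered, maps):
            assert (f.n_S, f.n_P, f.n_X) == oracle_census(cmap.contacts)

    def test_empty_mask_zeroes_everything(self, rng):
        maps = tuple(random_contact_map(rng, N=50, m=12) for _ in range(3))
        traj = ContactTrajectory(maps=maps, delta_t=5.0)
        for f in filtered_topology_trajectory(traj, set()):
            assert (f.m, f.n_S, f.n_P, f.n_X) == (0, 0, 0, 0)

    def test_random_mask_matches_per_frame_oracle(self, rng):
        maps = tuple(random_contact_map(rng, N=60, m=15) for _ in range(5))
        traj = ContactTrajectory(maps=maps, delta_t=5.0)
        universe = sorted(set().union(*(m.contacts for m in maps)))
        mask = {p for p in universe if rng.random() < 0.5}
        filtered = filtered_topology_trajectory(traj, mask)
        for f, cmap in zip(filtered, maps):
            subset = [c for c in cmap.contacts if c in mask]
            assert (f.n_S, f.n_P, f.n_X) == oracle_census(subset)
            assert f.m <= len(cmap)  # filtering never adds contacts


class TestCFactor:
    def test_single_pair(self):
        table = LifetimeTable(pairs=((2, 9),), runs=((100.0,),), delta_t=5.0, N=10)
        prof = c_factor(table)
        assert prof[2] == prof[9] == 100.0
        assert np.isnan(prof[1])  # no contacts: null, not zero

    def test_mean_over_two_pairs(self):
        table = LifetimeTable(
            pairs=((1, 5), (5, 10)), runs=((100.0,), (200.0,)), delta_t=5.0, N=10
        )
        prof = c_factor(table)
        assert prof[5] == 150.0
        assert prof[1] == 100.0 and prof[10] == 200.0

    def test_matches_brute_force(self, rng):
        pairs = tuple(
            sorted({(int(a), int(b)) for a, b in
                    [sorted(rng.integers(1, 21, 2)) for _ in range(30)] if a != b})
        )
        runs = tuple((float(rng.uniform(5, 500)),) for _ in pairs)
        table = LifetimeTable(pairs=pairs, runs=runs, delta_t=5.0, N=20)
        prof = c_factor(table)
        for res in range(1, 21):
            vals = [max(r) for p, r in zip(pairs, runs) if res in p]
            if vals:
                assert prof[res] == pytest.approx(np.mean(vals))
            else:
                assert np.isnan(prof[res])


class TestCumulativeContactTime:
    def test_all_candidate_pairs_reported(self, rng):
        subset = sorted(rng.choice(np.arange(1, 100), size=11, replace=False))
        rows = {(int(subset[0]), int(subset[5])): [1, 1, 0, 1]}
        kymo = build_kymograph(traj_from_rows(rows, 4, 100))
        out = cumulative_contact_time(kymo, subset)
        assert len(out) == 55
        assert out[(int(subset[0]), int(subset[5]))] == 15.0

    def test_absent_pair_is_zero(self):
        rows = {(1, 6): [1, 1]}
        kymo = build_kymograph(traj_from_rows(rows, 2, 20))
        out = cumulative_contact_time(kymo, {10, 15})
        assert out == {(10, 15): 0.0}
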