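"""Free-energy maps, native basins, NC traces and per-state soliton rates."""

import numpy as np
import pytest

from ilmscan import (
    AngleTrajectory,
    FreeEnergyMap,
    NativeBasinMask,
    StateRateTable,
    free_energy_map,
    free_energy_profile,
    native_basins,
    native_character,
    state_rates,
)
from ilmscan.entropy import ILMEvent
from ilmscan.free_energy import NativeCharacterTrace, _centered_moving_average


def single_site_angles(gamma, theta, frame_spacing=1.0):
    g = np.asarray(gamma, dtype=float)[:, None]
    t = np.asarray(theta, dtype=float)[:, None]
    return AngleTrajectory(gamma=g, theta=t, site_index=np.array([2]),
                           frame_spacing=frame_spacing)


def analytic_map(V, site=2):
    gb, tb = V.shape
    return FreeEnergyMap(
        V=V,
        gamma_edges=np.linspace(-180, 180, gb + 1),
        theta_edges=np.linspace(0, 180, tb + 1),
        site_index=site,
    )


class TestFreeEnergyMap:
    def test_two_bin_occupancy_gives_ln4(self):
        # 80% of frames in one bin, 20% in another: dV = -ln(0.2/0.8) = ln 4
        gamma = np.array([10.0] * 800 + [100.0] * 200)
        theta = np.full(1000, 90.0)
        fmap = free_energy_map(single_site_angles(gamma, theta), 2)
        occ = np.isfinite(fmap.V)
        assert occ.sum() == 2
        vals = np.sort(fmap.V[occ])
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(np.log(4.0), abs=1e-12)

    def test_uniform_samples_give_flat_map(self, rng):
        n = 200_000
        gamma = rng.uniform(-180, 180, n)
        theta = rng.uniform(0, 180, n)
        fmap = free_energy_map(single_site_angles(gamma, theta), 2,
                               gamma_bins=12, theta_bins=6)
        assert np.isfinite(fmap.V).all()
        assert fmap.V.max() < 0.2  # sampling noise only

    def test_empty_bins_are_infinite_and_min_zero(self, rng):
        gamma = rng.normal(60, 5, 2000)
        theta = rng.normal(90, 5, 2000)
        fmap = free_energy_map(single_site_angles(gamma, theta), 2)
        assert np.isinf(fmap.V).any()
        assert fmap.V[np.isfinite(fmap.V)].min() == 0.0

    def test_empty_trajectory_raises(self):
        with pytest.raises(ValueError):
            free_energy_map(single_site_angles([], []), 2)

    def test_few_frames_warn(self):
        with pytest.warns(UserWarning, match="noisy"):
            free_energy_map(single_site_angles([10.0] * 50, [90.0] * 50), 2)

    def test_boltzmann_sampling_recovers_harmonic_well(self, rng):
        """Samples from exp(-V) rebuild V within sampling noise where V < 3 kT."""
        n = 100_000
        sg, st_ = 30.0 / np.sqrt(2), 20.0 / np.sqrt(2)  # V = (g/30)^2 + ((t-90)/20)^2
        gamma = rng.normal(0.0, sg, n)
        theta = rng.normal(90.0, st_, n)
        fmap = free_energy_map(single_site_angles(gamma, theta), 2)
        gc = 0.5 * (fmap.gamma_edges[:-1] + fmap.gamma_edges[1:])
        tc = 0.5 * (fmap.theta_edges[:-1] + fmap.theta_edges[1:])
        V_true = (gc[:, None] / 30.0) ** 2 + ((tc[None, :] - 90.0) / 20.0) ** 2
        sel = (V_true < 3.0) & np.isfinite(fmap.V)
        rms = np.sqrt(np.mean((fmap.V[sel] - V_true[sel]) ** 2))
        assert rms < 0.15

    def test_profiles_match_marginal_construction(self, rng):
        gamma = rng.normal(60, 15, 5000)
        theta = rng.normal(90, 8, 5000)
        V, edges = free_energy_profile(single_site_angles(gamma, theta), 2, "gamma")
        assert V[np.isfinite(V)].min() == 0.0
        # the most occupied gamma bin sits near the mean
        assert abs(edges[np.argmin(np.where(np.isfinite(V), V, np.inf))] - 60) <= 10
        with pytest.raises(ValueError):
            free_energy_profile(single_site_angles(gamma, theta), 2, "phi")


class TestNativeBasins:
    def test_flat_map_puts_all_occupied_bins_in_mask(self):
        V = np.zeros((8, 4))
        mask = native_basins(analytic_map(V), 3.0)
        assert mask.mask.all()

    def test_single_deep_well_neighborhood(self):
        gi, ti = np.meshgrid(np.arange(12), np.arange(6), indexing="ij")
        V = 0.5 * ((gi - 6.0) ** 2 + (ti - 3.0) ** 2)
        mask = native_basins(analytic_map(V), 3.0)
        assert mask.mask[6, 3]
        assert mask.mask.sum() < V.size
        # connected neighborhood of the minimum
        assert mask.mask[5, 3] and mask.mask[7, 3]

    @pytest.mark.parametrize("second_min, expected", [(2.0, True), (4.0, False)])
    def test_double_well_level_set(self, second_min, expected):
        V = np.full((20, 10), 10.0)
        V[3, 5] = 0.0
        V[15, 5] = second_min
        mask = native_basins(analytic_map(V), 3.0)
        assert mask.mask[3, 5]
        assert bool(mask.mask[15, 5]) is expected

    def test_connected_component_mode_excludes_island(self):
        V = np.full((20, 10), 10.0)
        V[3, 5] = 0.0
        V[4, 5] = 1.0
        V[15, 5] = 2.0  # below cutoff but disconnected
        m_all = native_basins(analytic_map(V), 3.0)
        m_conn = native_basins(analytic_map(V), 3.0, connected_only=True)
        assert m_all.mask[15, 5]
        assert not m_conn.mask[15, 5]
        assert m_conn.mask[3, 5] and m_conn.mask[4, 5]

    def test_connected_component_wraps_periodic_gamma(self):
        V = np.full((20, 10), 10.0)
        V[0, 5] = 0.0
        V[19, 5] = 1.0  # touches through the periodic seam
        m = native_basins(analytic_map(V), 3.0, connected_only=True)
        assert m.mask[0, 5] and m.mask[19, 5]


class TestNativeCharacter:
    def _mask_all(self, value: bool):
        m = np.full((72, 36), value)
        return NativeBasinMask(
            mask=m,
            gamma_edges=np.linspace(-180, 180, 73),
            theta_edges=np.linspace(0, 180, 37),
            site_index=2,
        )

    def test_all_sites_inside_gives_100(self, random_angles):
        masks = {int(s): self._mask_all(True) for s in random_angles.site_index}
        for s, m in masks.items():
            m.site_index = s
        nc = native_character(random_angles, masks, smoothing_window=1)
        assert np.allclose(nc.NC, 100.0)
        assert all(nc.state_label == "native")

    def test_no_site_inside_gives_0(self, random_angles):
        masks = {int(s): self._mask_all(False) for s in random_angles.site_index}
        for s, m in masks.items():
            m.site_index = s
        nc = native_character(random_angles, masks, smoothing_window=1)
        assert np.allclose(nc.NC, 0.0)
        assert all(nc.state_label == "non_native")

    def test_half_in_half_out_gives_50(self, rng):
        n_sites = 8  # N - 3 even
        angles = AngleTrajectory(
            gamma=np.full((20, n_sites), 10.0), theta=np.full((20, n_sites), 90.0)
        )
        masks = {}
        for k, s in enumerate(angles.site_index):
            m = self._mask_all(k < n_sites // 2)
            m.site_index = int(s)
            masks[int(s)] = m
        nc = native_character(angles, masks, smoothing_window=1)
        assert np.allclose(nc.NC, 50.0)

    def test_missing_mask_raises(self, random_angles):
        with pytest.raises(ValueError, match="no native-basin mask"):
            native_character(random_angles, {}, smoothing_window=1)

    def test_nc_invariant_under_monotone_V_transform(self, rng):
        """NC depends only on the <= cutoff level set, not on V's scale."""
        gamma = rng.normal(60, 10, 3000)
        theta = rng.normal(90, 6, 3000)
        angles = single_site_angles(gamma, theta)
        fmap = free_energy_map(angles, 2)
        m1 = native_basins(fmap, 3.0)
        # monotone transform preserving the sub-level set: V' = 2V, cutoff' = 6
        fmap2 = FreeEnergyMap(V=2.0 * fmap.V, gamma_edges=fmap.gamma_edges,
                              theta_edges=fmap.theta_edges, site_index=2)
        m2 = native_basins(fmap2, 6.0)
        nc1 = native_character(angles, {2: m1}, smoothing_window=1)
        nc2 = native_character(angles, {2: m2}, smoothing_window=1)
        assert np.array_equal(nc1.NC, nc2.NC)

    def _angles_with_nc_sequence(self, nc_percent):
        """20-site trajectory whose per-frame NC follows ``nc_percent``.

        Each site's basin covers only positive-gamma bins; frames put
        the required number of sites at gamma = +90, the rest at -90.
        """
        n_sites = 20
        gamma = np.full((len(nc_percent), n_sites), -90.0)
        for f, nc in enumerate(nc_percent):
            k = int(round(nc / 100 * n_sites))
            gamma[f, :k] = 90.0
        angles = AngleTrajectory(
            gamma=gamma, theta=np.full_like(gamma, 90.0)
        )
        masks = {}
        for s in angles.site_index:
            m = self._mask_all(False)
            m.mask[36:, :] = True  # gamma > 0 half of the grid
            m.site_index = int(s)
            masks[int(s)] = m
        return angles, masks

    def test_hysteresis_prevents_label_chatter(self):
        # dip into the (threshold - hysteresis, threshold) band: no flip
        angles, masks = self._angles_with_nc_sequence([90, 90, 75, 80, 75, 90, 90])
        nc = native_character(angles, masks, smoothing_window=1,
                              threshold_NC=80.0, hysteresis=5.0)
        assert np.allclose(nc.NC[[0, 2]], [90.0, 75.0])
        assert all(nc.state_label == "native")
        # dip below the band: flips, and returns only at the threshold
        angles, masks = self._angles_with_nc_sequence([90, 70, 75, 80, 90])
        nc = native_character(angles, masks, smoothing_window=1,
                              threshold_NC=80.0, hysteresis=5.0)
        assert list(nc.state_label) == [
            "native", "non_native", "non_native", "native", "native"
        ]

    def test_smoothing_window_average(self):
        x = np.arange(10, dtype=float)
        sm = _centered_moving_average(x, 3)
        assert sm[5] == pytest.approx(np.mean(x[4:7]))
        assert sm.shape == x.shape


class TestStateRates:
    def test_published_row_arithmetic(self):
        """57 ns native with 1 soliton, 443 ns non-native with 222: 0.018 / 0.501 / 27.8."""
        t = StateRateTable(t_n=57.0, t_nn=443.0, N_n=1, N_nn=222)
        printed = t.printed()
        assert printed["P_n"] == pytest.approx(0.018)
        assert printed["P_nn"] == pytest.approx(0.501)
        assert printed["ratio"] == pytest.approx(27.8)

    @pytest.mark.parametrize(
        "t_n, t_nn, N_n, N_nn, P_n, P_nn, ratio",
        [
            (64.0, 436.0, 1, 83, 0.016, 0.190, 11.9),
            (185.0, 315.0, 4, 58, 0.022, 0.184, 8.4),
            (245.0, 255.0, 12, 22, 0.049, 0.086, 1.8),
            (478.0, 22.0, 28, 3, 0.059, 0.136, 2.3),
        ],
    )
    def test_more_published_rows(self, t_n, t_nn, N_n, N_nn, P_n, P_nn, ratio):
        t = StateRateTable(t_n=t_n, t_nn=t_nn, N_n=N_n, N_nn=N_nn)
        printed = t.printed()
        assert printed["P_n"] == pytest.approx(P_n)
        assert printed["P_nn"] == pytest.approx(P_nn)
        assert printed["ratio"] == pytest.approx(ratio)

    def test_native_rate_from_487ns(self):
        t = StateRateTable(t_n=487.0, t_nn=13.0, N_n=9, N_nn=0)
        assert t.printed()["P_n"] == pytest.approx(0.018)

    def test_equal_rates_give_unit_ratio(self):
        t = StateRateTable(t_n=100.0, t_nn=50.0, N_n=10, N_nn=5)
        assert t.ratio == pytest.approx(1.0)

    def test_zero_native_count_flags_infinite(self):
        t = StateRateTable(t_n=100.0, t_nn=100.0, N_n=0, N_nn=7)
        assert t.ratio_is_infinite
        assert np.isinf(t.ratio)

    def test_zero_duration_state_undefined(self):
        t = StateRateTable(t_n=0.0, t_nn=100.0, N_n=0, N_nn=7)
        assert np.isnan(t.P_n)

    def test_assignment_excludes_terminal_events(self):
        label = np.array(["native"] * 50 + ["non_native"] * 50, dtype=object)
        nc = NativeCharacterTrace(
            NC=np.zeros(100), smoothed_NC=np.zeros(100), state_label=label,
            smoothing_window=1, threshold_NC=80.0, hysteresis=5.0,
            frame_spacing=1000.0,  # 1 ns per frame
        )
        mk = lambda f, cls: ILMEvent(frame=f, time=float(f), site=10, S_value=0.3,
                                     amplitude=2.0, profile=np.zeros(17),
                                     event_class=cls)
        events = [mk(10, "soliton"), mk(20, "terminal"), mk(70, "soliton"),
                  mk(80, "soliton")]
        t = state_rates(nc, events)
        assert (t.N_n, t.N_nn) == (1, 2)
        assert t.t_n == pytest.approx(50.0)
        assert t.t_nn == pytest.approx(50.0)
        assert t.t_n + t.t_nn == pytest.approx(100 * 1000.0 * 1e-3)
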