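"""Spiking network: construction, drive, integration, masks, measurements."""

import math

import numpy as np
import pytest
from dataclasses import replace

from placecode import network as nw

TINY = nw.NetworkConfig(grid=20, seed=1)


@pytest.fixture(scope="module")
def tiny_net():
    return nw.build_network(TINY)


@pytest.fixture(scope="module")
def small_net():
    # 40x40: big enough for a Gaussian drive to sit away from the borders
    return nw.build_network(nw.NetworkConfig(grid=40, seed=2))


def drive_all(net, rng, sigma=5.0, peak=400.0, center=None, target="E", **kw):
    c = center or (net.cfg.grid / 2, net.cfg.grid / 2)
    stim = nw.StimulusConfig(center=c, sigma_cells=sigma, peak_inputs=peak,
                             target=target, **kw)
    return nw.generate_drive(stim, net, rng)


class TestBuild:
    def test_exact_population_split(self):
        net = nw.build_network(nw.NetworkConfig(grid=100, seed=0))
        assert net.n_e == 7500 and net.n_i == 2500

    def test_tiny_split(self, tiny_net):
        assert tiny_net.n_e == 300 and tiny_net.n_i == 100

    def test_deterministic_rebuild(self):
        a = nw.build_network(TINY)
        b = nw.build_network(TINY)
        assert np.array_equal(a.conn_targets, b.conn_targets)
        assert np.array_equal(a.conn_indptr, b.conn_indptr)

    def test_seed_changes_edges(self):
        b = nw.build_network(replace(TINY, seed=99))
        a = nw.build_network(TINY)
        assert not np.array_equal(a.conn_targets, b.conn_targets)

    def test_config_validation(self):
        with pytest.raises(nw.ConfigError):
            nw.NetworkConfig(grid=3)
        with pytest.raises(nw.ConfigError):
            nw.NetworkConfig(grid=21)
        with pytest.raises(nw.ConfigError):
            nw.NetworkConfig(e_fraction=0.8, i_fraction=0.2)
        with pytest.raises(nw.ConfigError):
            nw.NetworkConfig(dt_ms=0.5)

    def test_mean_out_degree_matches_probability_sum(self):
        # Monte-Carlo over 100 seeded builds on a small grid
        cfg = nw.NetworkConfig(grid=20, seed=0, conn_sigma_um=15.0)
        ref = nw.build_network(cfg)
        k = int(np.argmin(np.hypot(ref.i_x - 10, ref.i_y - 10)))  # interior I
        degs = [nw.build_network(replace(cfg, seed=s)).out_degree(k)
                for s in range(100)]
        ix, iy = float(ref.i_x[k]), float(ref.i_y[k])
        d2 = ((ref.e_x - ix) ** 2 + (ref.e_y - iy) ** 2) * cfg.pitch_um ** 2
        p = cfg.conn_peak * np.exp(-d2 / (2 * cfg.conn_sigma_um ** 2))
        expected = float(p.sum())
        assert expected == pytest.approx(ref.expected_out_degree(k))
        sd_of_mean = math.sqrt(float((p * (1 - p)).sum()) / len(degs))
        assert abs(np.mean(degs) - expected) <= 3 * sd_of_mean


class TestDrive:
    def test_zero_peak_no_events(self, tiny_net, rng):
        d = drive_all(tiny_net, rng, peak=0.0)
        assert d.cell_idx.size == 0

    def test_center_mean_count(self, tiny_net):
        # mean event count at the center cell ~ peak over many draws
        rng = np.random.default_rng(0)
        peak = 60.0
        stim = nw.StimulusConfig(center=(10.0, 10.0), sigma_cells=4.0,
                                 peak_inputs=peak, target="E")
        center_id = int(np.flatnonzero((tiny_net.e_x == 10) & (tiny_net.e_y == 10))[0])
        counts = []
        for _ in range(1000):
            d = nw.generate_drive(stim, tiny_net, rng)
            counts.append(int((d.cell_idx == center_id).sum()))
        sd_of_mean = 0.25 * peak / math.sqrt(len(counts))
        # rounding the truncated-normal draw adds < 0.5 of bias headroom
        assert abs(np.mean(counts) - peak) <= 3 * sd_of_mean + 0.5

    def test_far_tail_nearly_silent(self, small_net):
        rng = np.random.default_rng(0)
        stim = nw.StimulusConfig(center=(20.0, 20.0), sigma_cells=3.0,
                                 peak_inputs=100.0, target="E")
        far = (np.hypot(small_net.e_x - 20, small_net.e_y - 20) >= 12.0)  # 4 sigma
        tot = 0
        for _ in range(50):
            d = nw.generate_drive(stim, small_net, rng)
            tot += int(np.isin(d.cell_idx, np.flatnonzero(far)).sum())
        assert tot / 50 / far.sum() < 0.05 * 100.0

    def test_times_inside_window(self, tiny_net, rng):
        d = drive_all(tiny_net, rng)
        assert (d.times_ms >= 0).all() and (d.times_ms < d.duration_ms).all()

    def test_poisson_mode_runs(self, tiny_net, rng):
        d = drive_all(tiny_net, rng, event_mode="poisson", rate_hz=40.0)
        assert d.cell_idx.size > 0

    def test_unknown_target(self, tiny_net, rng):
        stim = nw.StimulusConfig(center=(5, 5), sigma_cells=2, peak_inputs=10,
                                 target="E")
        bad = replace(stim, target="X")
        with pytest.raises(nw.ConfigError):
            nw.generate_drive(bad, tiny_net, rng)


class TestSimulateTrial:
    def test_zero_drive_silent(self, tiny_net):
        tr = nw.simulate_trial(tiny_net, [], duration_ms=50.0)
        assert tr.e_spike_counts.sum() == 0
        assert tr.i_spike_counts.sum() == 0
        assert np.all(tr.i_net_min == 0.0)
        assert np.all(tr.i_net_mean == 0.0)

    def test_net_current_invariant_on_traces(self, small_net):
        rng = np.random.default_rng(3)
        drives = [drive_all(small_net, rng), drive_all(small_net, rng, target="I")]
        tr = nw.simulate_trial(small_net, drives, record_traces=True)
        syn = small_net.cfg.syn
        vt = small_net.cfg.adex_e.V_T
        expected = (tr.g_exc_t * (vt - syn.E_exc) + tr.g_inh_t * (vt - syn.E_inh))
        assert np.allclose(tr.i_net_t, expected)

    def test_inhibition_lags_excitation(self, small_net):
        rng = np.random.default_rng(4)
        drives = [drive_all(small_net, rng), drive_all(small_net, rng, target="I")]
        tr = nw.simulate_trial(small_net, drives, record_traces=True, trace_stride=2)
        ge = tr.g_exc_t.sum(axis=1)
        gi = tr.g_inh_t.sum(axis=1)
        t_exc = tr.trace_times[np.argmax(ge > 0.05 * ge.max())]
        t_inh = tr.trace_times[np.argmax(gi > 0.05 * gi.max())]
        assert gi.max() > 0
        assert t_inh > t_exc + 2.0

    def test_determinism(self, small_net):
        def run():
            rng = np.random.default_rng(5)
            tr = nw.simulate_trial(small_net, [drive_all(small_net, rng)])
            return tr
        a, b = run(), run()
        assert np.array_equal(a.e_spike_counts, b.e_spike_counts)
        assert np.array_equal(a.i_net_min, b.i_net_min)

    def test_single_neuron_rheobase_bracketing(self):
        p = replace(nw.RS_PYRAMIDAL, a=0.0, b=0.0)
        rh = nw.estimate_rheobase(p)
        assert nw.fires_with_current(p, 1.05 * rh)
        assert not nw.fires_with_current(p, 0.95 * rh)


class TestRheobase:
    def test_matches_analytic_bound_without_adaptation(self):
        p = replace(nw.RS_PYRAMIDAL, a=0.0, b=0.0)
        est = nw.estimate_rheobase(p)
        ana = nw.analytic_rheobase(p)
        assert abs(est - ana) / ana < 0.01

    def test_doubling_leak_increases_rheobase(self):
        p = replace(nw.RS_PYRAMIDAL, a=0.0, b=0.0)
        p2 = replace(p, g_L=2 * p.g_L)
        assert nw.estimate_rheobase(p2) > nw.estimate_rheobase(p)

    def test_reported_as_magnitude(self):
        assert nw.estimate_rheobase(nw.RS_PYRAMIDAL) > 0


class TestFieldsAndMasks:
    def _trial(self, net, i_net_min=None, i_net_mean=None, spikes=None):
        ne = net.n_e
        z = np.zeros(ne)
        return nw.TrialResult(
            duration_ms=50.0, dt_ms=0.1,
            e_spike_counts=spikes if spikes is not None else np.zeros(ne, int),
            i_spike_counts=np.zeros(net.n_i, int),
            e_spike_times=(np.empty(0, int), np.empty(0)),
            i_spike_times=(np.empty(0, int), np.empty(0)),
            i_net_min=i_net_min if i_net_min is not None else z,
            i_net_mean=i_net_mean if i_net_mean is not None else z,
        )

    def test_zero_conductance_empty_field(self, tiny_net):
        tr = self._trial(tiny_net)
        assert nw.compute_synaptic_field(tr, -270.0).n_cells == 0

    def test_boundary_inclusive(self, tiny_net):
        i_min = np.zeros(tiny_net.n_e)
        i_min[7] = -270.0
        tr = self._trial(tiny_net, i_net_min=i_min)
        mask = nw.compute_synaptic_field(tr, -270.0)
        assert mask.cells[7] and mask.n_cells == 1

    def test_positive_i_rh_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            nw.compute_synaptic_field(self._trial(tiny_net), 270.0)

    def test_purely_inhibitory_drive_adds_nothing(self, small_net):
        rng = np.random.default_rng(6)
        tr = nw.simulate_trial(small_net, [drive_all(small_net, rng, target="I")])
        assert tr.i_spike_counts.sum() > 0          # I cells do fire
        assert np.all(tr.i_net_min >= 0.0)          # (V_T - E_inh) > 0
        assert nw.compute_synaptic_field(tr, -270.0).n_cells == 0
        assert nw.compute_activated_area(tr).n_cells == 0

    def test_activated_area_counts_spikers(self, tiny_net):
        spikes = np.zeros(tiny_net.n_e, int)
        spikes[[1, 5]] = 2
        mask = nw.compute_activated_area(self._trial(tiny_net, spikes=spikes))
        assert mask.n_cells == 2

    def test_combine_masks_threshold(self, tiny_net):
        ne = tiny_net.n_e
        m1 = nw.FieldMask("synaptic_field", np.zeros(ne, bool))
        m2 = nw.FieldMask("synaptic_field", np.zeros(ne, bool))
        m1.cells[3] = True
        m1.cells[4] = True
        m2.cells[4] = True
        out = nw.combine_masks([m1, m2], min_frac=0.5)
        assert out.cells[3] and out.cells[4] and out.n_cells == 2
        out = nw.combine_masks([m1, m2], min_frac=0.75)
        assert out.n_cells == 1


class TestMeasure:
    def _mask_at(self, net, coords):
        cells = np.zeros(net.n_e, bool)
        for x, y in coords:
            idx = np.flatnonzero((net.e_x == x) & (net.e_y == y))
            assert idx.size == 1, f"({x},{y}) is not an E cell"
            cells[idx[0]] = True
        return nw.FieldMask("synaptic_field", cells)

    def test_two_cells_same_row(self, small_net):
        m = self._mask_at(small_net, [(10, 10), (20, 10)])
        out = nw.measure(m, small_net)
        assert out.diameter_cells == pytest.approx(10.0)
        assert out.projection_cells == 2

    def test_three_by_three_block(self, small_net):
        coords = [(x, y) for x in (10, 11, 12) for y in (10, 11, 12)
                  if not (x % 2 == 1 and y % 2 == 1)]
        m = self._mask_at(small_net, coords)
        out = nw.measure(m, small_net)
        assert out.diameter_cells == pytest.approx(2 * math.sqrt(2))
        assert out.projection_cells == 3

    def test_projection_counts_occupied_columns(self, small_net):
        m = self._mask_at(small_net, [(3, 4), (4, 4), (5, 4), (9, 4)])
        assert nw.measure(m, small_net).projection_cells == 4

    def test_empty_mask_flagged(self, small_net):
        m = nw.FieldMask("synaptic_field", np.zeros(small_net.n_e, bool))
        out = nw.measure(m, small_net)
        assert out.empty and out.diameter_cells == 0.0 and out.projection_cells == 0

    def test_single_cell_zero_diameter(self, small_net):
        m = self._mask_at(small_net, [(8, 8)])
        out = nw.measure(m, small_net)
        assert out.diameter_cells == 0.0 and out.projection_cells == 1

    def test_minimal_circle_against_exhaustive_oracle(self, rng):
        # compare Welzl with brute force over all pairs/triples
        from itertools import combinations
        from placecode.network import _min_enclosing_circle

        def brute(points):
            best = None
            pts = [np.asarray(p, float) for p in points]
            for a, b in combinations(pts, 2):
                c, r = (a + b) / 2, np.hypot(*(a - b)) / 2
                if all(np.hypot(*(p - c)) <= r + 1e-9 for p in pts):
                    best = r if best is None else min(best, r)
            for a, b, c3 in combinations(pts, 3):
                ax, ay = a; bx, by = b; cx, cy = c3
                d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                if abs(d) < 1e-12:
                    continue
                ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
                      + (cx**2 + cy**2) * (ay - by)) / d
                uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
                      + (cx**2 + cy**2) * (bx - ax)) / d
                ctr = np.array([ux, uy]); r = np.hypot(*(a - ctr))
                if all(np.hypot(*(p - ctr)) <= r + 1e-9 for p in pts):
                    best = r if best is None else min(best, r)
            return 2 * best

        for _ in range(30):
            n = int(rng.integers(2, 9))
            pts = rng.integers(0, 15, size=(n, 2))
            pts = np.unique(pts, axis=0)
            if pts.shape[0] < 2:
                continue
            assert _min_enclosing_circle(pts) == pytest.approx(brute(pts), abs=1e-6)


class TestRunExperiment:
    def test_unknown_protocol(self):
        with pytest.raises(nw.ConfigError):
            nw.run_experiment("bogus")

    def test_tiny_run_has_expected_columns(self, small_net):
        df = nw.run_experiment("addition_colocated", n_sweeps=2, seed=1,
                               net=small_net, net_cfg=small_net.cfg,
                               sweep=[2, 4], i_rh=-270.0,
                               params={"sigma_beta": 3.0})
        assert list(df["param"]) == [2, 4]
        for col in ("field_diameter_mean", "field_projection_mean",
                    "area_diameter_mean", "area_projection_mean"):
            assert col in df.columns

    def test_deterministic_repeat(self, small_net):
        kw = dict(n_sweeps=2, seed=7, net=small_net, net_cfg=small_net.cfg,
                  sweep=[3], i_rh=-270.0, params={"sigma": 3.0})
        a = nw.run_experiment("addition_separated", **kw)
        b = nw.run_experiment("addition_separated", **kw)
        assert a.equals(b)

    def test_sequential_variant_runs(self, small_net):
        df = nw.run_experiment("two_exc_one_inh", n_sweeps=1, seed=1,
                               net=small_net, net_cfg=small_net.cfg,
                               sweep=[2], i_rh=-270.0, variant="sequential",
                               params={"sigma": 3.0})
        assert len(df) == 1 and df["variant"].iloc[0] == "sequential"


class TestAreaFieldCoupling:
    def test_activated_area_mostly_inside_field(self):
        # definitional coupling via rheobase: firing requires the net input
        # current to have reached rheobase at some instant
        cfg = nw.NetworkConfig(grid=60, seed=3)
        net = nw.build_network(cfg)
        i_rh = -nw.estimate_rheobase(cfg.adex_e)
        rng = np.random.default_rng(8)
        out_frac = []
        for _ in range(3):
            stim = nw.StimulusConfig(center=(30, 30), sigma_cells=6.0,
                                     peak_inputs=400.0, target="E")
            tr = nw.simulate_trial(net, [nw.generate_drive(stim, net, rng)])
            area = nw.compute_activated_area(tr).cells
            field = nw.compute_synaptic_field(tr, i_rh, reduce="min").cells
            if area.sum():
                out_frac.append((area & ~field).sum() / area.sum())
        assert out_frac and max(out_frac) < 0.05
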