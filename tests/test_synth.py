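"""Generator tests: waveform shapes, population draws, layouts, rendering."""

import numpy as np
import pytest

from calsig import defaults as dflt
from calsig import signatures as sig
from calsig import synth
from conftest import STIM, canonical_params


class TestMakeTransient:
    def test_non_responder_is_flat(self, atp_grid):
        p = synth.TransientParams(baseline=0.3, peak_amplitude=0.0,
                                  plateau_level=0.0, noise_sd=0.0,
                                  class_label="1a")
        tr = synth.make_transient(p, atp_grid, 0, STIM)
        assert np.allclose(tr.values, 0.3)

    def test_peak_plateau_roundtrip(self, atp_grid):
        """Noiseless peak-plateau metrics recover the generating values."""
        p = synth.TransientParams(
            baseline=0.1, peak_amplitude=1.0, peak_time_s=68.0, rise_tau_s=8.0,
            decay_tau_s=synth.decay_tau_for_fwhm(
                1.0, synth.decay_floor_for(1.0, 0.79), 235.0),
            plateau_level=0.79, noise_sd=0.0, class_label="2a")
        tr = synth.make_transient(p, atp_grid, 0, STIM)
        m = sig.compute_metrics(tr, STIM)
        assert m.peak_height == pytest.approx(1.0, rel=0.02)
        assert m.plateau_height == pytest.approx(0.79, rel=0.02)

    def test_spike_interval_sets_rate(self, atp_grid):
        p = synth.TransientParams(
            baseline=0.1, peak_amplitude=1.0, peak_time_s=60.0, rise_tau_s=8.0,
            decay_tau_s=synth.decay_tau_for_fwhm(1.0, 0.03, 100.0),
            plateau_level=0.03, spike_interval_s=500.0, spike_amplitude=0.5,
            noise_sd=0.0, class_label="3b")
        m = sig.compute_metrics(synth.make_transient(p, atp_grid, 0, STIM),
                                STIM)
        assert m.spike_rate_per_s == pytest.approx(2.0e-3, rel=0.05)

    @pytest.mark.parametrize("secondary", synth.ALL_CLASSES)
    def test_noiseless_roundtrip_all_classes(self, secondary, atp_grid,
                                             wound_grid):
        """Extracted metrics match the construction's own ground truth."""
        grid = wound_grid if secondary.startswith("W") else atp_grid
        p = canonical_params(secondary)
        tr = synth.make_transient(p, grid, 0, STIM)
        m = sig.compute_metrics(tr, STIM)
        gt = synth.ground_truth_metrics(p, grid, STIM)
        if gt["has_peak"]:
            assert m.peak_height == pytest.approx(gt["peak_height"], rel=0.02)
        if gt["plateau_height"] >= 0.1:
            assert m.plateau_height == pytest.approx(gt["plateau_height"],
                                                     rel=0.1, abs=0.02)
        if gt["spike_rate_per_s"] > 0:
            assert m.spike_rate_per_s == pytest.approx(
                gt["spike_rate_per_s"], rel=0.05)

    def test_determinism(self, atp_grid):
        p = canonical_params("3b", noise_sd=0.05)
        a = synth.make_transient(p, atp_grid, 42, STIM)
        b = synth.make_transient(p, atp_grid, 42, STIM)
        assert np.array_equal(a.values, b.values)

    def test_errors(self, atp_grid):
        with pytest.raises(ValueError):
            synth.make_transient(
                synth.TransientParams(class_label="9z"), atp_grid, 0)
        with pytest.raises(ValueError):
            synth.make_transient(synth.TransientParams(),
                                 np.array([0.0]), 0)
        with pytest.raises(ValueError):
            synth.make_transient(
                synth.TransientParams(class_label="3b", spike_interval_s=0.0),
                atp_grid, 0)


class TestMakePopulation:
    def test_pure_mixture_gives_flat_traces(self, atp_grid):
        pop = synth.make_population({"1a": 1.0}, 10,
                                    synth.atp_shape_priors(0.0), 0, atp_grid)
        assert len(pop) == 10
        for tr, cls, p in pop:
            assert cls == "1a"
            assert tr.values.std() < 0.05

    def test_replicate_counts_within_multinomial_envelope(self, atp_grid):
        counts = dflt.ATP_CLASS_COUNTS[1]
        n = sum(counts.values())
        mix = {k: v / n for k, v in counts.items()}
        pop = synth.make_population(mix, n, synth.atp_shape_priors(0.0),
                                    7, atp_grid)
        drawn = {k: 0 for k in mix}
        for _, cls, _ in pop:
            drawn[cls] += 1
        for k, p in mix.items():
            sd = np.sqrt(n * p * (1 - p))
            assert abs(drawn[k] - n * p) <= 1.96 * sd + 1.0

    def test_primary_three_fraction(self, atp_grid):
        # primary proportions 21/33/47 split uniformly over secondaries
        mix = {}
        for prim, frac in (("1", 0.21), ("2", 0.33), ("3", 0.47)):
            secs = [s for s, pr in dflt.ATP_PRIMARY_OF_SECONDARY.items()
                    if pr == prim]
            for s in secs:
                mix[s] = frac / len(secs)
        tot = sum(mix.values())
        mix = {k: v / tot for k, v in mix.items()}
        grid = atp_grid[::10]    # coarse sampling; only class draws matter
        pop = synth.make_population(mix, 1000, synth.atp_shape_priors(0.0),
                                    11, grid)
        frac3 = np.mean([dflt.ATP_PRIMARY_OF_SECONDARY[c] == "3"
                         for _, c, _ in pop])
        assert frac3 == pytest.approx(0.47, abs=0.05)

    def test_mixture_errors(self, atp_grid):
        priors = synth.atp_shape_priors()
        with pytest.raises(ValueError):
            synth.make_population({}, 5, priors, 0, atp_grid)
        with pytest.raises(ValueError):
            synth.make_population({"1a": -0.5, "2a": 1.5}, 5, priors, 0,
                                  atp_grid)
        with pytest.raises(ValueError):
            synth.make_population({"1a": 0.4, "2a": 0.4}, 5, priors, 0,
                                  atp_grid)


class TestWoundLayout:
    def test_strip_is_excluded(self):
        layout = synth.make_wound_layout(rng_seed=2)
        for c in layout.cells:
            assert c.centroid_px[0] > layout.wound.edge[0, 0]

    def test_proximal_peaks_exceed_distal(self):
        layout = synth.make_wound_layout(rng_seed=2)
        edge_x = layout.wound.edge[0, 0]
        prox, dist = [], []
        for c in layout.cells:
            d_um = (c.centroid_px[0] - edge_x) * layout.pixel_size_um
            (prox if d_um < 100 else dist).append(c.params.peak_amplitude)
        assert np.mean(prox) > np.mean(dist)

    def test_zero_width_strip_raises(self):
        with pytest.raises(ValueError):
            synth.make_wound_layout(wound_strip_width_px=0)


class TestRendering:
    def test_static_cell_renders_constant(self):
        p = synth.TransientParams(baseline=0.5, peak_amplitude=0.0,
                                  plateau_level=0.0, noise_sd=0.0,
                                  class_label="1a")
        layout = synth.CellLayout((64, 64), 0.65,
                                  [synth.Cell((32.0, 32.0), 10.0, p, "1a")])
        im = synth.ImagingParams(read_noise_sd=0.0, shot_noise_frac=0.0,
                                 load_cv=0.0)
        seq, _ = synth.render_sequence(layout, 10.0, 100.0, imaging=im,
                                       rng_seed=0)
        inside = seq.green[:, 28:36, 28:36]
        assert np.allclose(inside, inside[0], atol=1e-4)

    def test_single_cell_trace_correlation(self):
        """Noiseless rendered ratio correlates >= 0.99 with the transient."""
        rng = np.random.default_rng(1)
        p = synth.atp_shape_priors(0.0)["2a"](rng)
        layout = synth.CellLayout((64, 64), 0.65,
                                  [synth.Cell((32.0, 32.0), 12.0, p, "2a")])
        im = synth.ImagingParams(read_noise_sd=0.0, shot_noise_frac=0.0,
                                 load_cv=0.0)
        seq, _ = synth.render_sequence(layout, 2.0, 2220.0, imaging=im,
                                       rng_seed=0, stimulus_time_s=STIM)
        times = np.arange(0.0, 2220.0 + 1e-9, 2.0)
        truth = p.baseline + synth.noiseless_values(p, times, STIM)
        mask = np.zeros((64, 64), bool)
        yy, xx = np.mgrid[0:64, 0:64]
        mask[(yy - 32) ** 2 + (xx - 32) ** 2 <= 8 ** 2] = True
        ratio = (seq.green[:, mask] / (seq.red[:, mask] + 1e-6)).mean(axis=1)
        r = np.corrcoef(ratio, truth)[0, 1]
        assert r >= 0.99

    def test_ratio_monotone_in_calcium(self):
        im = synth.ImagingParams()
        x = np.linspace(0.0, 3.0, 200)
        g, r = synth.dye_intensities(x, im)
        ratio = g / r
        assert np.all(np.diff(ratio) > 0)
        assert np.all(np.diff(g) >= 0) and np.all(np.diff(r) <= 0)

    def test_grid_of_cells_recovered(self):
        from calsig import segment as seg
        rng = np.random.default_rng(3)
        priors = synth.atp_shape_priors(0.0)
        cells = []
        for i in range(5):
            for j in range(5):
                cells.append(synth.Cell((30.0 + 50 * i, 30.0 + 50 * j), 14.0,
                                        priors["2a"](rng), "2a"))
        layout = synth.CellLayout((280, 280), 0.65, cells)
        seq, _ = synth.render_sequence(layout, 300.0, 2220.0, rng_seed=0,
                                       stimulus_time_s=STIM)
        comb = seg.combine_channels(seq.red[[0, -1]], seq.green[[0, -1]])
        rm = seg.extract_rois(seg.preprocess(comb))
        assert len(rm) == 25
        rec, prec, rmse = seg.score_segmentation(rm, layout, 5.0)
        assert rec == 1.0 and prec == 1.0
        assert rmse <= 2.0

    def test_render_determinism(self):
        layout = synth.make_monolayer_layout(n_cells=9, field_size_px=(96, 96),
                                             rng_seed=5)
        a, _ = synth.render_sequence(layout, 60.0, 600.0, rng_seed=8)
        b, _ = synth.render_sequence(layout, 60.0, 600.0, rng_seed=8)
        assert np.array_equal(a.green, b.green)
        assert np.array_equal(a.red, b.red)
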