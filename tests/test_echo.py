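"""Echo classification, NASC integration arithmetic, ESDU bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from echoscape.echo import (
    NASC_FACTOR,
    ASSEMBLAGE_LABELS,
    AlignmentError,
    ClassMask,
    Echogram,
    ThresholdConfig,
    classify_echoes,
    compute_slope,
    echo_integrate,
    esdu_segments,
    nasc_per_ping,
    partition_by_label,
)
from echoscape.scene import TRUTH_FISH, TRUTH_LAYER


def flat_echogram(sv_db, n_ping=40, n_bins=160, bin_m=0.5, bottom=75.0, spacing=2.5, freq=70.0):
    return Echogram(
        sv=np.full((n_ping, n_bins), float(sv_db)),
        depth_bin_m=bin_m,
        ping_x=np.arange(n_ping) * spacing,
        ping_y=np.zeros(n_ping),
        ping_times=np.arange(n_ping, dtype=float),
        bottom_depth=np.full(n_ping, bottom),
        frequency_khz=freq,
    )


def test_label_vocabulary_has_twelve_entries():
    assert len(ASSEMBLAGE_LABELS) == 12
    assert "M. niger" in ASSEMBLAGE_LABELS and "C. sufflamen" in ASSEMBLAGE_LABELS


class TestClassification:
    def test_noise_floor_yields_empty_masks(self):
        e70 = flat_echogram(-95.0)
        e200 = flat_echogram(-95.0, freq=200.0)
        mask = classify_echoes(e70, e200)
        assert not mask.fish_like.any() and not mask.no_fish.any()

    def test_grid_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            classify_echoes(flat_echogram(-60), flat_echogram(-60, n_ping=30, freq=200.0))

    def test_masks_are_disjoint_and_exclude_subbottom(self, echogram_pair):
        e70, e200, _ = echogram_pair
        mask = classify_echoes(e70, e200)
        assert not (mask.fish_like & mask.no_fish).any()
        below = ~e70.water_column()
        assert not mask.fish_like[below].any() and not mask.no_fish[below].any()

    def test_simulated_schools_and_layers_recovered(self, echogram_pair):
        """>=95% of fish-school cells fish-like; >=95% of layer cells no-fish."""
        e70, e200, truth = echogram_pair
        mask = classify_echoes(e70, e200)
        fish_cells = truth == TRUTH_FISH
        layer_cells = truth == TRUTH_LAYER
        assert (mask.fish_like & fish_cells).sum() / fish_cells.sum() >= 0.95
        assert (mask.no_fish & layer_cells).sum() / layer_cells.sum() >= 0.95

    def test_frequency_swap_symmetry(self, echogram_pair):
        e70, e200, _ = echogram_pair
        a = classify_echoes(e70, e200)
        b = classify_echoes(e200, e70)
        assert np.array_equal(a.fish_like, b.fish_like)
        assert np.array_equal(a.no_fish, b.no_fish)


class TestIntegration:
    def test_empty_mask_gives_zero(self):
        e = flat_echogram(-60.0)
        assert nasc_per_ping(e, np.zeros_like(e.sv, dtype=bool)).sum() == 0.0

    def test_uniform_layer_closed_form(self):
        """Sv = -70 dB over 10 m integrates to 4*pi*1852^2*1e-7*10 ~ 43.10."""
        e = flat_echogram(-70.0)
        mask = np.zeros_like(e.sv, dtype=bool)
        mask[:, 40:60] = True  # 20 bins x 0.5 m = 10 m
        sa = nasc_per_ping(e, mask)
        expected = NASC_FACTOR * 1e-7 * 10.0
        assert sa == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(43.10, abs=0.01)

    def test_additivity_over_disjoint_masks(self):
        e = flat_echogram(-65.0)
        rng = np.random.default_rng(0)
        m = rng.random(e.sv.shape) < 0.3
        half = rng.random(e.sv.shape) < 0.5
        m1, m2 = m & half, m & ~half
        assert np.allclose(nasc_per_ping(e, m1) + nasc_per_ping(e, m2), nasc_per_ping(e, m))

    def test_invariant_to_bin_refinement(self):
        """Halving the bin height changes a resolved layer's NASC by < 1%."""
        coarse = flat_echogram(-70.0, n_bins=160, bin_m=0.5)
        fine = flat_echogram(-70.0, n_bins=320, bin_m=0.25)
        mc = np.zeros_like(coarse.sv, dtype=bool)
        mc[:, 40:60] = True
        mf = np.zeros_like(fine.sv, dtype=bool)
        mf[:, 80:120] = True
        assert nasc_per_ping(coarse, mc)[0] == pytest.approx(nasc_per_ping(fine, mf)[0], rel=0.01)

    def test_esdu_mean_independent_of_ping_rate(self):
        """A constant field gives the same per-ESDU s_A at any ping rate."""
        masks = {}
        out = {}
        for spacing in (2.5, 1.25):
            n = int(100 / spacing)
            e = flat_echogram(-65.0, n_ping=n, spacing=spacing)
            m = np.zeros_like(e.sv, dtype=bool)
            m[:, 20:40] = True
            _, tab = echo_integrate(e, m, esdu_length_m=25.0)
            out[spacing] = tab["sa"].to_numpy()
        assert np.allclose(out[2.5], out[1.25][: len(out[2.5])])

    def test_esdu_segmentation_short_tail_merged(self):
        e = flat_echogram(-65.0, n_ping=44, spacing=2.5)  # 107.5 m track
        idx = esdu_segments(e, 25.0)
        # the 7.5-m tail (< half ESDU) joins the previous segment
        assert idx.max() == 3
        assert np.all(np.diff(idx) >= 0)


class TestSlope:
    def test_flat_bottom_zero(self):
        assert compute_slope(50.0, 50.0) == 0.0

    @pytest.mark.parametrize(
        "d0,d1,expected", [(50.0, 52.0, 8.0), (40.0, 40.02, 0.08), (52.0, 50.0, 8.0)]
    )
    def test_hand_computed_values(self, d0, d1, expected):
        assert compute_slope(d0, d1, 25.0) == pytest.approx(expected)

    def test_missing_when_too_few_depths(self):
        assert np.isnan(compute_slope(50.0, 52.0, 25.0, n_valid=1))


class TestPartition:
    def make_school_echogram(self):
        e = flat_echogram(-95.0, n_ping=40, n_bins=160)
        sv = e.sv.copy()
        sv[5:15, 20:40] = -60.0  # school A: t in [5,15), depth 10-20 m
        sv[25:35, 80:100] = -55.0  # school B: t in [25,35), depth 40-50 m
        e.sv = sv
        fish = sv > -70.0
        return e, ClassMask(fish_like=fish, no_fish=np.zeros_like(fish))

    def test_single_covering_polygon_takes_all(self):
        e, mask = self.make_school_echogram()
        poly = Polygon([(-1, -1), (50, -1), (50, 90), (-1, 90)])
        part = partition_by_label(e, mask, [("M. niger", poly)])
        _, tab = echo_integrate(e, mask.fish_like)
        assert np.allclose(part["M. niger"].to_numpy(), tab["sa"].to_numpy())
        assert part["unlabelled"].sum() == 0.0

    def test_no_polygons_all_unlabelled(self):
        e, mask = self.make_school_echogram()
        part = partition_by_label(e, mask, [])
        _, tab = echo_integrate(e, mask.fish_like)
        assert np.allclose(part["unlabelled"].to_numpy(), tab["sa"].to_numpy())

    def test_two_disjoint_schools_split_analytically(self):
        e, mask = self.make_school_echogram()
        pa = Polygon([(4, 9), (16, 9), (16, 21), (4, 21)])
        pb = Polygon([(24, 39), (36, 39), (36, 51), (24, 51)])
        part = partition_by_label(e, mask, [("M. niger", pa), ("loose school", pb)])
        # school A: 10 pings with 20 bins of -60 dB over 10 m
        sa_a = NASC_FACTOR * 10 ** (-6.0) * 10.0
        sa_b = NASC_FACTOR * 10 ** (-5.5) * 10.0
        n_pings = pd.Series(np.ones(40)).groupby(esdu_segments(e, 25.0)).size().to_numpy()
        got_a = (part["M. niger"].to_numpy() * n_pings).sum() / 10  # mean over school pings
        got_b = (part["loose school"].to_numpy() * n_pings).sum() / 10
        assert got_a == pytest.approx(sa_a, rel=1e-9)
        assert got_b == pytest.approx(sa_b, rel=1e-9)
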