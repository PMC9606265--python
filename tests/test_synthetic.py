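"""Generator contracts: geometry, determinism, label calibration."""

import numpy as np
import pytest
from scipy import ndimage

from engram import synthetic as sy
from engram.types import CELL_FOOTPRINT_PX, ParameterError


class TestLayerMask:
    def test_two_blades_and_determinism(self):
        m1 = sy.make_layer_mask(256, 256, 1.0, seed=1)
        m2 = sy.make_layer_mask(256, 256, 1.0, seed=1)
        assert ndimage.label(m1.grid)[1] == 2
        assert m1.grid.sum() > 0
        assert np.array_equal(m1.grid, m2.grid)

    def test_different_seed_differs(self):
        m1 = sy.make_layer_mask(256, 256, 1.0, seed=1)
        m3 = sy.make_layer_mask(256, 256, 1.0, seed=2)
        assert not np.array_equal(m1.grid, m3.grid)

    def test_thin_band_rejected(self):
        with pytest.raises(ParameterError):
            sy.make_layer_mask(256, 256, 1.0, sy.BandParams(thickness_px=8))

    def test_footprint_erosion(self, small_mask):
        adm = sy.admissible_centers(small_mask)
        assert adm.sum() > 0
        rows, cols = np.nonzero(adm)
        h = CELL_FOOTPRINT_PX // 2
        # every admissible pixel's 16x16 footprint lies inside the mask
        for r, c in zip(rows[:50], cols[:50]):
            assert small_mask.grid[r - h : r + h, c - h : c + h].all()


class TestCellmapSampling:
    def test_counts_and_containment(self, small_mask):
        spec = sy.GeneratorSpec(n_cells=500, f_tagged=0.1, f_cfos=0.04, rho=2.0, seed=7)
        cm = sy.sample_cellmap(small_mask, spec)
        assert len(cm) == 500
        assert len(cm.labeled("tagged")) == 50
        assert len(cm.labeled("cfos")) == 20
        pos = cm.positions()
        assert small_mask.contains(pos[:, 0], pos[:, 1]).all()

    def test_seed_reproducibility(self, small_mask):
        spec = sy.GeneratorSpec(n_cells=300, seed=11)
        a = sy.sample_cellmap(small_mask, spec)
        b = sy.sample_cellmap(small_mask, spec)
        assert np.array_equal(a.positions(), b.positions())
        assert a.labeled("cfos") == b.labeled("cfos")

    def test_rho_zero_forbids_doubles(self, small_mask):
        for seed in range(20):
            spec = sy.GeneratorSpec(n_cells=400, f_tagged=0.2, f_cfos=0.2, rho=0.0, seed=seed)
            cm = sy.sample_cellmap(small_mask, spec)
            assert not (cm.labeled("tagged") & cm.labeled("cfos"))

    def test_infeasible_rho_rejected(self):
        with pytest.raises(ParameterError):
            sy.GeneratorSpec(n_cells=100, f_tagged=0.5, f_cfos=0.5, rho=3.0)

    @pytest.mark.parametrize("rho", [0.0, 1.0, 3.0, 12.0])
    def test_overlap_calibration(self, small_mask, rho):
        """Mean observed/expected double count tracks rho within 10%."""
        from engram import overlap as ov

        ratios = []
        for seed in range(200):
            spec = sy.GeneratorSpec(
                n_cells=5000, f_tagged=0.03, f_cfos=0.03, rho=rho, seed=seed
            )
            cm = sy.sample_cellmap(small_mask, spec)
            r = ov.compute_overlap(ov.counts_from_cellmap(cm))
            ratios.append(r.overlap_over_chance)
        mean = np.mean(ratios)
        if rho == 0.0:
            assert mean == 0.0
        else:
            assert abs(mean / rho - 1.0) < 0.1

    def test_planted_clusters_are_compact(self, large_mask):
        model = sy.PlantedClusters(k=6, spread=20.0)
        spec = sy.GeneratorSpec(
            n_cells=600, f_tagged=0.1, f_cfos=0.1, rho=1.0, cluster_model=model, seed=3
        )
        cm = sy.sample_cellmap(large_mask, spec)
        pos = cm.positions("tagged")
        # mean nearest-neighbor distance far below that of a uniform draw
        from scipy.spatial import cKDTree

        d_planted = cKDTree(pos).query(pos, k=2)[0][:, 1].mean()
        uni = sy.sample_positions(large_mask, len(pos), np.random.default_rng(0))
        d_uniform = cKDTree(uni).query(uni, k=2)[0][:, 1].mean()
        assert d_planted < 0.6 * d_uniform


class TestIntensityTable:
    def test_fraction_targets_within_binomial_bounds(self):
        from scipy.stats import binom

        n = 2000
        tab = sy.simulate_intensity_table(n, 0.44, 0.40, 0.16, seed=2)
        counts = tab["true_state"].value_counts()
        for name, p in [("repressed", 0.44), ("permissive", 0.40), ("other", 0.16)]:
            lo, hi = binom.ppf([0.005, 0.995], n, p)
            assert lo <= counts[name] <= hi

    def test_pure_component(self):
        tab = sy.simulate_intensity_table(50, 1.0, 0.0, 0.0, seed=0)
        assert (tab["true_state"] == "repressed").all()

    def test_bad_fractions_rejected(self):
        with pytest.raises(ParameterError):
            sy.simulate_intensity_table(10, 0.5, 0.5, 0.5)

    def test_noiseless_table_is_anticorrelated(self):
        from scipy.stats import spearmanr

        tab = sy.simulate_intensity_table(1000, noise_sd=0.0, seed=4)
        from engram.expression import delta_fosb_signal

        t = delta_fosb_signal(tab)
        assert spearmanr(t["cfos_norm"], t["dfosb"]).statistic < 0


class TestCampariTable:
    def test_reactivated_fraction_within_binomial_bounds(self):
        from scipy.stats import binom

        n = 1000
        tab = sy.simulate_campari(n, frac_reactivated=0.23, seed=9)
        ratio = tab["red"] / (tab["red"] + tab["green"])
        k = int((ratio > 0.3).sum())
        lo, hi = binom.ppf([0.005, 0.995], n, 0.23)
        assert lo <= k <= hi

    def test_no_reactivation_stays_below_threshold(self):
        tab = sy.simulate_campari(500, frac_reactivated=0.0, seed=3)
        ratio = tab["red"] / (tab["red"] + tab["green"])
        assert ratio.max() < 0.3

    def test_determinism(self):
        a = sy.simulate_campari(100, seed=5)
        b = sy.simulate_campari(100, seed=5)
        assert a.equals(b)
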