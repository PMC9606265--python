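"""Expression-state analysis: difference signal, Spearman, KDE, z maps."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from engram import expression as ex
from engram import synthetic as sy
from engram.types import ParameterError


def naive_kde(points, grid_x, grid_y, hx, hy):
    """Double-loop kernel-sum oracle, peak-scaled."""
    out = np.zeros((len(grid_y), len(grid_x)))
    for iy, gy in enumerate(grid_y):
        for ix, gx in enumerate(grid_x):
            s = 0.0
            for px, py in points:
                s += np.exp(-0.5 * ((gx - px) / hx) ** 2 - 0.5 * ((gy - py) / hy) ** 2)
            out[iy, ix] = s
    return out / out.max()


class TestDeltaFosb:
    def test_arithmetic(self):
        t = pd.DataFrame(
            {"cfos": [10.0, 50.0], "pan_fosb": [80.0, 100.0], "fosb_cterm": [30.0, 100.0]}
        )
        out = ex.delta_fosb_signal(t, normalization_percentile=100)
        assert out["dfosb"].iloc[0] == pytest.approx(0.8 - 0.3)
        assert out["dfosb"].iloc[1] == pytest.approx(0.0)  # cterm >= pan clips

    def test_degenerate_channel_rejected(self):
        t = pd.DataFrame({"cfos": [1.0, 2.0], "pan_fosb": [0.0, 0.0], "fosb_cterm": [1.0, 2.0]})
        with pytest.raises(ParameterError):
            ex.delta_fosb_signal(t)

    def test_recovers_planted_component(self):
        tab = sy.simulate_intensity_table(2000, seed=5)
        out = ex.delta_fosb_signal(tab)
        rho = spearmanr(out["dfosb"], tab["true_dfosb"]).statistic
        assert rho > 0.9


class TestRankCorrelation:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert ex.rank_correlation(x, x * 2 + 1, n_permutations=99)[0] == pytest.approx(1.0)
        assert ex.rank_correlation(x, -x, n_permutations=99)[0] == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(ParameterError):
            ex.rank_correlation(np.ones(5), np.arange(5.0))

    def test_exhaustive_permutation_oracle(self):
        """n=5: rho and p match full 5!-enumeration of label permutations."""
        from itertools import permutations
        from scipy.stats import rankdata

        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 4.0])

        def rho_of(yy):
            rx, ry = rankdata(x), rankdata(yy)
            return np.corrcoef(rx, ry)[0, 1]

        obs = rho_of(y)
        all_rhos = [rho_of(np.array(p)) for p in permutations(y)]
        p_exact = np.mean([abs(r) >= abs(obs) - 1e-12 for r in all_rhos])
        rho, p = ex.rank_correlation(x, y, n_permutations=20000, seed=0)
        assert rho == pytest.approx(obs, abs=1e-12)
        assert p == pytest.approx(p_exact, abs=0.02)


class TestPeakScaledKde:
    def test_peak_is_one_and_oracle_equivalence(self, rng):
        pts = rng.uniform(0, 1, size=(50, 2))
        gx = np.linspace(0, 1, 12)
        gy = np.linspace(0, 1, 10)
        ours = ex.peak_scaled_kde(pts, gx, gy, bandwidth=0.1)
        oracle = naive_kde(pts, gx, gy, 0.1, 0.1)
        assert ours.max() == pytest.approx(1.0)
        assert np.allclose(ours, oracle, atol=1e-9)

    def test_swap_symmetry(self, rng):
        half = rng.uniform(0, 1, size=(30, 2))
        pts = np.vstack([half, half[:, ::-1]])  # symmetric under (x, y) swap
        g = np.linspace(0, 1, 15)
        dens = ex.peak_scaled_kde(pts, g, g, bandwidth=0.08)
        assert np.allclose(dens, dens.T, atol=1e-9)

    def test_zero_bandwidth_rejected(self, rng):
        pts = rng.uniform(0, 1, size=(20, 2))
        with pytest.raises(ParameterError):
            ex.peak_scaled_kde(pts, np.linspace(0, 1, 5), np.linspace(0, 1, 5), bandwidth=0.0)


class TestScrambledZMap:
    def test_determinism_and_marginal_preservation(self, rng):
        pts = rng.uniform(0, 1, size=(200, 2))
        g = np.linspace(0, 1, 20)
        z1, m1, s1 = ex.scrambled_zscore_map(pts, g, g, n_scrambles=20, bandwidth=0.1, seed=9)
        z2, _, _ = ex.scrambled_zscore_map(pts, g, g, n_scrambles=20, bandwidth=0.1, seed=9)
        assert np.array_equal(z1, z2)

    def test_independent_pairing_is_calibrated(self, rng):
        """On truly independent channels, few gridpoints exceed |z| = 3."""
        pts = np.column_stack([rng.uniform(0, 1, 400), rng.uniform(0, 1, 400)])
        g = np.linspace(0.1, 0.9, 24)
        z, _, _ = ex.scrambled_zscore_map(pts, g, g, n_scrambles=100, bandwidth="scott", seed=2)
        assert np.mean(np.abs(z) > 3) < 0.05

    def test_plugin_scramble_within_ensemble_range(self, rng):
        pts = np.column_stack([rng.uniform(0, 1, 300), rng.uniform(0, 1, 300)])
        scr = pts.copy()
        scr[:, 1] = scr[rng.permutation(300), 1]
        g = np.linspace(0.1, 0.9, 20)
        z, _, _ = ex.scrambled_zscore_map(scr, g, g, n_scrambles=100, bandwidth="scott", seed=3)
        assert np.mean(np.abs(z) < 3) >= 0.95

    def test_too_few_scrambles(self, rng):
        pts = rng.uniform(0, 1, size=(50, 2))
        g = np.linspace(0, 1, 5)
        with pytest.raises(ParameterError):
            ex.scrambled_zscore_map(pts, g, g, n_scrambles=1)


class TestStateFractions:
    def _table(self, cfos, dfosb):
        return pd.DataFrame({"cfos_norm": cfos, "dfosb": dfosb})

    def test_all_below_cuts_is_other(self):
        t = self._table([0.1, 0.2], [0.1, 0.05])
        f = ex.state_fractions(t, (0.5, 0.5))
        assert f == {"repressed": 0.0, "permissive": 0.0, "other": 1.0}

    def test_partition_sums_to_one(self, rng):
        t = self._table(rng.uniform(0, 1, 100), rng.uniform(0, 1, 100))
        f = ex.state_fractions(t, (0.4, 0.3))
        assert sum(f.values()) == pytest.approx(1.0)

    def test_monotone_rescaling_invariance(self, rng):
        cfos = rng.uniform(0, 1, 200)
        dfosb = rng.uniform(0, 1, 200)
        f1 = ex.state_fractions(self._table(cfos, dfosb), (0.4, 0.3))
        f2 = ex.state_fractions(self._table(cfos * 7.0, dfosb), (0.4 * 7.0, 0.3))
        assert f1 == f2

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            ex.state_fractions(self._table([], []), (0.5, 0.5))


class TestFullAnalysis:
    def test_planted_state_recovery(self):
        tab = sy.simulate_intensity_table(2000, 0.44, 0.40, 0.16, seed=5)
        res = ex.state_analysis(tab, n_scrambles=50, n_permutations=999, seed=5)
        truth = tab["true_state"].value_counts(normalize=True)
        for name in ("repressed", "permissive", "other"):
            assert res.fractions[name] == pytest.approx(truth[name], abs=0.05)
        assert res.spearman_rho < -0.3
        assert res.spearman_p < 0.01

    def test_anticorrelation_strengthens_with_repression(self):
        """More repressed cells -> stronger inverse cFos/ΔFosB correlation."""
        rhos = []
        for frac_rep in (0.10, 0.30, 0.50):
            other = 1.0 - frac_rep - 0.40
            tab = sy.simulate_intensity_table(1500, frac_rep, 0.40, other, seed=8)
            t = ex.delta_fosb_signal(tab)
            rhos.append(spearmanr(t["cfos_norm"], t["dfosb"]).statistic)
        assert rhos[0] > rhos[1] > rhos[2]
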