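"""Community colour-space statistics: distinctness bootstrap and group contrast."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from floralsignals.community_stats import (
    CommunitySizeError,
    focal_distinctness_test,
    uvgreen_group_test,
)
from floralsignals.synthetic_data import gen_loci_community


class TestFocalDistinctness:
    def test_focal_on_top_of_neighbour_is_not_distinct(self):
        # focal duplicates another member while the rest is diffuse
        rng = np.random.default_rng(0)
        xy = rng.uniform(-0.3, 0.3, size=(12, 2))
        xy[-1] = xy[0]
        df = pd.DataFrame(
            {"species": [f"s{i}" for i in range(11)] + ["focal"], "x": xy[:, 0], "y": xy[:, 1]}
        )
        res = focal_distinctness_test(df, "focal", n_boot=500, seed=1)
        assert res.T <= 0
        assert res.p >= 0.5

    def test_shifted_focal_detected(self):
        df = gen_loci_community(n=20, radius=0.1, focal_shift=0.5, seed=11)
        res = focal_distinctness_test(df, "focal", n_boot=1000, seed=5)
        assert res.T > 0.3
        assert res.p <= 0.01

    def test_matches_direct_reimplementation_bitwise(self):
        df = gen_loci_community(n=12, radius=0.15, focal_shift=0.25, seed=3)
        res = focal_distinctness_test(df, "focal", n_boot=400, seed=9, scheme="reassign-resample")
        from conftest import direct_focal_bootstrap

        T, p = direct_focal_bootstrap(
            df[["x", "y"]].to_numpy(), list(df["species"]), "focal", 400, 9
        )
        assert res.T == pytest.approx(T, abs=1e-15)
        assert res.p == p

    def test_reproducible_given_seed_and_sensitive_to_it(self):
        df = gen_loci_community(n=15, radius=0.1, focal_shift=0.12, seed=2)
        a = focal_distinctness_test(df, "focal", n_boot=300, seed=4)
        b = focal_distinctness_test(df, "focal", n_boot=300, seed=4)
        assert (a.T, a.p) == (b.T, b.p)

    def test_invariant_under_rotation_and_translation(self):
        df = gen_loci_community(n=15, radius=0.1, focal_shift=0.2, seed=6)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = df[["x", "y"]].to_numpy() @ R.T + np.array([0.05, -0.3])
        df2 = df.assign(x=xy[:, 0], y=xy[:, 1])
        a = focal_distinctness_test(df, "focal", n_boot=200, seed=8)
        b = focal_distinctness_test(df2, "focal", n_boot=200, seed=8)
        assert a.T == pytest.approx(b.T, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-9)

    def test_guards(self):
        df = gen_loci_community(n=20, seed=0)
        with pytest.raises(KeyError):
            focal_distinctness_test(df, "nope", seed=1)
        with pytest.raises(CommunitySizeError):
            focal_distinctness_test(df.iloc[:3], "focal", seed=1)
        with pytest.raises(ValueError):
            focal_distinctness_test(df, "focal", seed=None)

    def test_resampling_scheme_available(self):
        df = gen_loci_community(n=12, radius=0.1, focal_shift=0.4, seed=1)
        res = focal_distinctness_test(df, "focal", n_boot=200, seed=2, scheme="reassign-resample")
        assert res.scheme == "reassign-resample"
        assert res.p <= 0.05

    def test_null_calibration_small(self):
        """Under the exchangeable null the rejection rate tracks alpha.

        A reduced-size pilot of the full calibration run in the acceptance
        suite (which uses 500 simulated communities).
        """
        rejections = 0
        n_sim = 120
        for i in range(n_sim):
            df = gen_loci_community(n=20, radius=0.1, focal_shift=0.0, seed=1000 + i)
            res = focal_distinctness_test(df, "focal", n_boot=300, seed=2000 + i)
            rejections += res.p <= 0.05
        assert 0.01 <= rejections / n_sim <= 0.11


class TestUVGreenGroupContrast:
    @staticmethod
    def community(n_group=4, n_other=8, spread_group=0.001, seed=0):
        rng = np.random.default_rng(seed)
        g = np.array([0.1, -0.4]) + rng.normal(0, spread_group, (n_group, 2))
        o = rng.uniform(-0.4, 0.4, (n_other, 2))
        xy = np.vstack([g, o])
        df = pd.DataFrame(
            {
                "species": [f"g{i}" for i in range(n_group)] + [f"o{i}" for i in range(n_other)],
                "x": xy[:, 0],
                "y": xy[:, 1],
                "sector": ["UV-green"] * n_group + ["blue-green"] * n_other,
            }
        )
        return df

    def test_tight_group_detected(self):
        res = uvgreen_group_test(self.community())
        assert res.t < -3
        assert res.p < 0.01

    def test_welch_closed_form_hand_case(self):
        """A = {0, 0}, B = {1, 1, 0.8}: t and df from the Welch formulas."""
        a = np.array([0.0, 0.0])
        b = np.array([1.0, 1.0, 0.8])
        sa2, sb2 = a.var(ddof=1), b.var(ddof=1)
        se2 = sa2 / 2 + sb2 / 3
        t_hand = (a.mean() - b.mean()) / np.sqrt(se2)
        df_hand = se2**2 / ((sa2 / 2) ** 2 / 1 + (sb2 / 3) ** 2 / 2)
        res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
        assert res.statistic == pytest.approx(t_hand)
        assert res.df == pytest.approx(df_hand)
        # and the package applies exactly this Welch form to the distances
        df4 = self.community(n_group=2, n_other=3, spread_group=0.1, seed=2)
        out = uvgreen_group_test(df4)
        assert out.n_a == 1 and out.n_b == 3
        assert np.isnan(out.t)  # single within-group distance: Welch is undefined

    def test_calibration_under_shared_distribution(self):
        """Both groups drawn from one distribution: rejection near alpha."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            xy = rng.uniform(-0.3, 0.3, (14, 2))
            sectors = ["UV-green"] * 5 + ["blue"] * 9
            df = pd.DataFrame(
                {
                    "species": [f"s{i}" for i in range(14)],
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "sector": sectors,
                }
            )
            res = uvgreen_group_test(df)
            rejections += res.p <= 0.05
        # pairwise distances are dependent, so the t-test is only roughly
        # calibrated; the rate must sit near alpha, not far above it
        assert rejections / n_sim <= 0.15

    def test_size_guard(self):
        df = self.community(n_group=1, n_other=5)
        with pytest.raises(CommunitySizeError):
            uvgreen_group_test(df)


def test_power_increases_with_displacement():
    """Detection power is monotone in the focal displacement (within MC error)."""
    shifts = [0.0, 0.1, 0.2, 0.4]
    powers = []
    for shift in shifts:
        rej = 0
        for i in range(60):
            df = gen_loci_community(n=15, radius=0.1, focal_shift=shift, seed=300 + i)
            res = focal_distinctness_test(df, "focal", n_boot=200, seed=700 + i)
            rej += res.p <= 0.05
        powers.append(rej / 60)
    assert powers[-1] > 0.9
    for lo, hi in zip(powers, powers[1:]):
        assert hi >= lo - 0.10
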