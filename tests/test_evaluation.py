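"""ICC and Wilcoxon against independent oracles; report assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spinetrack import (
    ICCResult,
    OverlapScore,
    build_report,
    icc_two_way_mixed,
    trajectory_icc,
    wilcoxon_signed_rank,
)


def _icc3_anova_oracle(x, y):
    """Independent ICC(3,1) from explicit ANOVA sums of squares."""
    data = np.stack([x, y], axis=1)
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_err = np.sum((data - grand) ** 2) - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


def _wilcoxon_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating all sign assignments (n <= 12)."""
    from scipy.stats import rankdata

    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestICC:
    def test_identity_series(self, rng):
        x = rng.normal(size=10)
        assert icc_two_way_mixed(x, x) == pytest.approx(1.0)

    def test_constant_offset_is_one(self, rng):
        x = rng.normal(size=12)
        assert icc_two_way_mixed(x, x + 3.7) == pytest.approx(1.0)

    def test_opposite_motion_negative(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        assert icc_two_way_mixed(x, -x) < 0

    def test_bounded_above_by_one(self, rng):
        for _ in range(200):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            assert icc_two_way_mixed(x, y) <= 1.0 + 1e-12

    def test_matches_anova_oracle(self, rng):
        """500 random 10-frame instances against the from-scratch oracle."""
        for _ in range(500):
            x = rng.normal(size=10)
            y = 0.5 * x + rng.normal(size=10)
            assert icc_two_way_mixed(x, y) == pytest.approx(
                _icc3_anova_oracle(x, y), abs=1e-10
            )

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(size=12)
            y = x + 0.3 * r.normal(size=12)
            df = pd.DataFrame(
                {
                    "target": np.tile(np.arange(12), 2),
                    "rater": np.repeat(["gt", "model"], 12),
                    "score": np.concatenate([x, y]),
                }
            )
            icc = pg.intraclass_corr(df, "target", "rater", "score").set_index("Type")
            assert icc_two_way_mixed(x, y) == pytest.approx(
                icc.loc["ICC(C,1)", "ICC"], abs=1e-9
            )

    def test_zero_variance_sentinel(self):
        with pytest.warns(UserWarning):
            assert np.isnan(icc_two_way_mixed(np.ones(5), np.ones(5)))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            icc_two_way_mixed([1.0, 2.0], [1.0, 2.0])


class TestTrajectoryICC:
    def test_single_recording(self, rng):
        x = rng.normal(size=10)
        res = trajectory_icc({"r1": x + 1.0}, {"r1": x}, level="C3")
        assert res.n == 1
        assert res.icc == pytest.approx(1.0)
        assert res.icc_min == res.icc_max == res.icc

    def test_perfect_model(self, rng):
        gt = {f"r{i}": rng.normal(size=8) for i in range(4)}
        res = trajectory_icc(dict(gt), gt)
        assert res.icc == pytest.approx(1.0)
        assert res.n == 4

    def test_exclusions_respected(self, rng):
        x = rng.normal(size=10)
        res = trajectory_icc(
            {"good": x, "bad": -x}, {"good": x, "bad": x}, excluded={"bad"}
        )
        assert res.n == 1
        assert res.icc == pytest.approx(1.0)

    def test_no_recordings(self):
        res = trajectory_icc({}, {})
        assert res.n == 0 and np.isnan(res.icc)

    def test_small_angle_noise_keeps_icc_high(self, rng):
        """Per-frame angle noise of SD 0.2 deg on realistic dtheta series."""
        from spinetrack import KinematicsConfig, simulate_kinematics

        iccs = []
        for seed in range(10):
            poses = simulate_kinematics(KinematicsConfig(seed=seed, n_frames=40))
            theta = poses.angles_deg[:, 2]  # C2
            noisy = theta + rng.normal(0.0, 0.2, size=theta.shape)
            iccs.append(icc_two_way_mixed(np.diff(theta), np.diff(noisy)))
        assert np.mean(iccs) >= 0.9


class TestWilcoxon:
    def test_equal_samples_p_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_constant_offset_exact(self):
        a = np.arange(10, dtype=float)
        assert wilcoxon_signed_rank(a + 0.5, a) == pytest.approx(2 / 1024)

    def test_matches_enumeration_oracle(self, rng):
        for n in (5, 8, 12):
            for _ in range(40):
                a = rng.normal(size=n)
                b = a + rng.normal(scale=0.8, size=n)
                b[rng.integers(n)] = a[rng.integers(n)]  # occasional ties/zeros
                assert wilcoxon_signed_rank(a, b) == pytest.approx(
                    _wilcoxon_enumeration_oracle(a, b), abs=1e-12
                )

    def test_matches_scipy_exact_when_no_ties(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        for _ in range(30):
            a = rng.normal(size=14)
            b = rng.normal(size=14)
            ours = wilcoxon_signed_rank(a, b)
            theirs = scipy_wilcoxon(a, b, method="exact").pvalue
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_large_n_normal_approximation(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        a = rng.normal(size=60)
        b = a + rng.normal(scale=0.5, size=60) + 0.2
        ours = wilcoxon_signed_rank(a, b)
        theirs = scipy_wilcoxon(a, b, method="approx", correction=False).pvalue
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestBuildReport:
    def _scores(self, models, shift_by_model=None, n=12, seed=0):
        r = np.random.default_rng(seed)
        base = r.uniform(0.5, 0.7, size=n)
        out = []
        for m in models:
            shift = (shift_by_model or {}).get(m, 0.0)
            for i in range(n):
                v = min(base[i] + shift, 0.99)
                out.append(
                    OverlapScore(
                        iou=v, dsc=2 * v / (1 + v), vertebra="C3", frame=i,
                        recording_id="r0", model_id=m,
                    )
                )
        return out

    def test_single_model_no_comparisons(self):
        report = build_report(self._scores(["A"]))
        assert report.comparisons == []
        assert len(report.overlap) == 1
        assert report.overlap.loc[0, "iou_best"] == "A"

    def test_identical_scores_not_significant(self):
        report = build_report(self._scores(["A", "B"]))
        assert not report.overlap.loc[0, "iou_significant"]

    def test_dominant_model_flagged(self):
        report = build_report(
            self._scores(["A", "B", "C", "D"], shift_by_model={"A": 0.15})
        )
        row = report.overlap.iloc[0]
        assert row["iou_best"] == "A"
        assert row["iou_significant"]
        assert all(
            c.significant for c in report.comparisons if c.model_a == "A"
        )

    def test_markdown_renders(self):
        report = build_report(
            self._scores(["A", "B"]),
            [ICCResult(level="C1", model_id="A", icc=0.9, n=3)],
            [ICCResult(level="C1-C2", model_id="A", icc=0.6, n=2)],
        )
        text = report.to_markdown()
        assert "C1-C2" in text and "Overlap" in text
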