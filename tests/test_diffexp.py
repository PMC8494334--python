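import numpy as np
import pandas as pd
import pytest

from telocus.diffexp import call_de, de_test, de_timecourse, normalize, trajectory
from telocus.synth import Sample


def _nb(rng, mean, disp, size):
    lam = rng.gamma(1.0 / disp, mean * disp, size=size)
    return rng.poisson(lam)


class TestNormalize:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.integers(1, 200, size=50)
        df = pd.DataFrame({f"s{i}": col for i in range(4)})
        sf, norm = normalize(df)
        assert np.allclose(sf, 1.0)
        assert np.allclose(norm, df)

    def test_doubled_column_gets_factor_two(self, rng):
        col = rng.integers(1, 200, size=100)
        df = pd.DataFrame({"a": col, "b": col * 2, "c": col})
        sf, norm = normalize(df)
        # the doubled sample is scaled down by exactly 2 relative to the rest
        assert sf["b"] / sf["a"] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(norm["b"], norm["a"])

    def test_matches_literal_formula_oracle(self, rng):
        mat = rng.integers(0, 500, size=(200, 6)).astype(float)
        mat[: 50] += 1  # guarantee some all-nonzero rows
        df = pd.DataFrame(mat, columns=[f"s{i}" for i in range(6)])
        sf, _ = normalize(df)
        # literal median-of-ratios
        keep = (mat > 0).all(axis=1)
        gm = np.exp(np.log(mat[keep]).mean(axis=1))
        expected = np.median(mat[keep] / gm[:, None], axis=0)
        assert np.allclose(sf.to_numpy(), expected, atol=1e-12)

    def test_error_without_everywhere_nonzero_feature(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            normalize(df)


class TestDeTest:
    def test_identical_groups_null_result(self, rng):
        col = rng.integers(10, 300, size=100).astype(float)
        df = pd.DataFrame({"a1": col, "a2": col, "b1": col, "b2": col})
        res = de_test(df, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(res["log2fc"], 0.0, atol=1e-12)
        assert (res["pvalue"] > 0.9).all()

    def test_label_swap_negates_log2fc_and_keeps_p(self, rng):
        df = pd.DataFrame(
            _nb(rng, 100, 0.05, size=(300, 4)),
            columns=["a1", "a2", "b1", "b2"],
        ).astype(float)
        fwd = de_test(df, ["a1", "a2"], ["b1", "b2"])
        rev = de_test(df, ["b1", "b2"], ["a1", "a2"])
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-12)

    def test_all_zero_feature_is_null(self):
        df = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 12], "b1": [0, 9], "b2": [0, 11]},
            dtype=float,
        )
        res = de_test(df, ["a1", "a2"], ["b1", "b2"])
        assert res["pvalue"].iloc[0] == 1.0
        assert res["log2fc"].iloc[0] == 0.0

    def test_bh_matches_literal_implementation(self, rng):
        df = pd.DataFrame(
            _nb(rng, 80, 0.08, size=(500, 4)),
            columns=["a1", "a2", "b1", "b2"],
        ).astype(float)
        res = de_test(df, ["a1", "a2"], ["b1", "b2"])
        p = res["pvalue"].to_numpy()
        # literal BH step-up
        n = len(p)
        order = np.argsort(p)
        ranked = p[order] * n / (np.arange(n) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expected = np.minimum(np.empty_like(ranked), 1.0)
        expected = np.minimum(ranked, 1.0)
        bh = np.empty(n)
        bh[order] = expected
        assert np.allclose(res["padj"].to_numpy(), bh, atol=1e-12)
        srt = res.sort_values("pvalue")
        assert (np.diff(srt["padj"].to_numpy()) >= -1e-12).all()

    def test_requires_two_per_group(self, rng):
        df = pd.DataFrame({"a1": [1.0], "b1": [2.0], "b2": [3.0]})
        with pytest.raises(ValueError):
            de_test(df, ["a1"], ["b1", "b2"])


class TestCalls:
    @pytest.mark.parametrize(
        "log2fc, padj, expected",
        [
            (3.0, 0.01, "up"),
            (1.5, 0.001, "ns"),
            (-2.0, 0.05, "ns"),  # boundary: padj not < alpha
            (-2.0, 0.049, "down"),
            (2.0, 0.049, "up"),  # boundary: |lfc| >= cut is inclusive
            (-3.0, 0.2, "ns"),
            (float("nan"), float("nan"), "ns"),
        ],
    )
    def test_call_cutoffs(self, log2fc, padj, expected):
        assert call_de(log2fc, padj) == expected

    def test_strict_flag_excludes_boundary(self):
        assert call_de(2.0, 0.01, strict_lfc=True) == "ns"
        assert call_de(2.01, 0.01, strict_lfc=True) == "up"

    @pytest.mark.parametrize(
        "calls, expected",
        [
            (("up", "up", "up", "up"), "constant"),
            (("up", "up", "up", "ns"), "constant"),
            (("up", "ns", "down", "ns"), "switch"),
            (("ns", "ns", "up", "ns"), "transient"),
            (("ns", "ns", "ns", "ns"), "none"),
            (("up", "up", "ns", "ns"), "complex"),
            (("down", "down", "down", "down"), "constant"),
        ],
    )
    def test_trajectory_patterns(self, calls, expected):
        assert trajectory(list(calls)) == expected

    def test_trajectory_needs_four_calls(self):
        with pytest.raises(ValueError):
            trajectory(["up", "ns"])


class TestTimecourse:
    def test_planted_effect_detected_at_right_timepoint(self, rng):
        samples = [
            Sample(cond, tp, rep)
            for tp in (4, 8, 12, 17)
            for cond in ("MUT", "WT")
            for rep in (1, 2)
        ]
        n = 300
        base = np.exp(rng.uniform(np.log(30), np.log(200), n))
        cols = {}
        for s in samples:
            mean = base.copy()
            if s.condition == "MUT" and s.timepoint == 12:
                mean = mean.copy()
                mean[:10] *= 8  # planted log2FC = 3 at week 12
            cols[s.name] = _nb(rng, mean, 0.03, n)
        counts = pd.DataFrame(cols, index=[f"f{i}" for i in range(n)]).astype(float)
        res = de_timecourse(counts, samples)
        planted = res[(res["feature_id"].isin([f"f{i}" for i in range(10)]))]
        w12 = planted[planted["timepoint"] == 12]
        assert (w12["call"] == "up").mean() >= 0.8
        other = planted[planted["timepoint"] != 12]
        assert (other["call"] == "ns").mean() >= 0.9
        assert set(res.loc[res["feature_id"] == "f0", "trajectory"]) <= {"transient", "complex"}
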