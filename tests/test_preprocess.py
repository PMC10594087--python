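import numpy as np
import pytest
from scipy.stats import kstest, spearmanr

from ordnet import preprocess, simulate
from ordnet.datatypes import ItemPanel, ValidationError


def _write(path, text):
    path.write_text(text)
    return path


class TestLoadPanel:
    def test_listwise_deletion_drops_incomplete_rows(self, tmp_path):
        path = _write(
            tmp_path / "panel.csv",
            "subject_id,a,b\ns1,1,2\ns2,,3\ns3,0,6\n",
        )
        panel = preprocess.load_panel(path, "baseline")
        assert panel.n_subjects == 2
        assert list(panel.subject_ids) == ["s1", "s3"]

    def test_na_marker_is_missing(self, tmp_path):
        path = _write(tmp_path / "panel.csv", "subject_id,a,b\ns1,NA,2\ns2,1,3\n")
        panel = preprocess.load_panel(path, "baseline")
        assert panel.n_subjects == 1

    def test_out_of_range_score_raises_with_location(self, tmp_path):
        path = _write(tmp_path / "panel.csv", "subject_id,a,b\ns1,1,2\ns2,8,3\n")
        with pytest.raises(ValidationError, match="column 'a'"):
            preprocess.load_panel(path, "baseline")

    def test_negative_score_raises(self, tmp_path):
        path = _write(tmp_path / "panel.csv", "subject_id,a\ns1,-1\n")
        with pytest.raises(ValidationError):
            preprocess.load_panel(path, "baseline")

    def test_duplicate_subject_id_raises(self, tmp_path):
        path = _write(tmp_path / "panel.csv", "subject_id,a\ns1,1\ns1,2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            preprocess.load_panel(path, "baseline")

    def test_well_formed_612_by_13_file(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = ["subject_id," + ",".join(f"item{j}" for j in range(1, 14))]
        for i in range(612):
            rows.append(f"s{i}," + ",".join(map(str, rng.integers(0, 7, 13))))
        path = _write(tmp_path / "panel.csv", "\n".join(rows) + "\n")
        panel = preprocess.load_panel(path, "baseline")
        assert panel.n_subjects == 612
        assert panel.n_items == 13

    def test_tsv_delimiter_inferred_from_extension(self, tmp_path):
        path = _write(tmp_path / "panel.tsv", "subject_id\ta\tb\ns1\t1\t2\n")
        panel = preprocess.load_panel(path, "baseline")
        assert panel.n_items == 2

    def test_time_column_used_when_label_not_given(self, tmp_path):
        path = _write(
            tmp_path / "panel.csv", "subject_id,time,a\ns1,followup,1\ns2,followup,2\n"
        )
        panel = preprocess.load_panel(path)
        assert panel.time_label == "followup"


class TestExcludeItems:
    def _panel(self, p=13):
        rng = np.random.default_rng(1)
        labels = [f"item{j}" for j in range(1, p + 1)]
        return ItemPanel(
            [f"s{i}" for i in range(30)], "baseline", rng.integers(0, 7, (30, p)), labels
        )

    def test_dropping_item4_keeps_12_items_in_order(self):
        panel = preprocess.exclude_items(self._panel(), ["item4"])
        assert panel.n_items == 12
        assert "item4" not in panel.item_labels
        assert panel.item_labels[:4] == ["item1", "item2", "item3", "item5"]

    def test_empty_drop_is_identity(self):
        panel = self._panel()
        out = preprocess.exclude_items(panel, [])
        assert out.item_labels == panel.item_labels
        np.testing.assert_array_equal(out.scores, panel.scores)

    def test_unknown_item_raises(self):
        with pytest.raises(ValidationError, match="nonexistent"):
            preprocess.exclude_items(self._panel(), ["nonexistent"])


class TestNonparanormal:
    def test_strictly_increasing_column_stays_monotone(self):
        # use continuous input through the generic rank path; the
        # delta_n Winsorization collapses the most extreme ranks by
        # design, so monotonicity is strict only in the interior
        values = np.linspace(0, 1, 100).reshape(-1, 1)
        out = preprocess.nonparanormal_transform(values, ["x"])
        diffs = np.diff(out.values[:, 0])
        assert (diffs >= 0).all()
        assert (diffs[5:-5] > 0).all()

    def test_ties_map_to_identical_values(self):
        col = np.array([0, 1, 1, 2, 3, 3, 3, 4, 5, 6])
        panel = np.column_stack([col, np.arange(10)])
        out = preprocess.nonparanormal_transform(panel, ["a", "b"])
        tied = out.values[:, 0]
        assert tied[1] == tied[2]
        assert tied[4] == tied[5] == tied[6]

    def test_transform_is_rank_preserving(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 7, 500)
        out = preprocess.nonparanormal_transform(
            np.column_stack([col, rng.integers(0, 7, 500)]), ["a", "b"]
        )
        rho = spearmanr(col, out.values[:, 0]).statistic
        assert rho == pytest.approx(1.0)

    def test_transformed_marginal_is_close_to_standard_normal(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(size=(1000, 1))
        out = preprocess.nonparanormal_transform(values, ["x"])
        stat = kstest(out.values[:, 0], "norm").statistic
        assert stat <= 0.05

    def test_column_moments_near_standard(self):
        rng = np.random.default_rng(5)
        panel = rng.integers(0, 7, (500, 4))
        out = preprocess.nonparanormal_transform(panel, list("abcd"))
        assert np.abs(out.values.mean(axis=0)).max() < 0.1
        assert np.abs(out.values.std(axis=0, ddof=0) - 1).max() < 0.15

    def test_constant_column_raises_naming_item(self):
        panel = np.column_stack([np.ones(50, dtype=int), np.arange(50) % 7])
        with pytest.raises(ValidationError, match="'c1'"):
            preprocess.nonparanormal_transform(panel, ["c1", "c2"])

    def test_small_n_raises(self):
        with pytest.raises(ValidationError, match="n >= 10"):
            preprocess.nonparanormal_transform(np.arange(8).reshape(-1, 1), ["x"])


class TestCorrelation:
    def test_identical_columns_give_unit_correlation(self):
        col = np.random.default_rng(0).standard_normal(100)
        corr = preprocess.correlation(np.column_stack([col, col]), ["a", "b"])
        assert corr.values[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        corr = preprocess.correlation(rng.standard_normal((20000, 4)), list("abcd"))
        off = corr.values[np.triu_indices(4, k=1)]
        assert np.abs(off).max() < 0.05

    def test_exact_symmetry(self):
        rng = np.random.default_rng(2)
        corr = preprocess.correlation(rng.standard_normal((50, 6)))
        np.testing.assert_array_equal(corr.values, corr.values.T)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValidationError, match="3 complete rows"):
            preprocess.correlation(np.ones((2, 3)), list("abc"))

    def test_n_le_p_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            preprocess.correlation(rng.standard_normal((5, 6)))

    def test_invariance_to_shift_and_positive_scaling(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((200, 3))
        base = preprocess.correlation(x, list("abc")).values
        shifted = x.copy()
        shifted[:, 0] = 3.0 * shifted[:, 0] + 7.0
        again = preprocess.correlation(shifted, list("abc")).values
        np.testing.assert_allclose(base, again, atol=1e-12)


def test_pair_panels_aligns_common_subjects():
    rng = np.random.default_rng(6)
    b = ItemPanel([f"s{i}" for i in range(5)], "baseline", rng.integers(0, 7, (5, 3)), list("abc"))
    f = ItemPanel(
        [f"s{i}" for i in (4, 2, 0, 9)], "followup", rng.integers(0, 7, (4, 3)), list("abc")
    )
    pair = preprocess.pair_panels(b, f)
    assert list(pair.baseline.subject_ids) == ["s0", "s2", "s4"]
    assert list(pair.followup.subject_ids) == ["s0", "s2", "s4"]


def test_pipeline_determinism_from_file(tmp_path):
    pair, _ = simulate.make_paired_panel(simulate.default_config(n_subjects=80, seed=2))
    path = simulate.write_panel(pair.baseline, tmp_path / "p.csv")
    mats = []
    for _ in range(2):
        panel = preprocess.load_panel(path, "baseline")
        corr = preprocess.correlation(preprocess.nonparanormal_transform(panel))
        mats.append(corr.values.tobytes())
    assert mats[0] == mats[1]


def test_bivariate_normal_cdf_against_independence_and_symmetry():
    from scipy.special import ndtr

    assert preprocess.bivariate_normal_cdf(0.3, -0.7, 0.0) == pytest.approx(
        ndtr(0.3) * ndtr(-0.7), abs=1e-12
    )
    # comonotone limit
    assert preprocess.bivariate_normal_cdf(0.5, 1.5, 1.0) == pytest.approx(
        ndtr(0.5), abs=1e-12
    )
    # numerical check against quadrature for a nontrivial rho
    from scipy.integrate import quad

    h, k, rho = 0.4, -0.2, 0.6

    def integrand(r):
        det = 1 - r * r
        return np.exp(-(h * h - 2 * r * h * k + k * k) / (2 * det)) / (
            2 * np.pi * np.sqrt(det)
        )

    expected = ndtr(h) * ndtr(k) + quad(integrand, 0, rho)[0]
    assert preprocess.bivariate_normal_cdf(h, k, rho) == pytest.approx(expected, abs=1e-9)
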