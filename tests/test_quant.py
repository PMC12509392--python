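"""Impurity correction, interference filtering, rollup and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tmtquant as tq
from tmtquant import (
    DataError,
    ImpurityMatrix,
    ProteinQuantMatrix,
    correct_impurities,
    filter_interference,
    filter_missing_by_group,
    log2_transform,
    median_normalize,
    rollup_to_protein,
)
from tmtquant.containers import REPORTER_COLUMNS

N = 16


def random_impurity(rng: np.random.Generator) -> ImpurityMatrix:
    """Random diagonally dominant column-near-stochastic mixing matrix."""
    mat = np.zeros((N, N))
    for j in range(N):
        spill = rng.uniform(0.0, 0.06, size=2)
        mat[j, j] = 1.0 - spill.sum()
        if j > 0:
            mat[j - 1, j] = spill[0]
        if j < N - 1:
            mat[j + 1, j] = spill[1]
    return ImpurityMatrix(mat)


class TestImpurityMatrix:
    def test_identity_leaves_reporters_unchanged(self, psm_frame_factory):
        psms = psm_frame_factory([{c: 10.0 * (i + 1) for i, c in enumerate(REPORTER_COLUMNS)}])
        out = correct_impurities(psms, ImpurityMatrix.identity())
        np.testing.assert_allclose(
            out[list(REPORTER_COLUMNS)].to_numpy()[0],
            [10.0 * (i + 1) for i in range(N)],
        )

    def test_vendor_table_conversion_mass_offsets(self):
        # +1 Da moves signal two positions in the interleaved channel list
        table = pd.DataFrame(
            {"-2": 0.0, "-1": 0.0, "+1": 4.0, "+2": 0.0},
            index=list(tq.TMTPRO_CHANNELS),
        )
        m = ImpurityMatrix.from_vendor_table(table).values
        assert m[2, 0] == pytest.approx(0.04)  # 126 -> 127C
        assert m[0, 0] == pytest.approx(0.96)
        assert m[:, 15].sum() == pytest.approx(0.96)  # 134N +1 falls outside

    def test_rejects_wrong_shape_and_singular(self):
        with pytest.raises(DataError):
            ImpurityMatrix(np.eye(4))
        with pytest.raises(DataError):
            ImpurityMatrix(np.ones((N, N)) / N)  # rank 1 but column sums ok

    def test_two_channel_round_trip_known_values(self):
        # reduced 2-channel system embedded in the identity matrix
        mixing = np.eye(N)
        mixing[:2, :2] = [[0.95, 0.03], [0.05, 0.97]]
        true = np.full(N, 50.0)
        true[:2] = [100.0, 200.0]
        observed = mixing @ true
        assert observed[0] == pytest.approx(101.0)
        assert observed[1] == pytest.approx(199.0)
        psms = pd.DataFrame(
            [{"sequence": "AAAAAK", "protein": "P1", "interference": 0.0,
              **dict(zip(REPORTER_COLUMNS, observed))}]
        )
        out = correct_impurities(psms, ImpurityMatrix(mixing))
        np.testing.assert_allclose(
            out[list(REPORTER_COLUMNS)].to_numpy()[0], true, rtol=1e-12
        )

    def test_negative_solution_clipped_to_zero(self):
        # 2x2 system [[0.9,0.2],[0.1,0.8]] with observed [1,0]:
        # exact solution x = (8/7, -1/7); the negative component clips to 0
        mixing = np.eye(N)
        mixing[:2, :2] = [[0.9, 0.2], [0.1, 0.8]]
        observed = np.full(N, 10.0)
        observed[:2] = [1.0, 0.0]
        psms = pd.DataFrame(
            [{"sequence": "AAAAAK", "protein": "P1", "interference": 0.0,
              **dict(zip(REPORTER_COLUMNS, observed))}]
        )
        out = correct_impurities(psms, ImpurityMatrix(mixing))
        got = out[list(REPORTER_COLUMNS)].to_numpy()[0]
        assert got[0] == pytest.approx(8.0 / 7.0, rel=1e-9)
        assert got[1] == 0.0

    def test_incomplete_psms_pass_through_by_default(self, psm_frame_factory):
        psms = psm_frame_factory([{"reporter_126": np.nan}])
        out = correct_impurities(psms, ImpurityMatrix.default())
        row = out[list(REPORTER_COLUMNS)].to_numpy()[0]
        assert np.isnan(row[0]) and row[1] == 100.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        impurity = random_impurity(rng)
        true = rng.lognormal(10, 1.5, size=N)
        observed = impurity.values @ true
        psms = pd.DataFrame(
            [{"sequence": "AAAAAK", "protein": "P1", "interference": 0.0,
              **dict(zip(REPORTER_COLUMNS, observed))}]
        )
        out = correct_impurities(psms, impurity)
        np.testing.assert_allclose(
            out[list(REPORTER_COLUMNS)].to_numpy()[0], true, rtol=1e-9
        )


class TestInterferenceFilter:
    def test_boundary_kept_strictly_greater_removed(self, psm_frame_factory):
        psms = psm_frame_factory(
            [{"interference": v} for v in (0.10, 0.50, 0.51)]
        )
        kept, report = filter_interference(psms)
        assert list(kept["interference"]) == [0.10, 0.50]
        assert report.n_removed == 1

    def test_empty_and_all_clean(self, psm_frame_factory):
        empty = psm_frame_factory([]).iloc[:0]
        kept, report = filter_interference(empty)
        assert kept.empty and report.n_removed == 0
        clean = psm_frame_factory([{"interference": 0.0}] * 3)
        kept, report = filter_interference(clean)
        assert len(kept) == 3 and report.n_removed == 0

    def test_idempotent(self, psm_frame_factory):
        psms = psm_frame_factory(
            [{"interference": v} for v in (0.2, 0.6, 0.4, 0.9)]
        )
        once, _ = filter_interference(psms)
        twice, report = filter_interference(once)
        pd.testing.assert_frame_equal(once, twice)
        assert report.n_removed == 0


class TestRollup:
    def test_additivity_two_psms(self, psm_frame_factory, design):
        psms = psm_frame_factory(
            [{"sequence": "AAAAAK"}, {"sequence": "CCCCCK"}]
        )
        matrix, _ = rollup_to_protein(psms, design)
        assert (matrix.data.to_numpy() == 200.0).all()

    def test_splitting_a_psm_leaves_matrix_unchanged(self, psm_frame_factory, design):
        whole = psm_frame_factory([{"sequence": "AAAAAK"}])
        halves = psm_frame_factory(
            [
                {"sequence": "AAAAAK", **{c: 60.0 for c in REPORTER_COLUMNS}},
                {"sequence": "AAAAAK", **{c: 40.0 for c in REPORTER_COLUMNS}},
            ]
        )
        m1, _ = rollup_to_protein(whole, design)
        m2, _ = rollup_to_protein(halves, design)
        pd.testing.assert_frame_equal(m1.data, m2.data)

    def test_all_absent_channel_is_masked(self, psm_frame_factory, design):
        psms = psm_frame_factory([{"reporter_127C": np.nan}])
        matrix, _ = rollup_to_protein(psms, design)
        sample_3 = design.loc[design["channel"] == "127C", "sample_id"].iloc[0]
        assert matrix.mask.loc["P1", sample_3]

    def test_shared_peptides_excluded_with_warning(self, psm_frame_factory, design):
        psms = psm_frame_factory(
            [
                {"sequence": "AAAAAK", "protein": "P1"},
                {"sequence": "AAAAAK", "protein": "P2"},
                {"sequence": "CCCCCK", "protein": "P1"},
            ]
        )
        with pytest.warns(UserWarning, match="shared"):
            matrix, report = rollup_to_protein(psms, design)
        assert matrix.proteins == ["P1"]
        assert report.n_removed == 2

    def test_order_invariance(self, design, small_study):
        _, _, _, psms = small_study
        shuffled = psms.sample(frac=1.0, random_state=3)
        m1, _ = rollup_to_protein(psms, design)
        m2, _ = rollup_to_protein(shuffled, design)
        pd.testing.assert_frame_equal(m1.data, m2.data)


class TestMissingnessFilter:
    @staticmethod
    def _matrix(missing_young: int, missing_old: int, design) -> ProteinQuantMatrix:
        data = pd.DataFrame(
            [np.ones(16)], index=["P1"], columns=list(design["sample_id"])
        )
        young = design.loc[design["group"] == "young", "sample_id"].tolist()
        old = design.loc[design["group"] == "old", "sample_id"].tolist()
        data.loc["P1", young[:missing_young]] = np.nan
        data.loc["P1", old[:missing_old]] = np.nan
        return ProteinQuantMatrix(data, scale="raw")

    def test_half_missing_group_removed(self, design):
        matrix = self._matrix(4, 0, design)
        kept, report = filter_missing_by_group(matrix, design)
        assert kept.data.empty and report.removed == ["P1"]

    def test_fully_observed_retained(self, design):
        kept, _ = filter_missing_by_group(self._matrix(0, 0, design), design)
        assert kept.proteins == ["P1"]

    def test_three_of_eight_each_group_retained(self, design):
        kept, _ = filter_missing_by_group(self._matrix(3, 3, design), design)
        assert kept.proteins == ["P1"]

    def test_exclusive_boundary_switch(self, design):
        kept, _ = filter_missing_by_group(
            self._matrix(4, 0, design), design, inclusive=False
        )
        assert kept.proteins == ["P1"]

    def test_idempotent(self, design):
        m = self._matrix(4, 2, design)
        once, _ = filter_missing_by_group(m, design)
        twice, report = filter_missing_by_group(once, design)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert report.n_removed == 0


class TestTransforms:
    def test_log2_values_and_mask(self, design):
        data = pd.DataFrame(
            [[8.0, 1.0] + [4.0] * 14], index=["P1"], columns=list(design["sample_id"])
        )
        data.iloc[0, 5] = np.nan
        out = log2_transform(ProteinQuantMatrix(data, scale="raw"))
        assert out.scale == "log2"
        assert out.data.iloc[0, 0] == pytest.approx(3.0)
        assert out.data.iloc[0, 1] == pytest.approx(0.0)
        assert np.isnan(out.data.iloc[0, 5])

    def test_log2_coerces_zero_to_missing_and_rejects_negative(self, design):
        cols = list(design["sample_id"])
        data = pd.DataFrame([[0.0] + [2.0] * 15], index=["P1"], columns=cols)
        out = log2_transform(ProteinQuantMatrix(data, scale="raw"))
        assert np.isnan(out.data.iloc[0, 0])
        bad = pd.DataFrame([[2.0] * 16], index=["P1"], columns=cols)
        m = ProteinQuantMatrix(bad, scale="raw")
        m.data.iloc[0, 2] = -1.0
        with pytest.raises(DataError, match="negative"):
            log2_transform(m)

    def test_median_normalize_column_property(self, design):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(
            rng.normal(20, 3, size=(25, 16)),
            index=[f"P{i}" for i in range(25)],
            columns=list(design["sample_id"]),
        )
        data.iloc[0, 0] = np.nan
        out = median_normalize(ProteinQuantMatrix(data, scale="log2"))
        meds = out.data.median(axis=0, skipna=True)
        np.testing.assert_allclose(meds.to_numpy(), 0.0, atol=1e-12)

    def test_median_normalize_constant_column_becomes_zero(self, design):
        data = pd.DataFrame(
            np.tile([[1.0], [2.0], [3.0]], (1, 16)),
            index=["P1", "P2", "P3"],
            columns=list(design["sample_id"]),
        )
        out = median_normalize(ProteinQuantMatrix(data, scale="log2"))
        np.testing.assert_allclose(out.data["Y1"].to_numpy(), [-1.0, 0.0, 1.0])
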