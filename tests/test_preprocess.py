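"""Filtering, normalization and imputation rules."""

import numpy as np
import pandas as pd
import pytest

from mmomics.containers import FeatureMatrix, ProteinTable
from mmomics.preprocess import (PreprocessConfig, filter_by_presence,
                                filter_proteins, impute_minimum,
                                impute_proteomics, log2_transform,
                                pqn_normalize, quantile_normalize,
                                preprocess_targeted_lipidomics)
from mmomics.synthetic import (CohortDesign, NoiseModel,
                               expanded_lipid_catalog,
                               generate_lipidomics_cohort,
                               generate_proteomics_cohort)


def _fm(values, groups, scale="raw"):
    return FeatureMatrix(values=pd.DataFrame(values), groups=groups, scale=scale)


GROUPS_43 = {**{f"a{i}": "A" for i in range(4)}, **{f"b{i}": "B" for i in range(3)}}


def _presence_matrix(pattern):
    """pattern: dict feature -> list of 7 floats/None for a 4+3 cohort."""
    df = pd.DataFrame(pattern, dtype=float).T
    df.columns = list(GROUPS_43)
    return FeatureMatrix(values=df, groups=GROUPS_43, scale="raw")


class TestPresenceFilter:
    def test_boundary_is_inclusive_within_one_group(self):
        # 3/4 in A is exactly 0.75 -> retained even though absent from B
        m = _presence_matrix({"f": [1, 1, 1, None, None, None, None]})
        out = filter_by_presence(m)
        assert list(out.values.index) == ["f"]

    def test_below_threshold_in_both_groups_drops(self):
        m = _presence_matrix({"f": [1, 1, None, None, 1, 1, None]})  # 0.5, 0.667
        out = filter_by_presence(m)
        assert list(out.values.index) == []

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(10, 1, (10, 7))
        vals[rng.random((10, 7)) < 0.4] = np.nan
        df = pd.DataFrame(vals, index=[f"f{i}" for i in range(10)],
                          columns=list(GROUPS_43))
        m = FeatureMatrix(values=df, groups=GROUPS_43, scale="raw")
        expected = []
        for f in df.index:                       # independent rule re-statement
            in_a = df.loc[f, [s for s in df if GROUPS_43[s] == "A"]].notna().mean()
            in_b = df.loc[f, [s for s in df if GROUPS_43[s] == "B"]].notna().mean()
            if in_a >= 0.75 or in_b >= 0.75:
                expected.append(f)
        assert list(filter_by_presence(m).values.index) == expected

    def test_idempotent(self, lipid_cohort):
        m, _ = lipid_cohort
        once = filter_by_presence(m)
        twice = filter_by_presence(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_order_preserved(self):
        m = _presence_matrix({"z": [1] * 7, "a": [1] * 7, "m": [1] * 7})
        assert list(filter_by_presence(m).values.index) == ["z", "a", "m"]


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        m = _fm({"s1": [1.0, 3.0], "s2": [5.0, 7.0]}, {"s1": "A", "s2": "B"})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values["s1"], [3.0, 5.0])
        np.testing.assert_allclose(out.values["s2"], [3.0, 5.0])

    def test_identical_columns_fixed_point(self):
        m = _fm({"s1": [2.0, 9.0, 4.0], "s2": [2.0, 9.0, 4.0]},
                {"s1": "A", "s2": "B"})
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_complete_columns_share_sorted_values(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.lognormal(3, 1, (40, 6)),
                          columns=[f"s{i}" for i in range(6)])
        m = FeatureMatrix(values=df, groups={f"s{i}": "A" if i < 3 else "B"
                                             for i in range(6)}, scale="raw")
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_all_missing_column_errors(self):
        m = _fm({"s1": [1.0, 2.0], "s2": [np.nan, np.nan]},
                {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="no observed"):
            quantile_normalize(m)


class TestPQN:
    def test_doubled_sample_restored_to_reference(self):
        base = np.array([2.0, 4.0, 8.0, 16.0, 5.0])
        df = pd.DataFrame({"s1": base, "s2": base, "s3": base, "s4": 2 * base})
        m = FeatureMatrix(values=df, groups={s: "A" if s != "s4" else "B"
                                             for s in df}, scale="raw")
        out = pqn_normalize(m)
        np.testing.assert_allclose(out.values["s4"], base)

    def test_identical_samples_unchanged(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({f"s{i}": base for i in range(4)})
        m = FeatureMatrix(values=df, groups={f"s{i}": "A" if i < 2 else "B"
                                             for i in range(4)}, scale="raw")
        pd.testing.assert_frame_equal(pqn_normalize(m).values, m.values)

    def test_recovers_planted_dilution_factors(self):
        # untargeted-scale matrix: the quotient median identifies the
        # dilution to ~feature_sd/sqrt(n_features) on the log scale
        design = CohortDesign.from_counts({"RRMM": 10, "NDMM": 10})
        noise = NoiseModel(sample_dilution_sd=0.4, feature_sd=0.25,
                           mnar_threshold_quantile=0.0, mar_rate=0.0, seed=4)
        m, truth = generate_lipidomics_cohort(
            design, [], noise, lipid_catalog=expanded_lipid_catalog(2000))
        out = pqn_normalize(m)
        factors = next(p["pqn_factors"] for p in out.provenance
                       if isinstance(p, dict) and "pqn_factors" in p)
        planted = truth["dilution_factors"]
        # factors are identified up to a common scale: compare ratios
        est = np.array([factors[s] for s in planted.index])
        rel = est / planted.to_numpy()
        rel /= np.median(rel)
        assert np.abs(rel - 1).max() < 0.02

    def test_too_few_shared_features_errors(self):
        df = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [np.nan, np.nan, 3.0]})
        m = FeatureMatrix(values=df, groups={"s1": "A", "s2": "B"}, scale="raw")
        with pytest.raises(ValueError, match="shares only"):
            pqn_normalize(m)


class TestLog2AndMinImpute:
    def test_log2_values_and_missing_preserved(self):
        m = _fm({"s1": [8.0, 1.0], "s2": [np.nan, 4.0]}, {"s1": "A", "s2": "B"})
        out = log2_transform(m)
        assert out.scale == "log2"
        assert out.values.loc[0, "s1"] == 3.0
        assert out.values.loc[1, "s1"] == 0.0
        assert np.isnan(out.values.loc[0, "s2"])

    def test_log2_rejects_nonpositive(self):
        m = _fm({"s1": [8.0, 0.0], "s2": [1.0, 4.0]}, {"s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="non-positive"):
            log2_transform(m)

    def test_minimum_imputation_fills_global_min(self):
        m = _fm({"s1": [5.0, np.nan], "s2": [np.nan, 7.0]},
                {"s1": "A", "s2": "B"})
        out = impute_minimum(m)
        assert out.values.loc[1, "s1"] == 5.0
        assert out.values.loc[0, "s2"] == 5.0
        n_imputed = m.values.isna().sum().sum()
        assert (out.values != m.values.fillna(5.0)).sum().sum() == 0
        assert n_imputed == 2

    def test_no_missing_is_identity(self):
        m = _fm({"s1": [5.0, 1.0], "s2": [2.0, 7.0]}, {"s1": "A", "s2": "B"})
        pd.testing.assert_frame_equal(impute_minimum(m).values, m.values)


class TestProteinFilters:
    def _table(self, rows):
        ids = [f"p{i}" for i in range(len(rows))]
        proteins = pd.DataFrame(
            {"unique_peptides": [r[0] for r in rows], "score": [r[1] for r in rows]},
            index=ids)
        intens = pd.DataFrame(np.full((len(rows), 4), 10.0), index=ids,
                              columns=["a0", "a1", "b0", "b1"])
        groups = {"a0": "A", "a1": "A", "b0": "B", "b1": "B"}
        return ProteinTable(proteins=proteins, intensities=intens, groups=groups)

    def test_score_boundary_strict_peptide_inclusive(self):
        t = self._table([(2, 5.0), (2, 5.1), (1, 100.0), (2, 4.9)])
        out = filter_proteins(t)
        assert out.protein_ids == ["p1"]

    def test_hand_counted_survivors(self, design_20):
        table, truth = generate_proteomics_cohort(
            design_20, [], NoiseModel(mnar_threshold_quantile=0.0, mar_rate=0.0,
                                      seed=9), n_proteins=100)
        expected = int(((table.proteins["unique_peptides"] >= 2)
                        & (table.proteins["score"] > 5)).sum())
        out = filter_proteins(table)
        # no missing values, so the presence filter removes nothing further
        assert len(out.protein_ids) == expected
        assert (truth["features"].loc[out.protein_ids, "passes_id_filter"]).all()


class TestImputeProteomics:
    @pytest.fixture
    def log2_table(self, design_20):
        noise = NoiseModel(mnar_threshold_quantile=0.02, mar_rate=0.05, seed=6)
        table, truth = generate_proteomics_cohort(design_20, [], noise,
                                                  n_proteins=150)
        log_int = np.log2(table.intensities)
        return table.with_intensities(log_int, scale="log2"), truth

    def test_complete_proteins_untouched_and_counts_conserved(self, log2_table):
        table, _ = log2_table
        out = impute_proteomics(table)
        before, after = table.intensities, out.intensities
        assert not after.isna().any().any()
        observed = before.notna()
        pd.testing.assert_frame_equal(after[observed].dropna(how="all"),
                                      before[observed].dropna(how="all"))

    def test_partition_recorded_and_matches_rule(self, log2_table):
        table, _ = log2_table
        out = impute_proteomics(table, PreprocessConfig(seed=0))
        frac = table.intensities.isna().mean(axis=1)
        part = out.meta["imputation_partition"]
        assert set(part["mar"]) == set(frac.index[(frac > 0) & (frac < 0.25)])
        assert set(part["mnar"]) == set(frac.index[frac >= 0.25])

    def test_lls_beats_minimum_imputation_on_masked_entries(self, design_20):
        # correlated proteins so LLS has signal to exploit
        rng = np.random.default_rng(11)
        n, s = 60, 40
        latent = rng.normal(0, 1, s)
        data = 20 + 2 * np.outer(rng.normal(1, 0.2, n), latent) \
            + rng.normal(0, 0.3, (n, s))
        cols = [f"x{i}" for i in range(s)]
        groups = {c: "A" if i < 20 else "B" for i, c in enumerate(cols)}
        mask = rng.random((n, s)) < 0.10
        mask[:20] = False                       # keep a complete-protein pool
        masked = data.copy()
        masked[mask] = np.nan
        ids = [f"p{i}" for i in range(n)]
        proteins = pd.DataFrame({"unique_peptides": 3, "score": 10.0}, index=ids)
        table = ProteinTable(
            proteins=proteins,
            intensities=pd.DataFrame(masked, index=ids, columns=cols),
            groups=groups, scale="log2")
        out = impute_proteomics(table, PreprocessConfig(seed=1))
        lls_rmse = np.sqrt(np.nanmean(
            (out.intensities.to_numpy()[mask] - data[mask]) ** 2))
        min_rmse = np.sqrt(np.nanmean((np.nanmin(masked) - data[mask]) ** 2))
        assert lls_rmse < min_rmse

    def test_mnar_draws_centred_at_matrix_minimum(self):
        rng = np.random.default_rng(2)
        n, s = 40, 30
        data = rng.normal(20, 2, (n, s))
        data[:10, 15:] = np.nan                  # 50% missing -> MNAR branch
        ids = [f"p{i}" for i in range(n)]
        cols = [f"x{i}" for i in range(s)]
        table = ProteinTable(
            proteins=pd.DataFrame({"unique_peptides": 3, "score": 10.0}, index=ids),
            intensities=pd.DataFrame(data, index=ids, columns=cols),
            groups={c: "A" if i < 15 else "B" for i, c in enumerate(cols)},
            scale="log2")
        cfg = PreprocessConfig(seed=3, mnar_sd_factor=0.3)
        out = impute_proteomics(table, cfg)
        drawn = out.intensities.to_numpy()[:10, 15:]
        global_min = np.nanmin(data)
        sd = cfg.mnar_sd_factor * np.nanstd(data)
        se = sd / np.sqrt(drawn.size)
        assert abs(drawn.mean() - global_min) < 3 * se

    def test_fallback_warns_when_too_few_complete(self):
        # one missing value in 8 samples (12.5% < 25%) -> MAR branch, but
        # only one complete protein is available for the regression pool
        data = np.full((12, 8), 10.0)
        data[1:, 0] = np.nan
        ids = [f"p{i}" for i in range(12)]
        cols = [f"s{i}" for i in range(8)]
        table = ProteinTable(
            proteins=pd.DataFrame({"unique_peptides": 3, "score": 10.0}, index=ids),
            intensities=pd.DataFrame(data, index=ids, columns=cols),
            groups={c: "A" if i < 4 else "B" for i, c in enumerate(cols)},
            scale="log2")
        with pytest.warns(UserWarning, match="row-mean"):
            impute_proteomics(table, PreprocessConfig(lls_neighbors=10, seed=0))


def test_targeted_chain_is_deterministic(design_20):
    noise = NoiseModel(seed=8)
    m, _ = generate_lipidomics_cohort(design_20, [], noise)
    a = preprocess_targeted_lipidomics(m).values
    b = preprocess_targeted_lipidomics(m).values
    pd.testing.assert_frame_equal(a, b)
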