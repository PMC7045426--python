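"""The four handling strategies and Rubin's-rules pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scaleimpute import (
    AmputedDataset,
    MissingnessPlan,
    ampute,
    complete_case,
    impute_hotdeck,
    impute_mi,
    impute_mode,
    rubins_pool,
)

MCAR = MissingnessPlan(mechanism="MCAR", target_rate=0.1, seed=0)


def _with_mask(dataset, mask):
    return AmputedDataset(base=dataset, mask=np.asarray(mask, dtype=bool), plan=MCAR)


class TestCompleteCase:
    def test_all_observed_is_identity(self, tiny_dataset):
        amp = _with_mask(tiny_dataset, np.zeros((10, 3)))
        out = complete_case(amp).single()
        pd.testing.assert_frame_equal(out.items, tiny_dataset.items)

    def test_hand_enumeration(self, tiny_amputed):
        # rows 0, 3, 7 each have a missing cell -> 7 retained, order kept
        out = complete_case(tiny_amputed).single()
        assert list(out.ids) == [2, 3, 5, 6, 7, 9, 10]
        assert len(out.covariates) == 7

    def test_everyone_incomplete_raises(self, tiny_dataset):
        mask = np.zeros((10, 3), dtype=bool)
        mask[:, 0] = True
        with pytest.raises(ValueError, match="no complete respondents"):
            complete_case(_with_mask(tiny_dataset, mask))


class TestModeImputation:
    def test_most_frequent_value_wins(self, tiny_dataset):
        # column item_01 observed values after masking row 0: [2,3,4,1,2,3,4,1,2]
        mask = np.zeros((10, 3), dtype=bool)
        mask[0, 0] = True
        out = impute_mode(_with_mask(tiny_dataset, mask)).single()
        assert out.items.loc[0, "item_01"] == 2  # brute-force mode of the rest

    def test_tie_broken_to_smallest(self, tiny_scale, tiny_covariate_specs):
        from scaleimpute import SurveyDataset

        items = pd.DataFrame(
            {"item_01": [1, 1, 2, 2, 3], "item_02": [1] * 5, "item_03": [1] * 5}
        )
        covs = pd.DataFrame(
            {
                "gender": pd.Categorical(["male"] * 5, categories=["female", "male"]),
                "age": np.full(5, 16.0),
            }
        )
        ds = SurveyDataset(
            ids=np.arange(5), items=items, covariates=covs, scale=tiny_scale
        )
        mask = np.zeros((5, 3), dtype=bool)
        mask[4, 0] = True  # observed column becomes [1,1,2,2]: tie -> 1
        out = impute_mode(_with_mask(ds, mask)).single()
        assert out.items.loc[4, "item_01"] == 1

    def test_no_missing_is_identity_and_deterministic(self, tiny_dataset):
        amp = _with_mask(tiny_dataset, np.zeros((10, 3)))
        a = impute_mode(amp).single()
        b = impute_mode(amp).single()
        pd.testing.assert_frame_equal(a.items, tiny_dataset.items)
        pd.testing.assert_frame_equal(a.items, b.items)

    def test_fully_missing_column_raises(self, tiny_dataset):
        mask = np.zeros((10, 3), dtype=bool)
        mask[:, 1] = True
        with pytest.raises(ValueError, match="fully missing"):
            impute_mode(_with_mask(tiny_dataset, mask))


class TestHotDeck:
    def test_donor_pool_enumeration_and_frequencies(self, tiny_dataset):
        """One missing male cell whose male donor pool on that item is {2, 3}:
        every draw must come from the pool, with roughly equal frequency."""
        mask = np.zeros((10, 3), dtype=bool)
        mask[0, 0] = True  # male row; male observed item_01 pool = {2, 3, 4} rows 1..4
        # shrink the pool to {2, 3} by masking rows 3 (value 4) as well
        mask[3, 0] = True
        mask[4, 0] = True  # row 4 value 1 also masked -> pool rows 1,2 = {2, 3}
        amp = _with_mask(tiny_dataset, mask)
        draws = []
        for seed in range(2000):
            out = impute_hotdeck(amp, ["gender"], seed=seed).single()
            v = out.items.loc[0, "item_01"]
            assert v in (2, 3)
            draws.append(v)
        frac2 = np.mean(np.asarray(draws) == 2)
        assert abs(frac2 - 0.5) < 0.04

    def test_no_missing_is_identity(self, tiny_dataset):
        amp = _with_mask(tiny_dataset, np.zeros((10, 3)))
        out = impute_hotdeck(amp, ["gender"], seed=1).single()
        pd.testing.assert_frame_equal(out.items, tiny_dataset.items)

    def test_empty_donor_class_falls_back_to_full_pool(self, tiny_dataset, caplog):
        # all male item_01 values missing -> male class has no donor for item_01
        mask = np.zeros((10, 3), dtype=bool)
        mask[:5, 0] = True
        amp = _with_mask(tiny_dataset, mask)
        import logging

        with caplog.at_level(logging.INFO, logger="scaleimpute.imputation"):
            out = impute_hotdeck(amp, ["gender"], seed=3).single()
        female_pool = {2, 3, 4, 1, 2}
        assert set(out.items.loc[:4, "item_01"]) <= {1, 2, 3, 4}
        assert any("fallback" in rec.message for rec in caplog.records)
        # donor-origin: imputed values must be observed female values {1, 2, 3, 4}
        assert set(out.items.loc[:4, "item_01"]) <= female_pool

    def test_observed_cells_preserved(self, rses_preset):
        ds = rses_preset.generate(n=300, seed=6)
        amp = ampute(
            ds,
            MissingnessPlan(mechanism="MCAR", target_rate=0.2, seed=2),
            rses_preset.covariates,
        )
        out = impute_hotdeck(amp, list(rses_preset.donor_class_vars), seed=5).single()
        assert np.array_equal(
            out.items.to_numpy()[~amp.mask], ds.items.to_numpy()[~amp.mask]
        )

    def test_reproducible_from_seed(self, rses_preset):
        ds = rses_preset.generate(n=200, seed=6)
        amp = ampute(
            ds,
            MissingnessPlan(mechanism="MCAR", target_rate=0.2, seed=2),
            rses_preset.covariates,
        )
        a = impute_hotdeck(amp, ["gender"], seed=5).single()
        b = impute_hotdeck(amp, ["gender"], seed=5).single()
        pd.testing.assert_frame_equal(a.items, b.items)


@pytest.fixture(scope="module")
def mi_case(rses_preset):
    ds = rses_preset.generate(n=400, seed=6)
    amp = ampute(
        ds,
        MissingnessPlan(mechanism="MCAR", target_rate=0.2, seed=2),
        rses_preset.covariates,
    )
    completed = impute_mi(amp, rses_preset.covariates, m=5, n_iter=5, seed=7)
    return ds, amp, completed


class TestMultipleImputation:
    def test_m_completed_datasets(self, mi_case):
        _, _, completed = mi_case
        assert completed.m == 5

    def test_observed_cells_identical_in_every_set(self, mi_case):
        ds, amp, completed = mi_case
        base = ds.items.to_numpy()
        for out in completed.datasets:
            assert np.array_equal(out.items.to_numpy()[~amp.mask], base[~amp.mask])

    def test_imputed_values_are_observed_donor_values(self, mi_case):
        """PMM only copies observed values, so every imputed cell must equal
        some observed value of its own column (and hence be in range)."""
        ds, amp, completed = mi_case
        base = ds.items.to_numpy()
        for out in completed.datasets:
            vals = out.items.to_numpy()
            for j in range(vals.shape[1]):
                observed = set(base[~amp.mask[:, j], j])
                imputed = set(vals[amp.mask[:, j], j])
                assert imputed <= observed

    def test_between_imputation_variability(self, mi_case):
        _, amp, completed = mi_case
        masked_cells = [out.items.to_numpy()[amp.mask] for out in completed.datasets]
        stacked = np.stack(masked_cells)
        assert (stacked.std(axis=0) > 0).any()

    def test_m_below_two_rejected(self, mi_case, rses_preset):
        _, amp, _ = mi_case
        with pytest.raises(ValueError, match="m >= 2"):
            impute_mi(amp, rses_preset.covariates, m=1)

    def test_reproducible_from_seed(self, rses_preset):
        ds = rses_preset.generate(n=150, seed=6)
        amp = ampute(
            ds,
            MissingnessPlan(mechanism="MCAR", target_rate=0.15, seed=2),
            rses_preset.covariates,
        )
        a = impute_mi(amp, rses_preset.covariates, m=2, n_iter=3, seed=9)
        b = impute_mi(amp, rses_preset.covariates, m=2, n_iter=3, seed=9)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da.items, db.items)

    def test_crosscheck_against_statsmodels_mice(self, rses_preset):
        """Independent engine check: statsmodels' MICE (PMM-based chained
        equations) and this engine should both land the imputed-data mean
        near the complete-data mean on the same amputed input."""
        from statsmodels.imputation.mice import MICEData

        ds = rses_preset.generate(n=500, seed=16)
        amp = ampute(
            ds,
            MissingnessPlan(mechanism="MCAR", target_rate=0.15, seed=3),
            rses_preset.covariates,
        )
        ours = impute_mi(amp, rses_preset.covariates, m=5, n_iter=5, seed=4)
        our_mean = np.mean([d.total_scores().mean() for d in ours.datasets])

        frame = amp.items_with_missing()
        frame["age"] = ds.covariates["age"].to_numpy()
        md = MICEData(frame, perturbation_method="boot")
        np.random.seed(4)
        theirs = []
        for _ in range(5):
            md.update_all(2)
            theirs.append(md.data[ds.items.columns].sum(axis=1).mean())
        their_mean = np.mean(theirs)
        complete_mean = ds.total_scores().mean()
        assert abs(our_mean - complete_mean) < 0.35
        assert abs(our_mean - their_mean) < 0.5


class TestRubinsPool:
    def test_degenerate_agreement(self):
        pooled = rubins_pool([2.0, 2.0], [0.5, 0.5])
        assert pooled.point == 2.0
        assert pooled.between_var == 0.0
        assert pooled.total_var == 0.5
        assert np.isinf(pooled.df)

    def test_hand_computation(self):
        pooled = rubins_pool([1.0, 3.0], [1.0, 1.0])
        assert pooled.point == pytest.approx(2.0)
        assert pooled.within_var == pytest.approx(1.0)
        assert pooled.between_var == pytest.approx(2.0)
        assert pooled.total_var == pytest.approx(4.0)  # 1 + 1.5 * 2

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            rubins_pool([1.0], [1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(0, 100, allow_nan=False),
            ),
            min_size=2,
            max_size=12,
        )
    )
    def test_pooling_algebra(self, pairs):
        q = [p[0] for p in pairs]
        u = [p[1] for p in pairs]
        pooled = rubins_pool(q, u)
        m = len(q)
        assert pooled.total_var == pytest.approx(
            pooled.within_var + (1 + 1 / m) * pooled.between_var, rel=1e-12, abs=1e-12
        )
        assert pooled.total_var >= pooled.within_var - 1e-12
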