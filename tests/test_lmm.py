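"""Mixed-model fitting, AICc, and backward selection."""

import numpy as np
import pandas as pd
import pytest

from scannet.lmm import (
    DEFAULT_TERMS,
    NetworkMeasureLMM,
    aicc,
    backward_select,
    check_marginality,
)


def covariate_frame(seed=0, n_per=None):
    """41-row frame matching the study layout (4 groups, 4 classes)."""
    rng = np.random.default_rng(seed)
    rows = []
    layout = [
        ("S1", [("ELD", 5), ("LLD", 4)]),
        ("S2", [("ELD", 5), ("LLD", 4)]),
        ("Z1", [("EMD", 4), ("ND", 8)]),
        ("Z2", [("EMD", 3), ("ND", 8)]),
    ]
    for group, classes in layout:
        for cls, n in classes:
            for k in range(n):
                rows.append(
                    {
                        "id": f"{group}-{cls}-{k}",
                        "group_id": group,
                        "deprivation_class": cls,
                        "sex": "female" if (k + hash(cls)) % 3 else "male",
                        "age_class": "old" if k % 2 else "mature",
                    }
                )
    df = pd.DataFrame(rows)
    df["noise"] = rng.normal(size=len(df))
    return df


class TestAicc:
    def test_formula_arithmetic(self):
        # AIC = -2(-10) + 2*3 = 26; correction 2*3*4/(20-4) = 1.5
        assert aicc(-10.0, k=3, n=20) == pytest.approx(27.5)

    def test_k_zero_equals_aic(self):
        assert aicc(-10.0, k=0, n=20) == pytest.approx(20.0)

    def test_correction_vanishes_with_n(self):
        for n in (10**3, 10**6):
            assert aicc(-10.0, 3, n) - 26.0 == pytest.approx(
                2 * 3 * 4 / (n - 4), rel=1e-12
            )

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, k=5, n=6)


class TestMarginality:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="marginality"):
            check_marginality(("sex", "sex:deprivation_class"))
        check_marginality(("sex", "deprivation_class", "sex:deprivation_class"))


class TestFit:
    def test_noiseless_linear_response_recovered(self):
        """An exact linear function of sex and class is recovered with zero
        residual variance and no exception."""
        df = covariate_frame()
        sex_eff = {"female": 1.0, "male": -1.0}
        cls_eff = {"ELD": -2.0, "LLD": 0.5, "EMD": 1.0, "ND": 2.5}
        df["y"] = df.sex.map(sex_eff) + df.deprivation_class.map(cls_eff)
        res = NetworkMeasureLMM(
            df, "y", ("sex", "deprivation_class"), groups="group_id"
        ).fit()
        assert res.perfect_fit
        assert res.scale == pytest.approx(0.0, abs=1e-10)
        fitted = res.model.exog @ res.params.to_numpy()
        assert np.allclose(fitted, df["y"], atol=1e-8)

    def test_constant_response_zero_slopes(self):
        df = covariate_frame()
        df["y"] = 3.14
        res = NetworkMeasureLMM(df, "y", DEFAULT_TERMS, groups="group_id").fit()
        slopes = res.params.iloc[1:]
        assert np.allclose(slopes, 0.0, atol=1e-8)
        ftab = res.f_test_terms(include_intercept=False)
        assert (ftab["F"] == 0.0).all()

    def test_strong_class_effect_detected(self):
        """A 2-residual-SD class deficit yields a significant marginal F for
        the class term in the full model (checked over a handful of seeds)."""
        hits = 0
        for seed in range(10):
            df = covariate_frame(seed)
            df["y"] = np.where(df.deprivation_class == "ELD", -2.0, 0.0) + df["noise"]
            res = NetworkMeasureLMM(df, "y", DEFAULT_TERMS, groups="group_id").fit()
            ftab = res.f_test_terms().set_index("term")
            hits += ftab.loc["deprivation_class", "p"] < 0.05
        assert hits >= 9

    def test_one_group_rejected(self):
        df = covariate_frame()
        df["group_id"] = "G"
        df["y"] = df["noise"]
        with pytest.raises(ValueError, match="2 groups"):
            NetworkMeasureLMM(df, "y", ("sex",), groups="group_id")

    def test_too_few_rows_for_aicc(self):
        # 12 rows spanning all 8 sex x class cells (k = 11 parameters)
        rows = []
        k = 0
        for cls in ("ELD", "LLD", "EMD", "ND"):
            for sex in ("female", "male"):
                ages = ("mature", "old") if sex == "female" else ("mature",)
                for age in ages:
                    rows.append(
                        {"id": f"i{k}", "group_id": "G1" if k % 2 else "G2",
                         "deprivation_class": cls, "sex": sex, "age_class": age}
                    )
                    k += 1
        df = pd.DataFrame(rows)
        df["y"] = np.random.default_rng(0).normal(size=len(df))
        with pytest.raises(ValueError, match="AICc"):
            NetworkMeasureLMM(df, "y", DEFAULT_TERMS, groups="group_id").fit()

    def test_aliased_columns_reduce_term_df(self):
        """An empty sex x class cell drops one interaction column, shrinking
        the interaction's numerator df instead of crashing."""
        df = covariate_frame()
        df = df[~((df.deprivation_class == "ELD") & (df.sex == "female"))]
        df = df.reset_index(drop=True)
        df["y"] = df["noise"]
        res = NetworkMeasureLMM(df, "y", DEFAULT_TERMS, groups="group_id").fit()
        ftab = res.f_test_terms().set_index("term")
        assert ftab.loc["sex:deprivation_class", "df1"] == 2  # 3 cells - 1 aliased

    def test_summary_renders(self):
        df = covariate_frame()
        df["y"] = df["noise"]
        text = NetworkMeasureLMM(df, "y", ("sex",), groups="group_id").fit().summary()
        assert "AICc" in text and "Fixed-effect tests" in text


class TestBackwardSelect:
    def test_full_model_kept_when_best(self):
        """With strong effects on every term, nothing is dropped and the
        ledger holds a single step."""
        df = covariate_frame(3)
        cls_eff = {"ELD": -3.0, "LLD": 1.5, "EMD": -1.0, "ND": 3.0}
        df["y"] = (
            df.deprivation_class.map(cls_eff)
            + np.where(df.sex == "female", 2.0, -2.0)
            + np.where(df.age_class == "old", 1.5, -1.5)
            + np.where(
                (df.sex == "female") & (df.deprivation_class == "ND"), 3.0, 0.0
            )
            + 0.3 * df["noise"]
        )
        best, ledger = backward_select(df, "y", DEFAULT_TERMS, groups="group_id")
        assert ledger[-1].terms == DEFAULT_TERMS
        assert len(ledger) == 1

    def test_null_terms_dropped_class_kept(self):
        df = covariate_frame(4)
        df["y"] = np.where(df.deprivation_class == "ELD", -2.0, 0.0) + df["noise"]
        best, ledger = backward_select(df, "y", DEFAULT_TERMS, groups="group_id")
        terms = ledger[-1].terms
        assert "deprivation_class" in terms
        assert "sex:deprivation_class" not in terms

    def test_marginality_never_violated(self):
        """Across seeds, no intermediate model contains the interaction
        without both of its main effects."""
        for seed in range(8):
            df = covariate_frame(seed)
            df["y"] = df["noise"]
            _, ledger = backward_select(df, "y", DEFAULT_TERMS, groups="group_id")
            for step in ledger:
                ts = set(step.terms)
                if "sex:deprivation_class" in ts:
                    assert {"sex", "deprivation_class"} <= ts

    def test_ledger_records_candidates(self):
        df = covariate_frame(5)
        df["y"] = df["noise"]
        _, ledger = backward_select(df, "y", DEFAULT_TERMS, groups="group_id")
        first = ledger[0]
        # droppable at the full model: the interaction and the free main effect
        assert set(first.candidates) == {"age_class", "sex:deprivation_class"}
        assert all(np.isfinite(v) for v in first.candidates.values())
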