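"""Design construction, Gaussian log-scale fitting, model selection, hits."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from circuitquant import (
    DesignRankError,
    FoldChange,
    ModelSpec,
    ScreenSpec,
    build_design,
    call_hits,
    diagnose,
    fit,
    fit_screen,
    generate_screen_table,
    prepare_response,
    select_model,
)

SMALL_PARTS = {
    "response_element": ("RE1", "RE2"),
    "regulated_component": ("NarL", "NarX"),
    "transactivation_domain": ("VP48", "FLT"),
}
SMALL_REF = {"response_element": "RE1", "regulated_component": "NarL",
             "transactivation_domain": "VP48"}
SMALL_FACTORS = tuple(SMALL_PARTS)


def small_spec(**kw):
    return ScreenSpec(parts=SMALL_PARTS, reference=SMALL_REF, **kw)


def model(variant=1, **kw):
    kw.setdefault("factors", SMALL_FACTORS)
    return ModelSpec(response="mutant", variant=variant, **kw)


class TestBuildDesign:
    def test_reference_only_rows_give_intercept_only(self):
        table = pd.DataFrame({
            "response_element": ["RE1"] * 4, "regulated_component": ["NarL"] * 4,
            "transactivation_domain": ["VP48"] * 4,
            "condition": ["mutant"] * 4, "ru": [1.0, 2.0, 3.0, 4.0],
        })
        X, y = build_design(table, model())
        assert list(X.columns) == ["intercept"]
        assert np.allclose(y, np.log10([1, 2, 3, 4]))

    def test_single_two_level_factor_one_indicator(self):
        table = pd.DataFrame({
            "binding_domain": ["RBDCRD", "RBD"] * 3,
            "condition": ["mutant"] * 6, "ru": np.arange(1.0, 7.0),
        })
        spec = ModelSpec(response="mutant", factors=("binding_domain",),
                         reference={"binding_domain": "RBDCRD"})
        X, _ = build_design(table, spec)
        assert list(X.columns) == ["intercept", "binding_domain[RBD]"]
        assert X["binding_domain[RBD]"].tolist() == [0.0, 1.0] * 3

    def test_matches_brute_force_indicator_expansion(self):
        table = generate_screen_table(small_spec(seed=7)).data
        X, _ = build_design(table, model())
        sub = table[table.condition == "mutant"].reset_index(drop=True)
        for f, levels in SMALL_PARTS.items():
            for lev in levels:
                if lev == SMALL_REF[f]:
                    continue
                manual = (sub[f] == lev).astype(float)
                assert np.array_equal(X[f"{f}[{lev}]"].to_numpy(), manual.to_numpy())

    def test_interaction_columns_are_products(self):
        table = generate_screen_table(small_spec(seed=7)).data
        X, _ = build_design(table, model(variant=2))
        col = "response_element[RE2]:regulated_component[NarX]"
        assert np.array_equal(
            X[col].to_numpy(),
            X["response_element[RE2]"].to_numpy()
            * X["regulated_component[NarX]"].to_numpy(),
        )

    def test_rank_deficiency_names_aliased_columns(self):
        table = generate_screen_table(small_spec(seed=7)).data
        table = table[table["response_element"] == "RE1"]  # RE2 never observed
        table = table.assign(response_element="RE1")
        # duplicate a factor to force aliasing
        table = table.assign(transactivation_domain=table["regulated_component"]
                             .map({"NarL": "VP48", "NarX": "FLT"}))
        with pytest.raises(DesignRankError) as err:
            build_design(table, model())
        assert "transactivation_domain[FLT]" in err.value.aliased

    def test_nonpositive_response_named(self):
        table = pd.DataFrame({
            "binding_domain": ["RBDCRD", "RBD"], "condition": ["mutant"] * 2,
            "ru": [1.0, 0.0],
        })
        spec = ModelSpec(response="mutant", factors=("binding_domain",),
                         reference={"binding_domain": "RBDCRD"})
        with pytest.raises(ValueError, match="nonpositive RU in rows \\[1\\]"):
            build_design(table, spec)


class TestFit:
    def test_noise_free_recovery_matches_truth_and_normal_equations(self):
        spec = small_spec(
            effects={"regulated_component": {"NarX": (0.3, 0.1)},
                     "transactivation_domain": {"FLT": (-0.45, -0.2)}},
            replicate_sd=0.0, seed=1,
        )
        st = generate_screen_table(spec)
        X, y = build_design(st.data, model())
        res = fit(X, y)
        # normal-equations oracle
        A = X.to_numpy()
        beta = np.linalg.solve(A.T @ A, A.T @ y.to_numpy())
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-10)
        truth = {f"{r.factor}[{r.level}]": r.effect_on for r in st.truth.itertuples()}
        for name in X.columns[1:]:
            assert res.params[name] == pytest.approx(truth.get(name, 0.0), abs=1e-8)

    def test_constant_response_zero_effects(self):
        table = generate_screen_table(small_spec(replicate_sd=0.0, seed=2)).data
        res = fit_screen(table, model())
        assert np.allclose(res.params.to_numpy()[1:], 0.0, atol=1e-12)
        assert res.params["intercept"] == pytest.approx(0.5, abs=1e-12)

    def test_covariate_recovery(self):
        spec = small_spec(covariate_effects={"transfection_efficiency": 0.8},
                          replicate_sd=0.0, seed=3)
        table = generate_screen_table(spec).data
        res = fit_screen(table, model(covariates=("transfection_efficiency",)))
        assert res.params["transfection_efficiency"] == pytest.approx(0.8, abs=1e-8)

    def test_wald_type_one_error_calibrated(self):
        """Under a null screen the Wald test rejects at close to nominal rate."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_tests = 0
        for i in range(300):
            spec = small_spec(replicate_sd=0.1, n_replicates=2,
                              seed=int(rng.integers(2**31)))
            res = fit_screen(generate_screen_table(spec).data, model())
            pv = res.pvalues.drop("intercept")
            rejections += (pv < 0.05).sum()
            n_tests += len(pv)
        rate = rejections / n_tests
        assert 0.03 <= rate <= 0.07

    def test_exp_coefficient_equals_geometric_mean_ratio(self):
        """In a balanced noise-free design, 10**coef is the ratio of geometric
        mean RU between a level and the reference."""
        spec = small_spec(effects={"regulated_component": {"NarX": (0.3, 0.0)}},
                          replicate_sd=0.0, seed=4)
        table = generate_screen_table(spec).data
        res = fit_screen(table, model())
        sub = table[table.condition == "mutant"]
        gm = sub.groupby("regulated_component")["ru"].apply(
            lambda v: np.exp(np.mean(np.log(v))))
        ratio = gm["NarX"] / gm["NarL"]
        assert 10 ** res.params["regulated_component[NarX]"] == pytest.approx(
            ratio, rel=1e-10)

    def test_factor_orthogonality_in_balanced_design(self):
        """Dropping one factor leaves the other estimates unchanged,
        noise-free and balanced."""
        spec = small_spec(effects={"regulated_component": {"NarX": (0.3, 0.0)},
                                   "transactivation_domain": {"FLT": (0.2, 0.0)}},
                          replicate_sd=0.0, seed=5)
        table = generate_screen_table(spec).data
        full = fit_screen(table, model())
        reduced = fit_screen(table, model(factors=("response_element",
                                                   "regulated_component")))
        assert reduced.params["regulated_component[NarX]"] == pytest.approx(
            full.params["regulated_component[NarX]"], abs=1e-10)


class TestDiagnoseAndSelect:
    def test_perfect_fit_diagnostics(self):
        spec = small_spec(effects={"regulated_component": {"NarX": (0.3, 0.0)}},
                          covariate_effects={"transfection_efficiency": 0.6},
                          replicate_sd=0.0, seed=6)
        res = fit_screen(generate_screen_table(spec).data,
                         model(covariates=("transfection_efficiency",)))
        d = diagnose(res)
        assert d["r_squared"] == pytest.approx(1.0)
        assert d["spearman"] == pytest.approx(1.0)

    def test_permuted_response_destroys_fit(self):
        spec = small_spec(effects={"regulated_component": {"NarX": (0.6, 0.0)}},
                          replicate_sd=0.02, n_replicates=4, seed=7)
        table = generate_screen_table(spec).data
        rng = np.random.default_rng(0)
        shuffled = table.copy()
        shuffled["ru"] = rng.permutation(shuffled["ru"].to_numpy())
        res = fit_screen(shuffled, model())
        assert res.r_squared < 0.3

    def test_r_squared_equals_direct_recomputation(self):
        spec = small_spec(replicate_sd=0.1, seed=8)
        table = generate_screen_table(spec).data
        res = fit_screen(table, model())
        X, y = build_design(table, model())
        r = np.corrcoef(res.fitted, y.to_numpy())[0, 1]
        assert res.r_squared == pytest.approx(r ** 2, abs=1e-12)

    def test_interaction_data_selects_variant_three(self):
        spec = small_spec(
            effects={"regulated_component": {"NarX": (0.3, 0.1)}},
            interaction_effects=(({"response_element": "RE2",
                                   "regulated_component": "NarX",
                                   "transactivation_domain": "FLT"}, 0.8, 0.3),),
            replicate_sd=0.05, n_replicates=4, seed=9,
        )
        table = generate_screen_table(spec).data
        best, comparison = select_model(table, [model(1), model(2), model(3)])
        assert best.variant == 3
        assert (comparison["status"] == "ok").all()

    def test_identical_variants_tie_break_to_fewest_parameters(self):
        table = generate_screen_table(small_spec(replicate_sd=0.05, seed=10)).data
        best, _ = select_model(table, [model(1, interactions=()),
                                       model(2, interactions=())])
        assert best.variant == 1

    def test_no_interaction_data_keeps_simple_model_competitive(self):
        spec = small_spec(effects={"regulated_component": {"NarX": (0.5, 0.1)}},
                          replicate_sd=0.05, n_replicates=4, seed=11)
        table = generate_screen_table(spec).data
        _, comparison = select_model(table, [model(1), model(2), model(3)])
        r2 = comparison.set_index("variant")["r_squared"]
        assert r2[1] >= r2[3] - 0.05


class TestCallHits:
    def test_trivial_rules(self):
        ranges = {"a": FoldChange(150.0, 10.0), "b": FoldChange(95.0, 20.0)}
        default = call_hits(ranges).set_index("circuit")["hit"]
        strict = call_hits(ranges, rule="strict").set_index("circuit")["hit"]
        assert bool(default["a"]) and bool(strict["a"])
        assert not bool(default["b"]) and not bool(strict["b"])

    def test_strict_rule_subtracts_sd(self):
        ranges = {"edge": FoldChange(105.0, 10.0)}
        assert bool(call_hits(ranges)["hit"].iloc[0])
        assert not bool(call_hits(ranges, rule="strict")["hit"].iloc[0])

    def test_hit_count_matches_direct_threshold_count(self):
        rng = np.random.default_rng(13)
        folds = 10 ** rng.uniform(0, 3, 200)
        ranges = {i: FoldChange(f, 0.1 * f) for i, f in enumerate(folds)}
        hits = call_hits(ranges)
        assert hits["hit"].sum() == (folds > 100).sum()


class TestPrepareResponse:
    def test_dynamic_range_pairs_conditions(self):
        spec = small_spec(effects={"regulated_component": {"NarX": (0.4, 0.1)}},
                          replicate_sd=0.0, seed=14)
        table = generate_screen_table(spec).data
        dr = prepare_response(table, "dynamic_range")
        base = spec.intercept_on - spec.intercept_off
        ref_rows = dr[(dr.regulated_component == "NarL")]
        assert np.allclose(ref_rows["log10_ru"], base, atol=1e-12)
        narx = dr[dr.regulated_component == "NarX"]
        assert np.allclose(narx["log10_ru"], base + 0.3, atol=1e-12)
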