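"""Regression screen of circuit-part effects on normalized output.

Each screened circuit is a combination of categorical parts (response
element, regulated component, binding domain, transactivation domain,
linker).  Normalized output (RU) is modeled on the log10 scale with a
Gaussian identity-link model — ordinary least squares on log10(RU) — using
treatment coding against a stated reference configuration, so each
coefficient is the log10 effect of swapping one part of the reference
circuit.  Three nested interaction variants are fitted and the one with the
best fitted-vs-measured correlation is selected; significance is assessed per
coefficient with Wald tests, and circuits whose ON/OFF dynamic range exceeds
100-fold are called hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cytometry import FoldChange

__all__ = [
    "ModelSpec",
    "FitResult",
    "DesignRankError",
    "DEFAULT_FACTORS",
    "DEFAULT_REFERENCE",
    "VARIANT_INTERACTIONS",
    "prepare_response",
    "build_design",
    "fit",
    "diagnose",
    "select_model",
    "fit_screen",
    "call_hits",
]

DEFAULT_FACTORS = (
    "response_element",
    "regulated_component",
    "binding_domain",
    "transactivation_domain",
    "linker",
)

DEFAULT_REFERENCE = {
    "response_element": "RE1",
    "regulated_component": "NarL",
    "binding_domain": "RBDCRD",
    "transactivation_domain": "VP48",
    "linker": "6x_flex",
}

# Nested interaction sets standing in for the three candidate models: how the
# response element interacts with the parts it expresses.
VARIANT_INTERACTIONS: dict[int, tuple[tuple[str, ...], ...]] = {
    1: (),
    2: (("response_element", "regulated_component"),),
    3: (
        ("response_element", "regulated_component"),
        ("response_element", "transactivation_domain"),
        ("response_element", "regulated_component", "transactivation_domain"),
    ),
}


class DesignRankError(ValueError):
    """Raised when the design matrix is rank deficient; names aliased columns."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"design matrix is rank deficient; aliased columns: {self.aliased}")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response definition, interaction variant, covariates."""

    response: str = "mutant"          # "mutant" | "wild_type" | "dynamic_range"
    variant: int = 1
    factors: tuple[str, ...] = DEFAULT_FACTORS
    reference: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCE))
    covariates: tuple[str, ...] = ()
    interactions: tuple[tuple[str, ...], ...] | None = None   # overrides variant

    def interaction_terms(self) -> tuple[tuple[str, ...], ...]:
        if self.interactions is not None:
            return self.interactions
        if self.variant not in VARIANT_INTERACTIONS:
            raise ValueError(f"unknown interaction variant {self.variant}")
        return VARIANT_INTERACTIONS[self.variant]


@dataclass
class FitResult:
    """Coefficients on the log10 scale with Wald inference and diagnostics."""

    params: pd.Series
    bse: pd.Series
    wald: pd.Series
    pvalues: pd.Series
    fitted: np.ndarray
    resid: np.ndarray
    r_squared: float          # Pearson R^2 of fitted vs measured
    spearman: float
    nobs: int
    df_resid: int
    spec: ModelSpec | None = None

    @property
    def n_params(self) -> int:
        return len(self.params)

    def coefficient_table(self) -> pd.DataFrame:
        """Per-coefficient log10 effect, fold effect, SE, Wald stat, p-value."""
        return pd.DataFrame({
            "coef_log10": self.params,
            "fold_effect": 10.0 ** self.params,
            "se": self.bse,
            "wald": self.wald,
            "p_value": self.pvalues,
        })


def prepare_response(table: pd.DataFrame, response: str) -> pd.DataFrame:
    """Reduce the screen table to one row per observation with column ``log10_ru``.

    ``"mutant"`` / ``"wild_type"`` select that RAS condition; ``"dynamic_range"``
    pairs the two conditions per circuit x replicate and takes their RU ratio.
    Nonpositive RU values are rejected, naming the offending rows.
    """
    if response in ("mutant", "wild_type"):
        sub = table[table["condition"] == response].copy()
        bad = sub.index[sub["ru"] <= 0].tolist()
        if bad:
            raise ValueError(f"nonpositive RU in rows {bad}; cannot log-transform")
        sub["log10_ru"] = np.log10(sub["ru"].to_numpy(dtype=float))
        return sub
    if response == "dynamic_range":
        keys = [c for c in table.columns
                if c not in ("condition", "ru", "batch") and table[c].dtype == object] \
            + ["circuit", "replicate"]
        keys = list(dict.fromkeys(k for k in keys if k in table.columns))
        mut = table[table["condition"] == "mutant"].set_index(keys)
        wt = table[table["condition"] == "wild_type"].set_index(keys)
        joined = mut.join(wt[["ru"]], rsuffix="_wt", how="inner")
        bad = joined.index[(joined["ru"] <= 0) | (joined["ru_wt"] <= 0)].tolist()
        if bad:
            raise ValueError(f"nonpositive RU in rows {bad}; cannot log-transform")
        joined["log10_ru"] = np.log10(joined["ru"] / joined["ru_wt"])
        return joined.reset_index()
    raise ValueError("response must be 'mutant', 'wild_type' or 'dynamic_range'")


def _indicator_columns(table: pd.DataFrame, factor: str, reference: str) -> dict[str, np.ndarray]:
    levels = [l for l in pd.unique(table[factor]) if l != reference]
    return {f"{factor}[{lev}]": (table[factor] == lev).to_numpy(dtype=float)
            for lev in sorted(levels)}


def build_design(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Treatment-coded design matrix and log10 response for one model spec.

    Columns: intercept, one indicator per non-reference level of each factor,
    products of indicators for each interaction term, then covariates as
    numeric columns.  A rank-deficient design raises :class:`DesignRankError`
    naming the aliased columns.
    """
    data = prepare_response(table, spec.response)
    factors = [f for f in spec.factors if f in data.columns]
    for f in factors:
        if spec.reference[f] not in set(data[f]):
            raise ValueError(f"reference level {spec.reference[f]!r} absent from factor {f!r}")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(data))}
    per_factor: dict[str, dict[str, np.ndarray]] = {}
    for f in factors:
        per_factor[f] = _indicator_columns(data, f, spec.reference[f])
        cols.update(per_factor[f])
    for term in spec.interaction_terms():
        missing = [f for f in term if f not in per_factor]
        if missing:
            continue
        sets = [per_factor[f] for f in term]
        from itertools import product as _prod
        for combo in _prod(*(s.items() for s in sets)):
            name = ":".join(k for k, _ in combo)
            arr = np.ones(len(data))
            for _, v in combo:
                arr = arr * v
            cols[name] = arr
    for cov in spec.covariates:
        if cov not in data.columns:
            raise ValueError(f"covariate {cov!r} absent from table")
        cols[cov] = data[cov].to_numpy(dtype=float)

    X = pd.DataFrame(cols, index=data.index)
    if len(X) < X.shape[1]:
        raise ValueError("fewer rows than design columns; cannot fit")
    # greedy rank check naming aliased columns
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = []
        basis = np.empty((len(X), 0))
        for name in X.columns:
            cand = np.column_stack([basis, X[name].to_numpy()])
            if np.linalg.matrix_rank(cand) > basis.shape[1]:
                basis = cand
            else:
                aliased.append(name)
        raise DesignRankError(aliased)
    return X, data["log10_ru"]


def fit(design: pd.DataFrame, response: pd.Series,
        spec: ModelSpec | None = None) -> FitResult:
    """Gaussian identity-link fit of log10 response (ordinary least squares).

    Wald statistics are coefficient/SE with Student-t reference (the
    small-sample Wald test a Gaussian GLM summary reports).
    """
    res = sm.OLS(np.asarray(response, dtype=float), design).fit()
    fitted = np.asarray(res.fittedvalues)
    obs = np.asarray(response, dtype=float)
    if np.std(fitted) > 0 and np.std(obs) > 0:
        r = float(stats.pearsonr(fitted, obs).statistic)
        rho = float(stats.spearmanr(fitted, obs).statistic)
    else:
        r, rho = 0.0, 0.0
    return FitResult(
        params=pd.Series(res.params, index=design.columns),
        bse=pd.Series(res.bse, index=design.columns),
        wald=pd.Series(res.tvalues, index=design.columns),
        pvalues=pd.Series(res.pvalues, index=design.columns),
        fitted=fitted,
        resid=np.asarray(res.resid),
        r_squared=r ** 2,
        spearman=rho,
        nobs=int(res.nobs),
        df_resid=int(res.df_resid),
        spec=spec,
    )


def fit_screen(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Build the design for ``spec`` and fit it."""
    X, y = build_design(table, spec)
    return fit(X, y, spec)


def diagnose(fitres: FitResult) -> dict:
    """Residual and goodness-of-fit summary for a fitted model."""
    resid = fitres.resid
    return {
        "r_squared": fitres.r_squared,
        "spearman": fitres.spearman,
        "resid_mean": float(resid.mean()),
        "resid_sd": float(resid.std(ddof=1)) if resid.size > 1 else 0.0,
        "resid_min": float(resid.min()),
        "resid_max": float(resid.max()),
    }


def select_model(table: pd.DataFrame, variants) -> tuple[ModelSpec, pd.DataFrame]:
    """Fit each candidate and pick the best fitted-vs-measured correlation.

    Variants that fail to fit are recorded and excluded.  Ties (R^2 within
    1e-9) are broken toward the model with fewer parameters.
    """
    variants = list(variants)
    if len(variants) < 2:
        raise ValueError("model selection needs at least two candidate variants")
    rows = []
    results: list[tuple[ModelSpec, FitResult]] = []
    for spec in variants:
        try:
            res = fit_screen(table, spec)
        except Exception as exc:  # noqa: BLE001 - recorded, not silenced
            rows.append({"variant": spec.variant, "n_params": np.nan,
                         "r_squared": np.nan, "spearman": np.nan,
                         "status": f"failed: {exc}"})
            continue
        rows.append({"variant": spec.variant, "n_params": res.n_params,
                     "r_squared": res.r_squared, "spearman": res.spearman,
                     "status": "ok"})
        results.append((spec, res))
    comparison = pd.DataFrame(rows)
    if not results:
        raise RuntimeError("no candidate model could be fitted")
    best_r2 = max(res.r_squared for _, res in results)
    contenders = [(spec, res) for spec, res in results
                  if res.r_squared >= best_r2 - 1e-9]
    best = min(contenders, key=lambda sr: sr[1].n_params)[0]
    return best, comparison


def call_hits(dynamic_ranges: dict[object, FoldChange], threshold: float = 100.0,
              rule: str = "value") -> pd.DataFrame:
    """Call circuits whose ON/OFF dynamic range clears ``threshold``.

    ``rule="value"``: hit iff fold > threshold (the SD is annotated);
    ``rule="strict"``: hit iff fold - SD > threshold.
    """
    if rule not in ("value", "strict"):
        raise ValueError("rule must be 'value' or 'strict'")
    rows = []
    for cid, fc in dynamic_ranges.items():
        margin = fc.value - (fc.sd if np.isfinite(fc.sd) else 0.0)
        hit = (fc.value > threshold) if rule == "value" else (margin > threshold)
        rows.append({"circuit": cid, "fold": fc.value, "sd": fc.sd, "hit": bool(hit)})
    return pd.DataFrame(rows, columns=["circuit", "fold", "sd", "hit"])
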