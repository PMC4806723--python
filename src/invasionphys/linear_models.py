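"""Shared least-squares engine for factorial ANOVA / ANCOVA tables.

All four experiment analyses funnel through :func:`fit_anova`: fixed-effects
factorial models and models with a single random blocking factor (field plot
or spatial block). Fitting is ordinary least squares via statsmodels; the
random factor is handled classically by error strata rather than REML, which
keeps every F-ratio deterministic and reproducible:

* fixed terms that vary *within* levels of the blocking factor are tested
  against the residual mean square;
* fixed terms that are constant within every block (between-block terms) are
  tested against the blocking-factor mean square (containment scheme);
* the blocking factor itself is tested against the residual mean square.

Sums of squares default to Type II (marginal to other terms at the same
order), appropriate for the mildly unbalanced designs these experiments
produce; Type I/III are available via ``ss_type``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["ModelSpec", "fit_anova", "fit_ancova", "parse_formula"]

#: Columns of every ANOVA table returned by this module.
ANOVA_COLUMNS = ["term", "df_num", "df_den", "ss", "ms", "F", "p"]


@dataclass
class ModelSpec:
    """Declarative description of one ANOVA/ANCOVA model.

    Parameters
    ----------
    response
        Name of the response column.
    covariates
        Continuous regressors, reported before the factor terms (ANCOVA).
    fixed_factors
        Categorical fixed factors, main effects.
    interactions
        Tuples of factor names; each must be a subset of ``fixed_factors``.
    random_factor
        Optional blocking identifier column treated as a random factor.
    transform
        ``"none"`` or ``"log"`` (natural log applied to the response).
    """

    response: str
    covariates: list[str] = field(default_factory=list)
    fixed_factors: list[str] = field(default_factory=list)
    interactions: list[tuple[str, ...]] = field(default_factory=list)
    random_factor: str | None = None
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.transform not in ("none", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.random_factor is not None and self.random_factor in self.fixed_factors:
            raise ValueError("random factor cannot also be a fixed factor")
        for terms in self.interactions:
            unknown = set(terms) - set(self.fixed_factors)
            if unknown:
                raise ValueError(f"interaction references unlisted factors: {unknown}")


def _term_label(parts: tuple[str, ...]) -> str:
    return " x ".join(parts)


def _patsy_term(parts: tuple[str, ...], categorical: bool = True) -> str:
    if categorical:
        return ":".join(f"C(Q('{p}'))" for p in parts)
    return ":".join(f"Q('{p}')" for p in parts)


def _is_between(data: pd.DataFrame, cols: tuple[str, ...], random_factor: str) -> bool:
    """True when the term takes a single value inside every block level."""
    n_distinct = data.groupby(random_factor, observed=True)[list(cols)].nunique()
    return bool((n_distinct == 1).all().all())


def fit_anova(data: pd.DataFrame, spec: ModelSpec, ss_type: int = 2) -> pd.DataFrame:
    """Fit the model in ``spec`` and return a per-term ANOVA table.

    Returns a DataFrame with columns ``term, df_num, df_den, ss, ms, F, p``,
    terms in the order covariates, main effects, interactions, random factor,
    residual. Raises ``ValueError`` for degenerate inputs (constant response,
    zero residual degrees of freedom, rank-deficient design).
    """
    if ss_type not in (1, 2, 3):
        raise ValueError("ss_type must be 1, 2 or 3")
    needed = (
        [spec.response]
        + spec.covariates
        + spec.fixed_factors
        + ([spec.random_factor] if spec.random_factor else [])
    )
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")

    df = data[needed].dropna().copy()
    y = df[spec.response].to_numpy(dtype=float)
    if spec.transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires a strictly positive response")
        df[spec.response] = np.log(y)
        y = df[spec.response].to_numpy()
    if np.ptp(y) == 0:
        raise ValueError("response is constant: total sum of squares is zero")

    # fixed-effects formula terms, mapping patsy labels to readable labels
    rhs: list[str] = []
    label_of: dict[str, str] = {}
    for cov in spec.covariates:
        pt = _patsy_term((cov,), categorical=False)
        rhs.append(pt)
        label_of[pt] = cov
    for f in spec.fixed_factors:
        pt = _patsy_term((f,))
        rhs.append(pt)
        label_of[pt] = f
    for terms in spec.interactions:
        pt = _patsy_term(terms)
        rhs.append(pt)
        label_of[pt] = _term_label(terms)

    # Fixed-term SS come from the fixed-effects projection; the blocking
    # factor is then added and its stratum recovered from the residual
    # difference. (Exact for block designs orthogonal to the treatments,
    # i.e. any balanced layout; avoids aliasing between block dummies and
    # between-block fixed terms.)
    formula_fixed = f"Q('{spec.response}') ~ " + " + ".join(rhs)
    model_fixed = smf.ols(formula_fixed, data=df).fit()
    exog = model_fixed.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    table = sm.stats.anova_lm(model_fixed, typ=ss_type)

    if spec.random_factor:
        rand_pt = _patsy_term((spec.random_factor,))
        formula_full = f"{formula_fixed} + {rand_pt}"
        model_full = smf.ols(formula_full, data=df).fit()
        resid_ss = float(model_full.ssr)
        resid_df = float(model_full.df_resid)
        rand_ss = float(model_fixed.ssr) - resid_ss
        rand_df = float(model_fixed.df_resid) - resid_df
        if rand_df < 1:
            raise ValueError("blocking factor aliased with the fixed effects")
    else:
        resid_ss = float(table.loc["Residual", "sum_sq"])
        resid_df = float(table.loc["Residual", "df"])
    if resid_df < 1:
        raise ValueError("zero residual degrees of freedom")
    resid_ms = resid_ss / resid_df
    if spec.random_factor:
        rand_ms = rand_ss / rand_df

    rows = []
    for pt in rhs:
        ss = float(table.loc[pt, "sum_sq"])
        dfn = float(table.loc[pt, "df"])
        ms = ss / dfn
        if spec.random_factor:
            parts = tuple(label_of[pt].split(" x "))
            is_cov = parts[0] in spec.covariates
            if not is_cov and _is_between(df, parts, spec.random_factor):
                den_ms, den_df = rand_ms, rand_df
            else:
                den_ms, den_df = resid_ms, resid_df
        else:
            den_ms, den_df = resid_ms, resid_df
        fstat = ms / den_ms
        rows.append(
            {
                "term": label_of[pt],
                "df_num": dfn,
                "df_den": den_df,
                "ss": ss,
                "ms": ms,
                "F": fstat,
                "p": float(stats.f.sf(fstat, dfn, den_df)),
            }
        )
    if spec.random_factor:
        frand = rand_ms / resid_ms
        rows.append(
            {
                "term": spec.random_factor,
                "df_num": rand_df,
                "df_den": resid_df,
                "ss": rand_ss,
                "ms": rand_ms,
                "F": frand,
                "p": float(stats.f.sf(frand, rand_df, resid_df)),
            }
        )
    rows.append(
        {
            "term": "residual",
            "df_num": resid_df,
            "df_den": np.nan,
            "ss": resid_ss,
            "ms": resid_ms,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


def fit_ancova(data: pd.DataFrame, spec: ModelSpec, ss_type: int = 2) -> pd.DataFrame:
    """ANCOVA wrapper: requires ≥1 covariate that varies within every factor cell."""
    if not spec.covariates:
        raise ValueError("ANCOVA requires at least one covariate")
    if spec.fixed_factors:
        cells = data.groupby(list(spec.fixed_factors), observed=True)
        for cov in spec.covariates:
            if (cells[cov].nunique() < 2).any():
                raise ValueError(f"covariate {cov!r} is constant within a factor cell")
    return fit_anova(data, spec, ss_type=ss_type)


def parse_formula(formula: str, data: pd.DataFrame) -> ModelSpec:
    """Parse the small model grammar ``"ln(y) ~ age + species*year + (plot)"``.

    ``ln(...)`` log-transforms the response; ``a*b`` expands to both main
    effects plus their interaction, ``a:b`` to the interaction only; a term in
    parentheses is the random blocking factor. Bare names are covariates when
    their column is numeric and fixed factors otherwise.
    """
    lhs, _, rhs = formula.partition("~")
    lhs = lhs.strip()
    if not rhs:
        raise ValueError("formula must contain '~'")
    transform = "none"
    if lhs.startswith(("ln(", "log(")) and lhs.endswith(")"):
        transform = "log"
        lhs = lhs[lhs.index("(") + 1 : -1].strip()

    covariates: list[str] = []
    fixed: list[str] = []
    interactions: list[tuple[str, ...]] = []
    random_factor: str | None = None

    def add_main(name: str) -> None:
        if name not in data.columns:
            raise ValueError(f"unknown column {name!r}")
        if pd.api.types.is_numeric_dtype(data[name]):
            if name not in covariates:
                covariates.append(name)
        elif name not in fixed:
            fixed.append(name)

    for raw in rhs.split("+"):
        tok = raw.strip()
        if not tok:
            continue
        if tok.startswith("(") and tok.endswith(")"):
            random_factor = tok[1:-1].strip()
        elif "*" in tok:
            parts = tuple(t.strip() for t in tok.split("*"))
            for p in parts:
                add_main(p)
            interactions.append(parts)
        elif ":" in tok:
            parts = tuple(t.strip() for t in tok.split(":"))
            for p in parts:
                if p not in data.columns:
                    raise ValueError(f"unknown column {p!r}")
                if not pd.api.types.is_numeric_dtype(data[p]) and p not in fixed:
                    fixed.append(p)
            interactions.append(parts)
        else:
            add_main(tok)

    return ModelSpec(
        response=lhs,
        covariates=covariates,
        fixed_factors=fixed,
        interactions=interactions,
        random_factor=random_factor,
        transform=transform,
    )
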