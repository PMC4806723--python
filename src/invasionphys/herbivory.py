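"""Herbivore-exclusion analysis and the enemy-release test.

Paired field plots (control vs. herbivore exclusion, arranged in blocks)
are censused for both the invasive and the native species; the dependent
variables are per-plot summaries — number of individuals, mean fruit count
per individual, mean individual dry mass. Each response is analysed by a
mixed ANOVA with species, treatment and their interaction fixed and block
random.

The enemy release hypothesis (ERH) predicts that excluding herbivores helps
the native more than the invader (which, having escaped its specialist
enemies, has little to gain), i.e. a species-by-treatment interaction. The
verdict is operationalised as: interaction p < α for at least one response
(``rule="any"``) or for every response (``rule="all"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .linear_models import ModelSpec, fit_anova

__all__ = ["ErhResult", "EXCLUSION_RESPONSES", "exclusion_anova", "erh_test"]

EXCLUSION_RESPONSES = ("n_individuals", "mean_fruits", "mean_mass")


@dataclass
class ErhResult:
    """Verdict of the enemy-release interaction test across responses."""

    erh_supported: bool
    alpha: float
    rule: str
    interaction_rows: pd.DataFrame = field(repr=False)


def exclusion_anova(records: pd.DataFrame, response: str, ss_type: int = 2) -> pd.DataFrame:
    """Mixed ANOVA of one plot-level response: species*treatment fixed, block random.

    Responses are analysed untransformed (counts included), matching the
    conventional treatment of plot-level summaries. Raises when a treatment
    level is confounded with block (exclusion must vary within blocks).
    """
    if response not in records.columns:
        raise ValueError(f"unknown response {response!r}")
    for col in ("species", "treatment"):
        if records[col].nunique() < 2:
            raise ValueError(f"need both levels of {col!r}")
    if records["block"].nunique() < 2:
        raise ValueError("need at least two blocks")
    per_block = records.groupby("block", observed=True)["treatment"].nunique()
    if (per_block < 2).any():
        raise ValueError("treatment confounded with block: each block needs both treatments")
    spec = ModelSpec(
        response=response,
        fixed_factors=["species", "treatment"],
        interactions=[("species", "treatment")],
        random_factor="block",
    )
    return fit_anova(records, spec, ss_type=ss_type)


def erh_test(
    anova_tables: dict[str, pd.DataFrame], alpha: float = 0.05, rule: str = "any"
) -> ErhResult:
    """Extract the species-by-treatment rows and apply the ERH decision rule.

    ``anova_tables`` maps response name → table from :func:`exclusion_anova`.
    ``rule="any"``: supported when any response's interaction p < α;
    ``rule="all"``: every response must reject. α = 0 never supports.
    """
    if rule not in ("any", "all"):
        raise ValueError(f"unknown rule {rule!r}")
    if not anova_tables:
        raise ValueError("no ANOVA tables supplied")
    rows = []
    for response, table in anova_tables.items():
        hit = table[table["term"] == "species x treatment"]
        if hit.empty:
            raise ValueError(f"table for {response!r} lacks a species x treatment term")
        row = hit.iloc[0].copy()
        row["response"] = response
        rows.append(row)
    inter = pd.DataFrame(rows).reset_index(drop=True)
    rejected = inter["p"] < alpha
    supported = bool(rejected.any() if rule == "any" else rejected.all())
    return ErhResult(
        erh_supported=supported, alpha=alpha, rule=rule, interaction_rows=inter
    )


def exclusion_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM of each response by species × treatment (figure-style summary)."""
    rows = []
    for response in EXCLUSION_RESPONSES:
        if response not in records.columns:
            continue
        g = records.groupby(["species", "treatment"], observed=True)[response]
        s = g.agg(mean="mean", sem="sem", n="size").reset_index()
        s.insert(0, "response", response)
        rows.append(s)
    return pd.concat(rows, ignore_index=True)
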