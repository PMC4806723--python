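"""Relative interaction intensity (RII) and the competition-trial ANOVA.

A focal plant of each species is grown alone or with four neighbours of
either species (six pot combinations). For each performance metric B the
relative interaction intensity is

    RII = (B_w − B̄₀) / (B_w + B̄₀)

where B_w is the focal plant's performance with neighbours and B̄₀ is the
mean performance of the conspecific plants grown alone. RII is bounded in
[−1, 1]; negative values indicate competition, positive facilitation, −1
complete suppression. Because every focal plant of a species shares the
same alone-grown baseline, RII values within a species are not strictly
independent; following common practice the two-way ANOVA (focal species ×
competitor identity, fixed effects) treats them as independent replicates.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .linear_models import ModelSpec, fit_anova

__all__ = [
    "RESPONSES",
    "NEIGHBOR_LEVELS",
    "baseline_means",
    "rii",
    "rii_table",
    "rii_anova",
]

#: The four performance metrics RII is computed for.
RESPONSES = ("seeds", "total_mass", "above_mass", "root_mass")
NEIGHBOR_LEVELS = ("none", "conspecific", "heterospecific")


def baseline_means(records: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean of each response over alone-grown plants (B̄₀).

    Returns a DataFrame indexed by focal species with one column per
    response. A species represented by a single alone-grown plant triggers a
    warning (its baseline is that one value).
    """
    alone = records[records["neighbor_identity"] == "none"]
    counts = alone.groupby("focal_species").size()
    all_species = records["focal_species"].unique()
    missing = set(all_species) - set(counts.index)
    if missing:
        raise ValueError(f"no alone-grown plants for species: {sorted(missing)}")
    for sp, n in counts.items():
        if n == 1:
            warnings.warn(
                f"species {sp!r} has a single alone-grown plant; baseline is one value",
                stacklevel=2,
            )
    return alone.groupby("focal_species")[list(RESPONSES)].mean()


def rii(b_with: float, b_alone_mean: float) -> float:
    """(B_w − B̄₀)/(B_w + B̄₀): 0 at parity, −1 at complete suppression."""
    if b_with < 0 or b_alone_mean < 0:
        raise ValueError("performance values must be non-negative")
    if b_with + b_alone_mean == 0:
        raise ValueError("RII undefined when both performance and baseline are zero")
    return (b_with - b_alone_mean) / (b_with + b_alone_mean)


def rii_table(records: pd.DataFrame, drop_zero_performers: bool = False) -> pd.DataFrame:
    """One RII row per non-alone focal plant per response metric.

    Alone-grown plants define the baselines and are excluded from the
    output. Focal plants with zero performance (died, set no seed) are
    retained with RII = −1 unless ``drop_zero_performers``.
    """
    unknown = set(records["neighbor_identity"].unique()) - set(NEIGHBOR_LEVELS)
    if unknown:
        raise ValueError(f"unknown neighbor identity labels: {sorted(unknown)}")
    base = baseline_means(records)
    species = sorted(records["focal_species"].unique())
    if len(species) != 2:
        raise ValueError(f"exactly two focal species required, found {species}")
    other = {species[0]: species[1], species[1]: species[0]}
    with_nb = records[records["neighbor_identity"] != "none"]
    rows = []
    for _, rec in with_nb.iterrows():
        sp = rec["focal_species"]
        nb = rec["neighbor_identity"]
        for resp in RESPONSES:
            b_w = float(rec[resp])
            if drop_zero_performers and b_w == 0:
                continue
            rows.append(
                {
                    "pot_id": rec["pot_id"],
                    "focal_species": sp,
                    "neighbor_identity": nb,
                    # competitor = the neighbour's species identity, the
                    # factor the two-way ANOVA crosses with focal species
                    "competitor": sp if nb == "conspecific" else other[sp],
                    "response_name": resp,
                    "rii": rii(b_w, float(base.loc[sp, resp])),
                }
            )
    return pd.DataFrame(rows)


def rii_anova(rii_values: pd.DataFrame, response: str, ss_type: int = 2) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of RII: focal species × competitor identity.

    Returns the per-term table with an aggregate ``model`` row (all fixed
    terms pooled) prepended, matching the conventional competition-trial
    report layout.
    """
    sub = rii_values[rii_values["response_name"] == response]
    if sub.empty:
        raise ValueError(f"no RII values for response {response!r}")
    cells = sub.groupby(["focal_species", "competitor"], observed=True).size()
    if len(cells) < 4:
        raise ValueError("need both focal species crossed with both competitor species")
    spec = ModelSpec(
        response="rii",
        fixed_factors=["focal_species", "competitor"],
        interactions=[("focal_species", "competitor")],
    )
    table = fit_anova(sub, spec, ss_type=ss_type)
    fixed = table[table["term"] != "residual"]
    resid = table[table["term"] == "residual"].iloc[0]
    model_ss = fixed["ss"].sum()
    model_df = fixed["df_num"].sum()
    model_ms = model_ss / model_df
    model_f = model_ms / resid["ms"]
    model_row = pd.DataFrame(
        [
            {
                "term": "model",
                "df_num": model_df,
                "df_den": resid["df_num"],
                "ss": model_ss,
                "ms": model_ms,
                "F": model_f,
                "p": float(stats.f.sf(model_f, model_df, resid["df_num"])),
            }
        ]
    )
    return pd.concat([model_row, table], ignore_index=True)


def rii_summary(rii_values: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM of RII by response × focal species × competitor species."""
    g = rii_values.groupby(
        ["response_name", "focal_species", "competitor"], observed=True
    )["rii"]
    out = g.agg(mean="mean", sem="sem", n="size").reset_index()
    return out
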