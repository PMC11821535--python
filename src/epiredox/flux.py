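"""The ¹³C₆-glucose tracer flux-ratio panel.

After a primed-continuous U-¹³C₆-glucose infusion at isotopic steady
state, pairwise ratios of isotopologue enrichment fractions report
relative fluxes:

* V_PDH/V_CS (fraction of TCA-cycle entry fuelled by glucose) as
  m+2 acetyl-CoA / m+3 alanine, and independently as
  4,5-¹³C₂-glutamate / m+3 alanine;
* ¹³CO₂ / ¹³C₆-glucose (net glucose oxidation);
* m+3 pyruvate / ¹³C₆-glucose and m+3 lactate / ¹³C₆-glucose and their
  exchange m+3 lactate / m+3 pyruvate (glycolytic readouts);
* 4,5-¹³C₂-glutamate / m+2 acetyl-CoA (glutamine dilution: 1 means no
  net glutaminase carbon entry) and 2,3-¹³C₂-malate / 4,5-¹³C₂-glutamate
  (anaplerotic dilution further round the cycle).

Inputs are assumed natural-abundance-corrected enrichment fractions in
[0, 1]; ratios are computed per sample and then summarized per group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("epiredox")

__all__ = [
    "METABOLITES",
    "RATIO_DEFS",
    "validate_isotopologue_table",
    "compute_ratios",
    "glutamine_dilution_check",
    "group_summary",
]

#: Supported isotopologue enrichment measurements.
METABOLITES = (
    "GLUCOSE_M6",
    "ALANINE_M3",
    "PYRUVATE_M3",
    "LACTATE_M3",
    "ACETYLCOA_M2",
    "GLUTAMATE_C4C5_M2",
    "MALATE_C2C3_M2",
    "CO2_M1",
)

#: ratio name -> (numerator metabolite, denominator metabolite)
RATIO_DEFS: dict[str, tuple[str, str]] = {
    "v_pdh_vcs_acetylcoa": ("ACETYLCOA_M2", "ALANINE_M3"),
    "v_pdh_vcs_glutamate": ("GLUTAMATE_C4C5_M2", "ALANINE_M3"),
    "co2_per_glucose": ("CO2_M1", "GLUCOSE_M6"),
    "pyruvate_per_glucose": ("PYRUVATE_M3", "GLUCOSE_M6"),
    "lactate_per_glucose": ("LACTATE_M3", "GLUCOSE_M6"),
    "lactate_per_pyruvate": ("LACTATE_M3", "PYRUVATE_M3"),
    "glutamate_per_acetylcoa": ("GLUTAMATE_C4C5_M2", "ACETYLCOA_M2"),
    "malate_per_glutamate": ("MALATE_C2C3_M2", "GLUTAMATE_C4C5_M2"),
}


def validate_isotopologue_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format enrichment table: columns, panel membership,
    [0, 1] range and uniqueness per (sample, metabolite)."""
    required = {"sample_id", "mouse_id", "group", "metabolite", "enrichment"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"isotopologue table missing columns: {sorted(missing)}")
    unknown = set(table["metabolite"]) - set(METABOLITES)
    if unknown:
        raise ValueError(f"metabolites outside the supported panel: {sorted(unknown)}")
    enr = pd.to_numeric(table["enrichment"], errors="raise")
    if ((enr < 0) | (enr > 1)).any():
        raise ValueError("enrichment fractions must lie in [0, 1]")
    dup = table.duplicated(["sample_id", "metabolite"])
    if dup.any():
        raise ValueError(
            f"duplicate (sample, metabolite) rows: "
            f"{table.loc[dup, ['sample_id', 'metabolite']].values.tolist()}"
        )
    return table


def compute_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample flux-ratio panel from a long enrichment table.

    Missing metabolites or exactly-zero denominators leave that ratio NaN
    (flagged absent/undefined, never coerced to zero); values may exceed 1
    under measurement noise and are not capped.
    """
    validate_isotopologue_table(table)
    wide = table.pivot(index="sample_id", columns="metabolite", values="enrichment")
    meta = table.drop_duplicates("sample_id").set_index("sample_id")[["mouse_id", "group"]]
    out = meta.loc[wide.index].copy()
    n_undefined = 0
    for name, (num, den) in RATIO_DEFS.items():
        if num not in wide.columns or den not in wide.columns:
            out[name] = np.nan
            continue
        denominator = wide[den].astype(float)
        numerator = wide[num].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = numerator / denominator
        undefined = (denominator == 0) | denominator.isna() | numerator.isna()
        values[undefined] = np.nan
        n_undefined += int(undefined.sum())
        out[name] = values
    if n_undefined:
        logger.info("compute_ratios: %d ratio values undefined (zero/missing "
                    "denominator)", n_undefined)
    return out.reset_index()


def glutamine_dilution_check(ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-sample glutamine-dilution fraction = 1 - glutamate/acetyl-CoA.

    Near 0 means negligible net carbon flow through glutaminase; the
    metformin regime sits around 0.10-0.15.  Noisy over-unity input ratios
    give small negative dilutions, reported with a warning.
    """
    if "glutamate_per_acetylcoa" not in ratios.columns:
        raise ValueError("ratios table lacks glutamate_per_acetylcoa")
    out = ratios.copy()
    out["glutamine_dilution"] = 1.0 - out["glutamate_per_acetylcoa"]
    over = out["glutamine_dilution"] < 0
    if over.any():
        logger.warning(
            "glutamine dilution: %d samples with over-unity glutamate/acetyl-CoA "
            "(negative dilution, measurement noise)", int(over.sum()),
        )
    return out


def group_summary(
    ratios: pd.DataFrame,
    ratio_names: "list[str] | None" = None,
    control: str = "CONTROL",
):
    """Per-group mean, s.d. and n for each ratio, plus one-way ANOVA with
    comparisons vs control on per-mouse values.

    Groups with n < 2 are excluded with a warning.  Returns
    (summary DataFrame, comparisons DataFrame).
    """
    from .stats import anova_vs_control

    ratio_names = ratio_names or [c for c in RATIO_DEFS if c in ratios.columns]
    sizes = ratios.groupby("group")["sample_id"].count()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("group_summary: excluding groups with n<2: %s", small)
    data = ratios[~ratios["group"].isin(small)]
    if data["group"].nunique() < 2:
        raise ValueError("group summary needs >=2 groups with n>=2")
    if control not in set(data["group"]):
        raise ValueError(f"control group {control!r} absent")

    summary_rows, comparison_rows = [], []
    for name in ratio_names:
        sub = data.dropna(subset=[name])
        for group, vals in sub.groupby("group")[name]:
            summary_rows.append(
                {"ratio": name, "group": group, "mean": vals.mean(),
                 "sd": vals.std(ddof=1), "n": len(vals)}
            )
        groups = {
            g: {m: v[name].to_numpy() for m, v in gsub.groupby("mouse_id")}
            for g, gsub in sub.groupby("group")
        }
        if len(groups) >= 2 and all(len(u) >= 2 for u in groups.values()):
            anova, comps = anova_vs_control(groups, control_label=control)
            for _, row in comps.iterrows():
                comparison_rows.append(
                    {"ratio": name, "comparison": row["comparison"],
                     "t": row["t"], "p_raw": row["p_raw"],
                     "p_holm": row["p_holm"], "anova_F": anova.statistic,
                     "anova_p": anova.p_value}
                )
    return pd.DataFrame(summary_rows), pd.DataFrame(comparison_rows)
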