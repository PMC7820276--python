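"""Derived physiological, histological and qPCR indices.

Scalar formulas used throughout the study's phenotype readouts:
pulmonary artery systolic pressure from the tricuspid jet (4V^2 + RAP),
percent medial wall thickness, perivascular fibrosis index,
PCNA-positive cell percentage, relative qPCR quantification by the
2^-ddCt method, percent change of group means relative to the untreated
disease group, and the Mann-Whitney U group comparison with the
three-symbol significance annotation (* vs control, $ vs MCT+Saline,
# vs MCT+UCB).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "GroupComparisonResult",
    "percent_change",
    "pasp_from_tr_velocity",
    "medial_wall_thickness_pct",
    "fibrosis_index",
    "positive_cell_pct",
    "ddct_fold_change",
    "qpcr_fold_changes",
    "mann_whitney_u",
    "annotate_significance",
    "group_summary",
]

#: symbol per reference group in the stacked significance annotation
REFERENCE_SYMBOLS = {"CON": "*", "MCT+Saline": "$", "MCT+UCB": "#"}


def percent_change(reference_mean: float, treated_mean: float) -> float:
    """Signed percent change of ``treated`` relative to ``reference``.

    Negative values are reductions, positive values increases; e.g. the
    published 35.08% TR-max-PG reduction is percent_change(61.24, 39.76)
    = -35.08.
    """
    if reference_mean == 0:
        raise ValueError("reference mean must be non-zero")
    return 100.0 * (treated_mean - reference_mean) / reference_mean


def pasp_from_tr_velocity(v_max: float, rap: float) -> float:
    """Pulmonary artery systolic pressure: 4 V^2 + right atrial pressure.

    ``v_max`` is the maximal tricuspid regurgitant jet velocity (m/s),
    ``rap`` the right atrial pressure (mmHg, supplied explicitly).
    """
    if v_max < 0:
        raise ValueError("velocity must be non-negative")
    return 4.0 * v_max ** 2 + rap


def medial_wall_thickness_pct(medial_thickness: float,
                              external_diameter: float) -> float:
    """Percent medial wall thickness: (thickness x 2) / diameter x 100."""
    if not 0 < 2.0 * medial_thickness <= external_diameter:
        raise ValueError(
            "need 0 < 2*medial_thickness <= external_diameter"
        )
    return medial_thickness * 2.0 / external_diameter * 100.0


def fibrosis_index(fibrotic_area: float, short_vessel_diameter: float) -> float:
    """Perivascular fibrosis: fibrotic area / short vessel diameter (um)."""
    if short_vessel_diameter <= 0:
        raise ValueError("short vessel diameter must be positive")
    if fibrotic_area < 0:
        raise ValueError("fibrotic area must be non-negative")
    return fibrotic_area / short_vessel_diameter


def positive_cell_pct(positive: int, total: int) -> float:
    """Percentage of marker-positive cells among total cells."""
    if total <= 0:
        raise ValueError("total cell count must be positive")
    if not 0 <= positive <= total:
        raise ValueError("positive count must lie in [0, total]")
    return 100.0 * positive / total


def ddct_fold_change(ct_target: float, ct_reference: float,
                     calibrator_dct: float) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference gene); ddCt = dCt - calibrator
    (the mean dCt of the control group); fold change = 2^-ddCt.
    """
    for ct in (ct_target, ct_reference, calibrator_dct):
        if not np.isfinite(ct):
            raise ValueError("non-finite Ct value")
    ddct = (ct_target - ct_reference) - calibrator_dct
    return float(2.0 ** (-ddct))


def qpcr_fold_changes(records: pd.DataFrame, control_group: str = "CON",
                      target_col: str = "ct_target",
                      reference_col: str = "ct_reference",
                      group_col: str = "group") -> pd.DataFrame:
    """Per-sample 2^-ddCt fold changes, control-group mean scaled to 1.

    ``records`` has one row per sample with target and reference-gene
    (beta-actin) Ct values.  The calibrator is the control group's mean
    dCt; fold changes are then rescaled so the control-group mean fold
    change is exactly 1.
    """
    df = records.copy()
    if not np.isfinite(df[[target_col, reference_col]].to_numpy()).all():
        raise ValueError("non-finite Ct value")
    df["dct"] = df[target_col] - df[reference_col]
    control = df[df[group_col] == control_group]
    if control.empty:
        raise ValueError(f"no rows for control group {control_group!r}")
    calibrator = control["dct"].mean()
    df["fold_change"] = 2.0 ** (-(df["dct"] - calibrator))
    df["fold_change"] /= df.loc[df[group_col] == control_group,
                                "fold_change"].mean()
    return df


@dataclass
class GroupComparisonResult:
    variable: str
    group_a: str
    group_b: str
    u: float
    p_value: float
    symbols: str = ""


def mann_whitney_u(a, b, exact: bool | None = None, variable: str = "",
                   group_a: str = "a", group_b: str = "b"
                   ) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test with average ranks for ties.

    ``exact=None`` selects the exact enumeration null when the combined
    sample size is at most 12 and the data are tie-free, and the normal
    approximation with tie correction (and continuity correction)
    otherwise — the study's 7 vs 7 groups fall in the approximate
    regime.  The reported U is the statistic of group ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 observations per group")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if np.ptp(combined) == 0:
        warnings.warn("all values identical in both groups; p = 1",
                      RuntimeWarning, stacklevel=2)
        return GroupComparisonResult(variable, group_a, group_b,
                                     a.size * b.size / 2.0, 1.0)
    if exact is None:
        exact = (a.size + b.size) <= 12 and not has_ties
    method = "exact" if (exact and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparisonResult(variable, group_a, group_b,
                                 float(res.statistic),
                                 float(min(res.pvalue, 1.0)))


def annotate_significance(p_value: float, reference_group: str,
                          symbols: dict | None = None) -> str:
    """Stacked significance symbols for one comparison.

    The symbol identifies the reference group (* control, $ untreated
    disease, # UCB arm) and is repeated once, twice or three times for
    p < 0.05, < 0.01 and < 0.001.
    """
    symbols = symbols or REFERENCE_SYMBOLS
    if reference_group not in symbols:
        raise ValueError(f"unknown reference group {reference_group!r}")
    sym = symbols[reference_group]
    if p_value < 0.001:
        return sym * 3
    if p_value < 0.01:
        return sym * 2
    if p_value < 0.05:
        return sym
    return ""


def group_summary(table: pd.DataFrame, variables, group_col: str = "group",
                  disease_group: str = "MCT+Saline",
                  references: tuple = ("CON", "MCT+Saline", "MCT+UCB"),
                  exact: bool | None = None) -> pd.DataFrame:
    """Per-variable group means +/- SD, percent changes and annotations.

    For every (variable, group) the summary lists mean and SD, the
    percent change relative to the untreated disease group, and the
    stacked three-symbol annotation from Mann-Whitney comparisons with
    each reference group.
    """
    rows = []
    for var in variables:
        disease_mean = table.loc[table[group_col] == disease_group, var].mean()
        for group, sub in table.groupby(group_col, sort=False):
            vals = sub[var].to_numpy(dtype=float)
            ann = ""
            for ref in references:
                if ref == group:
                    continue
                ref_vals = table.loc[table[group_col] == ref, var].to_numpy()
                if ref_vals.size < 3:
                    continue
                res = mann_whitney_u(vals, ref_vals, exact=exact,
                                     variable=var, group_a=str(group),
                                     group_b=ref)
                ann += annotate_significance(res.p_value, ref)
            pct = (np.nan if group == disease_group or disease_mean == 0
                   else percent_change(disease_mean, vals.mean()))
            rows.append({"variable": var, "group": group,
                         "mean": vals.mean(), "sd": vals.std(ddof=1),
                         "pct_change_vs_disease": pct, "annotation": ann})
    return pd.DataFrame(rows)
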