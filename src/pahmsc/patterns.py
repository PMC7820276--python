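"""Pattern grouping (G1-G8), reversion subsets and predominance selection.

Every gene called a DEG in at least one of the four study comparisons is
assigned an up/down/none call per comparison; the disease call (MCT vs
CON) and a consensus treatment call across the three MSC arms place the
gene on a 3x3 pattern grid whose cells (minus none/none) are labelled
G1-G8.  The fixed anchors are G1 = disease-up & treatment-down,
G4 = disease-down & treatment-up and G2 = disease-unchanged &
treatment-up; the remaining labels follow a documented default map and
are configurable.

From G1/G4 the reversion subsets are the genes a given MSC arm moves
back toward control, and the predominance selection keeps those with a
significantly stronger reversion by UCB than by both AD and BM in the
head-to-head contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degstats import DegThresholds

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GROUP_MAP",
    "DEFAULT_MSC_COMPARISONS",
    "ReversionSelection",
    "classify_patterns",
    "select_reversed",
    "select_predominant",
    "export_heatmap_matrix",
]

#: (disease call, consensus treatment call) -> group label.  G1, G2 and
#: G4 are fixed by their definitions; the other five cells follow this
#: default and may be remapped.
DEFAULT_GROUP_MAP = {
    ("up", "down"): "G1",
    ("none", "up"): "G2",
    ("none", "down"): "G3",
    ("down", "up"): "G4",
    ("up", "up"): "G5",
    ("up", "none"): "G6",
    ("down", "down"): "G7",
    ("down", "none"): "G8",
}

DEFAULT_MSC_COMPARISONS = {"AD": "AD/MCT", "BM": "BM/MCT", "UCB": "UCB/MCT"}
DEFAULT_MCT_COMPARISON = "MCT/CON"

_GROUP_ORDER = ["G1", "G2", "G3", "G4", "G5", "G6", "G7", "G8"]
_CALL_CODE = {"up": 0, "none": 1, "down": 2}


def _frame(result) -> pd.DataFrame:
    f = getattr(result, "frame", result)
    return f.set_index("gene_id") if "gene_id" in f.columns else f


def _calls(frame: pd.DataFrame) -> pd.Series:
    call = np.where(
        frame["is_deg"],
        np.where(frame["direction"] == "up", "up", "down"),
        "none",
    )
    return pd.Series(call, index=frame.index)


def _consensus(msc_calls: pd.DataFrame) -> pd.Series:
    """'down' if >= 1 arm calls down and none up; symmetric for 'up'.

    A direct up/down conflict between arms yields NaN (unclassified).
    """
    any_up = (msc_calls == "up").any(axis=1)
    any_down = (msc_calls == "down").any(axis=1)
    out = pd.Series("none", index=msc_calls.index)
    out[any_up & ~any_down] = "up"
    out[any_down & ~any_up] = "down"
    out[any_up & any_down] = np.nan
    return out


def classify_patterns(results: dict,
                      mct_comparison: str = DEFAULT_MCT_COMPARISON,
                      msc_comparisons: dict | None = None,
                      group_map: dict | None = None) -> pd.DataFrame:
    """Assign every DEG to one of the pattern groups G1-G8.

    ``results`` maps comparison names to fitted results (or their
    frames); all four comparisons must be present and cover the same
    genes.  Genes with no DEG call anywhere are excluded; genes whose
    MSC arms directly conflict (one up, one down) are kept with
    ``group = NaN`` and logged.  Within each group rows are sorted by
    the up/none/down pattern over the four comparisons, then by
    decreasing disease |log2 fold change|.
    """
    msc_comparisons = msc_comparisons or DEFAULT_MSC_COMPARISONS
    group_map = group_map or DEFAULT_GROUP_MAP
    needed = [mct_comparison] + list(msc_comparisons.values())
    missing = [c for c in needed if c not in results]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")

    frames = {c: _frame(results[c]) for c in needed}
    genes = frames[mct_comparison].index
    for c, f in frames.items():
        if not genes.equals(f.index):
            if set(genes) != set(f.index):
                raise ValueError(f"comparison {c!r} scores a different gene set")
            frames[c] = f.loc[genes]

    mct_call = _calls(frames[mct_comparison])
    msc_calls = pd.DataFrame(
        {msc: _calls(frames[comp]) for msc, comp in msc_comparisons.items()}
    )
    consensus = _consensus(msc_calls)

    any_deg = frames[mct_comparison]["is_deg"].copy()
    for comp in msc_comparisons.values():
        any_deg |= frames[comp]["is_deg"]

    out = pd.DataFrame({"gene_id": genes, "mct_call": mct_call.values})
    for msc in msc_comparisons:
        out[f"{msc.lower()}_call"] = msc_calls[msc].values
    out["msc_consensus"] = consensus.values
    out[f"lmr_{mct_comparison}"] = frames[mct_comparison]["lmr"].values
    for msc, comp in msc_comparisons.items():
        out[f"lmr_{comp}"] = frames[comp]["lmr"].values
    out = out[any_deg.values].reset_index(drop=True)

    def label(row):
        if pd.isna(row["msc_consensus"]):
            return np.nan
        key = (row["mct_call"], row["msc_consensus"])
        return group_map.get(key, np.nan)

    out["group"] = out.apply(label, axis=1)
    n_unclassified = int(out["group"].isna().sum())
    if n_unclassified:
        logger.info("%d DEG(s) left unclassified (conflicting or unmapped "
                    "patterns)", n_unclassified)

    # sort: group order, then up/none/down pattern over the four
    # comparisons, then decreasing disease |lmr|
    call_cols = ["mct_call"] + [f"{m.lower()}_call" for m in msc_comparisons]
    out["_grp"] = out["group"].map(
        {g: i for i, g in enumerate(_GROUP_ORDER)}).fillna(len(_GROUP_ORDER))
    for c in call_cols:
        out[f"_{c}"] = out[c].map(_CALL_CODE)
    out["_mag"] = -out[f"lmr_{mct_comparison}"].abs()
    out = out.sort_values(
        ["_grp"] + [f"_{c}" for c in call_cols] + ["_mag"],
        kind="mergesort",
    ).reset_index(drop=True)
    return out.drop(columns=[c for c in out.columns if c.startswith("_")])


@dataclass
class ReversionSelection:
    """Genes of one source group reverted by one MSC arm."""

    source_group: str  # "G1" or "G4"
    msc: str
    reversed_gene_ids: list = field(default_factory=list)
    predominant_gene_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.source_group not in ("G1", "G4"):
            raise ValueError("source_group must be 'G1' or 'G4'")
        if not set(self.predominant_gene_ids) <= set(self.reversed_gene_ids):
            raise ValueError("predominant genes must be a subset of reversed")


def select_reversed(assignments: pd.DataFrame, msc: str) -> dict:
    """Reversion subsets per source group for one MSC arm.

    From G1 (disease-up) keep genes the arm calls down; from G4
    (disease-down) keep genes the arm calls up.  Returns
    ``{"G1": ReversionSelection, "G4": ReversionSelection}``.
    """
    call_col = f"{msc.lower()}_call"
    if call_col not in assignments.columns:
        raise ValueError(f"unknown MSC label {msc!r}")
    out = {}
    for group, wanted in (("G1", "down"), ("G4", "up")):
        members = assignments[assignments["group"] == group]
        reverted = members[members[call_col] == wanted]
        out[group] = ReversionSelection(
            group, msc, list(reverted["gene_id"]))
    return out


def select_predominant(reversed_sel: ReversionSelection,
                       head_to_head: dict,
                       thresholds: DegThresholds | None = None
                       ) -> ReversionSelection:
    """Keep reverted genes whose reversion is strongest for this arm.

    ``head_to_head`` maps comparison names (e.g. ``"UCB/AD"``,
    ``"UCB/BM"``) to fitted results of the same DEG machinery with the
    arm of interest as the test condition.  A gene is kept when it is
    significant in *every* head-to-head comparison with the sign
    matching the reversion direction (G1: the arm pushes lower, so
    lmr < 0; G4: lmr > 0).
    """
    if not head_to_head:
        raise ValueError("no head-to-head comparison tables supplied")
    thresholds = thresholds or DegThresholds()
    frames = {name: _frame(res) for name, res in head_to_head.items()}
    want_negative = reversed_sel.source_group == "G1"
    kept = []
    for gene in reversed_sel.reversed_gene_ids:
        ok = True
        for name, f in frames.items():
            if gene not in f.index:
                raise ValueError(f"gene {gene!r} missing from {name!r}")
            row = f.loc[gene]
            significant = (row["q"] <= thresholds.fdr
                           and abs(row["lmr"]) >= thresholds.lmr)
            sign_ok = row["lmr"] < 0 if want_negative else row["lmr"] > 0
            if not (significant and sign_ok):
                ok = False
                break
        if ok:
            kept.append(gene)
    return ReversionSelection(reversed_sel.source_group, reversed_sel.msc,
                              list(reversed_sel.reversed_gene_ids), kept)


def export_heatmap_matrix(assignments: pd.DataFrame,
                          comparisons: list | None = None) -> pd.DataFrame:
    """Ordered genes x comparisons matrix of log2 fold changes.

    Rows keep the group-sorted order of ``classify_patterns`` (grouped
    G1 onward); a ``group`` column records the group boundaries.  Column
    order equals the comparison order given.
    """
    if assignments.empty:
        raise ValueError("no assignments to export")
    if comparisons is None:
        comparisons = [c[len("lmr_"):] for c in assignments.columns
                       if c.startswith("lmr_")]
    classified = assignments[assignments["group"].notna()]
    out = pd.DataFrame({"gene_id": classified["gene_id"],
                        "group": classified["group"]})
    for comp in comparisons:
        col = f"lmr_{comp}"
        if col not in classified.columns:
            raise ValueError(f"missing fold changes for comparison {comp!r}")
        out[comp] = classified[col].values
    return out.reset_index(drop=True)
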