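"""Synthetic data emulating the 5-condition x 2-replicate microarray study.

The generator plants known disease (MCT) up/down shifts on a random gene
subset and, per MSC treatment arm, moves a nested subset of those genes
back toward baseline (full or partial reversion).  The defaults mirror
the study design: conditions CON, MCT(+Saline), MCT+AD, MCT+BM, MCT+UCB
with two biological replicates each, independent Gaussian noise on the
log2 scale, and a UCB arm that reverts a strict superset of the genes
reverted by the AD and BM arms.  Ground truth is returned alongside the
matrix so recovery can be scored exactly.

Also generates the companion fixtures the downstream stages consume:
gene-set libraries (GMT), interaction tables (SIF) and phenotype tables
seeded with the published echocardiographic group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .enrichment import GeneSetLibrary
from .matrix import ExpressionMatrix
from .network import InteractionSet

__all__ = [
    "ReversionProfile",
    "SimulationConfig",
    "generate_expression",
    "generate_phenotypes",
    "generate_gene_sets",
    "generate_interactions",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_SD",
    "PHENOTYPE_GROUPS",
]


@dataclass(frozen=True)
class ReversionProfile:
    """Per-arm fractions of planted genes reverted fully / partially."""

    full: float = 0.0
    partial: float = 0.0

    def __post_init__(self):
        if not (0 <= self.full <= 1 and 0 <= self.partial <= 1):
            raise ValueError("reversion fractions must lie in [0, 1]")
        if self.full + self.partial > 1:
            raise ValueError("full + partial reversion fractions exceed 1")


def _default_reversion():
    # UCB reverts a strict superset of the genes reverted by AD/BM
    # (nested prefix assignment, see generate_expression).
    return {
        "AD": ReversionProfile(full=0.40, partial=0.10),
        "BM": ReversionProfile(full=0.35, partial=0.10),
        "UCB": ReversionProfile(full=0.70, partial=0.10),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic expression study.

    Conditions are ordered: first the control, second the untreated
    disease condition; the rest are treatment arms (all MCT-exposed).
    ``effect_size`` is the planted disease shift in log2 units;
    ``noise_sd`` is the per-measurement Gaussian noise on the log2
    scale.
    """

    n_genes: int = 1000
    conditions: tuple = ("CON", "MCT", "AD", "BM", "UCB")
    replicates_per_condition: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    effect_size: float = 2.0
    fraction_mct_up: float = 0.10
    fraction_mct_down: float = 0.10
    reversion_profile: dict = field(default_factory=_default_reversion)
    partial_range: tuple = (0.3, 0.7)  # x effect_size
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.conditions) < 2:
            raise ValueError("need a control and a disease condition")
        if self.replicates_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")
        for frac in (self.fraction_mct_up, self.fraction_mct_down):
            if not 0 <= frac <= 1:
                raise ValueError("planted fractions must lie in [0, 1]")
        if self.fraction_mct_up + self.fraction_mct_down > 1:
            raise ValueError("planted fractions sum above 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_sd < 0 or self.effect_size < 0:
            raise ValueError("baseline_sd and effect_size must be >= 0")
        prof = {}
        for msc in self.conditions[2:]:
            p = self.reversion_profile.get(msc, ReversionProfile())
            if isinstance(p, dict):
                p = ReversionProfile(**p)
            prof[msc] = p
        self.reversion_profile = prof

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["conditions"] = list(self.conditions)
        data["partial_range"] = list(self.partial_range)
        data["reversion_profile"] = {
            m: {"full": p.full, "partial": p.partial}
            for m, p in self.reversion_profile.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        if "partial_range" in data:
            data["partial_range"] = tuple(data["partial_range"])
        return cls(**data)


def generate_expression(config: SimulationConfig):
    """Simulate a log2 expression matrix plus its planted ground truth.

    Returns ``(matrix, truth)`` where ``truth`` is a DataFrame with one
    row per gene: ``gene_id``, ``mct_direction`` (up/down/null),
    ``reverted_by`` (comma-joined arm labels) and a ``rev_<ARM>``
    column per arm holding the planted reversion magnitude (log2 units).
    Identical configs (same seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(5, len(str(n)))
    gene_ids = [f"g{i:0{width}d}" for i in range(n)]

    if config.effect_size == 0:
        n_up = n_down = 0
    else:
        n_up = int(round(config.fraction_mct_up * n))
        n_down = int(round(config.fraction_mct_down * n))
    perm = rng.permutation(n)
    up_idx = perm[:n_up]
    down_idx = perm[n_up:n_up + n_down]
    direction = np.zeros(n)
    direction[up_idx] = 1.0
    direction[down_idx] = -1.0

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    # nested prefix assignment over a single shuffled order of planted
    # genes makes the UCB-reverted set a superset of the AD/BM sets
    # whenever its fractions are larger
    planted = np.concatenate([up_idx, down_idx])
    planted_order = rng.permutation(planted)
    n_planted = planted_order.size
    rev_mag = {}
    for msc in config.conditions[2:]:
        prof = config.reversion_profile[msc]
        n_full = int(round(prof.full * n_planted))
        n_part = int(round(prof.partial * n_planted))
        mag = np.zeros(n)
        mag[planted_order[:n_full]] = config.effect_size
        lo, hi = config.partial_range
        mag[planted_order[n_full:n_full + n_part]] = (
            rng.uniform(lo, hi, size=n_part) * config.effect_size
        )
        rev_mag[msc] = mag

    reps = config.replicates_per_condition
    columns, means = [], []
    for ci, cond in enumerate(config.conditions):
        if ci == 0:
            mu = baseline
        else:
            mu = baseline + direction * config.effect_size
            if ci >= 2:
                mu = mu - direction * rev_mag[cond]
        for r in range(reps):
            columns.append(f"{cond}_{r + 1}")
            means.append(mu)
    mean_matrix = np.column_stack(means)
    values = mean_matrix + rng.normal(0.0, config.noise_sd, size=mean_matrix.shape)

    condition_of = {f"{cond}_{r + 1}": cond
                    for cond in config.conditions for r in range(reps)}
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=columns), condition_of
    )

    mct_dir = np.where(direction > 0, "up", np.where(direction < 0, "down", "null"))
    truth = pd.DataFrame({"gene_id": gene_ids, "mct_direction": mct_dir})
    for msc in config.conditions[2:]:
        truth[f"rev_{msc}"] = rev_mag[msc]
    truth["reverted_by"] = [
        ",".join(m for m in config.conditions[2:] if rev_mag[m][i] > 0)
        for i in range(n)
    ]
    return matrix, truth


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

PHENOTYPE_GROUPS = ("CON", "MCT+Saline", "MCT+AD", "MCT+BM", "MCT+UCB")

#: Echocardiographic group means seeded from the published values
#: (TR max PG in mmHg, PVAT in ms, TAPSE in mm, RV FAC in %); histology
#: and cell-count means are realistic values for <120 um pulmonary
#: arteries in this model.
DEFAULT_GROUP_MEANS = {
    "CON": {"TR_max_PG": 11.95, "PVAT": 18.99, "TAPSE": 2.80, "RV_FAC": 46.0,
            "medial_thickness": 8.0, "external_diameter": 100.0,
            "fibrotic_area": 300.0, "short_vessel_diameter": 60.0,
            "pcna_positive": 5.0, "total_cells": 100.0},
    "MCT+Saline": {"TR_max_PG": 61.24, "PVAT": 12.65, "TAPSE": 1.71,
                   "RV_FAC": 24.95, "medial_thickness": 28.0,
                   "external_diameter": 100.0, "fibrotic_area": 1500.0,
                   "short_vessel_diameter": 60.0, "pcna_positive": 40.0,
                   "total_cells": 100.0},
    "MCT+AD": {"TR_max_PG": 52.83, "PVAT": 16.62, "TAPSE": 2.19,
               "RV_FAC": 33.33, "medial_thickness": 20.0,
               "external_diameter": 100.0, "fibrotic_area": 1000.0,
               "short_vessel_diameter": 60.0, "pcna_positive": 25.0,
               "total_cells": 100.0},
    "MCT+BM": {"TR_max_PG": 43.93, "PVAT": 15.26, "TAPSE": 2.16,
               "RV_FAC": 42.34, "medial_thickness": 18.0,
               "external_diameter": 100.0, "fibrotic_area": 900.0,
               "short_vessel_diameter": 60.0, "pcna_positive": 22.0,
               "total_cells": 100.0},
    "MCT+UCB": {"TR_max_PG": 39.76, "PVAT": 14.22, "TAPSE": 2.66,
                "RV_FAC": 35.94, "medial_thickness": 14.0,
                "external_diameter": 100.0, "fibrotic_area": 600.0,
                "short_vessel_diameter": 60.0, "pcna_positive": 12.0,
                "total_cells": 100.0},
}

#: Per-variable SDs; echo SDs follow the published per-group values
#: closely enough at one shared value per variable.
DEFAULT_SD = {
    "TR_max_PG": 4.31, "PVAT": 1.32, "TAPSE": 0.15, "RV_FAC": 4.45,
    "medial_thickness": 2.0, "external_diameter": 8.0,
    "fibrotic_area": 120.0, "short_vessel_diameter": 5.0,
    "pcna_positive": 4.0, "total_cells": 10.0,
}

_COUNT_VARS = ("pcna_positive", "total_cells")


def generate_phenotypes(group_means: dict | None = None,
                        sd: dict | None = None,
                        n_per_group: int = 7,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate a per-animal phenotype table (one row per animal).

    Gaussian per-variable noise around per-group means; measurement
    positivity and consistency constraints (external diameter at least
    twice the medial thickness, positive cells bounded by total cells)
    are enforced by clipping.  ``sd=0`` for a variable makes every
    animal equal its group mean exactly.  The tricuspid jet velocity
    ``V_tr`` is derived from TR max PG via the 4V^2 relation.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    group_means = group_means or DEFAULT_GROUP_MEANS
    sd = sd or DEFAULT_SD
    if any(v < 0 for v in sd.values()):
        raise ValueError("sd values must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in group_means:
        means = group_means[group]
        for i in range(n_per_group):
            row = {"animal_id": f"{group}_{i + 1}", "group": group}
            for var, mu in means.items():
                s = sd.get(var, 0.0)
                val = mu if s == 0 else rng.normal(mu, s)
                val = max(val, 1e-6)
                if var in _COUNT_VARS and s > 0:
                    val = float(max(round(val), 1))
                row[var] = val
            if "external_diameter" in row and "medial_thickness" in row:
                row["external_diameter"] = max(
                    row["external_diameter"], 2.0 * row["medial_thickness"]
                )
            if "pcna_positive" in row and "total_cells" in row:
                row["total_cells"] = max(row["total_cells"], 1.0)
                row["pcna_positive"] = min(row["pcna_positive"],
                                           row["total_cells"])
            if "TR_max_PG" in row:
                row["V_tr"] = float(np.sqrt(row["TR_max_PG"] / 4.0))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene sets and interactions
# ---------------------------------------------------------------------------

def generate_gene_sets(truth: pd.DataFrame, n_terms: int = 50,
                       term_size_range: tuple = (10, 30),
                       enriched_terms: int = 5, seed: int = 0,
                       purity: float = 0.9) -> GeneSetLibrary:
    """Gene-set library with ``enriched_terms`` sets biased to planted DEGs.

    Enriched sets draw a ``purity`` fraction of their members from the
    planted (non-null) genes; remaining sets are uniform draws from all
    genes.
    """
    if enriched_terms > n_terms:
        raise ValueError("enriched_terms cannot exceed n_terms")
    lo, hi = term_size_range
    all_genes = truth["gene_id"].to_numpy()
    if hi > all_genes.size:
        raise ValueError("term sizes cannot exceed the number of genes")
    planted = truth.loc[truth["mct_direction"] != "null", "gene_id"].to_numpy()
    rng = np.random.default_rng(seed)
    terms, names = {}, {}
    for i in range(n_terms):
        tid = f"T{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        if i < enriched_terms and planted.size:
            n_from_planted = min(int(np.ceil(purity * size)), planted.size)
            members = set(rng.choice(planted, n_from_planted, replace=False))
            rest = np.setdiff1d(all_genes, np.array(sorted(members)))
            members |= set(rng.choice(rest, size - len(members), replace=False))
            names[tid] = "planted-enriched"
        else:
            members = set(rng.choice(all_genes, size, replace=False))
            names[tid] = "uniform"
        terms[tid] = frozenset(members)
    return GeneSetLibrary(terms, names)


def generate_interactions(gene_ids, edge_density: float,
                          seed: int = 0) -> InteractionSet:
    """Erdos-Renyi undirected interaction set over ``gene_ids``."""
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("empty gene list")
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if edge_density >= 1 or rng.random() < edge_density:
                edges.append((gene_ids[i], "pp", gene_ids[j]))
    return InteractionSet.from_edges(edges, source="synthetic")
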