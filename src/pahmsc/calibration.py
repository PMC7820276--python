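"""End-to-end calibration runs on synthetic data.

Two study-condition benchmarks drive the validation of the DEG
procedure: the realized false-discovery proportion on pure-null
matrices, and direction-correct recovery of planted disease genes at
the calibration effect size.  Both run the full pipeline (simulation,
quantile normalization, integrative DEG statistic) from scratch.
"""

from __future__ import annotations

import numpy as np

from .degstats import ComparisonSpec, DegThresholds, run_comparison
from .preprocess import quantile_normalize
from .simulate import SimulationConfig, generate_expression

__all__ = ["null_fdp_simulation", "planted_recovery"]

_MCT_VS_CON = ComparisonSpec("MCT/CON", "MCT", "CON")


def _child_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32) % np.uint32(2**31)


def null_fdp_simulation(n_runs: int = 200, n_genes: int = 1000,
                        seed: int = 1,
                        thresholds: DegThresholds | None = None) -> dict:
    """Mean realized false-discovery proportion on null matrices.

    Each run simulates a 5-condition x 2-replicate matrix with no
    planted effect, quantile-normalizes it, runs the integrative DEG
    procedure for the disease-vs-control contrast at default thresholds
    and records the false-discovery proportion among called DEGs
    (0 when nothing is called).  Returns the mean over runs, its
    Monte-Carlo standard error and the per-run values.
    """
    thresholds = thresholds or DegThresholds()
    fdps = []
    for child in _child_seeds(seed, n_runs):
        config = SimulationConfig(n_genes=n_genes, effect_size=0.0,
                                  seed=int(child))
        matrix, truth = generate_expression(config)
        matrix = quantile_normalize(matrix)
        res = run_comparison(matrix, _MCT_VS_CON, thresholds=thresholds,
                             seed=int(child))
        called = res.frame["is_deg"].to_numpy()
        if called.any():
            null_gene = (truth["mct_direction"] == "null").to_numpy()
            fdps.append(float((called & null_gene).sum() / called.sum()))
        else:
            fdps.append(0.0)
    fdps = np.asarray(fdps)
    se = float(fdps.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else 0.0
    return {
        "mean_fdp": float(fdps.mean()),
        "se": se,
        "n_runs": n_runs,
        "nominal": thresholds.fdr,
        "fdps": fdps,
    }


def planted_recovery(n_genes: int = 1000, effect_size: float = 2.0,
                     noise_sd: float = 0.3, seed: int = 7,
                     thresholds: DegThresholds | None = None) -> dict:
    """Recovery of planted disease genes at the calibration settings.

    Simulates a matrix with the stated planted effect, runs the
    disease-vs-control contrast and scores the fraction of planted
    genes called DEGs (recovery) and the fraction of recovered genes
    whose called direction matches the planted direction.
    """
    config = SimulationConfig(n_genes=n_genes, effect_size=effect_size,
                              noise_sd=noise_sd, seed=seed)
    matrix, truth = generate_expression(config)
    matrix = quantile_normalize(matrix)
    res = run_comparison(matrix, _MCT_VS_CON, thresholds=thresholds,
                         seed=seed)
    frame = res.frame.set_index("gene_id")
    planted = truth[truth["mct_direction"] != "null"]
    called = frame.loc[planted["gene_id"], "is_deg"].to_numpy()
    direction = frame.loc[planted["gene_id"], "direction"].to_numpy()
    truth_dir = planted["mct_direction"].to_numpy()
    recovered = called
    recovery = float(recovered.mean()) if len(planted) else float("nan")
    if recovered.any():
        direction_acc = float(
            (direction[recovered] == truth_dir[recovered]).mean())
    else:
        direction_acc = float("nan")
    return {
        "recovery": recovery,
        "direction_accuracy": direction_acc,
        "n_planted": int(len(planted)),
        "n_called_overall": res.n_degs,
    }
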