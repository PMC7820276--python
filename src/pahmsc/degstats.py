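"""Integrative permutation-based differential-expression statistic.

For each two-condition comparison the procedure computes, per gene,

* a pooled-variance Student *t* statistic, and
* the log2-median-ratio (difference of group medians on the log2 scale,
  i.e. the log2 fold change of the linear-scale medians);

estimates an empirical null for each statistic by permuting the sample
labels within the comparison and pooling the permuted statistics across
all genes; smooths the pooled null with a Gaussian kernel density
estimate and reads off two-sided tail probabilities; combines the two
empirical p-values with Stouffer's method (signed z-scores, equal
weights); and converts the combined p-values into Storey q-values.

The two statistics are strongly dependent — with two replicates per
condition the median difference coincides with the mean difference, so
the t and log2-median-ratio statistics share their numerator.  The
combined z is therefore calibrated, by default, against its own pooled
permutation null (the same label splits that build the marginal nulls),
which keeps the combined p-values uniform under the null regardless of
that dependence; the independence-assuming normal closed form
``2(1 - Phi(|z|))`` remains available via ``combined_null="normal"``.
A gene is called differentially expressed when its q-value is at or
below the FDR threshold *and* its absolute log2-median-ratio is at or
above the fold-change threshold (0.58, i.e. 1.5-fold).

The entry points are the :class:`IntegrativeDEModel` /
:class:`IntegrativeDEResults` pair (statsmodels-style model object) and
the :func:`run_comparison` convenience wrapper.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .matrix import ExpressionMatrix

__all__ = [
    "ComparisonSpec",
    "DegThresholds",
    "NullModel",
    "IntegrativeDEModel",
    "IntegrativeDEResults",
    "t_statistic",
    "log2_median_ratio",
    "build_null",
    "empirical_pvalue",
    "combine_stouffer",
    "storey_qvalues",
    "run_comparison",
    "PRIMARY_COMPARISONS",
    "HEAD_TO_HEAD_COMPARISONS",
]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class ComparisonSpec:
    """A named test-vs-reference condition contrast, e.g. MCT vs CON."""

    name: str
    test_condition: str
    reference_condition: str

    def __post_init__(self):
        if self.test_condition == self.reference_condition:
            raise ValueError("test and reference conditions must differ")


#: The four contrasts of the study design: disease vs control, then each
#: MSC arm vs the untreated disease condition.
PRIMARY_COMPARISONS = (
    ComparisonSpec("MCT/CON", "MCT", "CON"),
    ComparisonSpec("AD/MCT", "AD", "MCT"),
    ComparisonSpec("BM/MCT", "BM", "MCT"),
    ComparisonSpec("UCB/MCT", "UCB", "MCT"),
)

#: Head-to-head contrasts used for the predominance selection.
HEAD_TO_HEAD_COMPARISONS = (
    ComparisonSpec("UCB/AD", "UCB", "AD"),
    ComparisonSpec("UCB/BM", "UCB", "BM"),
)


@dataclass(frozen=True)
class DegThresholds:
    """DEG calling rule: FDR <= fdr and |log2-median-ratio| >= lmr.

    The default log2-median-ratio cut of 0.58 is round(log2(1.5), 2),
    i.e. a 1.5-fold change.
    """

    fdr: float = 0.05
    lmr: float = 0.58

    def __post_init__(self):
        if self.fdr <= 0 or self.lmr <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class NullModel:
    """Pooled permutation null for one statistic, KDE-smoothed.

    ``values`` holds the statistic recomputed for every gene under every
    permutation split, pooled into one vector; ``bandwidth`` is the
    Gaussian kernel width used for tail probabilities.
    """

    kind: str  # "t" or "lmr"
    values: np.ndarray
    bandwidth: float
    n_permutations: int

    def __post_init__(self):
        if self.values.size == 0:
            raise ValueError("empty null sample")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


# ---------------------------------------------------------------------------
# per-gene statistics
# ---------------------------------------------------------------------------

def _pooled_sd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    return np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))


def _t_matrix(a: np.ndarray, b: np.ndarray, sd_floor: float = 0.0) -> np.ndarray:
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp = np.maximum(_pooled_sd(a, b), sd_floor)
    se = sp * np.sqrt(1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # degenerate zero-variance, zero-difference genes get t = 0, not NaN
    t[(se == 0) & (diff == 0)] = 0.0
    return t


def _lmr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.median(a, axis=1) - np.median(b, axis=1)


def t_statistic(a, b, sd_floor: float = 0.0) -> float:
    """Pooled-variance two-sample t (df = n_a + n_b - 2).

    Positive when ``mean(a) > mean(b)``.  The pooled standard deviation
    is floored at ``sd_floor`` so degenerate zero-variance replicate
    pairs return 0 rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per side")
    return float(_t_matrix(a[None, :], b[None, :], sd_floor)[0])


def log2_median_ratio(a, b) -> float:
    """median(a) - median(b) for log2-scale replicate values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty replicate group")
    return float(np.median(a) - np.median(b))


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _exhaustive_splits(n_a: int, n_b: int) -> list:
    """All distinct non-identity reassignments of pooled samples.

    Samples 0..n_a-1 are the observed test group.  For balanced designs
    the split and its complement give the same two-sided statistic
    magnitude, so splits are deduplicated by pinning sample 0 to the
    test side.  The observed assignment itself is excluded.
    """
    n = n_a + n_b
    observed = tuple(range(n_a))
    splits = []
    for comb in itertools.combinations(range(n), n_a):
        if comb == observed:
            continue
        if n_a == n_b and 0 not in comb:
            continue
        splits.append(comb)
    return splits


def _make_splits(n_a: int, n_b: int, n_perm: int | None, seed: int) -> list:
    if n_perm is None:
        splits = _exhaustive_splits(n_a, n_b)
        if len(splits) > 20000:
            raise ValueError("exhaustive enumeration too large; pass n_perm")
        return splits
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    return [tuple(rng.permutation(n)[:n_a]) for _ in range(n_perm)]


def _stat_for_split(x: np.ndarray, split, kind: str, sd_floor: float) -> np.ndarray:
    idx_a = np.asarray(split)
    idx_b = np.setdiff1d(np.arange(x.shape[1]), idx_a)
    if kind == "t":
        return _t_matrix(x[:, idx_a], x[:, idx_b], sd_floor)
    if kind == "lmr":
        return _lmr_matrix(x[:, idx_a], x[:, idx_b])
    raise ValueError(f"unknown statistic kind {kind!r}")


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb kernel width for a pooled null sample.

    The spread is measured on the sign-symmetrized sample (the null is
    used two-sidedly), which makes the bandwidth — and therefore the
    empirical p-values — exactly invariant under exchanging the test
    and reference labels.
    """
    x = np.asarray(x, dtype=float)
    m = x.size
    y = np.concatenate([x, -x])
    s = y.std(ddof=1) if m > 1 else 0.0
    q75, q25 = np.percentile(y, [75, 25])
    iqr = q75 - q25
    spread = min(s, iqr / 1.34) if iqr > 0 else s
    if spread <= 0:
        spread = max(abs(x).max(), 1.0)
    return float(0.9 * spread * m ** (-1 / 5))


def build_null(
    m: ExpressionMatrix,
    spec: ComparisonSpec,
    kind: str,
    n_perm: int | None = None,
    seed: int = 0,
    sd_floor: float | None = None,
    bandwidth: float | None = None,
) -> NullModel:
    """Pool permuted statistics across all genes into one empirical null.

    With ``n_perm=None`` the sample-label reassignments within the two
    compared conditions are enumerated exhaustively (a 2v2 design has
    only a handful of distinct splits; resolution comes from pooling
    across genes).  Otherwise ``n_perm`` random label shuffles are drawn.
    """
    cols_a = m.samples_for(spec.test_condition)
    cols_b = m.samples_for(spec.reference_condition)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 samples per condition for permutation")
    x = m.values[cols_a + cols_b].to_numpy(dtype=float)
    if sd_floor is None:
        sd_floor = default_sd_floor(x[:, : len(cols_a)], x[:, len(cols_a):]) \
            if kind == "t" else 0.0
    splits = _make_splits(len(cols_a), len(cols_b), n_perm, seed)
    pooled = np.concatenate(
        [_stat_for_split(x, s, kind, sd_floor) for s in splits]
    )
    pooled = pooled[np.isfinite(pooled)]
    if bandwidth is None:
        bandwidth = silverman_bandwidth(pooled)
    return NullModel(kind, pooled, bandwidth, len(splits))


def default_sd_floor(a: np.ndarray, b: np.ndarray) -> float:
    """Variance floor: 1st percentile of gene-wise pooled SDs (>= 1e-8)."""
    sp = _pooled_sd(a, b)
    return float(max(np.percentile(sp, 1), 1e-8))


# ---------------------------------------------------------------------------
# empirical p-values, combination, FDR
# ---------------------------------------------------------------------------

def empirical_pvalue(stat, null: NullModel):
    """Two-sided tail probability of the KDE-smoothed null beyond |stat|.

    The KDE is a Gaussian mixture with one component per pooled null
    value, so the tail mass has the closed form

        p = (1/M) * sum_i [ Phi((-|s| - x_i)/h) + 1 - Phi((|s| - x_i)/h) ]

    clamped to ``[1/(M+1), 1]`` so downstream normal quantiles stay
    finite.
    """
    s = np.atleast_1d(np.asarray(stat, dtype=float))
    if not np.isfinite(s).all():
        raise ValueError("non-finite statistic")
    x = null.values
    h = null.bandwidth
    absd = np.abs(s)[:, None]
    p = (special.ndtr((-absd - x) / h) + special.ndtr((x - absd) / h)).mean(axis=1)
    p = np.clip(p, 1.0 / (x.size + 1), 1.0)
    return float(p[0]) if np.isscalar(stat) or np.ndim(stat) == 0 else p


def combine_stouffer(p_t, p_lmr, sign_t=1.0, sign_lmr=None):
    """Combine the two empirical p-values with Stouffer's method.

    Each two-sided p is mapped to ``z = Phi^{-1}(1 - p/2)`` carrying the
    sign of its effect; the combined z is ``(z_t + z_lmr)/sqrt(2)`` and
    the combined p is the two-sided normal tail ``2(1 - Phi(|z|))``.
    Disagreeing signs (possible because medians and means can disagree)
    attenuate the combined z rather than being special-cased.
    """
    p_t = np.asarray(p_t, dtype=float)
    p_lmr = np.asarray(p_lmr, dtype=float)
    for p in (p_t, p_lmr):
        if (p <= 0).any() or (p > 1).any():
            raise ValueError("p-values must lie in (0, 1]")
    if sign_lmr is None:
        sign_lmr = sign_t
    z_t = np.sign(sign_t) * -special.ndtri(p_t / 2.0)
    z_l = np.sign(sign_lmr) * -special.ndtri(p_lmr / 2.0)
    z = (z_t + z_l) / _SQRT2
    p = np.clip(2.0 * special.ndtr(-np.abs(z)), np.finfo(float).tiny, 1.0)
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def storey_qvalues(p_values, lambda_: float = 0.5):
    """Storey q-values with the single-lambda pi0 estimate.

    pi0_hat = #{p > lambda} / (m (1 - lambda)), clipped to (0, 1];
    q_i = min over p_j >= p_i of pi0_hat * m * p_j / rank(p_j).
    With ``lambda_=0`` the estimate is pi0 = 1 and the q-values reduce
    to Benjamini-Hochberg step-up values.

    Returns ``(q, pi0)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 <= lambda_ < 1:
        raise ValueError("lambda_ must lie in [0, 1)")
    m = p.size
    if lambda_ == 0:
        pi0 = 1.0
    else:
        n_above = int((p > lambda_).sum())
        if n_above == 0:
            warnings.warn(
                "no p-values above lambda; falling back to pi0 = 1",
                RuntimeWarning,
                stacklevel=2,
            )
            pi0 = 1.0
        else:
            pi0 = min(n_above / (m * (1.0 - lambda_)), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1, dtype=float)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class IntegrativeDEModel:
    """Integrative differential-expression model for one comparison.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Normalized log2-intensity matrix.
    comparison : ComparisonSpec
        Test vs reference conditions.
    thresholds : DegThresholds, optional
        DEG calling rule (default FDR <= 0.05, |lmr| >= 0.58).
    lambda_ : float
        Storey pi0 tuning value (default 0.5).
    bandwidth : float, optional
        Fixed KDE bandwidth; defaults to Silverman's rule per null.
    combined_null : {"permutation", "normal"}
        How the combined Stouffer z is converted to a p-value:
        ``"permutation"`` (default) reads the two-sided tail of the
        combined z's own pooled permutation null, which stays calibrated
        under the strong t/lmr dependence of few-replicate designs;
        ``"normal"`` uses the independence closed form 2(1 - Phi(|z|)).
    """

    def __init__(self, matrix: ExpressionMatrix, comparison: ComparisonSpec,
                 thresholds: DegThresholds | None = None,
                 lambda_: float = 0.5, bandwidth: float | None = None,
                 combined_null: str = "permutation"):
        if combined_null not in ("permutation", "normal"):
            raise ValueError("combined_null must be 'permutation' or 'normal'")
        self.matrix = matrix
        self.comparison = comparison
        self.thresholds = thresholds or DegThresholds()
        self.lambda_ = lambda_
        self.bandwidth = bandwidth
        self.combined_null = combined_null

    def fit(self, n_perm: int | None = None, seed: int = 0) -> "IntegrativeDEResults":
        """Run the full integrative procedure and return results.

        ``n_perm=None`` enumerates label splits exhaustively (the default
        for the study's two-replicate design); an integer draws that many
        random permutations seeded by ``seed``.
        """
        m, spec = self.matrix, self.comparison
        cols_a = m.samples_for(spec.test_condition)
        cols_b = m.samples_for(spec.reference_condition)
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ValueError("need >= 2 samples per condition")
        x = m.values[cols_a + cols_b].to_numpy(dtype=float)
        a, b = x[:, : len(cols_a)], x[:, len(cols_a):]
        sd_floor = default_sd_floor(a, b)

        t_obs = _t_matrix(a, b, sd_floor)
        lmr_obs = _lmr_matrix(a, b)

        # one shared set of label splits feeds both marginal nulls and,
        # in "permutation" mode, the combined-z null
        splits = _make_splits(len(cols_a), len(cols_b), n_perm, seed)
        t_perm = [_stat_for_split(x, s, "t", sd_floor) for s in splits]
        lmr_perm = [_stat_for_split(x, s, "lmr", 0.0) for s in splits]
        null_t = NullModel(
            "t", np.concatenate(t_perm),
            self.bandwidth or silverman_bandwidth(np.concatenate(t_perm)),
            len(splits))
        pooled_lmr = np.concatenate(lmr_perm)
        null_lmr = NullModel(
            "lmr", pooled_lmr,
            self.bandwidth or silverman_bandwidth(pooled_lmr), len(splits))

        p_t = empirical_pvalue(t_obs, null_t)
        p_lmr = empirical_pvalue(lmr_obs, null_lmr)
        sign_t = np.where(t_obs >= 0, 1.0, -1.0)
        sign_lmr = np.where(lmr_obs >= 0, 1.0, -1.0)
        z, p_norm = combine_stouffer(p_t, p_lmr, sign_t, sign_lmr)

        if self.combined_null == "normal":
            p_comb = p_norm
            null_z = None
        else:
            pt_perm = empirical_pvalue(np.concatenate(t_perm), null_t)
            pl_perm = empirical_pvalue(np.concatenate(lmr_perm), null_lmr)
            z_perm, _ = combine_stouffer(
                pt_perm, pl_perm,
                np.where(np.concatenate(t_perm) >= 0, 1.0, -1.0),
                np.where(np.concatenate(lmr_perm) >= 0, 1.0, -1.0))
            null_z = NullModel(
                "z", z_perm,
                self.bandwidth or silverman_bandwidth(z_perm), len(splits))
            p_comb = empirical_pvalue(z, null_z)
        q, pi0 = storey_qvalues(p_comb, self.lambda_)

        thr = self.thresholds
        is_deg = (q <= thr.fdr) & (np.abs(lmr_obs) >= thr.lmr)
        direction = np.where(lmr_obs >= 0, "up", "down")

        frame = pd.DataFrame(
            {
                "gene_id": m.gene_ids,
                "t": t_obs,
                "lmr": lmr_obs,
                "p_t": p_t,
                "p_lmr": p_lmr,
                "z": z,
                "p": p_comb,
                "q": q,
                "is_deg": is_deg,
                "direction": direction,
            }
        )
        return IntegrativeDEResults(self, frame, pi0, null_t, null_lmr, null_z)


class IntegrativeDEResults:
    """Fitted per-gene results of :class:`IntegrativeDEModel`."""

    def __init__(self, model: IntegrativeDEModel, frame: pd.DataFrame,
                 pi0: float, null_t: NullModel, null_lmr: NullModel,
                 null_z: NullModel | None = None):
        self.model = model
        self.frame = frame
        self.pi0 = pi0
        self.null_t = null_t
        self.null_lmr = null_lmr
        self.null_z = null_z

    @property
    def comparison(self) -> ComparisonSpec:
        return self.model.comparison

    @property
    def thresholds(self) -> DegThresholds:
        return self.model.thresholds

    @property
    def n_degs(self) -> int:
        return int(self.frame["is_deg"].sum())

    @property
    def degs(self) -> pd.DataFrame:
        return self.frame[self.frame["is_deg"]]

    def summary(self) -> str:
        f = self.frame
        thr = self.thresholds
        up = int((f["is_deg"] & (f["direction"] == "up")).sum())
        down = self.n_degs - up
        lines = [
            "Integrative differential-expression results",
            "=" * 45,
            f"comparison:        {self.comparison.name} "
            f"({self.comparison.test_condition} vs "
            f"{self.comparison.reference_condition})",
            f"genes tested:      {len(f)}",
            f"permutation splits t/lmr: {self.null_t.n_permutations}"
            f"/{self.null_lmr.n_permutations}",
            f"KDE bandwidth t/lmr:      {self.null_t.bandwidth:.4g}"
            f"/{self.null_lmr.bandwidth:.4g}",
            f"pi0 estimate:      {self.pi0:.4f}",
            f"DEG rule:          q <= {thr.fdr} and |lmr| >= {thr.lmr}",
            f"DEGs called:       {self.n_degs} (up {up}, down {down})",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @staticmethod
    def frame_from_tsv(path) -> pd.DataFrame:
        f = pd.read_csv(path, sep="\t")
        f["is_deg"] = f["is_deg"].astype(bool)
        return f


def run_comparison(
    m: ExpressionMatrix,
    spec: ComparisonSpec,
    thresholds: DegThresholds | None = None,
    n_perm: int | None = None,
    seed: int = 0,
) -> IntegrativeDEResults:
    """One-call wrapper: fit the integrative DEG model for one contrast."""
    return IntegrativeDEModel(m, spec, thresholds=thresholds).fit(
        n_perm=n_perm, seed=seed
    )
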