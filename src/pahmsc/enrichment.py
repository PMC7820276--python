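"""Hypergeometric gene-set (GO biological process) enrichment.

A local one-sided hypergeometric test over a GMT gene-set library, with
an optional EASE-style conservative variant, replacing the web-based
enrichment service used interactively in the original analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneSetLibrary",
    "hypergeometric_tail",
    "enrich",
    "enrichment_matrix",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSetLibrary:
    """A named collection of gene sets (GMT-serializable)."""

    terms: dict = field(default_factory=dict)  # term_id -> frozenset of genes
    names: dict = field(default_factory=dict)  # term_id -> description

    def __post_init__(self):
        for tid, members in list(self.terms.items()):
            members = frozenset(members)
            if not members:
                raise ValueError(f"term {tid!r} is empty")
            self.terms[tid] = members
            self.names.setdefault(tid, tid)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def to_gmt(self, path) -> None:
        write_gmt(self, path)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetLibrary":
        return read_gmt(path)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(library.terms):
            members = "\t".join(sorted(library.terms[tid]))
            fh.write(f"{tid}\t{library.names[tid]}\t{members}\n")


def read_gmt(path) -> GeneSetLibrary:
    terms, names = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            tid, desc, members = fields[0], fields[1], fields[2:]
            terms[tid] = frozenset(m for m in members if m)
            names[tid] = desc
    return GeneSetLibrary(terms, names)


def hypergeometric_tail(k: int, K: int, n: int, N: int,
                        mode: str = "standard") -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` background genes of which ``K`` belong to the term; ``n`` genes
    drawn (the query); ``k`` of them hit the term.  ``mode="ease"``
    evaluates the tail at ``max(k - 1, 0)`` instead of ``k`` (the
    conservative EASE-score variant used by DAVID).
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if mode == "ease":
        k = max(k - 1, 0)
    elif mode != "standard":
        raise ValueError(f"unknown mode {mode!r}")
    # sf(k-1) = P(X >= k); exact for k = 0 too (== 1)
    return float(min(hypergeom.sf(k - 1, N, K, n), 1.0))


def enrich(query, library: GeneSetLibrary, background, alpha: float = 0.05,
           mode: str = "standard") -> pd.DataFrame:
    """Term-level enrichment of ``query`` against ``background``.

    Returns one row per term with at least one query hit, sorted by
    ascending p (ties broken by term id), with columns ``k, K, n, N, p,
    neglog10p`` and a ``represented`` flag for ``p < alpha``.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    N = len(background)
    n = len(query)
    rows = []
    for tid in library:
        members = library.terms[tid] & background
        K = len(members)
        k = len(members & query)
        if k == 0:
            continue
        p = hypergeometric_tail(k, K, n, N, mode=mode)
        rows.append(
            {
                "term_id": tid,
                "term_name": library.names[tid],
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "neglog10p": -np.log10(p),
                "represented": p < alpha,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "K", "n", "N", "p",
                 "neglog10p", "represented"],
    )
    if len(out):
        out = out.sort_values(["p", "term_id"], kind="mergesort")
        out = out.reset_index(drop=True)
    return out


def enrichment_matrix(results_by_group: dict) -> pd.DataFrame:
    """Terms x gene-groups matrix of -log10(p) for heat-map export.

    ``results_by_group`` maps a group label (e.g. ``"G1"``) to the frame
    returned by :func:`enrich`.  Terms absent from a group get 0.
    """
    cols = {}
    for group, frame in results_by_group.items():
        cols[group] = frame.set_index("term_id")["neglog10p"]
    out = pd.DataFrame(cols).fillna(0.0)
    out.index.name = "term_id"
    return out.sort_index()
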