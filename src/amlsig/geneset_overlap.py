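"""Hypergeometric overrepresentation of a query gene set against GMT sets.

One-sided upper-tail test: for a universe of N genes containing a set of K,
the probability of drawing at least k members in a query of n. The universe
is always explicit — by convention all measured genes (those in the probe
annotation), not the whole genome — because overlap p-values are meaningless
without a declared universe. Benjamini-Hochberg q-values control the FDR
across the sets tested.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PipelineError
from .io_formats import GeneSetCollection

OVERLAP_COLUMNS = [
    "set_name",
    "universe_size",
    "set_size",
    "query_size",
    "overlap",
    "p_value",
    "q_value",
    "overlap_members",
]


def hypergeom_overlap_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail overlap probability P(X >= k), X ~ Hypergeometric(N, K, n).

    Computed through the survival function (log-space internally), stable for
    large universes.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def enrich_genesets(
    query,
    collection: GeneSetCollection,
    universe,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Overrepresentation of ``query`` in each set of ``collection``.

    Query genes outside the universe are dropped with a warning; set members
    are intersected with the universe before counting. Returns one row per
    set with K > 0 after intersection, sorted by (q, p, set_name). The
    ``significant`` column marks q < ``q_threshold``.
    """
    universe = set(universe)
    if not universe:
        raise PipelineError("empty universe")
    query = set(query)
    if not query:
        raise PipelineError("empty query gene set")
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
        query &= universe
        if not query:
            raise PipelineError("no query gene lies in the universe")

    N, n = len(universe), len(query)
    rows = []
    for s in collection:
        members = set(s.members) & universe
        if not members:
            continue
        overlap = sorted(query & members)
        rows.append(
            {
                "set_name": s.name,
                "universe_size": N,
                "set_size": len(members),
                "query_size": n,
                "overlap": len(overlap),
                "p_value": hypergeom_overlap_p(N, len(members), n, len(overlap)),
                "overlap_members": ",".join(overlap),
            }
        )
    if not rows:
        raise PipelineError("no gene set intersects the universe")
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["q_value"] < q_threshold
    out = out.sort_values(
        ["q_value", "p_value", "set_name"], kind="stable"
    ).reset_index(drop=True)
    return out[OVERLAP_COLUMNS + ["significant"]]
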