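"""Murine DEG mapping and cross-cohort enrichment testing.

A murine DEG list is mapped through an explicit ortholog map to human gene
symbols and on to the probes present in both cohorts' annotations. For each
mapped probe, the difference-from-reference values of the two cohorts are
compared with a Welch two-sample t-test (unequal variances; the cohorts are
typically badly unbalanced, e.g. 237 vs 537 samples). Benjamini-Hochberg
q-values are reported alongside raw p-values; significance defaults to raw
p < alpha with an FDR mode available. Probe-level results are aggregated to a
gene-level signature by the any-concordant-probe rule: a gene enters the
signature if at least one of its probes is significantly enriched in cohort A
and none is significantly enriched in cohort B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PipelineError
from .io_formats import DEGList, OrthologMap, ProbeAnnotation

ENRICHMENT_COLUMNS = [
    "probe_id",
    "human_symbol",
    "mouse_symbol",
    "mean_diff_A",
    "mean_diff_B",
    "delta",
    "t_stat",
    "df",
    "p_value",
    "q_value",
    "enriched_in",
    "flag",
]


@dataclass
class MappedSignatureInput:
    """Mouse gene -> human ortholog -> probe rows, plus the unmapped report.

    ``mapped`` columns: mouse_symbol, human_symbol, probe_id.
    ``unmapped_report`` columns: mouse_symbol, stage (``no_ortholog`` or
    ``no_probe``). Every input DEG gene appears either in ``mapped`` or in
    the report.
    """

    mapped: pd.DataFrame
    unmapped_report: pd.DataFrame


@dataclass
class SignatureResult:
    """Gene-level signature with per-gene probe summaries.

    ``genes`` are the human symbols in the signature, sorted by their best
    probe p-value. ``summary`` has one row per gene with >= 1 significant
    probe, with ``status`` in {"signature", "discordant"} — discordant genes
    (significant probes in both directions) are excluded from ``genes``.
    """

    genes: list[str]
    summary: pd.DataFrame


def map_degs_to_probes(
    degs: DEGList,
    orthologs: OrthologMap,
    annot_a: ProbeAnnotation,
    annot_b: ProbeAnnotation,
) -> MappedSignatureInput:
    """Map murine DEG symbols to human orthologs and shared probes.

    One output row per (mouse gene, human ortholog, probe) combination where
    the probe is annotated to the ortholog in *both* datasets. Genes lost at
    any step are reported with the stage at which they were lost.
    """
    g2p_a = annot_a.gene_to_probes()
    g2p_b = annot_b.gene_to_probes()
    rows: list[tuple[str, str, str]] = []
    unmapped: list[tuple[str, str]] = []
    for mouse in degs.genes():
        humans = sorted(orthologs.human_orthologs(mouse))
        if not humans:
            unmapped.append((mouse, "no_ortholog"))
            continue
        found = False
        for human in humans:
            probes = sorted(set(g2p_a.get(human, [])) & set(g2p_b.get(human, [])))
            for probe in probes:
                rows.append((mouse, human, probe))
                found = True
        if not found:
            unmapped.append((mouse, "no_probe"))
    mapped = pd.DataFrame(rows, columns=["mouse_symbol", "human_symbol", "probe_id"])
    report = pd.DataFrame(unmapped, columns=["mouse_symbol", "stage"])
    if mapped.empty:
        raise PipelineError(
            "no DEG could be mapped to a probe present in both datasets; "
            f"unmapped report:\n{report.to_string(index=False)}"
        )
    return MappedSignatureInput(mapped=mapped, unmapped_report=report)


def _welch_rows(xa: np.ndarray, xb: np.ndarray):
    """Welch t per row with explicit handling of zero-variance degeneracies."""
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    delta = ma - mb
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    flag = np.full(len(t), "", dtype=object)
    degenerate = se2 == 0
    equal = degenerate & (delta == 0)
    unequal = degenerate & (delta != 0)
    t[equal], p[equal], df[equal] = 0.0, 1.0, np.nan
    t[unequal] = np.sign(delta[unequal]) * np.inf
    p[unequal], df[unequal] = 0.0, np.nan
    flag[unequal] = "degenerate"
    return ma, mb, delta, t, df, p, flag


def _pooled_rows(xa: np.ndarray, xb: np.ndarray):
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    delta = ma - mb
    df_val = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df_val
    se2 = sp2 * (1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
    df = np.full(len(t), float(df_val))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    flag = np.full(len(t), "", dtype=object)
    degenerate = se2 == 0
    equal = degenerate & (delta == 0)
    unequal = degenerate & (delta != 0)
    t[equal], p[equal] = 0.0, 1.0
    t[unequal] = np.sign(delta[unequal]) * np.inf
    p[unequal] = 0.0
    flag[unequal] = "degenerate"
    return ma, mb, delta, t, df, p, flag


def enrichment_test(
    d_a: pd.DataFrame,
    d_b: pd.DataFrame,
    mapped: MappedSignatureInput,
    alpha: float = 0.05,
    use_fdr: bool = False,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-probe test of difference-from-reference means between cohorts.

    For every probe in ``mapped``, tests H0: mean of cohort-A differences
    equals mean of cohort-B differences (two-sided; Welch by default, pooled
    variance with ``pooled=True``). Returns a table with one row per probe:
    cohort means, delta = mean_diff_A - mean_diff_B, t, df, p, BH q across
    all tested probes, and the enrichment call (``A`` iff delta > 0 and
    significant; ``B`` symmetric; otherwise ``none``).
    """
    per_probe = (
        mapped.mapped.groupby("probe_id")
        .agg(
            human_symbol=("human_symbol", lambda s: ",".join(sorted(set(s)))),
            mouse_symbol=("mouse_symbol", lambda s: ",".join(sorted(set(s)))),
        )
        .sort_index()
    )
    probes = list(per_probe.index)
    missing = [p for p in probes if p not in d_a.index or p not in d_b.index]
    if missing:
        raise PipelineError(f"mapped probes absent from difference matrices: {missing[:5]}")
    if d_a.shape[1] < 2 or d_b.shape[1] < 2:
        raise PipelineError("each cohort needs at least 2 samples for the t-test")

    xa = d_a.loc[probes].to_numpy(dtype=float)
    xb = d_b.loc[probes].to_numpy(dtype=float)
    rows = _pooled_rows(xa, xb) if pooled else _welch_rows(xa, xb)
    ma, mb, delta, t, df, p, flag = rows
    q = multipletests(p, method="fdr_bh")[1]
    sig = (q < alpha) if use_fdr else (p < alpha)
    enriched = np.where(sig & (delta > 0), "A", np.where(sig & (delta < 0), "B", "none"))
    return pd.DataFrame(
        {
            "probe_id": probes,
            "human_symbol": per_probe["human_symbol"].to_numpy(),
            "mouse_symbol": per_probe["mouse_symbol"].to_numpy(),
            "mean_diff_A": ma,
            "mean_diff_B": mb,
            "delta": delta,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "q_value": q,
            "enriched_in": enriched,
            "flag": flag,
        },
        columns=ENRICHMENT_COLUMNS,
    )


def call_signature(
    table: pd.DataFrame, alpha: float = 0.05, use_fdr: bool = False
) -> SignatureResult:
    """Aggregate probe-level enrichment calls to a gene-level signature.

    A gene enters the signature iff at least one of its probes is significant
    with ``enriched_in == "A"`` and none is significant with
    ``enriched_in == "B"``; genes with significant probes in both directions
    are flagged ``discordant`` and excluded. An empty signature is a valid
    result.
    """
    if table.empty:
        raise PipelineError("enrichment table is empty")
    rows = []
    crit = table["q_value"] if use_fdr else table["p_value"]
    significant = crit < alpha
    for gene, sub in table.groupby("human_symbol"):
        sig_a = significant.loc[sub.index] & (sub["delta"] > 0)
        sig_b = significant.loc[sub.index] & (sub["delta"] < 0)
        if not sig_a.any():
            continue
        status = "discordant" if sig_b.any() else "signature"
        best = sub.loc[sig_a, "p_value"].min()
        rows.append(
            {
                "human_symbol": gene,
                "mouse_symbol": ",".join(sorted(set(sub["mouse_symbol"]))),
                "n_probes": len(sub),
                "n_probes_enriched_A": int(sig_a.sum()),
                "n_probes_enriched_B": int(sig_b.sum()),
                "best_p": best,
                "status": status,
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "human_symbol",
            "mouse_symbol",
            "n_probes",
            "n_probes_enriched_A",
            "n_probes_enriched_B",
            "best_p",
            "status",
        ],
    )
    if len(summary):
        summary = summary.sort_values(
            ["best_p", "human_symbol"], kind="stable"
        ).reset_index(drop=True)
    genes = list(summary.loc[summary["status"] == "signature", "human_symbol"])
    return SignatureResult(genes=genes, summary=summary)


def signature_fraction(n_signature_genes: int, n_degs: int) -> float:
    """Signature size as a percentage of the input DEG list, one decimal."""
    if n_degs <= 0:
        raise ValueError("n_degs must be positive")
    return round(100.0 * n_signature_genes / n_degs, 1)


def overlap_degs(set1, set2) -> dict:
    """Exact intersection of two gene-symbol sets (Venn-count arithmetic)."""
    s1, s2 = set(set1), set(set2)
    inter = sorted(s1 & s2)
    return {
        "n1": len(s1),
        "n2": len(s2),
        "intersection_size": len(inter),
        "intersection_members": inter,
    }
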