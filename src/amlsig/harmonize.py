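"""Cross-dataset harmonization: common probes, joint quantile normalization,
reference-probe selection, and difference-from-reference matrices.

Two expression cohorts measured on the same platform but processed as
separate datasets differ in location, scale and per-sample offsets. Rather
than latent-factor batch correction, the approach here anchors every sample
to an internal reference: after joint quantile normalization, probes with
low variance AND low mean in *both* datasets (housekeeping-like probes) form
a reference set, and each sample's expression is re-expressed as the
difference from that sample's mean reference value. Any per-sample additive
offset cancels exactly in the difference, so downstream tests compare
biology rather than processing artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

from .errors import PipelineError
from .io_formats import ExpressionMatrix


@dataclass
class ReferenceSet:
    """Selected reference probes and per-sample reference values.

    ``per_sample_reference`` maps every sample (of both datasets) to
    r_j = mean over the reference probes of that sample's normalized values.
    """

    probe_ids: frozenset[str]
    per_sample_reference: pd.Series
    selection_params: dict

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise PipelineError("reference set is empty")
        if not np.isfinite(self.per_sample_reference.to_numpy()).all():
            raise PipelineError("non-finite per-sample reference value")


def restrict_to_common_probes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their probe intersection, lexicographic order."""
    common = sorted(set(a.probe_ids) & set(b.probe_ids))
    if not common:
        raise PipelineError("datasets share no probes")
    return a.with_values(a.values.loc[common]), b.with_values(b.values.loc[common])


def _quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the per-rank mean target distribution.

    Ties within a column receive the mean of the target values over their
    rank span, so tied inputs stay tied and the result is deterministic.
    """
    x = values.to_numpy(dtype=float)
    n_rows, n_cols = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=0)
    target = sorted_vals.mean(axis=1)

    out = np.empty_like(x)
    for j in range(n_cols):
        assigned = np.empty(n_rows)
        assigned[order[:, j]] = target
        col = x[:, j]
        # average the assigned targets over each tie group
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.zeros(len(counts))
        np.add.at(sums, inverse, assigned)
        out[:, j] = sums[inverse] / counts[inverse]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize_joint(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Quantile-normalize all samples of both datasets to one pooled target.

    Pooling guarantees the two datasets end on a shared value distribution
    (their "value ranges" become compatible by construction); per-dataset
    normalization would leave the cross-dataset location/scale gap intact.
    Requires a common probe space (apply :func:`restrict_to_common_probes`
    first).
    """
    if list(a.values.index) != list(b.values.index):
        raise PipelineError("matrices are not on a common probe space; restrict first")
    n_total = a.values.shape[1] + b.values.shape[1]
    if n_total < 2:
        raise PipelineError("quantile normalization needs at least 2 samples")
    pooled = pd.concat([a.values, b.values], axis=1)
    normed = _quantile_normalize_frame(pooled)
    return (
        a.with_values(normed[a.values.columns]),
        b.with_values(normed[b.values.columns]),
    )


def select_reference_probes(
    aq: ExpressionMatrix,
    bq: ExpressionMatrix,
    q_var: float = 0.25,
    q_mean: float = 0.25,
    min_reference: int = 10,
    mode: str = "low",
) -> ReferenceSet:
    """Select probes with low variance and low mean in both datasets.

    Within each dataset, a probe qualifies if its across-sample variance is
    at or below the ``q_var`` quantile of variances and its mean at or below
    the ``q_mean`` quantile of means (quantiles taken within that dataset,
    so the rule is scale-free). The reference set is the intersection of the
    two datasets' qualifying probes; each sample's reference value r_j is the
    arithmetic mean of the reference probes in that sample.

    ``mode="matched"`` replaces the low-mean criterion by closeness of the
    two datasets' means (|mean_A - mean_B| at or below its ``q_mean``
    quantile), for platforms where absolute intensity is not comparable.
    """
    if not (0 < q_var <= 1) or not (0 < q_mean <= 1):
        raise PipelineError("q_var and q_mean must lie in (0, 1]")
    if list(aq.values.index) != list(bq.values.index):
        raise PipelineError("matrices are not on a common probe space")

    def _qualify(values: pd.DataFrame) -> pd.Series:
        means = values.mean(axis=1)
        variances = values.var(axis=1, ddof=1)
        ok_var = variances <= variances.quantile(q_var)
        ok_mean = means <= means.quantile(q_mean)
        return ok_var & ok_mean

    if mode == "low":
        qualifies = _qualify(aq.values) & _qualify(bq.values)
    elif mode == "matched":
        var_ok_a = aq.values.var(axis=1, ddof=1)
        var_ok_b = bq.values.var(axis=1, ddof=1)
        low_var = (var_ok_a <= var_ok_a.quantile(q_var)) & (
            var_ok_b <= var_ok_b.quantile(q_var)
        )
        gap = (aq.values.mean(axis=1) - bq.values.mean(axis=1)).abs()
        qualifies = low_var & (gap <= gap.quantile(q_mean))
    else:
        raise PipelineError(f"unknown reference selection mode {mode!r}")

    probes = sorted(qualifies.index[qualifies])
    if len(probes) < min_reference:
        raise PipelineError(
            f"only {len(probes)} reference probes qualify (minimum {min_reference}); "
            "increase q_var/q_mean"
        )
    ref_a = aq.values.loc[probes].mean(axis=0)
    ref_b = bq.values.loc[probes].mean(axis=0)
    per_sample = pd.concat([ref_a, ref_b])
    return ReferenceSet(
        probe_ids=frozenset(probes),
        per_sample_reference=per_sample,
        selection_params={
            "q_var": q_var,
            "q_mean": q_mean,
            "min_reference": min_reference,
            "mode": mode,
        },
    )


def compute_difference_matrix(m: ExpressionMatrix, ref: ReferenceSet) -> pd.DataFrame:
    """Difference-from-reference matrix: d_ij = x_ij - r_j.

    Reference probes remain rows of the result (their differences hover near
    zero by construction). Adding a constant to every value of one sample
    leaves that sample's column unchanged — the anchor makes the analysis
    exactly shift-invariant per sample.
    """
    missing = [s for s in m.sample_ids if s not in ref.per_sample_reference.index]
    if missing:
        raise PipelineError(f"samples missing from per-sample reference: {missing[:5]}")
    r = ref.per_sample_reference[m.values.columns]
    return m.values.sub(r, axis=1)
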