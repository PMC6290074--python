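"""Two-cohort expression simulator with planted signal and known truth.

Emulates the statistical structure the cross-cohort enrichment analysis
assumes: two microarray-like cohorts of log2 intensities measured on a shared
probe space, separated by a dataset-level location/scale batch effect and
per-sample additive offsets; a pool of housekeeping probes with low mean and
low variance in both datasets (the candidates for reference-gene selection);
and a planted set of signature genes upregulated by a fixed log2 effect in
cohort A only. A matching murine DEG list, mouse-to-human ortholog map and a
right-censored survival cohort tied to expression complete the inputs the
pipeline consumes.

Value model per probe *i*, sample *j*::

    x_ij = mu_i + batch_d(j) + c_j + delta * 1[i in signature, cohort(j) = A] + eps_ij

with ``mu_i ~ Uniform(baseline_mean_range)`` for ordinary probes and
``Normal(reference_mean, reference_sd)`` for housekeeping probes (whose noise
SD is also ``reference_sd``), ``batch_A = 0``, ``batch_B = batch_offset_B``,
``c_j ~ Normal(0, sample_offset_sd)``, ``eps_ij ~ Normal(0, noise_sd)``.
Dataset B is additionally scaled about its own grand mean by
``batch_scale_B``, mimicking a platform dynamic-range difference without
moving the global location twice. Everything is deterministic given the
master seed; each artifact draws from an independent substream derived from
``(seed, stream_offset)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_formats import (
    DEGList,
    ExpressionMatrix,
    OrthologMap,
    ProbeAnnotation,
    SurvivalTable,
)

# Fixed substream offsets, one per generated artifact.
_STREAM_STRUCTURE = 0
_STREAM_MATRIX_A = 1
_STREAM_MATRIX_B = 2
_STREAM_DEGS = 3
_STREAM_SURVIVAL = 4

_SUBTYPES = ("S1", "S2", "S3", "S4")


@dataclass
class SimulationConfig:
    """Parameters of the two-cohort generator.

    Defaults are the study conditions the pipeline is exercised under: two
    cohorts of 40 samples, a planted signature of 10 genes at +1.0 log2 in
    cohort A, measurement noise SD 0.5, a location batch shift of +2.0 log2
    and a 1.15x dynamic-range distortion on dataset B, per-sample offsets of
    SD 0.3, and a 100-probe housekeeping pool at low mean (4.0) and low
    variance (SD 0.15) against baselines uniform on [6, 12].
    """

    n_probes: int = 560
    n_genes: int = 200
    probes_per_gene: int = 2
    n_samples_A: int = 40
    n_samples_B: int = 40
    n_reference_probes: int = 100
    n_signature_genes: int = 10
    effect_delta: float = 1.0
    batch_offset_B: float = 2.0
    batch_scale_B: float = 1.15
    sample_offset_sd: float = 0.3
    noise_sd: float = 0.5
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    reference_mean: float = 4.0
    reference_sd: float = 0.15
    ortholog_fanout: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_signature_genes > self.n_genes:
            raise ConfigurationError("n_signature_genes exceeds n_genes")
        if self.n_reference_probes > self.n_probes:
            raise ConfigurationError("n_reference_probes exceeds n_probes")
        if self.n_genes * self.probes_per_gene + self.n_reference_probes > self.n_probes:
            raise ConfigurationError(
                "n_probes must cover n_genes*probes_per_gene gene probes plus "
                "the reference pool"
            )
        if self.probes_per_gene < 1:
            raise ConfigurationError("probes_per_gene must be >= 1")
        if min(self.sample_offset_sd, self.noise_sd, self.reference_sd) < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.batch_scale_B <= 0:
            raise ConfigurationError("batch_scale_B must be > 0")
        if self.ortholog_fanout < 1:
            raise ConfigurationError("ortholog_fanout must be >= 1")


@dataclass
class SimulationTruth:
    """Ground truth of one simulation, for parameter-recovery testing."""

    signature_genes: frozenset[str]  # mouse symbols
    signature_probes: frozenset[str]
    reference_probe_pool: frozenset[str]
    ortholog_map: OrthologMap
    config: SimulationConfig

    def mouse_genes(self) -> list[str]:
        """All simulated mouse symbols, signature and background."""
        return sorted(self.ortholog_map.mapping)


def _mouse_symbol(i: int) -> str:
    return f"Gene{i + 1:04d}"


def _human_symbol(i: int) -> str:
    return f"GENE{i + 1:04d}"


def simulate_two_cohort_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ProbeAnnotation, OrthologMap, SimulationTruth]:
    """Generate cohort A and B matrices plus annotation, orthology and truth."""
    config.validate()
    c = config
    rng_struct = np.random.default_rng([c.seed, _STREAM_STRUCTURE])

    n_gene_probes = c.n_genes * c.probes_per_gene
    probe_ids = [f"PR{i + 1:06d}" for i in range(c.n_probes)]
    gene_probes = probe_ids[:n_gene_probes]
    ref_probes = probe_ids[n_gene_probes : n_gene_probes + c.n_reference_probes]
    filler_probes = probe_ids[n_gene_probes + c.n_reference_probes :]

    annotation: dict[str, str] = {}
    for g in range(c.n_genes):
        for p in range(c.probes_per_gene):
            annotation[gene_probes[g * c.probes_per_gene + p]] = _human_symbol(g)
    for i, probe in enumerate(ref_probes):
        annotation[probe] = f"HKG{i + 1:04d}"
    for i, probe in enumerate(filler_probes):
        annotation[probe] = f"BG{i + 1:04d}"

    ortho: dict[str, frozenset[str]] = {}
    for g in range(c.n_genes):
        humans = {_human_symbol(g)}
        # optional 1->many fan-out: extra human symbols without probes
        for k in range(1, c.ortholog_fanout):
            humans.add(f"{_human_symbol(g)}P{k}")
        ortho[_mouse_symbol(g)] = frozenset(humans)
    ortholog_map = OrthologMap(ortho)

    sig_idx = np.sort(rng_struct.choice(c.n_genes, size=c.n_signature_genes, replace=False))
    signature_genes = frozenset(_mouse_symbol(int(g)) for g in sig_idx)
    signature_probes = frozenset(
        gene_probes[int(g) * c.probes_per_gene + p]
        for g in sig_idx
        for p in range(c.probes_per_gene)
    )

    lo, hi = c.baseline_mean_range
    mu = rng_struct.uniform(lo, hi, size=c.n_probes)
    is_ref = np.zeros(c.n_probes, dtype=bool)
    is_ref[n_gene_probes : n_gene_probes + c.n_reference_probes] = True
    mu[is_ref] = rng_struct.normal(c.reference_mean, c.reference_sd, size=c.n_reference_probes)
    probe_noise_sd = np.where(is_ref, c.reference_sd, c.noise_sd)

    is_sig = np.array([p in signature_probes for p in probe_ids])

    def _make_matrix(stream: int, n_samples: int, cohort: str, planted: bool) -> np.ndarray:
        rng = np.random.default_rng([c.seed, stream])
        offsets = rng.normal(0.0, c.sample_offset_sd, size=n_samples)
        eps = rng.normal(0.0, 1.0, size=(c.n_probes, n_samples)) * probe_noise_sd[:, None]
        x = mu[:, None] + offsets[None, :] + eps
        if planted:
            x[is_sig, :] += c.effect_delta
        return x

    x_a = _make_matrix(_STREAM_MATRIX_A, c.n_samples_A, "A", planted=True)
    x_b = _make_matrix(_STREAM_MATRIX_B, c.n_samples_B, "B", planted=False)
    x_b = x_b + c.batch_offset_B
    grand_b = x_b.mean()
    x_b = grand_b + (x_b - grand_b) * c.batch_scale_B

    samples_a = [f"A_s{j + 1:03d}" for j in range(c.n_samples_A)]
    samples_b = [f"B_s{j + 1:03d}" for j in range(c.n_samples_B)]
    rng_meta = np.random.default_rng([c.seed, _STREAM_STRUCTURE, 1])
    meta_a = pd.DataFrame(
        {
            "dataset": "dsA",
            "cohort": "A",
            "subtype": rng_meta.choice(_SUBTYPES, size=c.n_samples_A),
        },
        index=pd.Index(samples_a, name="sample_id"),
    )
    meta_b = pd.DataFrame(
        {
            "dataset": "dsB",
            "cohort": "B",
            "subtype": rng_meta.choice(_SUBTYPES, size=c.n_samples_B),
        },
        index=pd.Index(samples_b, name="sample_id"),
    )

    mat_a = ExpressionMatrix(
        pd.DataFrame(x_a, index=pd.Index(probe_ids, name="probe_id"), columns=samples_a),
        sample_meta=meta_a,
    )
    mat_b = ExpressionMatrix(
        pd.DataFrame(x_b, index=pd.Index(probe_ids, name="probe_id"), columns=samples_b),
        sample_meta=meta_b,
    )
    truth = SimulationTruth(
        signature_genes=signature_genes,
        signature_probes=signature_probes,
        reference_probe_pool=frozenset(ref_probes),
        ortholog_map=ortholog_map,
        config=dataclasses.replace(c),
    )
    return mat_a, mat_b, ProbeAnnotation(annotation), ortholog_map, truth


def simulate_deg_list(truth: SimulationTruth, n_decoys: int, seed: int) -> DEGList:
    """Murine DEG list: every signature gene plus ``n_decoys`` decoy genes.

    All emitted entries satisfy the provenance thresholds (|LFC| >= 1.5,
    adjusted p < 0.05) — decoys stand for genes truly differential in the
    murine comparison but without a planted human counterpart.
    """
    if n_decoys < 0:
        raise ConfigurationError("n_decoys must be >= 0")
    rng = np.random.default_rng([seed, _STREAM_DEGS])
    background = sorted(set(truth.mouse_genes()) - set(truth.signature_genes))
    if n_decoys > len(background):
        raise ConfigurationError(
            f"n_decoys={n_decoys} exceeds the {len(background)} non-signature genes"
        )
    decoys = sorted(rng.choice(background, size=n_decoys, replace=False).tolist())
    genes = sorted(truth.signature_genes) + decoys
    entries = pd.DataFrame(
        {
            "gene": genes,
            "direction": 1,
            "lfc": rng.uniform(1.5, 4.0, size=len(genes)),
            "adj_p": rng.uniform(1e-8, 0.049, size=len(genes)),
        }
    )
    return DEGList(entries=entries)


def simulate_survival_cohort(
    n: int,
    hazard_ratio: float,
    baseline_median_days: float,
    censor_rate: float,
    seed: int,
) -> SurvivalTable:
    """Right-censored survival cohort linked to a standard-normal covariate.

    Event times are exponential with median ``baseline_median_days``;
    patients in the top expression quartile (the floor(n/4) largest values)
    have their hazard multiplied by ``hazard_ratio``. Censoring times are
    independent exponentials whose per-patient rate is calibrated so the
    expected censored fraction equals ``censor_rate`` exactly.
    """
    if n < 8:
        raise ConfigurationError("survival cohort needs n >= 8")
    if hazard_ratio <= 0 or baseline_median_days <= 0:
        raise ConfigurationError("hazard_ratio and baseline_median_days must be > 0")
    if not 0 <= censor_rate < 1:
        raise ConfigurationError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng([seed, _STREAM_SURVIVAL])
    expression = rng.standard_normal(n)
    k = n // 4
    order = np.argsort(expression, kind="stable")
    top = np.zeros(n, dtype=bool)
    top[order[n - k :]] = True
    lam = np.log(2.0) / baseline_median_days * np.where(top, hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        # P(C < T) = mu/(lam+mu) = censor_rate when mu = lam*c/(1-c)
        mu = lam * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / mu)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time = event_time
        event = np.ones(n, dtype=int)
    data = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "time_days": time,
            "event": event,
            "expression": expression,
        }
    )
    return SurvivalTable(data=data)
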