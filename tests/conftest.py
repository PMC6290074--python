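
import pandas as pd
import pytest

import amlsig as a


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study conditions: quick to simulate, same structure."""
    return a.SimulationConfig(
        n_probes=132,
        n_genes=50,
        probes_per_gene=2,
        n_samples_A=12,
        n_samples_B=12,
        n_reference_probes=24,
        n_signature_genes=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    mat_a, mat_b, annot, orth, truth = a.simulate_two_cohort_expression(small_config)
    return {
        "matrix_a": mat_a,
        "matrix_b": mat_b,
        "annotation": annot,
        "orthologs": orth,
        "truth": truth,
    }


@pytest.fixture()
def toy_matrix():
    values = pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=pd.Index(["P1", "P2", "P3"], name="probe_id"),
        columns=["s1", "s2"],
    )
    return a.ExpressionMatrix(values=values)


def run_pipeline_on_truth(sim, q_var=0.25, q_mean=0.25, alpha=0.05, n_decoys=20,
                          seed=None, use_fdr=False):
    """Helper: full in-memory pipeline from a simulation dict to a signature."""
    truth = sim["truth"]
    seed = truth.config.seed if seed is None else seed
    ar, br = a.restrict_to_common_probes(sim["matrix_a"], sim["matrix_b"])
    aq, bq = a.quantile_normalize_joint(ar, br)
    ref = a.select_reference_probes(aq, bq, q_var=q_var, q_mean=q_mean)
    d_a = a.compute_difference_matrix(aq, ref)
    d_b = a.compute_difference_matrix(bq, ref)
    degs = a.simulate_deg_list(truth, n_decoys=n_decoys, seed=seed)
    mapped = a.map_degs_to_probes(degs, sim["orthologs"], sim["annotation"],
                                  sim["annotation"])
    table = a.enrichment_test(d_a, d_b, mapped, alpha=alpha, use_fdr=use_fdr)
    signature = a.call_signature(table, alpha=alpha, use_fdr=use_fdr)
    return table, signature
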