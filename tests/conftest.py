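import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from capturecall import (  # noqa: E402
    RepeatAnnotation,
    generate_reference,
    plant_genes,
    plant_repeats,
    simulate_capture_reads,
    simulate_haplotypes,
)
from capturecall.variant_caller import build_pileup  # noqa: E402


@pytest.fixture(scope="session")
def study():
    """A 100 kb simulated study: reference, repeats, genes, two animals."""
    ref = generate_reference(100_000, 0.42, seed=7)
    repeats = plant_repeats(ref, 0.30, 400, seed=11)
    genes = plant_genes(ref, repeats, n_genes=5, exons_per_gene=4, seed=2)
    truths = simulate_haplotypes(ref, genes, n_neutral=50, causal_cds_offset=363, seed=3, repeats=repeats)
    return {
        "ref": ref,
        "repeats": repeats,
        "genes": genes,
        "truths": truths,
        "case": truths["case_calf"],
        "control": truths["carrier_cow"],
    }


@pytest.fixture(scope="session")
def clean_pileups(study):
    """Error-free, gapless, deep pileups for both animals (exact-recovery regime)."""
    out = {}
    for aid, truth in study["truths"].items():
        reads = simulate_capture_reads(
            truth, study["ref"], mean_cov=60, gap_fraction=0.0, read_len=76,
            err_rate=0.0, seed=9, depth_sigma=0.15,
        )
        out[aid] = build_pileup(reads, study["ref"])
    return out
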