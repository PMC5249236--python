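import numpy as np
import pandas as pd
import pytest

from mkintegrity.datatypes import GenotypePanel, SampleLineage


def make_panel(calls, subjects=None):
    """Wrap a samples x SNPs dosage array in a panel with MNC lineage rows."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_snps = calls.shape
    snps = pd.DataFrame(
        {
            "name": [f"rs{i}" for i in range(n_snps)],
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1) * 1000,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = [
        SampleLineage(f"S{i}", subjects[i] if subjects else f"S{i}", "MNC", "")
        for i in range(n_samples)
    ]
    return GenotypePanel(calls, snps, samples)


@pytest.fixture
def paired_study():
    """Small paired iPSC/MK study with planted effects and an arm duplication."""
    import mkintegrity as mk

    tx = mk.simulate_transcript_annotation(1200, seed=11, transcripts_per_gene=2)
    cat = mk.simulate_geneset_catalog(600, 20, 25, seed=12)
    truth = mk.make_expression_truth(
        tx,
        catalog=cat,
        n_de=120,
        de_effect=2.0,
        enriched_terms={"GO:7000000": ("up_in_MK", 2.0)},
        arm_duplication=("P001", "A", "MK", "1", "q", 2.0),
        seed=13,
    )
    study, truth = mk.simulate_expression_study(
        14, truth, transcripts=tx, noise_sd=0.5, seed=14
    )
    return study, truth, tx, cat
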