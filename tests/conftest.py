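import numpy as np
import pytest

from rrbspipe import Genome, simulate_genome


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """CpG-enriched two-contig genome with spike-in, shared across tests."""
    return simulate_genome(2, 5000, cpg_enrichment=4.0, seed=11, spikein_length=1500)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_genome(*seqs: str, spikein: str | None = None) -> Genome:
    """Hand-built genome from explicit sequences (contig_1, contig_2, ...)."""
    contigs = {f"contig_{i + 1}": s for i, s in enumerate(seqs)}
    spike = set()
    if spikein is not None:
        contigs["spike"] = spikein
        spike = {"spike"}
    return Genome(contigs=contigs, spikein_names=spike)
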