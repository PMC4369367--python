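import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tillseq import PoolLayout
from tillseq.counts import counts_from_reads
from tillseq.simulate import (
    ReadModel,
    generate_read_batches,
    pool_composition,
    simulate_population,
)

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


def random_reference(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def trimmed_reads_by_library(dosages, references, model, layout, seed):
    """Generate reads and strip barcodes, grouped per library (bypasses demux)."""
    reads: dict[str, list] = {lib: [] for lib in layout.libraries}
    blen = model.barcode_length
    for batch in generate_read_batches(dosages, references, model, layout, seed=seed):
        lst = reads[batch.library]
        for (s1, q1), (s2, q2) in batch.pairs():
            lst.append((s1[blen:], q1[blen:]))
            lst.append((s2[blen:], q2[blen:]))
    return reads


@pytest.fixture(scope="session")
def layout():
    return PoolLayout()


@pytest.fixture(scope="session")
def small_refs():
    rng = np.random.default_rng(11)
    return {
        "ampA": random_reference(rng, 500),
        "ampB": random_reference(rng, 400),
    }


@pytest.fixture(scope="session")
def small_screen(layout, small_refs):
    """Error-free deep simulation of a small screen, counted in single mode.

    Returns (truth ledger, dosage table, CountsTensor).
    """
    truth = simulate_population(
        layout, small_refs, mutation_rate=2.2e-5, seed=42, unique_sites=True
    )
    dosages = pool_composition(truth, layout)
    model = ReadModel(mean_depth=2500, error_scale=0.0)
    reads = trimmed_reads_by_library(dosages, small_refs, model, layout, seed=43)
    tensor = counts_from_reads(reads, small_refs, mode="single")
    return truth, dosages, tensor
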