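import numpy as np
import pandas as pd
import pytest

from bescreen import design, simulate
from bescreen.reference import standard_codon_table

_BASES = np.array(list("ACGT"))


@pytest.fixture(scope="session")
def toy():
    """Toy genome + annotation with planted filter structure."""
    cfg = simulate.SimConfig()
    genome, annotations, essential = simulate.build_toy_genome(cfg, seed=11)
    return genome, annotations, essential


@pytest.fixture(scope="session")
def codon_table():
    return standard_codon_table()


@pytest.fixture(scope="session")
def toy_guides(toy):
    """Filtered candidates with consequences on the toy genome."""
    genome, annotations, _ = toy
    params = design.DesignParams()
    cands = design.enumerate_guides(genome, params)
    kept, report = design.apply_filters(cands, genome, annotations, params)
    table = standard_codon_table()
    records = []
    for c in kept:
        edits = design.predict_edits(c, genome, params)
        cons = design.annotate_consequence(c, edits, genome, annotations, table, {})
        records.append((c, cons))
    return records, report


def random_library(n_guides: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "guide_id": [f"g{i:04d}" for i in range(n_guides)],
            "protospacer": ["".join(rng.choice(_BASES, 20)) for _ in range(n_guides)],
            "context30": ["".join(rng.choice(_BASES, 30)) for _ in range(n_guides)],
        }
    )
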