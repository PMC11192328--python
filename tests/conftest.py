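import numpy as np
import pandas as pd
import pytest

from invascreen import CountMatrix, LibraryTable


@pytest.fixture
def toy_library() -> LibraryTable:
    """Two targeting genes (3 sgRNAs each) plus 12 non-targeting controls."""
    rows = []
    rng = np.random.default_rng(7)
    spacers = iter(
        dict.fromkeys("".join(rng.choice(list("ACGT"), 20)) for _ in range(100))
    )
    for gene, n in [("GENE1", 3), ("GENE2", 3)]:
        for j in range(n):
            rows.append((f"{gene}_sg{j+1}", gene, next(spacers)))
    for j in range(12):
        rows.append((f"NTC_sg{j+1:02d}", "NTC", next(spacers)))
    return LibraryTable(pd.DataFrame(rows, columns=["sgrna_id", "gene_id", "protospacer"]))


@pytest.fixture
def toy_counts(toy_library) -> CountMatrix:
    rng = np.random.default_rng(3)
    n = len(toy_library)
    data = {
        "T0_r1": rng.integers(500, 1500, n),
        "endpoint_r1": rng.integers(500, 1500, n),
        "T0_r2": rng.integers(500, 1500, n),
        "endpoint_r2": rng.integers(500, 1500, n),
    }
    return CountMatrix(pd.DataFrame(data, index=pd.Index(toy_library.sgrna_ids,
                                                         name="sgrna_id")))
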