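import numpy as np
import pytest

from lambdaseascape.data import synthetic_catalog
from lambdaseascape.genotypes import (
    FocalMutation,
    MutationCatalog,
    WatermarkMutation,
)


@pytest.fixture(scope="session")
def catalog():
    """Default 10-locus catalog (trio at 3034/3319/3321)."""
    return synthetic_catalog()


def small_catalog(L: int, n_required: int = 3) -> MutationCatalog:
    """A tiny exact-position catalog on a short synthetic amplicon.

    Focal locus i sits at amplicon position 10*i + 5 (1-based), with
    watermarks at +2 and +4; the first ``n_required`` loci are flagged
    OmpF-required.
    """
    length = 10 * L + 10
    rng = np.random.default_rng(123)
    seq = "".join(rng.choice(list("ACGT"), length))
    other = {"A": "G", "C": "T", "G": "A", "T": "C"}
    loci = []
    for i in range(L):
        pos = 10 * i + 5
        wms = tuple(
            WatermarkMutation(pos + d, seq[pos + d - 1], other[seq[pos + d - 1]])
            for d in (2, 4)
        )
        loci.append(
            FocalMutation(
                locus_index=i,
                genome_position=pos,
                wt_base=seq[pos - 1],
                mut_base=other[seq[pos - 1]],
                watermarks=wms,
                ompf_required=i < n_required,
            )
        )
    return MutationCatalog(loci=tuple(loci), amplicon_reference=seq, amplicon_offset=0)


@pytest.fixture(scope="session")
def catalog4():
    return small_catalog(4)
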