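import numpy as np
import pandas as pd
import pytest

from panelsim.synthetic_data import GenotypePanel


def make_panel(dosages, inbred=None, chrom=None) -> GenotypePanel:
    """Wrap a raw dosage matrix in a GenotypePanel with stub metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, p = dosages.shape
    if chrom is None:
        chrom = ["chr1"] * p
    pos = []
    counter = {}
    for c in chrom:
        counter[c] = counter.get(c, 0) + 1
        pos.append(counter[c])
    loci = pd.DataFrame(
        {
            "locus_id": [f"locus{j}" for j in range(p)],
            "chromosome": chrom,
            "position": pos,
        }
    )
    if inbred is None:
        inbred = not np.any(dosages == 1)
    return GenotypePanel(
        dosages=dosages,
        individual_ids=[f"ind{i}" for i in range(n)],
        loci=loci,
        inbred=inbred,
    )


def random_inbred_panel(n, p, seed, maf_low=0.1, maf_high=0.9) -> GenotypePanel:
    """Independent-loci inbred panel (no LD) for oracle tests."""
    rng = np.random.default_rng(seed)
    freq = rng.uniform(maf_low, maf_high, p)
    d = (2 * (rng.random((n, p)) < freq)).astype(np.int8)
    return make_panel(d)


@pytest.fixture
def toy_panel():
    """10 inbred individuals x 6 loci with assorted allele frequencies."""
    rng = np.random.default_rng(42)
    d = 2 * (rng.random((10, 6)) < 0.5)
    d[:, 0] = [2, 0, 0, 0, 0, 0, 0, 0, 0, 0]
    return make_panel(d)
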