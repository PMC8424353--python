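import numpy as np
import pandas as pd
import pytest

from icedrift.genio import GenotypeDataset, LocusDef


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_dataset(alleles, areas=None, years=None, loci=None, repeat_unit=2):
    """Small helper: dataset from an (n, L, 2) allele array."""
    alleles = np.asarray(alleles, dtype=np.int64)
    n, L = alleles.shape[:2]
    meta = pd.DataFrame(
        {
            "id": [f"ind{i:03d}" for i in range(n)],
            "area": areas if areas is not None else ["X"] * n,
            "year": years if years is not None else [2000] * n,
            "sex": pd.NA,
            "mother_id": pd.NA,
        }
    )
    loci = loci or [LocusDef(f"L{l + 1}", repeat_unit) for l in range(L)]
    return GenotypeDataset(loci=loci, meta=meta, alleles=alleles)


@pytest.fixture
def toy_dataset():
    """6 individuals, 2 loci, two areas, one missing genotype."""
    alleles = np.array(
        [
            [[100, 102], [150, 150]],
            [[100, 100], [150, 152]],
            [[102, 102], [152, 152]],
            [[100, 102], [-1, -1]],
            [[102, 104], [150, 152]],
            [[104, 104], [150, 150]],
        ]
    )
    return make_dataset(
        alleles,
        areas=["N", "N", "N", "S", "S", "S"],
        years=[1996, 2001, 2008, 2012, 2015, 2016],
    )


@pytest.fixture(scope="session")
def structured_dataset():
    """Mid-size structured monitoring dataset shared by read-only tests."""
    from icedrift.synthdata import SynthSpec, generate_structured_series

    spec = SynthSpec(
        n_per_group=25, fst0=0.02, fst_logit_slope=0.4, he_logit_slope=-0.05
    )
    ds, truth = generate_structured_series(spec, np.random.default_rng(7))
    return ds, truth, spec
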