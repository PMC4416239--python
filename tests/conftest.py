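import numpy as np
import pytest

from rrascan.rra_catalog import RRALocus
from rrascan.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """One complete synthetic study at the default conditions (seed 1)."""
    out = tmp_path_factory.mktemp("study")
    return simulate_study(SimulationConfig(seed=1), str(out))


@pytest.fixture(scope="session")
def catalog(study):
    return study["catalog"]


def make_locus(chrom="chr1", pos=100, ref="A", alt="G", vtype=None,
               rra_class="B", ref_af=0.005):
    """Hand-built catalog locus for unit tests that need no panel."""
    if vtype is None:
        vtype = ("SNV" if len(ref) == len(alt) == 1
                 else "INS" if len(alt) > len(ref) else "DEL")
    return RRALocus(
        chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=[alt],
        variant_type=vtype, ref_af=ref_af,
        n_homref=0, n_het=1, n_homalt=99, n_missing=0, rra_class=rra_class,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
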