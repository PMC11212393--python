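import numpy as np
import pandas as pd
import pytest

from asbqtl.asb import AsbSite
from asbqtl.simulate import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared across unit tests."""
    cfg = SyntheticConfig(n_chromosomes=1, chrom_length=250_000, n_peaks=60,
                          n_cows=12, n_offpeak_snps=150, seed=7)
    return simulate_study(cfg)


def make_site(site_id="s", chrom="chr1", pos=1000, ref="A", alt="G",
              agg_ref=60, agg_alt=40, flank5="ACGTA", flank3="TTGCA",
              n_cows_asb=2) -> AsbSite:
    return AsbSite(site_id=site_id, chrom=chrom, pos=pos, ref_allele=ref,
                   alt_allele=alt, agg_ref=agg_ref, agg_alt=agg_alt,
                   n_cows_asb=n_cows_asb, flank5=flank5, flank3=flank3)


@pytest.fixture
def site_factory():
    return make_site


def random_flanks(rng: np.random.Generator) -> tuple[str, str]:
    b = "ACGT"
    return ("".join(rng.choice(list(b), 5)), "".join(rng.choice(list(b), 5)))


@pytest.fixture
def counts_row():
    def _row(sample, chrom, pos, ref, alt, ref_count, alt_count):
        return dict(sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                    ref_count=ref_count, alt_count=alt_count)
    return _row


@pytest.fixture
def counts_frame(counts_row):
    def _frame(rows):
        return pd.DataFrame([counts_row(*r) for r in rows])
    return _frame
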