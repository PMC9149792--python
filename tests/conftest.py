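import numpy as np
import pandas as pd
import pytest

from gwasim import GenotypePanel, simulate_maf_filtered_panel


def make_panel(calls, ploidy_mode="haploid", pos=None, chrom="chrI",
               genome_length=None):
    """Build a panel from a raw samples × variants call matrix."""
    from gwasim.population import _refresh_variant_stats

    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 10
    variants = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
        "ref": "A", "alt": "C", "is_cnv": False,
    })
    ploidy = 1 if ploidy_mode == "haploid" else 2
    _refresh_variant_stats(variants, calls, ploidy)
    panel = GenotypePanel(
        sample_ids=[f"sample_{i:04d}" for i in range(n)],
        variants=variants, calls=calls, ploidy_mode=ploidy_mode,
        genome_length=genome_length)
    panel.validate()
    return panel


@pytest.fixture(scope="session")
def small_filtered_panel():
    """120 samples × 300 common markers, MAF >= 5%."""
    return simulate_maf_filtered_panel(120, 300, seed=901)
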