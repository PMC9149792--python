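"""Panel simulation, filtering and diversity statistics."""

import numpy as np
import pytest

from gwasim import (PRESETS, PopulationConfig, append_markers, cnv_recode,
                    filter_biallelic, filter_maf, filter_missing,
                    nucleotide_diversity, simulate_panel, singleton_fraction)
from gwasim.population import MISSING, _minor_allele_carriers

from conftest import make_panel


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def test_simulation_is_reproducible():
    cfg = PopulationConfig(n_samples=40, n_variants=200, singleton_rate=0.1,
                           seed=7)
    a = simulate_panel(cfg)
    b = simulate_panel(cfg)
    assert a.equals(b)
    c = simulate_panel(cfg.replace(seed=8))
    assert not np.array_equal(a.calls, c.calls)


@pytest.mark.parametrize("kwargs", [
    dict(n_samples=1),
    dict(n_samples=20, n_variants=0),
    dict(n_samples=20, structure_model="clades", n_clades=2,
         clade_proportions=(0.6, 0.6)),
    dict(n_samples=20, recent_clone_fraction=0.5),  # needs clades
    dict(n_samples=20, singleton_rate=1.5),
    dict(n_samples=20, maf_spectrum=(0.0, 1.0)),
    dict(n_samples=20, genome_length=5, n_variants=100),
])
def test_invalid_configs_raise(kwargs):
    kwargs.setdefault("n_variants", 100)
    with pytest.raises(ValueError):
        PopulationConfig(**kwargs).validate()


def test_singleton_rate_is_honoured():
    cfg = PopulationConfig(n_samples=60, n_variants=400, seed=3,
                           singleton_rate=0.0)
    assert singleton_fraction(simulate_panel(cfg)) == 0.0
    cfg = cfg.replace(singleton_rate=0.25)
    assert singleton_fraction(simulate_panel(cfg)) == pytest.approx(0.25)


def test_singleton_fraction_matches_carrier_tally():
    panel = simulate_panel(PopulationConfig(
        n_samples=30, n_variants=250, singleton_rate=0.3, seed=11))
    # brute force: per-variant minor-allele carrier count
    count = 0
    for j in range(panel.n_variants):
        col = panel.calls[:, j]
        obs = col[col != MISSING]
        alt = obs.sum()
        minor_is_alt = alt / obs.size <= 0.5
        carriers = np.sum(obs > 0) if minor_is_alt else np.sum(obs < 1)
        count += carriers == 1
    assert singleton_fraction(panel) == pytest.approx(count /
                                                      panel.n_variants)


@pytest.mark.parametrize("preset", ["sake-like", "diversity-like"])
def test_preset_realizes_pi_and_singleton_targets(preset):
    cfg = PRESETS[preset].replace(seed=5)
    panel = simulate_panel(cfg)
    pi = nucleotide_diversity(panel)
    assert pi == pytest.approx(cfg.pi_target, rel=0.15)
    assert singleton_fraction(panel) == pytest.approx(cfg.singleton_rate,
                                                      abs=0.02)


def test_maf_spectrum_matches_target_cdf():
    """Realized folded MAFs follow the generator's Beta spectrum.

    Oracle: hand-rolled empirical CDF compared with the analytic target
    CDF (Kolmogorov–Smirnov distance).
    """
    from scipy.stats import beta

    a, b = 2.0, 2.0
    panel = simulate_panel(PopulationConfig(
        n_samples=1000, n_variants=3000, maf_spectrum=(a, b), seed=17))
    maf = np.sort(panel.variants["maf"].to_numpy())
    ecdf = np.arange(1, maf.size + 1) / maf.size
    target = beta.cdf(2.0 * maf, a, b)  # site frequency = 0.5 * Beta(a, b)
    ks = np.max(np.abs(ecdf - target))
    assert ks < 0.05


def test_clone_subclade_creates_maf_049_excess():
    """A near-identical subclade of 23/47 samples yields an excess of
    variants at minor allele frequency exactly 23/47 ≈ 0.489."""
    cfg = PRESETS["sake-like"].replace(seed=29)
    raw = simulate_panel(cfg)
    kept = filter_maf(filter_biallelic(raw), 0.05)
    maf = kept.variants["maf"].to_numpy()
    frac_near_049 = np.mean(maf >= 0.45)
    assert frac_near_049 > 0.06  # strong over-representation
    # clone-fixed variants sit at the clone fraction exactly
    assert np.isclose(raw.variants["maf"].to_numpy(), 23 / 47).sum() > 0
    # unstructured control: no such excess
    control = simulate_maf_ctrl()
    cmaf = control.variants["maf"].to_numpy()
    assert frac_near_049 > 3 * np.mean(cmaf >= 0.45)


def simulate_maf_ctrl():
    cfg = PRESETS["sake-like"].replace(
        seed=29, structure_model="unstructured", n_clades=1,
        recent_clone_fraction=0.0)
    return filter_maf(filter_biallelic(simulate_panel(cfg)), 0.05)


def test_diploid_mode_produces_valid_panel():
    cfg = PopulationConfig(n_samples=40, n_variants=150, seed=19,
                           ploidy_mode="diploid", singleton_rate=0.1,
                           missing_rate=0.02)
    panel = simulate_panel(cfg)
    panel.validate()
    assert panel.calls.max() == 2
    assert 0 < nucleotide_diversity(panel) < 1


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def test_filter_biallelic_drops_monomorphic_and_keeps_order():
    calls = np.array([
        [0, 1, 0, 1],
        [0, 0, 1, 1],
        [0, 1, 0, 0],
    ])
    panel = make_panel(calls)
    out = filter_biallelic(panel)
    assert out.n_variants == 3  # first site monomorphic -> one allele
    assert list(out.variants["pos"]) == [20, 30, 40]
    assert filter_biallelic(out).equals(out)  # identity on clean panels


def test_filter_missing_threshold_boundary():
    # a site missing in 12 samples survives threshold 12 but not 11
    calls = np.zeros((20, 2), dtype=int)
    calls[:, 1] = 1
    calls[:12, 0] = MISSING
    calls[0, 0] = MISSING
    panel = make_panel(calls)
    assert filter_missing(panel, 11).n_variants == 1
    assert filter_missing(panel, 12).n_variants == 2
    with pytest.raises(ValueError):
        filter_missing(panel, -1)


def test_filter_maf_boundary_keeps_exact_threshold():
    calls = np.zeros((50, 3), dtype=int)
    calls[:2, 0] = 1   # maf 0.04 -> removed
    calls[:3, 1] = 1   # maf 0.06 -> kept
    calls[:25, 2] = 1  # maf 0.50 -> kept
    panel = make_panel(calls)
    out = filter_maf(panel, 0.05)
    assert list(out.variants["pos"]) == [20, 30]
    # exact boundary kept
    calls = np.zeros((40, 1), dtype=int)
    calls[:2, 0] = 1  # maf exactly 0.05
    assert filter_maf(make_panel(calls), 0.05).n_variants == 1
    with pytest.raises(ValueError):
        filter_maf(panel, 0.7)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_filters_commute_and_are_idempotent(seed):
    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 2, size=(30, 120)).astype(np.int16)
    calls[rng.random(calls.shape) < 0.05] = MISSING
    panel = make_panel(calls)

    a = filter_maf(filter_missing(panel, 1), 0.1)
    b = filter_missing(filter_maf(panel, 0.1), 1)
    assert a.equals(b)
    assert filter_maf(a, 0.1).equals(a)  # idempotent
    # nested MAF filters collapse to the max threshold
    assert filter_maf(filter_maf(panel, 0.05), 0.2).equals(
        filter_maf(panel, 0.2))
    assert filter_maf(panel, 0.0).n_variants == np.sum(
        ~np.isnan(panel.variants["maf"].to_numpy()))


def test_filter_missing_matches_direct_count():
    rng = np.random.default_rng(5)
    calls = rng.integers(0, 2, size=(40, 200)).astype(np.int16)
    calls[rng.random(calls.shape) < 0.05] = MISSING
    panel = make_panel(calls)
    survivors = filter_missing(panel, 3).n_variants
    oracle = sum(int(np.sum(calls[:, j] == MISSING)) <= 3
                 for j in range(200))
    assert survivors == oracle


def test_filter_maf_matches_allele_count_oracle():
    panel = simulate_panel(PopulationConfig(
        n_samples=80, n_variants=300, singleton_rate=0.2, seed=23,
        missing_rate=0.01))
    survivors = filter_maf(panel, 0.05).n_variants
    oracle = 0
    for j in range(panel.n_variants):
        col = panel.calls[:, j]
        obs = col[col != MISSING]
        af = obs.sum() / obs.size
        oracle += min(af, 1 - af) >= 0.05
    assert survivors == oracle


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------


def test_pi_two_samples_one_difference():
    calls = np.array([[0], [1]])
    assert nucleotide_diversity(make_panel(calls),
                                genome_length=100) == pytest.approx(0.01)


def test_pi_monomorphic_is_zero():
    calls = np.zeros((6, 4), dtype=int)
    assert nucleotide_diversity(make_panel(calls), genome_length=50) == 0.0


def test_pi_matches_all_pairs_hamming_oracle():
    rng = np.random.default_rng(13)
    calls = rng.integers(0, 2, size=(5, 40))
    panel = make_panel(calls)
    L = 1000
    total = 0.0
    n = 5
    for j in range(40):
        diffs = sum(calls[i, j] != calls[k, j]
                    for i in range(n) for k in range(i + 1, n))
        total += diffs / (n * (n - 1) / 2)
    assert nucleotide_diversity(panel, genome_length=L) == \
        pytest.approx(total / L)
    with pytest.raises(ValueError):
        nucleotide_diversity(panel, genome_length=0)


def test_singleton_fraction_of_empty_panel_is_an_error():
    panel = make_panel(np.zeros((4, 1), dtype=int)).take_variants([])
    with pytest.raises(ValueError):
        singleton_fraction(panel)


# ---------------------------------------------------------------------------
# CNV recoding
# ---------------------------------------------------------------------------


def test_cnv_recode_encoding_rule():
    cn = np.array([[1], [1], [3], [2]])
    markers = cnv_recode(cn)
    # codes 1,1,2,2 stored as calls 0,0,1,1 with alleles "1"/"2"
    assert markers.n_variants == 1
    assert list(markers.calls[:, 0] + 1) == [1, 1, 2, 2]
    assert bool(markers.variants["is_cnv"].iloc[0])


def test_cnv_without_variation_is_dropped():
    assert cnv_recode(np.ones((5, 3), dtype=int)).n_variants == 0


def test_cnv_retained_count_matches_distinct_code_oracle():
    rng = np.random.default_rng(31)
    cn = rng.integers(0, 5, size=(20, 50))
    markers = cnv_recode(cn)
    oracle = sum(len({1 if c <= 1 else 2 for c in cn[:, j]}) == 2
                 for j in range(50))
    assert markers.n_variants == oracle
    with pytest.raises(ValueError):
        cnv_recode(np.array([[-1, 2]]))


def test_cnv_markers_append_to_a_panel():
    panel = make_panel(np.array([[0, 1], [1, 0], [1, 1]]))
    cnv = cnv_recode(np.array([[1], [2], [1]]),
                     sample_ids=panel.sample_ids)
    merged = append_markers(panel, cnv)
    merged.validate()
    assert merged.n_variants == 3
    assert merged.variants["is_cnv"].sum() == 1
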