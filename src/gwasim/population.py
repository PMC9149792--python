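"""Simulation and filtering of structured, yeast-like genotype panels.

Generates haploid or diploid biallelic SNP panels whose summary
characteristics — sample size, nucleotide diversity (π), singleton
fraction, minor-allele-frequency (MAF) spectrum, relatedness structure —
can be dialled to emulate real *Saccharomyces cerevisiae* subpopulations,
and provides the marker-filtering steps used to prepare a GWAS genotype
matrix (biallelic-only, missingness, MAF), plus VCF and PLINK-style text
I/O.

Population structure follows a Balding–Nichols model: per-variant
ancestral frequencies are drawn from a folded Beta spectrum, then drifted
independently within each clade.  An optional "recent clone" subclade —
a block of samples copying a single ancestral haplotype — reproduces the
hallmark of very recent common ancestry: an excess of variants at a minor
allele frequency equal to the clone fraction.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING = -1

_BASES = np.array(list("ACGT"))

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PopulationConfig:
    """Parameters of one synthetic population panel.

    Parameters
    ----------
    n_samples, n_variants
        Panel dimensions (isolates × polymorphic sites).
    genome_length
        Genome size in bp used as the π denominator and the range of
        variant positions.  If ``None`` and ``pi_target`` is set, it is
        solved so that the expected π matches the target; otherwise it
        defaults to ``100 * n_variants``.
    pi_target
        Desired average pairwise nucleotide diversity.
    structure_model
        ``"unstructured"`` (panmictic) or ``"clades"`` (Balding–Nichols
        drift between clades).
    n_clades, clade_proportions, clade_divergence
        Number of clades, their sample-share (defaults to equal) and the
        per-clade drift parameter F in [0, 1).
    recent_clone_fraction
        Fraction of samples forced into one near-identical subclade
        (carved out of clade 0); these samples share a single haplotype.
    singleton_rate
        Target fraction of variants whose minor allele is carried by
        exactly one sample.
    maf_spectrum
        ``(a, b)`` of the Beta distribution from which per-site ancestral
        frequencies are drawn (scaled onto (0, 0.5]).
    missing_rate
        Missing-completely-at-random genotype rate.
    ploidy_mode
        ``"haploid"`` (calls in {0,1}) or ``"diploid"`` (calls in {0,1,2}).
    seed
        Integer or :class:`numpy.random.SeedSequence`; identical config +
        seed reproduces the panel bit for bit.
    """

    n_samples: int
    n_variants: int
    genome_length: int | None = None
    pi_target: float | None = None
    structure_model: str = "unstructured"
    n_clades: int = 1
    clade_proportions: tuple[float, ...] | None = None
    clade_divergence: float | tuple[float, ...] = 0.0
    recent_clone_fraction: float = 0.0
    singleton_rate: float = 0.0
    maf_spectrum: tuple[float, float] = (0.5, 1.5)
    missing_rate: float = 0.0
    ploidy_mode: str = "haploid"
    seed: int | np.random.SeedSequence | None = None
    name: str | None = None

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("invalid config: n_samples must be >= 2")
        if self.n_variants < 1:
            raise ValueError("invalid config: n_variants must be >= 1")
        if self.structure_model not in ("unstructured", "clades"):
            raise ValueError(f"invalid config: unknown structure_model "
                             f"{self.structure_model!r}")
        if self.ploidy_mode not in ("haploid", "diploid"):
            raise ValueError("invalid config: ploidy_mode must be "
                             "'haploid' or 'diploid'")
        for name in ("recent_clone_fraction", "singleton_rate",
                     "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"invalid config: {name}={v} not in [0,1]")
        a, b = self.maf_spectrum
        if a <= 0 or b <= 0:
            raise ValueError("invalid config: maf_spectrum Beta parameters "
                             "must be positive")
        if self.structure_model == "clades":
            props = self._resolved_proportions()
            if len(props) != self.n_clades:
                raise ValueError("invalid config: clade_proportions length "
                                 "does not match n_clades")
            if abs(sum(props) - 1.0) > 1e-8:
                raise ValueError("invalid config: clade_proportions must "
                                 "sum to 1")
            for f in self._resolved_divergence():
                if not 0.0 <= f < 1.0:
                    raise ValueError("invalid config: clade_divergence must "
                                     "be in [0, 1)")
            n_clone = int(round(self.recent_clone_fraction * self.n_samples))
            counts = _clade_counts(self.n_samples, props)
            if n_clone > counts[0]:
                raise ValueError("invalid config: recent_clone_fraction "
                                 "exceeds the share of clade 0")
        elif self.recent_clone_fraction > 0:
            raise ValueError("invalid config: recent_clone_fraction requires "
                             "structure_model='clades'")
        if self.genome_length is not None and \
                self.genome_length < self.n_variants:
            raise ValueError("invalid config: genome_length smaller than "
                             "n_variants")
        if self.pi_target is not None and self.pi_target <= 0:
            raise ValueError("invalid config: pi_target must be positive")

    def _resolved_proportions(self) -> tuple[float, ...]:
        if self.clade_proportions is not None:
            return tuple(self.clade_proportions)
        return tuple([1.0 / self.n_clades] * self.n_clades)

    def _resolved_divergence(self) -> tuple[float, ...]:
        d = self.clade_divergence
        if np.isscalar(d):
            return tuple([float(d)] * self.n_clades)
        return tuple(float(x) for x in d)  # type: ignore[union-attr]

    @property
    def ploidy(self) -> int:
        return 1 if self.ploidy_mode == "haploid" else 2

    def replace(self, **kwargs) -> "PopulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GenotypePanel:
    """A samples × variants matrix of biallelic allele counts.

    ``calls[i, j]`` is the number of alternate alleles sample *i* carries
    at variant *j* (``MISSING`` = −1 for a missing call).  ``variants`` is
    a DataFrame with one row per variant: ``chrom``, ``pos`` (1-based),
    ``ref``, ``alt``, ``maf``, ``n_missing``, ``n_alleles`` (distinct
    alleles observed among non-missing calls) and ``is_cnv``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray
    ploidy_mode: str = "haploid"
    genome_length: int | None = None

    @property
    def ploidy(self) -> int:
        return 1 if self.ploidy_mode == "haploid" else 2

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        n, m = self.calls.shape
        if n != self.n_samples or m != self.n_variants:
            raise ValueError("calls shape does not match sample_ids × "
                             "variants")
        valid = (self.calls == MISSING) | (
            (self.calls >= 0) & (self.calls <= self.ploidy))
        if not valid.all():
            raise ValueError("calls contain values outside "
                             f"[0, {self.ploidy}] ∪ {{{MISSING}}}")
        key = list(zip(self.variants["chrom"], self.variants["pos"]))
        if any(key[i] >= key[i + 1] for i in range(len(key) - 1)):
            raise ValueError("variants not strictly increasing by "
                             "(chrom, pos)")

    # -- subsetting ---------------------------------------------------------

    def take_variants(self, index) -> "GenotypePanel":
        """Subset to the given variant positions (order preserved)."""
        index = np.asarray(index)
        if index.dtype != bool:
            index = index.astype(np.intp)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index].copy(),
            ploidy_mode=self.ploidy_mode,
            genome_length=self.genome_length,
        )

    def take_samples(self, index) -> "GenotypePanel":
        """Subset samples and recompute per-variant summaries."""
        index = np.asarray(index)
        calls = self.calls[index].copy()
        variants = self.variants.copy().reset_index(drop=True)
        _refresh_variant_stats(variants, calls, self.ploidy)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in index],
            variants=variants,
            calls=calls,
            ploidy_mode=self.ploidy_mode,
            genome_length=self.genome_length,
        )

    def equals(self, other: "GenotypePanel") -> bool:
        return (self.sample_ids == other.sample_ids
                and self.ploidy_mode == other.ploidy_mode
                and np.array_equal(self.calls, other.calls)
                and self.variants.equals(other.variants))


# ---------------------------------------------------------------------------
# Per-site allele bookkeeping
# ---------------------------------------------------------------------------


def _site_allele_counts(calls: np.ndarray, ploidy: int):
    """Return (alt allele count, total called alleles, n_missing) per site."""
    missing = calls == MISSING
    n_called = (~missing).sum(axis=0)
    alt = np.where(missing, 0, calls).sum(axis=0)
    total = n_called * ploidy
    return alt.astype(np.int64), total.astype(np.int64), \
        missing.sum(axis=0).astype(np.int64)


def _site_maf(calls: np.ndarray, ploidy: int) -> np.ndarray:
    alt, total, _ = _site_allele_counts(calls, ploidy)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    return np.minimum(af, 1.0 - af)


def _site_n_alleles(calls: np.ndarray, ploidy: int) -> np.ndarray:
    alt, total, _ = _site_allele_counts(calls, ploidy)
    return np.where(total == 0, 0, (alt > 0).astype(int)
                    + (alt < total).astype(int))


def _refresh_variant_stats(variants: pd.DataFrame, calls: np.ndarray,
                           ploidy: int) -> None:
    alt, total, n_missing = _site_allele_counts(calls, ploidy)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    variants["maf"] = np.minimum(af, 1.0 - af)
    variants["n_missing"] = n_missing
    variants["n_alleles"] = np.where(
        total == 0, 0, (alt > 0).astype(int) + (alt < total).astype(int))


def _minor_allele_carriers(calls: np.ndarray, ploidy: int) -> np.ndarray:
    """Number of samples carrying at least one copy of the minor allele."""
    alt, total, _ = _site_allele_counts(calls, ploidy)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    obs = calls != MISSING
    alt_carriers = ((calls > 0) & obs).sum(axis=0)
    ref_carriers = ((calls < ploidy) & obs).sum(axis=0)
    # ties (af == 0.5): call the alternate allele the minor one
    return np.where(af <= 0.5, alt_carriers, ref_carriers)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _clade_counts(n: int, props: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n samples among clades."""
    raw = np.asarray(props) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


@dataclass
class _Structure:
    clades: list[np.ndarray]        # per clade: independent member indices
    clone: np.ndarray               # clone member indices (may be empty)
    divergence: tuple[float, ...]


def _build_structure(cfg: PopulationConfig) -> _Structure:
    n = cfg.n_samples
    if cfg.structure_model == "unstructured":
        return _Structure([np.arange(n)], np.empty(0, dtype=int), (0.0,))
    props = cfg._resolved_proportions()
    counts = _clade_counts(n, props)
    bounds = np.cumsum([0] + counts)
    clades = [np.arange(bounds[c], bounds[c + 1])
              for c in range(cfg.n_clades)]
    n_clone = int(round(cfg.recent_clone_fraction * n))
    clone = clades[0][:n_clone]
    clades[0] = clades[0][n_clone:]
    return _Structure(clades, clone, cfg._resolved_divergence())


def _drift_frequencies(rng, p0: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols clade frequencies around ancestral p0."""
    if f <= 0:
        return p0
    c = (1.0 - f) / f
    return rng.beta(np.maximum(p0 * c, 1e-8),
                    np.maximum((1.0 - p0) * c, 1e-8))


def _draw_common_sites(rng, cfg: PopulationConfig, struct: _Structure,
                       n_sites: int) -> np.ndarray:
    """Draw polymorphic, non-singleton site columns (batched rejection).

    A column is accepted when it is polymorphic and its minor allele is
    carried by at least two samples, so that the singleton fraction of the
    panel is controlled solely by ``singleton_rate``.
    """
    n, ploidy = cfg.n_samples, cfg.ploidy
    a, b = cfg.maf_spectrum
    out: list[np.ndarray] = []
    got = 0
    tries = 0
    while got < n_sites:
        tries += 1
        if tries > 2000:
            raise RuntimeError("site sampler failed to converge; check the "
                               "MAF spectrum and structure parameters")
        batch = max(int(1.6 * (n_sites - got)) + 8, 16)
        p0 = np.clip(0.5 * rng.beta(a, b, size=batch), 1e-4, 0.5)
        calls = np.empty((n, batch), dtype=np.int16)
        p_clade0 = p0
        for c, members in enumerate(struct.clades):
            pc = _drift_frequencies(rng, p0, struct.divergence[c])
            if c == 0:
                p_clade0 = pc
            if members.size:
                calls[members] = rng.binomial(
                    ploidy, pc[None, :], size=(members.size, batch))
        if struct.clone.size:
            ancestor = rng.binomial(ploidy, p_clade0).astype(np.int16)
            calls[struct.clone] = ancestor[None, :]
        alt = calls.sum(axis=0)
        total = n * ploidy
        polymorphic = (alt > 0) & (alt < total)
        alt_carriers = (calls > 0).sum(axis=0)
        ref_carriers = (calls < ploidy).sum(axis=0)
        minor_carriers = np.where(alt / total <= 0.5,
                                  alt_carriers, ref_carriers)
        ok = polymorphic & (minor_carriers >= 2)
        if ok.any():
            out.append(calls[:, ok])
            got += int(ok.sum())
    return np.concatenate(out, axis=1)[:, :n_sites]


def _draw_singleton_sites(rng, cfg: PopulationConfig,
                          n_sites: int) -> np.ndarray:
    calls = np.zeros((cfg.n_samples, n_sites), dtype=np.int16)
    if n_sites:
        carriers = rng.integers(0, cfg.n_samples, size=n_sites)
        calls[carriers, np.arange(n_sites)] = 1
    return calls


def _expected_pi_per_variant(cfg: PopulationConfig,
                             seed: np.random.SeedSequence) -> float:
    """Mean per-site π of the generator, via a deterministic pilot draw."""
    rng = np.random.default_rng(seed)
    struct = _build_structure(cfg)
    total_alleles = cfg.n_samples * cfg.ploidy
    pilot = min(2000, max(400, cfg.n_variants))
    calls = _draw_common_sites(rng, cfg, struct, pilot)
    alt, total, _ = _site_allele_counts(calls, cfg.ploidy)
    pairs = total * (total - 1) / 2.0
    pi_common = float(np.mean(alt * (total - alt) / pairs))
    pi_singleton = 2.0 / total_alleles
    s = cfg.singleton_rate
    return s * pi_singleton + (1.0 - s) * pi_common


def simulate_panel(config: PopulationConfig) -> GenotypePanel:
    """Simulate a genotype panel according to ``config``.

    Reproducible: identical config + seed yields an identical panel.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed) \
        if not isinstance(config.seed, np.random.SeedSequence) \
        else config.seed
    s_cal, s_sites, s_pos, s_miss = ss.spawn(4)

    n, m = config.n_samples, config.n_variants
    L = config.genome_length
    if L is None:
        if config.pi_target is not None:
            per_site = _expected_pi_per_variant(config, s_cal)
            L = int(round(m * per_site / config.pi_target))
        else:
            L = 100 * m
    L = max(L, m)

    struct = _build_structure(config)
    rng = np.random.default_rng(s_sites)
    m_singleton = int(round(config.singleton_rate * m))
    m_common = m - m_singleton
    common = _draw_common_sites(rng, config, struct, m_common)
    singles = _draw_singleton_sites(rng, config, m_singleton)

    calls = np.empty((n, m), dtype=np.int16)
    is_single = np.zeros(m, dtype=bool)
    is_single[rng.choice(m, size=m_singleton, replace=False)] = True
    calls[:, ~is_single] = common
    calls[:, is_single] = singles

    rng_pos = np.random.default_rng(s_pos)
    pos = np.unique(rng_pos.integers(1, L + 1, size=int(1.3 * m) + 64))
    while pos.size < m:
        pos = np.unique(np.concatenate(
            [pos, rng_pos.integers(1, L + 1, size=m)]))
    pos = np.sort(rng_pos.choice(pos, size=m, replace=False))
    ref_idx = rng_pos.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng_pos.integers(1, 4, size=m)) % 4

    if config.missing_rate > 0:
        rng_miss = np.random.default_rng(s_miss)
        mask = rng_miss.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    variants = pd.DataFrame({
        "chrom": "chrI",
        "pos": pos.astype(np.int64),
        "ref": _BASES[ref_idx],
        "alt": _BASES[alt_idx],
        "is_cnv": False,
    })
    _refresh_variant_stats(variants, calls, config.ploidy)
    panel = GenotypePanel(
        sample_ids=[f"sample_{i:04d}" for i in range(n)],
        variants=variants,
        calls=calls,
        ploidy_mode=config.ploidy_mode,
        genome_length=L,
    )
    logger.info("simulated panel %s: n=%d m=%d L=%d",
                config.name or "<unnamed>", n, m, L)
    return panel


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_biallelic(panel: GenotypePanel) -> GenotypePanel:
    """Keep only sites with exactly two observed alleles."""
    n_alleles = panel.variants["n_alleles"].to_numpy()
    keep = np.flatnonzero(n_alleles == 2)
    if keep.size == 0:
        warnings.warn("filter_biallelic removed every variant", stacklevel=2)
    return panel.take_variants(keep)


def filter_missing(panel: GenotypePanel,
                   max_missing_count: int) -> GenotypePanel:
    """Drop variants missing in more than ``max_missing_count`` samples.

    ``max_missing_count=0`` keeps only fully-called sites.
    """
    if max_missing_count < 0:
        raise ValueError("max_missing_count must be >= 0")
    keep = np.flatnonzero(
        panel.variants["n_missing"].to_numpy() <= max_missing_count)
    return panel.take_variants(keep)


def filter_maf(panel: GenotypePanel, min_maf: float = 0.05) -> GenotypePanel:
    """Drop variants with minor allele frequency strictly below ``min_maf``.

    The boundary is kept: a site at exactly ``min_maf`` survives.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    maf = panel.variants["maf"].to_numpy()
    keep = np.flatnonzero(maf >= min_maf)  # NaN MAF (unrepresentable) drops
    return panel.take_variants(keep)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def nucleotide_diversity(panel: GenotypePanel,
                         genome_length: int | None = None) -> float:
    """Average pairwise nucleotide diversity π.

    π = Σ_sites [pairwise differences / pairs] / genome_length, computed
    from per-site allele counts over non-missing calls (the per-site
    definition used by vcftools ``--window-pi`` with a whole-genome
    window).
    """
    L = genome_length if genome_length is not None else panel.genome_length
    if L is None or L <= 0:
        raise ValueError("genome_length must be positive")
    alt, total, _ = _site_allele_counts(panel.calls, panel.ploidy)
    ok = total >= 2
    pairs = total[ok] * (total[ok] - 1) / 2.0
    diffs = alt[ok] * (total[ok] - alt[ok])
    return float(np.sum(diffs / pairs) / L)


def singleton_fraction(panel: GenotypePanel) -> float:
    """Fraction of variants whose minor allele sits in exactly one sample."""
    if panel.n_variants == 0:
        raise ValueError("singleton fraction undefined for an empty panel")
    carriers = _minor_allele_carriers(panel.calls, panel.ploidy)
    return float(np.mean(carriers == 1))


# ---------------------------------------------------------------------------
# Copy-number markers
# ---------------------------------------------------------------------------


def cnv_recode(copy_numbers: np.ndarray,
               sample_ids: list[str] | None = None,
               gene_ids: list[str] | None = None) -> GenotypePanel:
    """Recode a samples × genes copy-number matrix into 1/2 markers.

    Copy number ≤ 1 → code 1 (single copy), ≥ 2 → code 2 (amplified);
    genes without variation among samples are dropped.  The returned
    panel stores code − 1 in its calls ({0, 1}, haploid convention) with
    ``ref="1"`` / ``alt="2"`` and ``is_cnv=True``, so CNV markers can be
    appended to a SNP panel and tested like any other marker.
    """
    cn = np.asarray(copy_numbers)
    if (cn < 0).any():
        raise ValueError("copy numbers must be >= 0")
    codes = np.where(cn >= 2, 2, 1).astype(np.int16)
    varying = np.flatnonzero(codes.min(axis=0) != codes.max(axis=0))
    codes = codes[:, varying]
    n, g = codes.shape
    if sample_ids is None:
        sample_ids = [f"sample_{i:04d}" for i in range(n)]
    if gene_ids is None:
        gene_ids = [f"gene_{j}" for j in range(cn.shape[1])]
    variants = pd.DataFrame({
        "chrom": "cnv",
        "pos": np.asarray(varying, dtype=np.int64) + 1,
        "ref": "1",
        "alt": "2",
        "is_cnv": True,
        "gene": [gene_ids[j] for j in varying],
    })
    calls = (codes - 1).astype(np.int16)
    _refresh_variant_stats(variants, calls, 1)
    return GenotypePanel(sample_ids=list(sample_ids), variants=variants,
                         calls=calls, ploidy_mode="haploid")


def append_markers(panel: GenotypePanel,
                   markers: GenotypePanel) -> GenotypePanel:
    """Concatenate two panels over the same samples, re-sorted by
    (chrom, pos)."""
    if panel.sample_ids != markers.sample_ids:
        raise ValueError("panels must share identical sample_ids")
    if panel.ploidy_mode != markers.ploidy_mode:
        raise ValueError("panels must share the same ploidy mode")
    variants = pd.concat([panel.variants, markers.variants],
                         ignore_index=True)
    calls = np.concatenate([panel.calls, markers.calls], axis=1)
    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].to_numpy()))
    return GenotypePanel(
        sample_ids=list(panel.sample_ids),
        variants=variants.iloc[order].reset_index(drop=True),
        calls=calls[:, order],
        ploidy_mode=panel.ploidy_mode,
        genome_length=panel.genome_length,
    )


# ---------------------------------------------------------------------------
# VCF I/O (pysam)
# ---------------------------------------------------------------------------


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write the panel as an uncompressed VCF with GT calls."""
    header = pysam.VariantHeader()
    length = int(panel.genome_length or
                 (panel.variants["pos"].max() if panel.n_variants else 1))
    for chrom in pd.unique(panel.variants["chrom"]):
        header.contigs.add(str(chrom), length=max(
            length, int(panel.variants.loc[
                panel.variants["chrom"] == chrom, "pos"].max())))
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in panel.sample_ids:
        header.add_sample(sid)
    ploidy = panel.ploidy
    with pysam.VariantFile(path, "w", header=header) as vf:
        for j in range(panel.n_variants):
            row = panel.variants.iloc[j]
            rec = vf.new_record(contig=str(row["chrom"]),
                                start=int(row["pos"]) - 1,
                                alleles=(str(row["ref"]), str(row["alt"])))
            for i, sid in enumerate(panel.sample_ids):
                c = int(panel.calls[i, j])
                if c == MISSING:
                    gt = (None,) * ploidy
                elif ploidy == 1:
                    gt = (c,)
                else:
                    gt = (0, 0) if c == 0 else ((0, 1) if c == 1 else (1, 1))
                rec.samples[sid]["GT"] = gt
            vf.write(rec)


def read_vcf(path: str) -> GenotypePanel:
    """Read a VCF into a panel.

    Biallelic records become allele-count calls.  Records with more than
    one ALT allele are carried with missing calls and their observed
    allele count in ``n_alleles``, so that :func:`filter_biallelic` can
    census and drop them; their genotypes are not representable in the
    biallelic call matrix.
    """
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        rows = []
        cols = []
        ploidy = 1
        for rec in vf:
            alts = rec.alts or ()
            counts = np.full(len(samples), MISSING, dtype=np.int16)
            observed: set[int] = set()
            n_missing = 0
            for i, sid in enumerate(samples):
                alleles = rec.samples[sid].allele_indices
                if alleles is None:
                    alleles = (None,)
                ploidy = max(ploidy, len(alleles))
                called = [a for a in alleles if a is not None]
                observed.update(called)
                if not called:
                    n_missing += 1
                elif len(alts) <= 1:
                    counts[i] = sum(1 for a in called if a > 0)
            multi = len(alts) > 1
            if multi:
                counts[:] = MISSING
            rows.append({
                "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": ",".join(alts) if alts else ".",
                "is_cnv": False,
                "n_missing": n_missing,
                "n_alleles": len(observed),
            })
            cols.append(counts)
    variants = pd.DataFrame(rows)
    calls = (np.stack(cols, axis=1) if cols
             else np.empty((len(samples), 0), dtype=np.int16))
    ploidy_mode = "haploid" if ploidy == 1 else "diploid"
    alt_c, total, _ = _site_allele_counts(calls, 1 if ploidy == 1 else 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, alt_c / np.maximum(total, 1), np.nan)
    variants["maf"] = np.minimum(af, 1.0 - af)
    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].to_numpy()))
    return GenotypePanel(sample_ids=samples,
                         variants=variants.iloc[order].reset_index(drop=True),
                         calls=calls[:, order], ploidy_mode=ploidy_mode)


# ---------------------------------------------------------------------------
# PLINK-style transposed text I/O
# ---------------------------------------------------------------------------


def write_plink_text(panel: GenotypePanel, prefix: str) -> None:
    """Write ``<prefix>.variants.tsv`` (metadata) and ``<prefix>.calls.tsv``
    (variants × samples integer matrix, −1 = missing)."""
    panel.variants.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
    mat = pd.DataFrame(panel.calls.T, columns=panel.sample_ids)
    with open(f"{prefix}.calls.tsv", "w") as fh:
        fh.write(f"#ploidy={panel.ploidy_mode}\n")
        mat.to_csv(fh, sep="\t", index=False)


def read_plink_text(prefix: str) -> GenotypePanel:
    variants = pd.read_csv(f"{prefix}.variants.tsv", sep="\t")
    with open(f"{prefix}.calls.tsv") as fh:
        first = fh.readline().strip()
        ploidy_mode = first.split("=", 1)[1] if first.startswith("#ploidy") \
            else "haploid"
        mat = pd.read_csv(fh, sep="\t")
    calls = mat.to_numpy(dtype=np.int16).T
    return GenotypePanel(sample_ids=list(mat.columns), variants=variants,
                         calls=calls, ploidy_mode=ploidy_mode)


# ---------------------------------------------------------------------------
# Flat key=value config files and bundled population presets
# ---------------------------------------------------------------------------

_LIST_FIELDS = {"clade_proportions", "maf_spectrum", "clade_divergence"}


def save_config(config: PopulationConfig, path: str) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            v = getattr(config, f.name)
            if v is None:
                continue
            if f.name in _LIST_FIELDS and not np.isscalar(v):
                v = ",".join(str(x) for x in v)
            fh.write(f"{f.name} = {v}\n")


def load_config(path: str) -> PopulationConfig:
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(PopulationConfig)}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if key in ("structure_model", "ploidy_mode", "name"):
                kwargs[key] = raw
            elif key in _LIST_FIELDS and "," in raw:
                kwargs[key] = tuple(float(x) for x in raw.split(","))
            elif key in ("n_samples", "n_variants", "genome_length",
                         "n_clades", "seed"):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
    return PopulationConfig(**kwargs)


#: Presets emulating the six study populations (marker counts scaled
#: down 100× from the raw polymorphic-site totals; sample sizes, π,
#: singleton fractions and the sake clone fraction kept at full scale).
PRESETS: dict[str, PopulationConfig] = {
    "1011-like": PopulationConfig(
        n_samples=1011, n_variants=16258, pi_target=0.0044,
        singleton_rate=0.313, maf_spectrum=(0.15, 1.1),
        structure_model="clades", n_clades=6, clade_divergence=0.15,
        missing_rate=0.001, name="1011-like"),
    "mixed-like": PopulationConfig(
        n_samples=71, n_variants=1421, pi_target=0.0032,
        singleton_rate=0.028, maf_spectrum=(1.5, 1.2),
        structure_model="clades", n_clades=2, clade_divergence=0.05,
        name="mixed-like"),
    "mosaic3-like": PopulationConfig(
        n_samples=113, n_variants=4968, pi_target=0.0042,
        singleton_rate=0.350, maf_spectrum=(0.3, 1.1),
        structure_model="clades", n_clades=3, clade_divergence=0.10,
        name="mosaic3-like"),
    "sake-like": PopulationConfig(
        n_samples=47, n_variants=1003, pi_target=0.0008,
        singleton_rate=0.145, maf_spectrum=(0.18, 3.0),
        structure_model="clades", n_clades=1,
        recent_clone_fraction=23 / 47, name="sake-like"),
    "diversity-like": PopulationConfig(
        n_samples=133, n_variants=9351, pi_target=0.0049,
        singleton_rate=0.542, maf_spectrum=(0.25, 1.3),
        structure_model="unstructured", name="diversity-like"),
    "wine-like": PopulationConfig(
        n_samples=323, n_variants=2843, pi_target=0.0012,
        singleton_rate=0.370, maf_spectrum=(0.15, 1.1),
        structure_model="clades", n_clades=2,
        clade_proportions=(0.85, 0.15), clade_divergence=0.25,
        recent_clone_fraction=0.08, name="wine-like"),
}
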