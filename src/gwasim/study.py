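"""Orchestration of the simulation study and real-data association.

One *study* = one population (bundled preset, ad-hoc config, or loaded
files) × one trait architecture (Mendelian: 1 causal SNP; complex: 10;
or pure-noise null traits) × ``n_runs`` independent replicates.  Each
replicate draws causal variants and a phenotype at the target
heritability, fits the null mixed model, scans every marker, derives a
permutation family-wise threshold, and records a confusion summary with
λ and the heritability estimate.

Seeding is counter-based: run *i* of a study with master seed *s* uses
``SeedSequence(s, spawn_key=(1, i))``, so runs are independent and any
single run can be replayed in isolation.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import confusion_rates, genomic_inflation, \
    permutation_threshold
from .lmm import AssociationEngine, AssociationResult
from .population import PRESETS, GenotypePanel, PopulationConfig, \
    filter_biallelic, filter_maf, filter_missing, read_plink_text, read_vcf, \
    simulate_panel
from .traits import read_phenotype, sample_causal, simulate_trait

logger = logging.getLogger(__name__)

_N_CAUSAL_BY_TRAIT = {"mendelian": 1, "complex": 10, "null": 0}


@dataclass
class StudyConfig:
    """Parameters of one simulation study."""

    preset: str | None = None
    population: PopulationConfig | None = None
    trait_type: str = "complex"
    n_causal: int | None = None
    h2: float = 0.8
    n_runs: int = 100
    n_perm: int = 100
    fwer: float = 0.05
    maf_min: float = 0.05
    max_missing_count: int = 0
    downsample_to: int | None = None
    linkage_window: float | None = None
    seed: int = 0
    name: str | None = None

    def validate(self) -> None:
        if self.trait_type not in _N_CAUSAL_BY_TRAIT:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if self.resolved_n_causal() < 0:
            raise ValueError("n_causal must be >= 0")
        if self.resolved_n_causal() >= 1 and self.h2 > 0 and \
                self.trait_type == "null":
            raise ValueError("null studies must use h2 = 0")

    def resolved_n_causal(self) -> int:
        if self.n_causal is not None:
            return self.n_causal
        return _N_CAUSAL_BY_TRAIT[self.trait_type]


@dataclass
class StudyResult:
    runs: pd.DataFrame
    aggregate: dict
    panel: GenotypePanel = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Panel preparation
# ---------------------------------------------------------------------------


def _run_seed(master: int, i: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master, spawn_key=(1, i))


def prepare_panel(config: StudyConfig,
                  panel: GenotypePanel | None = None) -> GenotypePanel:
    """Simulate (or accept) a panel and apply the standard marker filters."""
    if panel is None:
        if config.population is not None:
            pop = config.population
        elif config.preset is not None:
            pop = PRESETS[config.preset]
        else:
            raise ValueError("study config needs a preset, a population "
                             "config, or an explicit panel")
        if pop.seed is None:
            pop = pop.replace(
                seed=np.random.SeedSequence(config.seed, spawn_key=(0,)))
        panel = simulate_panel(pop)
    panel = filter_biallelic(panel)
    panel = filter_missing(panel, config.max_missing_count)
    panel = filter_maf(panel, config.maf_min)
    if config.downsample_to is not None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(2,)))
        panel = downsample(panel, config.downsample_to, rng,
                           min_maf=config.maf_min)
    return panel


def downsample(panel: GenotypePanel, n: int,
               rng: np.random.Generator | int | None = None,
               min_maf: float | None = None) -> GenotypePanel:
    """Uniformly subsample ``n`` individuals and re-filter variants.

    Sites monomorphic in the subsample are removed; the MAF filter is
    re-applied when ``min_maf`` is given.
    """
    if n > panel.n_samples:
        raise ValueError(f"cannot downsample {panel.n_samples} samples "
                         f"to {n}")
    rng = np.random.default_rng(rng)
    idx = np.sort(rng.choice(panel.n_samples, size=n, replace=False))
    sub = panel.take_samples(idx)
    sub = filter_biallelic(sub)
    if min_maf is not None:
        sub = filter_maf(sub, min_maf)
    return sub


def simulate_maf_filtered_panel(n_samples: int, n_variants: int,
                                seed: int | np.random.SeedSequence,
                                maf_spectrum=(2.0, 2.0),
                                min_maf: float = 0.05,
                                ploidy_mode: str = "haploid"
                                ) -> GenotypePanel:
    """Unstructured panel with exactly ``n_variants`` markers at
    MAF ≥ ``min_maf`` (oversample, filter, then thin deterministically)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_panel, s_pick = ss.spawn(2)
    m_raw = int(n_variants * 1.25) + 64
    cfg = PopulationConfig(
        n_samples=n_samples, n_variants=m_raw,
        genome_length=100 * m_raw, singleton_rate=0.0,
        maf_spectrum=tuple(maf_spectrum), ploidy_mode=ploidy_mode,
        seed=s_panel)
    panel = filter_maf(simulate_panel(cfg), min_maf)
    if panel.n_variants < n_variants:
        raise RuntimeError("oversampling margin too small for the "
                           "requested MAF-filtered marker count")
    rng = np.random.default_rng(s_pick)
    keep = np.sort(rng.choice(panel.n_variants, size=n_variants,
                              replace=False))
    return panel.take_variants(keep)


# ---------------------------------------------------------------------------
# The study loop
# ---------------------------------------------------------------------------


def run_study(config: StudyConfig,
              panel: GenotypePanel | None = None) -> StudyResult:
    """Run the full simulate → fit → scan → threshold → evaluate loop.

    A failure in one replicate is logged and skipped; the study
    continues.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    panel = prepare_panel(config, panel)
    k = config.resolved_n_causal()
    h2 = 0.0 if config.trait_type == "null" else config.h2
    engine = AssociationEngine(panel)
    dataset = config.name or config.preset or "ad-hoc"
    rows = []
    for i in range(config.n_runs):
        t0 = time.perf_counter()
        rng = np.random.default_rng(_run_seed(config.seed, i))
        try:
            if k > 0:
                causal = sample_causal(panel, k, config.maf_min, rng)
                trait = simulate_trait(panel, causal, h2, rng)
                y = trait.phenotype
                h2_realized = trait.h2_realized
            else:
                causal = np.empty(0, dtype=int)
                y = rng.standard_normal(panel.n_samples)
                h2_realized = 0.0
            null_fit = engine.fit_null(y)
            result = engine.scan(y, null_fit=null_fit)
            lam = genomic_inflation(result.statistics)
            if config.n_perm > 0:
                thr = permutation_threshold(
                    None, y, n_perm=config.n_perm, fwer=config.fwer,
                    rng=rng, engine=engine, null_fit=null_fit)
                conf = confusion_rates(
                    result.p_values, thr, causal,
                    variants=panel.variants,
                    linkage_window=config.linkage_window,
                    lambda_gc=lam, run_id=f"run_{i:04d}")
                n_sig = int(np.sum(result.p_values <= thr))
            else:
                thr, conf, n_sig = math.nan, None, 0
            row = {
                "run_id": f"run_{i:04d}", "dataset": dataset,
                "trait_type": config.trait_type, "threshold": thr,
                "tp": conf.tp if conf else 0, "fp": conf.fp if conf else 0,
                "tn": conf.tn if conf else 0, "fn": conf.fn if conf else 0,
                "tpr": conf.tpr if conf else math.nan,
                "fpr": conf.fpr if conf else math.nan,
                "fnr": conf.fnr if conf else math.nan,
                "tnr": conf.tnr if conf else math.nan,
                "n_linked_excluded":
                    conf.n_linked_excluded if conf else 0,
                "lambda_gc": lam,
                "h2_est": null_fit.h2_est,
                "h2_realized": h2_realized,
                "n_significant": n_sig,
                "any_significant": n_sig > 0,
                "min_p": float(result.p_values.min()),
                "seconds": time.perf_counter() - t0,
            }
            rows.append(row)
            logger.info(
                "run=%s dataset=%s thr=%.3g tp=%s fp=%s lambda=%.3f "
                "h2=%.3f t=%.2fs", row["run_id"], dataset, thr, row["tp"],
                row["fp"], lam, null_fit.h2_est, row["seconds"])
        except Exception:
            logger.exception("run %d of study %s failed; continuing",
                             i, dataset)
    runs = pd.DataFrame(rows)
    aggregate = _aggregate(runs, config)
    return StudyResult(runs=runs, aggregate=aggregate, panel=panel)


def _aggregate(runs: pd.DataFrame, config: StudyConfig) -> dict:
    agg: dict = {
        "dataset": config.name or config.preset or "ad-hoc",
        "trait_type": config.trait_type,
        "n_runs_completed": len(runs),
    }
    if runs.empty:
        return agg
    for col in ("tpr", "fpr", "lambda_gc", "h2_est", "threshold"):
        vals = runs[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            agg[f"{col}_median"] = float(np.median(vals))
            q1, q3 = np.percentile(vals, [25, 75])
            agg[f"{col}_iqr"] = float(q3 - q1)
            agg[f"{col}_mean"] = float(np.mean(vals))
    agg["fwer_observed"] = float(runs["any_significant"].mean())
    return agg


# ---------------------------------------------------------------------------
# Real-data mode
# ---------------------------------------------------------------------------


@dataclass
class RealAssociation:
    result: AssociationResult
    threshold: float
    significant: pd.DataFrame
    h2_est: float


def load_panel(path: str) -> GenotypePanel:
    """Load a genotype panel from a VCF (``.vcf``/``.vcf.gz``) or a
    PLINK-style text prefix."""
    if path.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    return read_plink_text(path)


def associate_real(genotypes: str | GenotypePanel,
                   phenotype: str | pd.Series,
                   maf_min: float = 0.05,
                   max_missing_count: int = 0,
                   n_perm: int = 100,
                   fwer: float = 0.05,
                   seed: int = 0) -> RealAssociation:
    """End-to-end association on user data.

    The phenotype's sample ids must match the panel's exactly (the
    panel is reordered to the phenotype); mismatches raise with the
    offending ids listed.
    """
    panel = load_panel(genotypes) if isinstance(genotypes, str) \
        else genotypes
    pheno = read_phenotype(phenotype) if isinstance(phenotype, str) \
        else phenotype
    missing = [s for s in pheno.index if s not in set(panel.sample_ids)]
    extra = [s for s in panel.sample_ids if s not in set(pheno.index)]
    if missing or extra:
        raise ValueError(
            "sample id mismatch between phenotype and genotypes; "
            f"phenotype-only ids: {missing[:10]}; "
            f"genotype-only ids: {extra[:10]}")
    order = [panel.sample_ids.index(s) for s in pheno.index]
    panel = panel.take_samples(np.asarray(order))
    panel = filter_biallelic(panel)
    panel = filter_missing(panel, max_missing_count)
    panel = filter_maf(panel, maf_min)

    engine = AssociationEngine(panel)
    y = pheno.to_numpy(dtype=float)
    null_fit = engine.fit_null(y)
    result = engine.scan(y, null_fit=null_fit)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    thr = permutation_threshold(None, y, n_perm=n_perm, fwer=fwer,
                                rng=rng, engine=engine, null_fit=null_fit)
    table = result.to_frame()
    significant = table[table["p_value"] <= thr].reset_index(drop=True)
    return RealAssociation(result=result, threshold=thr,
                           significant=significant,
                           h2_est=null_fit.h2_est)
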