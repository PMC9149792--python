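"""Additive quantitative-trait simulation at a target heritability.

Implements the GCTA-style simulation model (``--simu-qt``): causal
variants are drawn uniformly from the common markers, per-variant allelic
effects b_j are i.i.d. standard normal on the *standardized* genotype
scale, and the environmental residual is scaled to the realized genetic
variance so that Var(g) / Var(g + e) equals the target heritability h²
in expectation.  Because effects act on standardized genotypes, |b_j|
is exchangeable across causal variants and independent of their minor
allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import MISSING, GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class TraitRealization:
    """One simulated phenotype with its generating ground truth."""

    phenotype: np.ndarray
    causal_ids: np.ndarray
    effects: np.ndarray
    h2_target: float
    h2_realized: float
    genetic_values: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if len(self.causal_ids) != len(self.effects):
            raise ValueError("causal_ids and effects length mismatch")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must be in [0, 1]")


def sample_causal(panel: GenotypePanel, k: int, min_maf: float = 0.05,
                  rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw ``k`` distinct causal variant indices uniformly among the
    variants with MAF ≥ ``min_maf``."""
    rng = np.random.default_rng(rng)
    maf = panel.variants["maf"].to_numpy()
    eligible = np.flatnonzero(maf >= min_maf)
    if eligible.size < k:
        raise ValueError(
            f"only {eligible.size} variants with MAF >= {min_maf}; "
            f"cannot sample {k} causal variants")
    return np.sort(rng.choice(eligible, size=k, replace=False))


def standardized_genotypes(panel: GenotypePanel,
                           index=None) -> np.ndarray:
    """Mean-imputed, centered genotypes scaled by the binomial allele-
    frequency standard deviation (GCTA convention: √(c·p(1−p)) with
    c = ploidy)."""
    calls = panel.calls if index is None else panel.calls[:, index]
    X = calls.astype(np.float64)
    missing = calls == MISSING
    with np.errstate(invalid="ignore"):
        mean = np.where(missing, np.nan, X).sum(axis=0)
    n_obs = (~missing).sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("variant with no observed calls")
    mean = np.where(missing, np.nan, X)
    mean = np.nansum(mean, axis=0) / n_obs
    p = mean / panel.ploidy
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("monomorphic variant encountered; filter the "
                         "panel before standardizing")
    sd = np.sqrt(panel.ploidy * p * (1.0 - p))
    X = np.where(missing, mean[None, :], X)
    return (X - mean[None, :]) / sd[None, :]


def simulate_trait(panel: GenotypePanel, causal_ids,
                   h2: float,
                   rng: np.random.Generator | int | None = None
                   ) -> TraitRealization:
    """Simulate one additive trait from the given causal variants.

    g_i = Σ_j w_ij b_j with w the standardized genotypes and b_j i.i.d.
    standard normal; e_i ~ N(0, Var(g)·(1−h2)/h2); phenotype = g + e.
    h2 = 0 yields a pure-noise N(0, 1) trait (null calibration); h2 = 1
    yields the genetic values exactly.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    rng = np.random.default_rng(rng)
    causal_ids = np.asarray(causal_ids, dtype=int)
    n = panel.n_samples
    k = causal_ids.size

    if k:
        W = standardized_genotypes(panel, causal_ids)
        effects = rng.standard_normal(k)
        g = W @ effects
    else:
        effects = np.empty(0)
        g = np.zeros(n)

    if h2 == 0.0 or k == 0:
        y = rng.standard_normal(n)
        h2_realized = 0.0
    elif h2 == 1.0:
        y = g.copy()
        h2_realized = 1.0
    else:
        var_g = float(np.var(g, ddof=1))
        e = rng.normal(0.0, np.sqrt(var_g * (1.0 - h2) / h2), size=n)
        y = g + e
        h2_realized = var_g / float(np.var(y, ddof=1))
    return TraitRealization(phenotype=y, causal_ids=causal_ids,
                            effects=effects, h2_target=h2,
                            h2_realized=h2_realized, genetic_values=g)


# ---------------------------------------------------------------------------
# Phenotype and ground-truth tables
# ---------------------------------------------------------------------------


def write_phenotypes(traits: dict[str, TraitRealization],
                     sample_ids: list[str], path: str) -> None:
    """Tab-separated (sample_id, trait_id, value) long table."""
    rows = []
    for trait_id, tr in traits.items():
        for sid, v in zip(sample_ids, tr.phenotype):
            rows.append((sid, trait_id, v))
    pd.DataFrame(rows, columns=["sample_id", "trait_id", "value"]) \
        .to_csv(path, sep="\t", index=False)


def write_causal_table(traits: dict[str, TraitRealization],
                       panel: GenotypePanel, path: str) -> None:
    """Sidecar ground-truth table (trait_id, variant index, chrom, pos,
    effect)."""
    rows = []
    for trait_id, tr in traits.items():
        for idx, b in zip(tr.causal_ids, tr.effects):
            row = panel.variants.iloc[int(idx)]
            rows.append((trait_id, int(idx), row["chrom"],
                         int(row["pos"]), b))
    pd.DataFrame(rows, columns=["trait_id", "variant_index", "chrom",
                                "pos", "effect"]) \
        .to_csv(path, sep="\t", index=False)


def read_phenotype(path: str) -> pd.Series:
    """Read a two-column (sample id, value) tab-separated phenotype file,
    with or without a header line."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].astype(float).to_numpy(),
                     index=df.iloc[:, 0].to_numpy(), name="phenotype")
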