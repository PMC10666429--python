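"""Per-sample SNP counts and heterozygosity, call-rate-stratified
heterozygosity of merged cohorts, the minor-allele-frequency spectrum, and
the median/iqr/mean/sd summary convention.

Heterozygosity here is *SNP heterozygosity*: the fraction of an individual's
non-missing genotypes at variant sites that are heterozygous.  It is defined
over the sites present in the (filtered) matrix, with no monomorphic-genome
denominator — deep-sequenced single genomes typically show H around 0.6 on
this definition, and merged complete-case cohorts substantially less,
because private variants are enriched for heterozygotes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryStats:
    """median / iqr / mean / sd of a set of values (Table-style convention).

    iqr is Q3 - Q1 with linear interpolation; sd uses the n-1 denominator
    (a single value reports sd = 0 with ``degenerate`` set).
    """

    median: float
    iqr: float
    mean: float
    sd: float
    n: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "median": self.median, "iqr": self.iqr,
            "mean": self.mean, "sd": self.sd, "n": self.n,
        }


def summarize(values) -> SummaryStats:
    """Summary of a value vector: median, iqr, mean, sd (ddof=1)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("summarize needs at least one value")
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation
    degenerate = v.size == 1
    sd = 0.0 if degenerate else float(np.std(v, ddof=1))
    return SummaryStats(
        median=float(np.median(v)), iqr=float(q3 - q1),
        mean=float(np.mean(v)), sd=sd, n=int(v.size), degenerate=degenerate,
    )


def sample_stats(m: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample N_SNP, missing rate and heterozygosity H.

    H = heterozygous / non-missing genotypes; a sample with no non-missing
    genotype gets H = NaN with a warning.
    """
    if m.n_sites == 0:
        raise ValueError("empty matrix")
    g = m.genotypes
    n_called = (g != MISSING).sum(axis=1)
    n_het = (g == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    if (n_called == 0).any():
        bad = [s for s, c in zip(m.samples, n_called) if c == 0]
        warnings.warn(f"samples with no called genotypes: {bad}", stacklevel=2)
    return pd.DataFrame(
        {
            "sample_id": m.samples,
            "n_snp": n_called.astype(int),
            "missing_rate": 1.0 - n_called / m.n_sites,
            "het": het,
        }
    )


def het_by_call_rate(m: GenotypeMatrix) -> pd.DataFrame:
    """Heterozygote fraction stratified by the number of samples called.

    One row per call count 1..n_samples: number of sites, het and hom
    genotype counts among called genotypes at those sites, and the het
    fraction.  The bins partition all called genotypes, so merged-cohort
    heterozygosity decomposes exactly over call-rate strata.
    """
    if m.n_samples < 2:
        raise ValueError("call-rate stratification needs a merged matrix (n >= 2)")
    g = m.genotypes
    called = g != MISSING
    n_called_site = called.sum(axis=0)
    rows = []
    for k in range(1, m.n_samples + 1):
        in_bin = n_called_site == k
        het = int(((g == 1) & called)[:, in_bin].sum())
        called_gt = int(called[:, in_bin].sum())
        hom = called_gt - het
        rows.append(
            {
                "n_called": k,
                "n_sites": int(in_bin.sum()),
                "n_het": het,
                "n_hom": hom,
                "het_fraction": het / called_gt if called_gt else np.nan,
            }
        )
    return pd.DataFrame(rows)


def maf_spectrum(m: GenotypeMatrix) -> pd.DataFrame:
    """Minor-allele-frequency histogram over the achievable per-site values.

    Site maf = minor-allele count / (2 x called samples at the site), so the
    denominator shrinks with missingness (the PLINK ``--freq`` convention).
    Sites with zero calls are excluded and counted in the log.  Columns:
    maf, n_sites, fraction (fractions sum to 1).
    """
    g = m.genotypes
    called = (g != MISSING).sum(axis=0)
    alt = np.where(g == MISSING, 0, g).sum(axis=0)
    ok = called > 0
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("maf_spectrum: %d sites with zero calls excluded", n_skipped)
    freq = alt[ok] / (2.0 * called[ok])
    maf = np.minimum(freq, 1.0 - freq)
    vals, counts = np.unique(np.round(maf, 10), return_counts=True)
    return pd.DataFrame(
        {"maf": vals, "n_sites": counts, "fraction": counts / counts.sum()}
    )


def overall_het(m: GenotypeMatrix) -> float:
    """Heterozygote fraction over all called genotypes of the matrix."""
    g = m.genotypes
    called = (g != MISSING).sum()
    if called == 0:
        raise ValueError("no called genotypes")
    return float((g == 1).sum() / called)
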