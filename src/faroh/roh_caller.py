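"""Sliding-window detection of runs of homozygosity (ROH) per sample.

The algorithm follows the PLINK ``--homozyg`` dialect:

1. slide a window of ``window_snps`` consecutive SNPs along each chromosome;
   a window is *homozygous* if it contains at most ``window_het_max``
   heterozygous and at most ``window_missing_max`` missing calls;
2. a SNP is *supported* if the fraction of windows overlapping it that are
   homozygous is at least ``hit_fraction_min``;
3. candidate runs are maximal stretches of consecutive supported SNPs,
   broken where the bp gap between adjacent SNPs exceeds ``max_gap_kb``;
4. a run is emitted if it has at least ``min_snps`` SNPs, spans at least
   ``min_kb`` (inclusive bp span / 1000) and its kb-per-SNP density does not
   exceed ``density_kb_per_snp_max``.  Run boundaries are the outermost
   supported *homozygous* SNPs of the stretch.

Only windows fully inside a chromosome are counted, so calls within a
window of a chromosome end may differ marginally from PLINK's.

Two parameter presets are provided: ``plink-default`` (gap 1000 kb, minimum
100 SNPs) and ``ref20`` (gap 100 kb, minimum 25 SNPs), the latter matching
the settings common in population-isolate ROH comparisons.

``sweep_roh`` produces per-sample NROH / SROH / AVROH across a grid of
minimum lengths by calling once at the smallest grid value and
post-filtering by length — window support does not depend on ``min_kb``, so
this is exactly equivalent to independent re-calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    hit_fraction_min: float = 0.05
    min_snps: int = 100
    min_kb: float = 100.0
    max_gap_kb: float = 1000.0
    density_kb_per_snp_max: float = 50.0

    def __post_init__(self) -> None:
        for name in (
            "window_snps", "hit_fraction_min", "min_snps",
            "min_kb", "max_gap_kb", "density_kb_per_snp_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: PLINK default --homozyg settings (gap 1000 kb, >=100 SNPs per run).
PLINK_DEFAULT = ROHParams()
#: Alternative profile: gap 100 kb, >=25 SNPs per run.
REF20 = ROHParams(min_snps=25, max_gap_kb=100.0)

PROFILES = {"plink-default": PLINK_DEFAULT, "ref20": REF20}


@dataclass(frozen=True)
class ROHSegment:
    """One called run: 1-based inclusive bp span on one chromosome."""

    sample_id: str
    chrom: int
    start_pos: int
    end_pos: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_pos - self.start_pos + 1) / 1000.0


def call_roh(m: GenotypeMatrix, sample: str, p: ROHParams = PLINK_DEFAULT) -> list[ROHSegment]:
    """Call ROH segments for one sample of a matrix."""
    g_all = m.genotypes[m.sample_index(sample)]
    segments: list[ROHSegment] = []
    for chrom in sorted(m.sites["chrom"].unique()):
        on = (m.sites["chrom"] == chrom).to_numpy()
        pos = m.sites.loc[on, "pos"].to_numpy()
        g = g_all[on]
        segments.extend(_call_chromosome(g, pos, int(chrom), sample, p))
    return segments


def _call_chromosome(
    g: np.ndarray, pos: np.ndarray, chrom: int, sample: str, p: ROHParams
) -> list[ROHSegment]:
    n = len(g)
    w = p.window_snps
    if n < w:
        logger.info(
            "chrom %d: %d SNPs < window of %d, no calls for %s",
            chrom, n, w, sample,
        )
        return []
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    chet = np.concatenate(([0], np.cumsum(het)))
    cmis = np.concatenate(([0], np.cumsum(mis)))
    n_win = n - w + 1
    het_w = chet[w:] - chet[:-w]
    mis_w = cmis[w:] - cmis[:-w]
    hom_win = (het_w <= p.window_het_max) & (mis_w <= p.window_missing_max)

    # support fraction per SNP: windows [s-w+1, s] clipped to [0, n_win-1]
    idx = np.arange(n)
    lo = np.maximum(idx - w + 1, 0)
    hi = np.minimum(idx, n_win - 1)
    chw = np.concatenate(([0], np.cumsum(hom_win)))
    n_hom_cover = chw[hi + 1] - chw[lo]
    n_cover = hi - lo + 1
    supported = n_hom_cover / n_cover >= p.hit_fraction_min

    # maximal stretches of consecutive supported SNPs, broken at large gaps
    gap_break = np.zeros(n, dtype=bool)
    gap_break[1:] = (pos[1:] - pos[:-1]) > p.max_gap_kb * 1000.0
    edges = np.diff(np.concatenate(([0], supported.astype(np.int8), [0])))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    runs: list[tuple[int, int]] = []
    for a, b in zip(starts, ends):
        cuts = a + np.nonzero(gap_break[a + 1 : b + 1])[0] + 1
        lo_edge = a
        for c in cuts:
            runs.append((lo_edge, c - 1))
            lo_edge = c
        runs.append((lo_edge, b))

    hom = (g == 0) | (g == 2)
    out = []
    for a, b in runs:
        hom_idx = np.nonzero(hom[a : b + 1])[0]
        if hom_idx.size == 0:
            continue
        a2, b2 = a + hom_idx[0], a + hom_idx[-1]
        n_snps = b2 - a2 + 1
        length_kb = (pos[b2] - pos[a2] + 1) / 1000.0
        if n_snps < p.min_snps or length_kb < p.min_kb:
            continue
        if length_kb / n_snps > p.density_kb_per_snp_max:
            continue
        out.append(
            ROHSegment(
                sample_id=sample, chrom=chrom,
                start_pos=int(pos[a2]), end_pos=int(pos[b2]), n_snps=n_snps,
            )
        )
    return out


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Segment list as a table (sample, chrom, start, end, n_snps, kb)."""
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id, "chrom": s.chrom,
                "start_pos": s.start_pos, "end_pos": s.end_pos,
                "n_snps": s.n_snps, "length_kb": s.length_kb,
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start_pos", "end_pos", "n_snps", "length_kb"],
    )


DEFAULT_GRID_KB = tuple(float(x) for x in range(100, 5001, 100))


def sweep_roh(
    m: GenotypeMatrix,
    p: ROHParams = PLINK_DEFAULT,
    grid_kb=DEFAULT_GRID_KB,
) -> pd.DataFrame:
    """NROH / SROH / AVROH per sample across a grid of minimum lengths (kb).

    The caller runs once per sample at the smallest grid value; larger
    minima are applied by filtering emitted segments on length, which is
    equivalent because window support is independent of ``min_kb``.
    Columns: sample_id, min_kb, nroh, sroh_kb, avroh_kb.
    """
    grid = sorted(float(x) for x in grid_kb)
    if not grid:
        raise ValueError("empty grid")
    base = replace(p, min_kb=grid[0])
    rows = []
    for sample in m.samples:
        lengths = np.array(
            [s.length_kb for s in call_roh(m, sample, base)], dtype=float
        )
        for x in grid:
            sel = lengths >= x
            nroh = int(sel.sum())
            sroh = float(lengths[sel].sum())
            rows.append(
                {
                    "sample_id": sample, "min_kb": x, "nroh": nroh,
                    "sroh_kb": sroh,
                    "avroh_kb": sroh / nroh if nroh else 0.0,
                }
            )
    return pd.DataFrame(rows)
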