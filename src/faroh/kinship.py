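"""KING-style pairwise kinship from genotype-concordance counts.

For a pair of individuals the estimators use only four counts over the
markers genotyped in both: each individual's heterozygote count, the count
of sites where both are heterozygous, and the count of opposite homozygotes.
Two estimators are provided:

* ``within``  — the within-family estimator
  phi = (N_AaAa - 2 N_AAaa) / (N_Aa^i + N_Aa^j);
* ``robust``  — the between-family (KING-robust) estimator, which normalises
  by the *lower* of the two heterozygote counts to guard against inflation
  when individual-level heterozygosity differs:
  phi = (N_AaAa - 2 N_AAaa) / (2 N_Aa^i) + 1/2 - (N_Aa^i + N_Aa^j) / (4 N_Aa^i),
  with i relabelled to the individual with the lower heterozygosity rate.

Relatedness is R = 2 phi.  Estimates may be negative; they are reported
untruncated and flagged.

Two marker-set modes are exposed: ``pairwise-shared`` counts over the
markers non-missing in the two samples of each pair, while ``complete-case``
first restricts to markers called in every sample of the matrix.  On merged
cohorts with private variants the two modes differ systematically.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

MARKER_SET_MODES = ("complete-case", "pairwise-shared")


@dataclass(frozen=True)
class PairCounts:
    """Genotype-concordance counts for one pair over shared markers."""

    n_het_i: int
    n_het_j: int
    n_both_het: int
    n_opp_hom: int
    m_shared: int

    def __post_init__(self) -> None:
        if min(self.n_het_i, self.n_het_j, self.n_both_het,
               self.n_opp_hom, self.m_shared) < 0:
            raise ValueError("negative count")
        if self.n_both_het > min(self.n_het_i, self.n_het_j):
            raise ValueError("n_both_het exceeds an individual het count")
        if max(self.n_het_i, self.n_het_j, self.n_opp_hom) > self.m_shared:
            raise ValueError("count exceeds m_shared")


@dataclass(frozen=True)
class KinshipResult:
    """Kinship estimate for one pair; relatedness is exactly 2 phi."""

    phi: float
    estimator: str

    @property
    def relatedness(self) -> float:
        return 2.0 * self.phi


def pair_counts(m: GenotypeMatrix, i: str, j: str) -> PairCounts:
    """Concordance counts for samples ``i``, ``j`` over markers called in both."""
    if i == j:
        raise ValueError("pair must be two distinct samples")
    gi = m.genotypes[m.sample_index(i)]
    gj = m.genotypes[m.sample_index(j)]
    return counts_from_vectors(gi, gj)


def counts_from_vectors(gi: np.ndarray, gj: np.ndarray) -> PairCounts:
    shared = (gi != MISSING) & (gj != MISSING)
    m_shared = int(shared.sum())
    if m_shared == 0:
        raise ValueError("no shared non-missing markers for this pair")
    a, b = gi[shared], gj[shared]
    return PairCounts(
        n_het_i=int((a == 1).sum()),
        n_het_j=int((b == 1).sum()),
        n_both_het=int(((a == 1) & (b == 1)).sum()),
        n_opp_hom=int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum()),
        m_shared=m_shared,
    )


def kinship_within(c: PairCounts) -> KinshipResult:
    """Within-family estimator: (N_AaAa - 2 N_AAaa) / (N_Aa^i + N_Aa^j)."""
    denom = c.n_het_i + c.n_het_j
    if denom == 0:
        raise ValueError("no heterozygotes in either individual")
    phi = (c.n_both_het - 2.0 * c.n_opp_hom) / denom
    return KinshipResult(phi=phi, estimator="within")


def kinship_robust(c: PairCounts) -> KinshipResult:
    """Between-family (robust) estimator, normalised by the lower het count.

    The individual with the lower heterozygosity rate takes the role of i.
    With equal het counts the expression reduces algebraically to the
    within-family form, which is used as the deterministic tie-break.
    """
    lo, hi = sorted((c.n_het_i, c.n_het_j))
    if lo == 0:
        raise ValueError("lower heterozygote count is zero")
    if lo == hi:
        return KinshipResult(phi=kinship_within(c).phi, estimator="robust")
    phi = (
        (c.n_both_het - 2.0 * c.n_opp_hom) / (2.0 * lo)
        + 0.5
        - 0.25 * (lo + hi) / lo
    )
    return KinshipResult(phi=phi, estimator="robust")


def kinship_matrix(
    m: GenotypeMatrix,
    estimator: str = "robust",
    marker_set: str = "complete-case",
) -> pd.DataFrame:
    """Kinship for all n(n-1)/2 unordered pairs of a matrix.

    Columns: id1, id2, m_shared, n_het_1, n_het_2, n_both_het, n_opp_hom,
    phi, relatedness, estimator, error.  Per-pair failures (no shared
    markers, no heterozygotes) flag the row rather than dropping it.
    """
    if m.n_samples < 2:
        raise ValueError("kinship needs at least two samples")
    if estimator not in ("within", "robust"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if marker_set not in MARKER_SET_MODES:
        raise ValueError(f"unknown marker-set mode {marker_set!r}")

    work = m
    if marker_set == "complete-case":
        complete = (m.genotypes != MISSING).all(axis=0)
        work = m.subset_sites(complete)

    fn = kinship_within if estimator == "within" else kinship_robust
    rows = []
    for i, j in combinations(work.samples, 2):
        row: dict = {"id1": i, "id2": j, "estimator": estimator, "error": ""}
        try:
            c = pair_counts(work, i, j)
            row.update(
                m_shared=c.m_shared, n_het_1=c.n_het_i, n_het_2=c.n_het_j,
                n_both_het=c.n_both_het, n_opp_hom=c.n_opp_hom,
            )
            r = fn(c)
            row["phi"] = r.phi
            row["relatedness"] = r.relatedness
        except ValueError as exc:
            row.setdefault("m_shared", 0)
            row["phi"] = np.nan
            row["relatedness"] = np.nan
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
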