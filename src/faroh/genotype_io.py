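"""VCF input/output, site filtering, cohort merging and genotype-level QC.

The central container is :class:`GenotypeMatrix`: a samples x sites matrix of
diploid genotype codes (0 hom-ref, 1 het, 2 hom-alt, -1 missing) over
autosomal biallelic SNPs, with per-site metadata (chrom, pos, ref, alt, qual).

Two site-filtering profiles are supported, mirroring the two criteria used
to pre-process the cohort VCFs:

* ``basic``    — biallelic SNPs with ``QUAL > 30``;
* ``advanced`` — additionally ``FILTER == PASS`` and a per-genotype used-read-
  depth ``FMT/DPU > 10`` (genotypes failing the depth bound are set missing,
  sites with no surviving genotype are dropped).

Merging follows union-of-sites semantics: a sample's genotype is missing at
every site its own VCF does not carry, which is what drives the call-rate
structure of merged small cohorts.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MISSING = -1
AUTOSOMES = frozenset(str(c) for c in range(1, 23))
NUCLEOTIDES = frozenset("ACGT")

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]


class VCFFormatError(ValueError):
    """Raised when an input VCF is unusable (missing GT, bad records)."""


class ReferenceMismatchError(ValueError):
    """Raised when two inputs disagree on the reference allele at a position."""


@dataclass(frozen=True)
class SiteFilterSpec:
    """Site/genotype filtering profile applied while reading a VCF.

    mode ``basic`` keeps biallelic SNPs with ``qual > qual_min``; mode
    ``advanced`` additionally requires FILTER == PASS at the site and a
    per-genotype depth (``FMT/DPU``) strictly above ``depth_min``.
    """

    mode: str = "basic"
    qual_min: float = 30.0
    depth_min: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("basic", "advanced"):
            raise ValueError(f"unknown filter mode {self.mode!r}")

    @property
    def require_pass(self) -> bool:
        return self.mode == "advanced"


@dataclass(frozen=True)
class QCSpec:
    """Post-merge QC thresholds: sample missingness, site missingness, HWE."""

    mind_max: float = 0.1
    geno_max: float = 0.1
    hwe_p_min: float = 1e-7

    def __post_init__(self) -> None:
        for name in ("mind_max", "geno_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min must be in [0, 1]")


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid genotype codes with per-site metadata.

    ``sites`` is a DataFrame with columns chrom (int), pos (int, 1-based),
    ref, alt (single nucleotides) and qual (float), sorted by (chrom, pos)
    with unique (chrom, pos, ref, alt) keys.  ``genotypes`` is an int8 array
    of shape (n_samples, n_sites); -1 marks a missing call.
    """

    samples: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(self.sites):
            key = self.sites[["chrom", "pos"]].to_numpy()
            if np.lexsort((key[:, 1], key[:, 0])).tolist() != list(range(len(key))):
                order = np.lexsort((key[:, 1], key[:, 0]))
                self.sites = self.sites.iloc[order].reset_index(drop=True)
                self.genotypes = self.genotypes[:, order]
            if self.sites.duplicated(["chrom", "pos", "ref", "alt"]).any():
                raise ValueError("duplicate (chrom, pos, ref, alt) site keys")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> pd.DataFrame:
        return self.sites[["chrom", "pos", "ref", "alt"]]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in keep]
        return GenotypeMatrix(list(keep), self.sites.copy(), self.genotypes[idx])

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            list(self.samples), self.sites.loc[mask].copy(), self.genotypes[:, mask]
        )

    def missing_rates(self) -> np.ndarray:
        """Per-sample fraction of missing genotype calls."""
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return (self.genotypes == MISSING).mean(axis=1)

    def site_missing_rates(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.genotypes == MISSING).mean(axis=0)


def _normalise_chrom(chrom: str) -> str | None:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return c if c in AUTOSOMES else None


def load_vcf(path: str, spec: SiteFilterSpec = SiteFilterSpec()) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`, applying a filter profile.

    Only autosomal biallelic single-nucleotide records with
    ``QUAL > spec.qual_min`` are retained.  In ``advanced`` mode the record
    must additionally be FILTER == PASS, and each genotype must have
    ``FMT/DPU > spec.depth_min`` — failing genotypes become missing and sites
    with no surviving genotype are dropped.  A missing DPU field in advanced
    mode counts as a failing genotype (logged once per file).
    """
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception variants
        raise VCFFormatError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise VCFFormatError(f"{path}: VCF has no samples / no GT field")

    chroms: list[int] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    gts: list[np.ndarray] = []
    n_dropped = 0
    warned_no_depth = False

    for v in vcf:
        chrom = _normalise_chrom(v.CHROM)
        if chrom is None:
            n_dropped += 1
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        if v.REF not in NUCLEOTIDES or v.ALT[0] not in NUCLEOTIDES:
            n_dropped += 1
            continue
        if v.QUAL is None or not v.QUAL > spec.qual_min:
            n_dropped += 1
            continue
        if spec.require_pass and v.FILTER is not None:  # None == PASS in cyvcf2
            n_dropped += 1
            continue
        # gts012=True: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        if spec.mode == "advanced":
            depth = v.format("DPU")
            if depth is None:
                depth = v.format("DP")
            if depth is None:
                if not warned_no_depth:
                    logger.warning(
                        "%s: no FMT/DPU (or DP) field; genotypes fail the "
                        "advanced depth filter", path,
                    )
                    warned_no_depth = True
                g[:] = MISSING
            else:
                d = depth.astype(float).reshape(len(samples), -1)[:, 0]
                g[~(d > spec.depth_min)] = MISSING
            if np.all(g == MISSING):
                n_dropped += 1
                continue
        chroms.append(int(chrom))
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        # htslib stores QUAL as float32; round to 4 dp so text-written quals
        # (<= 1 dp) round-trip exactly
        quals.append(round(float(v.QUAL), 4))
        gts.append(g)

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "qual": quals}
    )
    geno = (
        np.stack(gts, axis=1)
        if gts
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    logger.info(
        "%s: kept %d sites, dropped %d records (%s filter)",
        path, len(sites), n_dropped, spec.mode,
    )
    return GenotypeMatrix(samples, sites, geno)


def write_vcf(
    m: GenotypeMatrix,
    path: str,
    *,
    filters: np.ndarray | None = None,
    depths: np.ndarray | None = None,
    contig_lengths: dict[int, int] | None = None,
) -> str:
    """Write a matrix as a VCFv4.1 text file (gzip if path ends in .gz).

    ``filters`` is an optional per-site array of FILTER strings (default
    PASS); ``depths`` an optional samples x sites integer array emitted as
    the per-genotype ``DPU`` field.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write("##source=faroh\n")
        chrom_set = sorted(set(m.sites["chrom"])) if m.n_sites else []
        for c in chrom_set:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FILTER=<ID=MaxSB,Description="Strand bias above threshold">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depths is not None:
            fh.write(
                '##FORMAT=<ID=DPU,Number=1,Type=Integer,'
                'Description="Read depth used">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples)
            + "\n"
        )
        fmt = "GT:DPU" if depths is not None else "GT"
        quals = m.sites["qual"].to_numpy()
        for k in range(m.n_sites):
            row = m.sites.iloc[k]
            filt = "PASS" if filters is None else str(filters[k])
            cells = []
            for s in range(m.n_samples):
                cell = gt_str[int(m.genotypes[s, k])]
                if depths is not None:
                    cell += f":{int(depths[s, k])}"
                cells.append(cell)
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                f"{quals[k]:g}\t{filt}\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )
    return str(path)


def merge_cohort(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge matrices over the union of sites, missing-filling absent sites.

    The merged site set is the union keyed by (chrom, pos, ref, alt); a
    sample's genotype is missing wherever its input lacks the site.  Sample
    order is concatenation order.  Conflicting reference alleles at the same
    (chrom, pos) are fatal.
    """
    if len(matrices) < 2:
        raise ValueError("merge_cohort needs at least two matrices")
    all_samples = [s for m in matrices for s in m.samples]
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("duplicate sample ids across merge inputs")

    union = pd.concat([m.sites for m in matrices], ignore_index=True)
    # qual differs between inputs for shared sites; keep the maximum.
    union = (
        union.groupby(["chrom", "pos", "ref", "alt"], as_index=False)["qual"]
        .max()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    by_pos = union.groupby(["chrom", "pos"])["ref"].nunique()
    if (by_pos > 1).any():
        bad = by_pos[by_pos > 1].index[0]
        raise ReferenceMismatchError(
            f"conflicting reference alleles at chrom {bad[0]} pos {bad[1]}"
        )

    key = pd.MultiIndex.from_frame(union[["chrom", "pos", "ref", "alt"]])
    lookup = pd.Series(np.arange(len(union)), index=key)
    geno = np.full((len(all_samples), len(union)), MISSING, dtype=np.int8)
    row = 0
    for m in matrices:
        if m.n_sites:
            cols = lookup.loc[
                pd.MultiIndex.from_frame(m.site_keys())
            ].to_numpy()
            geno[row : row + m.n_samples, cols] = m.genotypes
        row += m.n_samples
    return GenotypeMatrix(all_samples, union[SITE_COLUMNS], geno)


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote configurations no more probable than the observed one
    (the SNP-HWE convention used by PLINK).  Monomorphic input returns 1.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotypes observed")
    rare = 2 * min(n_hom1, n_hom2) + n_het
    common = 2 * max(n_hom1, n_hom2) + n_het
    if rare == 0:
        return 1.0

    # log P(het = h | allele counts) up to a shared constant:
    #   P(h) ∝ n! / (hom_r! hom_c! h!) * 2^h
    hs = np.arange(rare % 2, min(rare, common) + 1, 2)
    hom_r = (rare - hs) // 2
    hom_c = n - hs - hom_r
    logp = (
        hs * math.log(2.0)
        - _lgamma_arr(hom_r + 1)
        - _lgamma_arr(hom_c + 1)
        - _lgamma_arr(hs + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.searchsorted(hs, n_het)]
    return float(min(1.0, p[p <= obs * (1.0 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    return gammaln(np.asarray(x, dtype=float))


@dataclass
class QCLog:
    """Counts removed at each QC stage, in application order."""

    samples_removed: list[str] = field(default_factory=list)
    n_sites_geno_removed: int = 0
    n_sites_hwe_removed: int = 0
    hwe_skipped: bool = False


def apply_qc(m: GenotypeMatrix, qc: QCSpec = QCSpec()) -> tuple[GenotypeMatrix, QCLog]:
    """Apply sample-missingness, site-missingness and HWE filters, in order.

    Samples with missing rate > ``mind_max`` are removed first, then sites
    with missing rate > ``geno_max`` (recomputed on the surviving samples),
    then sites whose exact HWE p-value falls below ``hwe_p_min``.  The HWE
    stage is skipped (and logged) for single-sample matrices, where the test
    is degenerate.
    """
    if m.n_sites == 0 or m.n_samples == 0:
        raise ValueError("cannot QC an empty matrix")
    log = QCLog()

    keep_samples = [
        s for s, r in zip(m.samples, m.missing_rates()) if r <= qc.mind_max
    ]
    log.samples_removed = [s for s in m.samples if s not in keep_samples]
    if not keep_samples:
        raise ValueError(
            f"all {m.n_samples} samples exceed mind_max={qc.mind_max}"
        )
    out = m.subset_samples(keep_samples) if log.samples_removed else m

    site_ok = out.site_missing_rates() <= qc.geno_max
    log.n_sites_geno_removed = int((~site_ok).sum())
    out = out.subset_sites(site_ok)

    if out.n_samples < 2:
        log.hwe_skipped = True
        logger.info("HWE filter skipped: single-sample matrix is degenerate")
        return out, log

    g = out.genotypes
    n_hom1 = (g == 0).sum(axis=0)
    n_het = (g == 1).sum(axis=0)
    n_hom2 = (g == 2).sum(axis=0)
    pvals = np.ones(out.n_sites)
    called = n_hom1 + n_het + n_hom2
    for k in range(out.n_sites):
        if called[k]:
            pvals[k] = hwe_exact_p(int(n_hom1[k]), int(n_het[k]), int(n_hom2[k]))
    hwe_ok = pvals >= qc.hwe_p_min
    log.n_sites_hwe_removed = int((~hwe_ok).sum())
    out = out.subset_sites(hwe_ok)
    logger.info(
        "QC: removed %d samples, %d sites (geno), %d sites (HWE)",
        len(log.samples_removed), log.n_sites_geno_removed, log.n_sites_hwe_removed,
    )
    return out, log
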