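"""Synthetic diploid cohorts with known truth.

Generates small multi-chromosome SNP cohorts that emulate the statistical
structure the analysis modules assume:

* site allele frequencies from a configurable model — by default the alt
  allele frequency is Beta(3, 3), which makes the heterozygote fraction at
  an individual's *variant* sites exactly 0.6 (matching deep-sequenced
  single genomes), optionally mixed with a rare-variant stratum;
* optional pedigree structure realised by gene-drop with recombination
  under a 1 cM/Mb map and Haldane (no-interference) crossovers, recording
  both pedigree-expected and realised IBD kinship per pair;
* autozygosity from a founder event ``founder_g`` generations back, planted
  as non-overlapping homozygous tracts whose lengths are exponential with
  mean 100/(2 g) cM and whose per-sample count is Poisson;
* per-genotype miscalls, missingness, and QUAL / FILTER / per-genotype
  depth fields for the site-filtering code paths.

Sites are generated in linkage equilibrium apart from planted tracts and
pedigree descent, which keeps every oracle analytic.  All randomness flows
from a single master seed through named substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, write_vcf

import pandas as pd


# ---------------------------------------------------------------------------
# pedigrees

class Pedigree:
    """A pedigree as a parent map, with expected-kinship recursion.

    Founders have no parents and are mutually unrelated and non-inbred.
    ``samples`` lists the members whose genotypes a simulation emits
    (default: every member).
    """

    def __init__(self) -> None:
        self.parents: dict[str, tuple[str, str] | None] = {}
        self.order: list[str] = []
        self.samples: list[str] = []
        self._depth: dict[str, int] = {}
        self._memo: dict[tuple[str, str], float] = {}

    def add_founder(self, name: str) -> "Pedigree":
        self._add(name, None)
        return self

    def add_child(self, name: str, p1: str, p2: str) -> "Pedigree":
        for p in (p1, p2):
            if p not in self.parents:
                raise ValueError(f"unknown parent {p!r}")
        self._add(name, (p1, p2))
        return self

    def _add(self, name: str, parents) -> None:
        if name in self.parents:
            raise ValueError(f"duplicate member {name!r}")
        self.parents[name] = parents
        self.order.append(name)
        self._depth[name] = (
            0 if parents is None
            else 1 + max(self._depth[p] for p in parents)
        )
        self.samples = list(self.order)

    @property
    def founders(self) -> list[str]:
        return [m for m in self.order if self.parents[m] is None]

    def inbreeding(self, a: str) -> float:
        par = self.parents[a]
        return 0.0 if par is None else self.expected_kinship(*par)

    def expected_kinship(self, a: str, b: str) -> float:
        """Pedigree kinship coefficient phi(a, b) by tabular recursion."""
        key = (a, b) if a <= b else (b, a)
        if key in self._memo:
            return self._memo[key]
        if a == b:
            phi = 0.5 * (1.0 + self.inbreeding(a))
        else:
            # recurse on the deeper member; it cannot be the other's ancestor
            if self._depth[a] > self._depth[b]:
                a, b = b, a
            par = self.parents[b]
            phi = 0.0 if par is None else 0.5 * (
                self.expected_kinship(a, par[0]) + self.expected_kinship(a, par[1])
            )
        self._memo[key] = phi
        return phi


def parent_offspring_pedigree() -> Pedigree:
    """Founder pair and child; phi(parent, child) = 1/4."""
    p = Pedigree().add_founder("fa").add_founder("mo").add_child("ch", "fa", "mo")
    p.samples = ["fa", "ch"]
    return p


def full_sib_pedigree() -> Pedigree:
    """Two full sibs; phi = 1/4 in expectation."""
    p = (
        Pedigree().add_founder("fa").add_founder("mo")
        .add_child("s1", "fa", "mo").add_child("s2", "fa", "mo")
    )
    p.samples = ["s1", "s2"]
    return p


def half_sib_pedigree() -> Pedigree:
    """Two half sibs sharing one parent; phi = 1/8."""
    p = (
        Pedigree().add_founder("fa").add_founder("mo1").add_founder("mo2")
        .add_child("h1", "fa", "mo1").add_child("h2", "fa", "mo2")
    )
    p.samples = ["h1", "h2"]
    return p


def half_cousin_pedigree() -> Pedigree:
    """Children of half sibs (by unrelated mates); phi = 1/32."""
    p = half_sib_pedigree()
    p.add_founder("m1").add_founder("m2")
    p.add_child("c1", "h1", "m1").add_child("c2", "h2", "m2")
    p.samples = ["c1", "c2"]
    return p


def unrelated_pedigree(n: int = 2) -> Pedigree:
    p = Pedigree()
    for k in range(n):
        p.add_founder(f"u{k + 1}")
    return p


# ---------------------------------------------------------------------------
# cohort specification

@dataclass(frozen=True)
class AlleleFreqModel:
    """Mixture model for per-site alt allele frequencies.

    A fraction ``1 - rare_fraction`` of sites draw the alt frequency from
    Beta(beta_a, beta_b); the rest draw a minor-allele frequency uniformly
    from [rare_maf_min, rare_maf_max] (alt allele = minor).  The symmetric
    Beta(3, 3) default puts the variant-site heterozygote fraction of a
    single genome at exactly 0.6.
    """

    beta_a: float = 3.0
    beta_b: float = 3.0
    rare_fraction: float = 0.3
    rare_maf_min: float = 0.001
    rare_maf_max: float = 0.05

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        q = rng.beta(self.beta_a, self.beta_b, size=n)
        rare = rng.random(n) < self.rare_fraction
        q[rare] = rng.uniform(self.rare_maf_min, self.rare_maf_max, rare.sum())
        return q


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    The scaled-down defaults (four 200 Mb chromosomes at 1 SNP/kb, eight
    samples, a founder event 50 generations back planting ~200 exponential
    tracts per sample — about a quarter of the genome autozygous, as seen
    in strongly bottlenecked isolates) emulate an isolated-population
    cohort at a size that simulates in seconds.  ``seed`` is mandatory.
    """

    seed: int
    n_samples: int = 8
    chrom_lengths_mb: tuple = (200.0, 200.0, 200.0, 200.0)
    snp_density_per_kb: float = 1.0
    allele_freq: AlleleFreqModel = AlleleFreqModel()
    pedigree: Pedigree | None = None
    founder_g: float | None = 50.0
    segments_per_sample: float = 200.0
    cm_per_mb: float = 1.0
    error_rate: float = 0.0
    missing_rate: float = 0.0
    qual_low_fraction: float = 0.05
    filter_fail_fraction: float = 0.02
    mean_depth: float = 37.0

    def __post_init__(self) -> None:
        for name in ("error_rate", "missing_rate", "qual_low_fraction",
                     "filter_fail_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} out of [0, 1]")
        if self.snp_density_per_kb <= 0 or self.n_samples < 1:
            raise ValueError("invalid density or sample count")
        if self.pedigree is not None and len(self.pedigree.samples) != self.n_samples:
            raise ValueError("pedigree sample list must match n_samples")


@dataclass
class CohortTruth:
    """Ground truth recorded alongside an emitted cohort."""

    founder_g: float | None
    tracts: dict[str, list[dict]]
    expected_kinship: dict[tuple[str, str], float]
    realized_kinship: dict[tuple[str, str], float]
    site_stratum: np.ndarray | None
    error_mask: np.ndarray
    missing_mask: np.ndarray
    manifest: dict

    def tract_lengths_mb(self, sample: str | None = None) -> np.ndarray:
        """Drawn (exponential) tract lengths, pooled or for one sample."""
        pools = (
            [self.tracts.get(sample, [])] if sample is not None
            else list(self.tracts.values())
        )
        return np.array([t["length_mb"] for pool in pools for t in pool])


@dataclass
class SimulatedCohort:
    """A simulated cohort: emitted genotypes, site fields and truth."""

    spec: CohortSpec
    matrix: GenotypeMatrix
    filters: np.ndarray
    depths: np.ndarray
    truth: CohortTruth
    vcf_paths: list[str] = field(default_factory=list)

    def per_sample_matrices(self) -> list[GenotypeMatrix]:
        """Single-sample matrices restricted to each sample's variant calls.

        This mirrors per-sample variant-only VCFs: hom-ref and missing
        genotypes are absent, so merging reintroduces them as missing.
        """
        out = []
        for k, sample in enumerate(self.matrix.samples):
            keep = np.isin(self.matrix.genotypes[k], (1, 2))
            out.append(
                GenotypeMatrix(
                    [sample],
                    self.matrix.sites.loc[keep].copy(),
                    self.matrix.genotypes[k : k + 1, keep],
                )
            )
        return out


# ---------------------------------------------------------------------------
# simulation internals

def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _site_positions(
    chrom_lengths_mb, density_per_kb: float, rng: np.random.Generator
) -> pd.DataFrame:
    frames = []
    for c, mb in enumerate(chrom_lengths_mb, start=1):
        length_bp = int(mb * 1e6)
        n = int(round(mb * 1000.0 * density_per_kb))
        pos = np.unique(rng.integers(1, length_bp + 1, size=n))
        while len(pos) < n:  # top up collisions
            extra = rng.integers(1, length_bp + 1, size=n - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        if len(pos) > n:
            pos = np.sort(rng.choice(pos, n, replace=False))
        frames.append(pd.DataFrame({"chrom": c, "pos": pos}))
    return pd.concat(frames, ignore_index=True)


def _random_bases(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, n)
    alt_i = (ref_i + rng.integers(1, 4, n)) % 4
    return bases[ref_i], bases[alt_i]


def _gamete(
    hap_a: tuple[np.ndarray, np.ndarray],
    hap_b: tuple[np.ndarray, np.ndarray],
    pos: np.ndarray,
    length_bp: int,
    cm_per_mb: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One meiotic product: Haldane crossovers on a cm_per_mb linear map."""
    morgans = length_bp / 1e6 * cm_per_mb / 100.0
    n_cross = rng.poisson(morgans)
    cross = np.sort(rng.integers(1, length_bp + 1, size=n_cross))
    src = (rng.integers(0, 2) + np.searchsorted(cross, pos)) % 2
    pick = src.astype(bool)
    alleles = np.where(pick, hap_b[0], hap_a[0])
    origins = np.where(pick, hap_b[1], hap_a[1])
    return alleles, origins


def _gene_drop(
    ped: Pedigree,
    sites: pd.DataFrame,
    chrom_lengths_mb,
    q: np.ndarray,
    cm_per_mb: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[tuple[str, str], float]]:
    """Drop founder haplotypes down the pedigree; return genotypes of
    ``ped.samples`` and realised IBD kinship per emitted pair."""
    chrom_idx = [
        (c, (sites["chrom"] == c).to_numpy(), int(mb * 1e6))
        for c, mb in enumerate(chrom_lengths_mb, start=1)
    ]
    haps: dict[str, list] = {}
    origin_counter = 0
    for member in ped.order:
        par = ped.parents[member]
        pair = []
        if par is None:
            for _ in range(2):
                alleles = (rng.random(len(sites)) < q).astype(np.int8)
                origins = np.full(len(sites), origin_counter, dtype=np.int32)
                origin_counter += 1
                pair.append((alleles, origins))
        else:
            for parent in par:
                al = np.empty(len(sites), dtype=np.int8)
                orr = np.empty(len(sites), dtype=np.int32)
                for c, mask, length_bp in chrom_idx:
                    pos = sites.loc[mask, "pos"].to_numpy()
                    pa = (haps[parent][0][0][mask], haps[parent][0][1][mask])
                    pb = (haps[parent][1][0][mask], haps[parent][1][1][mask])
                    a, o = _gamete(pa, pb, pos, length_bp, cm_per_mb, rng)
                    al[mask] = a
                    orr[mask] = o
                pair.append((al, orr))
        haps[member] = pair

    geno = np.empty((len(ped.samples), len(sites)), dtype=np.int8)
    for k, s in enumerate(ped.samples):
        geno[k] = haps[s][0][0] + haps[s][1][0]

    realized: dict[tuple[str, str], float] = {}
    from itertools import combinations

    for a, b in combinations(ped.samples, 2):
        oa = [haps[a][0][1], haps[a][1][1]]
        ob = [haps[b][0][1], haps[b][1][1]]
        ibd = sum((x == y).mean() for x in oa for y in ob) / 4.0
        realized[(a, b)] = float(ibd)
    return geno, realized


class TractPlacementError(RuntimeError):
    pass


def _plant_tracts(
    geno_row: np.ndarray,
    sites: pd.DataFrame,
    chrom_lengths_mb,
    q: np.ndarray,
    founder_g: float,
    segments_per_sample: float,
    cm_per_mb: float,
    rng: np.random.Generator,
    max_attempts_factor: int = 200,
) -> list[dict]:
    """Overwrite one sample with non-overlapping homozygous tracts.

    Lengths are exponential with mean 100/(2 g) cM; each tract copies a
    single ancestral haplotype (one allele drawn per site, then doubled).
    """
    mean_mb = 100.0 / (2.0 * founder_g) / cm_per_mb
    k = rng.poisson(segments_per_sample)
    # longest-first placement packs far better than arrival order and does
    # not change the (iid) length distribution of the planted set
    lengths = np.sort(rng.exponential(mean_mb, size=k))[::-1]
    chrom_bp = {c: int(mb * 1e6) for c, mb in enumerate(chrom_lengths_mb, start=1)}
    weights = np.array([chrom_bp[c] for c in chrom_bp], dtype=float)
    weights /= weights.sum()
    placed: dict[int, list[tuple[int, int]]] = {c: [] for c in chrom_bp}
    tracts: list[dict] = []
    attempts = 0
    cap = max(1, k) * max_attempts_factor
    chrom_ids = list(chrom_bp)
    pos_all = sites["pos"].to_numpy()
    chrom_all = sites["chrom"].to_numpy()
    for L in lengths:
        L_bp = max(1, int(round(L * 1e6)))
        while True:
            attempts += 1
            if attempts > cap:
                raise TractPlacementError(
                    f"could not place {k} tracts (mean {mean_mb:.2f} Mb) "
                    "without overlap; genome too small for the spec"
                )
            c = chrom_ids[rng.choice(len(chrom_ids), p=weights)]
            if L_bp >= chrom_bp[c]:
                continue
            start = int(rng.integers(1, chrom_bp[c] - L_bp + 1))
            end = start + L_bp - 1
            if any(s <= end and start <= e for s, e in placed[c]):
                continue
            placed[c].append((start, end))
            break
        in_tract = (chrom_all == c) & (pos_all >= start) & (pos_all <= end)
        alleles = (rng.random(in_tract.sum()) < q[in_tract]).astype(np.int8)
        geno_row[in_tract] = 2 * alleles
        tracts.append(
            {
                "chrom": int(c), "start_pos": start, "end_pos": end,
                "length_mb": float(L), "n_snps": int(in_tract.sum()),
            }
        )
    return tracts


# ---------------------------------------------------------------------------
# public generators

def simulate_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
    layout: str = "per-sample",
) -> SimulatedCohort:
    """Generate a cohort per ``spec``; optionally emit VCFs and a truth sidecar.

    ``layout`` is ``per-sample`` (one variant-only VCF per sample, the form
    single-genome callers produce) or ``multi-sample`` (one VCF carrying
    every genotype including hom-ref).  Identical specs produce
    byte-identical output.
    """
    if layout not in ("per-sample", "multi-sample"):
        raise ValueError(f"unknown layout {layout!r}")
    rngs = _streams(
        spec.seed,
        ("sites", "alleles", "genotypes", "tracts", "error", "missing", "fields"),
    )
    sites = _site_positions(spec.chrom_lengths_mb, spec.snp_density_per_kb, rngs["sites"])
    n_sites = len(sites)
    q = spec.allele_freq.draw(n_sites, rngs["alleles"])
    ref, alt = _random_bases(n_sites, rngs["sites"])

    expected: dict[tuple[str, str], float] = {}
    realized: dict[tuple[str, str], float] = {}
    if spec.pedigree is not None:
        samples = list(spec.pedigree.samples)
        geno, realized = _gene_drop(
            spec.pedigree, sites, spec.chrom_lengths_mb, q,
            spec.cm_per_mb, rngs["genotypes"],
        )
        from itertools import combinations

        for a, b in combinations(samples, 2):
            expected[(a, b)] = spec.pedigree.expected_kinship(a, b)
    else:
        samples = [f"S{k + 1}" for k in range(spec.n_samples)]
        geno = rngs["genotypes"].binomial(2, q, size=(spec.n_samples, n_sites)).astype(np.int8)

    tracts: dict[str, list[dict]] = {}
    if spec.founder_g is not None and spec.segments_per_sample > 0:
        for k, s in enumerate(samples):
            tracts[s] = _plant_tracts(
                geno[k], sites, spec.chrom_lengths_mb, q,
                spec.founder_g, spec.segments_per_sample, spec.cm_per_mb,
                rngs["tracts"],
            )

    error_mask = rngs["error"].random(geno.shape) < spec.error_rate
    if error_mask.any():
        shift = 1 + rngs["error"].integers(0, 2, size=int(error_mask.sum()))
        geno[error_mask] = ((geno[error_mask] + shift) % 3).astype(np.int8)
    missing_mask = rngs["missing"].random(geno.shape) < spec.missing_rate
    geno[missing_mask] = MISSING

    frng = rngs["fields"]
    low = frng.random(n_sites) < spec.qual_low_fraction
    qual = np.where(low, frng.uniform(5.0, 30.0, n_sites), frng.uniform(31.0, 1500.0, n_sites))
    qual = np.round(qual, 1)
    filters = np.where(
        frng.random(n_sites) < spec.filter_fail_fraction, "MaxSB", "PASS"
    )
    depths = frng.poisson(spec.mean_depth, size=geno.shape)

    site_df = sites.assign(ref=ref, alt=alt, qual=qual)
    matrix = GenotypeMatrix(samples, site_df, geno)
    # GenotypeMatrix sorts sites; our positions are generated sorted per chrom
    truth = CohortTruth(
        founder_g=spec.founder_g,
        tracts=tracts,
        expected_kinship=expected,
        realized_kinship=realized,
        site_stratum=None,
        error_mask=error_mask,
        missing_mask=missing_mask,
        manifest={
            "n_sites": int(n_sites),
            "n_samples": len(samples),
            "n_qual_low": int(low.sum()),
            "n_qual_pass": int((~low).sum()),
            "n_filter_fail": int((filters == "MaxSB").sum()),
            "n_tracts": {s: len(t) for s, t in tracts.items()},
        },
    )
    cohort = SimulatedCohort(
        spec=spec, matrix=matrix, filters=filters, depths=depths, truth=truth
    )
    if out_dir is not None:
        cohort.vcf_paths = _emit(cohort, Path(out_dir), layout)
    return cohort


def make_private_shared_cohort(
    n_samples: int = 8,
    n_shared_sites: int = 2000,
    n_private_sites: int = 1000,
    private_het: float = 0.8,
    shared_het: float = 0.3,
    chrom_length_mb: float | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SimulatedCohort:
    """Cohort with two site strata: private (variant in one sample, mostly
    heterozygous) and shared (variant in all, less heterozygous).

    Emulates the call-rate structure of merged single-genome VCFs, where
    private variants are of recent origin and enriched for heterozygotes:
    after a union merge, heterozygosity decreases from the call-rate-1 bin
    to the all-samples bin.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rngs = _streams(seed, ("sites", "geno", "fields"))
    n_sites = n_shared_sites + n_samples * n_private_sites
    if chrom_length_mb is None:
        chrom_length_mb = max(1.0, n_sites / 1000.0)  # ~1 SNP/kb
    sites = _site_positions((chrom_length_mb,), n_sites / (chrom_length_mb * 1000.0), rngs["sites"])
    sites = sites.iloc[:n_sites]
    ref, alt = _random_bases(len(sites), rngs["sites"])

    stratum = np.zeros(len(sites), dtype=np.int32)  # 0 = shared, k = private to sample k
    order = rngs["sites"].permutation(len(sites))
    private_of = {}
    cursor = n_shared_sites
    for k in range(n_samples):
        idx = order[cursor : cursor + n_private_sites]
        stratum[idx] = k + 1
        private_of[k] = idx
        cursor += n_private_sites

    samples = [f"S{k + 1}" for k in range(n_samples)]
    geno = np.zeros((n_samples, len(sites)), dtype=np.int8)
    g = rngs["geno"]
    shared_idx = np.nonzero(stratum == 0)[0]
    for k in range(n_samples):
        geno[k, shared_idx] = np.where(
            g.random(len(shared_idx)) < shared_het, 1, 2
        ).astype(np.int8)
        idx = private_of[k]
        geno[k, idx] = np.where(g.random(len(idx)) < private_het, 1, 2).astype(np.int8)

    qual = np.round(rngs["fields"].uniform(31.0, 1500.0, len(sites)), 1)
    site_df = sites.assign(ref=ref, alt=alt, qual=qual)
    matrix = GenotypeMatrix(samples, site_df, geno)
    spec = CohortSpec(
        seed=seed, n_samples=n_samples,
        chrom_lengths_mb=(chrom_length_mb,),
        snp_density_per_kb=n_sites / (chrom_length_mb * 1000.0),
        founder_g=None, segments_per_sample=0.0,
        qual_low_fraction=0.0, filter_fail_fraction=0.0,
    )
    truth = CohortTruth(
        founder_g=None, tracts={}, expected_kinship={}, realized_kinship={},
        site_stratum=stratum,
        error_mask=np.zeros(geno.shape, dtype=bool),
        missing_mask=np.zeros(geno.shape, dtype=bool),
        manifest={
            "n_sites": int(len(sites)),
            "n_shared": int(n_shared_sites),
            "n_private_per_sample": int(n_private_sites),
            "union_size": int(len(sites)),
            "call_rate_bins": {
                1: int(n_samples * n_private_sites),
                n_samples: int(n_shared_sites),
            },
        },
    )
    cohort = SimulatedCohort(
        spec=spec, matrix=matrix,
        filters=np.full(len(sites), "PASS"),
        depths=rngs["fields"].poisson(37.0, size=geno.shape),
        truth=truth,
    )
    if out_dir is not None:
        cohort.vcf_paths = _emit(cohort, Path(out_dir), "per-sample")
    return cohort


# ---------------------------------------------------------------------------
# emission

def _emit(cohort: SimulatedCohort, out_dir: Path, layout: str) -> list[str]:
    out_dir.mkdir(parents=True, exist_ok=True)
    m = cohort.matrix
    contigs = {
        c: int(mb * 1e6)
        for c, mb in enumerate(cohort.spec.chrom_lengths_mb, start=1)
    }
    paths = []
    if layout == "multi-sample":
        p = out_dir / "cohort.vcf"
        write_vcf(m, str(p), filters=cohort.filters, depths=cohort.depths,
                  contig_lengths=contigs)
        paths.append(str(p))
    else:
        for k, sample in enumerate(m.samples):
            keep = np.isin(m.genotypes[k], (1, 2))
            sub = GenotypeMatrix(
                [sample], m.sites.loc[keep].copy(), m.genotypes[k : k + 1, keep]
            )
            p = out_dir / f"{sample}.vcf"
            write_vcf(
                sub, str(p),
                filters=cohort.filters[keep],
                depths=cohort.depths[k : k + 1, keep],
                contig_lengths=contigs,
            )
            paths.append(str(p))
    _write_truth_sidecar(cohort, out_dir / "truth.json")
    return paths


def _write_truth_sidecar(cohort: SimulatedCohort, path: Path) -> None:
    t = cohort.truth
    payload = {
        "seed": cohort.spec.seed,
        "founder_g": t.founder_g,
        "manifest": t.manifest,
        "tracts": t.tracts,
        "expected_kinship": {f"{a}|{b}": v for (a, b), v in t.expected_kinship.items()},
        "realized_kinship": {f"{a}|{b}": v for (a, b), v in t.realized_kinship.items()},
        "n_errors": int(t.error_mask.sum()),
        "n_missing": int(t.missing_mask.sum()),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
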