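"""Genomic variant I/O, site filtering, pseudo-phasing and windowing.

This module owns the two in-memory substrates of the pipeline:

* :class:`GenotypeStore` — diploid genotypes as read from a multi-sample
  VCF, indexed by chromosome, together with per-site QUAL/depth metadata
  needed by the site filters.
* :class:`HaplotypeMatrix` — a sites x haplotypes matrix of derived-allele
  codes (0 ancestral/REF, 1 derived/ALT, -1 missing) with population
  labels, the input of every divergence and introgression statistic.

Coordinate conventions: VCF positions are 1-based; windows and BED
intervals are 0-based half-open.  A 1-based site ``p`` falls in window
``[start, end)`` iff ``start < p <= end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "HaplotypeMatrix",
    "GenotypeStore",
    "ChromGenotypes",
    "SiteFilterConfig",
    "WindowConfig",
    "read_genotypes",
    "read_popmap",
    "filter_sites",
    "pseudo_phase",
    "iter_windows",
    "pop_allele_freqs",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Per-chromosome haplotype alleles with population labels.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    positions : ndarray of int
        1-based site coordinates, strictly increasing.
    alleles : ndarray of int8, shape (n_sites, n_haplotypes)
        Codes in {0, 1, MISSING}.
    sample_of_haplotype : list of str
        Sample id of each haplotype column (two columns per diploid).
    pop_of_sample : dict
        Sample id -> population label.
    length : int
        Chromosome (or locus) length in bp; used for usable-site
        accounting by windowed statistics.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    sample_of_haplotype: list
    pop_of_sample: dict
    length: int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (sites x haplotypes)")
        if self.alleles.shape[0] != self.positions.shape[0]:
            raise ValueError("positions and alleles disagree on site count")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if len(self.sample_of_haplotype) != self.alleles.shape[1]:
            raise ValueError("sample_of_haplotype length != haplotype count")
        for s in self.sample_of_haplotype:
            if s not in self.pop_of_sample:
                raise ValueError(f"sample {s!r} missing from pop_of_sample")
        bad = set(np.unique(self.alleles)) - {0, 1, MISSING}
        if bad:
            raise ValueError(f"invalid allele codes: {sorted(bad)}")

    # -- conveniences -------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def pop_of_haplotype(self) -> np.ndarray:
        return np.array(
            [self.pop_of_sample[s] for s in self.sample_of_haplotype]
        )

    @property
    def populations(self) -> list:
        seen = []
        for s in self.sample_of_haplotype:
            p = self.pop_of_sample[s]
            if p not in seen:
                seen.append(p)
        return seen

    def haplotype_indices(self, pop: str) -> np.ndarray:
        """Column indices of the haplotypes belonging to *pop*."""
        idx = np.flatnonzero(self.pop_of_haplotype == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population label {pop!r}")
        return idx

    def site_indices(self, window) -> np.ndarray:
        """Indices of sites inside a 0-based half-open window."""
        start, end = window
        return np.flatnonzero(
            (self.positions > start) & (self.positions <= end)
        )

    def slice_window(self, window) -> "HaplotypeMatrix":
        idx = self.site_indices(window)
        start, end = window
        return HaplotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[idx],
            alleles=self.alleles[idx],
            sample_of_haplotype=self.sample_of_haplotype,
            pop_of_sample=self.pop_of_sample,
            length=end - start,
        )


@dataclass
class ChromGenotypes:
    """Raw per-chromosome diploid genotypes plus filter metadata."""

    positions: np.ndarray          # (S,) int64, 1-based
    genotypes: np.ndarray          # (S, n_samples, 2) int8, MISSING = -1
    qual: np.ndarray               # (S,) float, NaN if absent
    depth: np.ndarray              # (S, n_samples) float, NaN if absent
    n_alt: np.ndarray              # (S,) int, number of ALT alleles
    phased: np.ndarray             # (S, n_samples) bool
    length: int = 0                # chromosome length (max position if unknown)


@dataclass
class GenotypeStore:
    """Diploid genotypes for any number of chromosomes."""

    samples: list
    pop_of_sample: dict
    chroms: dict = field(default_factory=dict)   # chrom -> ChromGenotypes

    @property
    def n_sites(self) -> int:
        return sum(c.positions.size for c in self.chroms.values())


@dataclass
class SiteFilterConfig:
    """Site-level filters mirroring standard resequencing QC.

    ``min_depth``/``max_depth`` bound the mean per-genotype read depth of
    a site (computed over called genotypes); ``min_maf`` and
    ``min_call_rate`` are inclusive boundaries.  Any threshold set to
    ``None`` disables that filter.
    """

    min_qual: float | None = None
    min_depth: float | None = None
    max_depth: float | None = None
    biallelic_only: bool = False
    min_maf: float | None = None
    min_call_rate: float | None = None

    def __post_init__(self):
        if self.min_maf is not None and not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.min_call_rate is not None and not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in [0, 1]")
        if (
            self.min_depth is not None
            and self.max_depth is not None
            and self.min_depth > self.max_depth
        ):
            raise ValueError("min_depth must be <= max_depth")


@dataclass
class WindowConfig:
    """Non-overlapping (or stepped) genome windows.

    ``min_usable_sites`` is the strict eligibility bound for the
    haplotype-based statistics: a 10-kb window needs more than half of its
    bases usable, i.e. the default 5,001 usable sites.
    """

    size: int = 10_000
    step: int | None = None
    min_usable_sites: int = 5_001

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("window size must be positive")
        if self.step is None:
            self.step = self.size
        if self.step <= 0:
            raise ValueError("window step must be positive")
        if self.min_usable_sites > self.size:
            raise ValueError("min_usable_sites cannot exceed window size")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_popmap(path) -> dict:
    """Read a two-column ``sample<TAB>population`` map."""
    pop_of_sample = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            pop_of_sample[fields[0]] = fields[1]
    return pop_of_sample


def read_genotypes(vcf_path, popmap_path) -> GenotypeStore:
    """Read a multi-sample VCF into a :class:`GenotypeStore`.

    Every sample in the VCF must appear in the popmap; missing genotypes
    are preserved as :data:`MISSING`.
    """
    from cyvcf2 import VCF

    pop_of_sample = read_popmap(popmap_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_of_sample]
    if absent:
        raise ValueError(
            "VCF samples missing from popmap: " + ", ".join(absent)
        )

    per_chrom: dict = {}
    for v in vcf:
        rec = per_chrom.setdefault(
            v.CHROM, {"pos": [], "gt": [], "qual": [], "dp": [],
                      "nalt": [], "phased": []}
        )
        rec["pos"].append(v.POS)
        gts = v.genotypes  # [[a0, a1, phased], ...]
        gt_row = np.empty((len(samples), 2), dtype=np.int8)
        ph_row = np.empty(len(samples), dtype=bool)
        for i, g in enumerate(gts):
            a0 = MISSING if g[0] < 0 else g[0]
            a1 = MISSING if g[1] < 0 else g[1]
            gt_row[i] = (a0, a1)
            ph_row[i] = bool(g[2])
        rec["gt"].append(gt_row)
        rec["phased"].append(ph_row)
        rec["qual"].append(np.nan if v.QUAL is None else float(v.QUAL))
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            rec["dp"].append(np.full(len(samples), np.nan))
        else:
            dp = dp.astype(float).reshape(len(samples))
            dp[dp < 0] = np.nan
            rec["dp"].append(dp)
        rec["nalt"].append(len(v.ALT))

    chroms = {}
    # chromosome lengths from the header when present
    header_len = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            body = line.split("<", 1)[-1].rstrip(">")
            kv = dict(p.split("=", 1) for p in body.split(",") if "=" in p)
            if "ID" in kv and "length" in kv:
                header_len[kv["ID"]] = int(kv["length"])
    for chrom, rec in per_chrom.items():
        pos = np.asarray(rec["pos"], dtype=np.int64)
        chroms[chrom] = ChromGenotypes(
            positions=pos,
            genotypes=np.stack(rec["gt"]) if rec["gt"] else
            np.empty((0, len(samples), 2), dtype=np.int8),
            qual=np.asarray(rec["qual"], dtype=float),
            depth=np.stack(rec["dp"]) if rec["dp"] else
            np.empty((0, len(samples))),
            n_alt=np.asarray(rec["nalt"], dtype=int),
            phased=np.stack(rec["phased"]) if rec["phased"] else
            np.empty((0, len(samples)), dtype=bool),
            length=header_len.get(chrom, int(pos.max()) if pos.size else 0),
        )
    return GenotypeStore(
        samples=samples, pop_of_sample=pop_of_sample, chroms=chroms
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _site_masks(cg: ChromGenotypes, cfg: SiteFilterConfig) -> dict:
    """Boolean pass-masks per filter for one chromosome."""
    S = cg.positions.size
    called = cg.genotypes[:, :, 0] != MISSING  # (S, n)
    masks = {}
    if cfg.min_qual is not None:
        # sites without a QUAL annotation pass
        masks["qual"] = np.where(
            np.isnan(cg.qual), True, cg.qual >= cfg.min_qual
        )
    if cfg.min_depth is not None or cfg.max_depth is not None:
        with np.errstate(invalid="ignore"):
            mean_dp = np.nanmean(np.where(called, cg.depth, np.nan), axis=1)
        ok = np.ones(S, dtype=bool)
        if cfg.min_depth is not None:
            ok &= np.where(np.isnan(mean_dp), True, mean_dp >= cfg.min_depth)
        if cfg.max_depth is not None:
            ok &= np.where(np.isnan(mean_dp), True, mean_dp <= cfg.max_depth)
        masks["depth"] = ok
    if cfg.biallelic_only:
        masks["biallelic"] = cg.n_alt == 1
    if cfg.min_maf is not None:
        alt = np.where(cg.genotypes == MISSING, 0, cg.genotypes).sum(axis=(1, 2))
        n_called = 2 * called.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_called > 0, alt / np.maximum(n_called, 1), 0.0)
        maf = np.minimum(p, 1 - p)
        masks["maf"] = maf >= cfg.min_maf
    if cfg.min_call_rate is not None:
        rate = called.mean(axis=1) if S else np.empty(0)
        masks["call_rate"] = rate >= cfg.min_call_rate
    return masks


FILTER_ORDER = ("qual", "depth", "biallelic", "maf", "call_rate")


def filter_sites(store: GenotypeStore, cfg: SiteFilterConfig):
    """Apply site filters; return (filtered store, per-filter removal counts).

    A removed site is attributed to the first filter it fails in the
    fixed order qual, depth, biallelic, maf, call_rate, so the counts sum
    to the total number of removed sites.
    """
    counts = {name: 0 for name in FILTER_ORDER}
    new_chroms = {}
    for chrom, cg in store.chroms.items():
        masks = _site_masks(cg, cfg)
        keep = np.ones(cg.positions.size, dtype=bool)
        removed_by = np.full(cg.positions.size, -1)
        for i, name in enumerate(FILTER_ORDER):
            if name not in masks:
                continue
            newly = keep & ~masks[name]
            removed_by[newly] = i
            keep &= masks[name]
        for i, name in enumerate(FILTER_ORDER):
            counts[name] += int((removed_by == i).sum())
        new_chroms[chrom] = ChromGenotypes(
            positions=cg.positions[keep],
            genotypes=cg.genotypes[keep],
            qual=cg.qual[keep],
            depth=cg.depth[keep],
            n_alt=cg.n_alt[keep],
            phased=cg.phased[keep],
            length=cg.length,
        )
    out = GenotypeStore(
        samples=store.samples,
        pop_of_sample=store.pop_of_sample,
        chroms=new_chroms,
    )
    counts = {k: v for k, v in counts.items() if v or k in
              {n for n in FILTER_ORDER if n in
               _enabled_filters(cfg)}}
    return out, counts


def _enabled_filters(cfg: SiteFilterConfig):
    names = []
    if cfg.min_qual is not None:
        names.append("qual")
    if cfg.min_depth is not None or cfg.max_depth is not None:
        names.append("depth")
    if cfg.biallelic_only:
        names.append("biallelic")
    if cfg.min_maf is not None:
        names.append("maf")
    if cfg.min_call_rate is not None:
        names.append("call_rate")
    return names


# ---------------------------------------------------------------------------
# pseudo-phasing
# ---------------------------------------------------------------------------

def pseudo_phase(store: GenotypeStore, seed: int) -> dict:
    """Randomly phase heterozygous genotypes into two haplotypes per sample.

    Heterozygous variants are assigned to one of the two haplotypes
    uniformly at random (already-phased genotypes are taken as given);
    homozygous and missing genotypes are copied.  Returns a dict
    ``chrom -> HaplotypeMatrix``.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for chrom in sorted(store.chroms):
        cg = store.chroms[chrom]
        gt = cg.genotypes.copy()
        het = (
            (gt[:, :, 0] != gt[:, :, 1])
            & (gt[:, :, 0] != MISSING)
            & (gt[:, :, 1] != MISSING)
            & ~cg.phased
        )
        flip = het & (rng.random(het.shape) < 0.5)
        a0 = np.where(flip, gt[:, :, 1], gt[:, :, 0])
        a1 = np.where(flip, gt[:, :, 0], gt[:, :, 1])
        haps = np.empty((gt.shape[0], 2 * gt.shape[1]), dtype=np.int8)
        haps[:, 0::2] = a0
        haps[:, 1::2] = a1
        sample_of_hap = [s for s in store.samples for _ in range(2)]
        out[chrom] = HaplotypeMatrix(
            chrom=chrom,
            positions=cg.positions,
            alleles=haps,
            sample_of_haplotype=sample_of_hap,
            pop_of_sample=store.pop_of_sample,
            length=cg.length,
        )
    return out


# ---------------------------------------------------------------------------
# windows and frequencies
# ---------------------------------------------------------------------------

def iter_windows(chrom_length: int, cfg: WindowConfig):
    """Yield 0-based half-open windows tiling a chromosome.

    A trailing window that would extend past the chromosome end is
    dropped.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    start = 0
    while start + cfg.size <= chrom_length:
        yield (start, start + cfg.size)
        start += cfg.step


def pop_allele_freqs(haps: HaplotypeMatrix, window=None, pops=None):
    """Per-site per-population derived-allele frequencies in a window.

    Returns ``(freqs, usable, positions)`` where ``freqs`` maps each
    population to an array of derived counts over non-missing counts and
    ``usable`` masks out sites at which any requested population is
    entirely missing.
    """
    if window is None:
        window = (0, haps.length)
    idx = haps.site_indices(window)
    if pops is None:
        pops = haps.populations
    freqs = {}
    usable = np.ones(idx.size, dtype=bool)
    for pop in pops:
        cols = haps.haplotype_indices(pop)
        sub = haps.alleles[np.ix_(idx, cols)]
        called = sub != MISSING
        n = called.sum(axis=1)
        der = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(n > 0, der / np.maximum(n, 1), np.nan)
        usable &= n > 0
        freqs[pop] = f
    return freqs, usable, haps.positions[idx]
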