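"""Synthetic multi-population genomic data with known demographic truth.

The generator emulates the study system the pipeline targets: a pair of
marine stickleback lineages (Japan Sea, ``JS``, and Pacific Ocean,
``PO``) that split 1e5-1e6 generations ago with low bidirectional
migration (m ~ 1e-6 per generation, backwards in time), a
bottleneck-then-expansion history in the Japan Sea lineage, an optional
allopatric Atlantic lineage, and a distant outgroup used to polarise
alleles.  Loci are short (~2-10 kb) independent non-recombining
fragments, mirroring a 2-kb-locus / 125-kb-spacing sampling design.

Five divergence scenarios are supported, each crossed with three growth
variants:

============  ===========================================================
scenario      migration epochs (backwards in time, generations)
============  ===========================================================
``I``         none
``IM``        continuous over ``[0, T]``
``IAM``       ancient only, ``[T_anc_stop, T]``
``IRM``       recent only, ``[0, T_rec_start]``
``IARM``      both windows
============  ===========================================================

``m12`` is the proportion of the Japan Sea population that are migrants
from the Pacific Ocean per generation (backwards in time), ``m21`` the
converse.  Growth variants: ``constant``; ``bottleneck`` (JS size is
``N_JSB`` during ``[T_G, T]`` and ``N_JS`` in ``[0, T_G]``); ``growth``
(JS grows exponentially from ``N_JSB`` at ``T_G`` to ``N_JS`` at
present).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import msprime
import numpy as np

from .gio import MISSING, HaplotypeMatrix

SCENARIOS = ("I", "IM", "IAM", "IRM", "IARM")
GROWTH_VARIANTS = ("constant", "growth", "bottleneck")
HYBRID_CLASSES = ("parentA", "parentB", "F1", "F2", "BC_A", "BC_B")

#: default autosomal mutation rate, per site per generation (1-yr generations)
MU_DEFAULT = 7.1e-9

__all__ = [
    "SCENARIOS",
    "GROWTH_VARIANTS",
    "HYBRID_CLASSES",
    "MU_DEFAULT",
    "DemographicParams",
    "LocusSpec",
    "ParameterError",
    "simulate_demography",
    "simulate_five_taxon",
    "concat_loci",
    "simulate_hybrid_genotypes",
    "make_fixture_dataset",
    "build_demography",
]


class ParameterError(ValueError):
    """A demographic parameter violates its domain invariant."""


@dataclass
class DemographicParams:
    """Parameters of one divergence-with-gene-flow scenario.

    Times are in generations before present; sizes are diploid effective
    sizes.  ``m12``/``m21`` are backwards-in-time per-generation migrant
    fractions.  Scenario ``I`` forces both to zero.
    """

    scenario: str = "IM"
    growth: str = "bottleneck"
    T: float = 7e5
    T_G: float = 3e5
    T_anc_stop: float | None = None
    T_rec_start: float | None = None
    m12: float = 1.3e-6
    m21: float = 1.05e-6
    N_PO: float = 1.0e5
    N_JS: float = 2.0e5
    N_JSB: float = 1.22e4
    N_ANC: float = 1.0e5
    mu: float = MU_DEFAULT
    gen_time: float = 1.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if self.growth not in GROWTH_VARIANTS:
            raise ParameterError(f"unknown growth variant {self.growth!r}")
        for name in ("N_PO", "N_JS", "N_JSB", "N_ANC"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("m12", "m21"):
            m = getattr(self, name)
            if not 0 <= m < 1:
                raise ParameterError(f"{name} must satisfy 0 <= m < 1")
        if self.scenario == "I" and (self.m12 or self.m21):
            raise ParameterError("scenario I requires m12 = m21 = 0")
        if not 0 < self.T_G < self.T:
            raise ParameterError("need 0 < T_G < T")
        if self.scenario in ("IAM", "IARM"):
            if self.T_anc_stop is None or not 0 < self.T_anc_stop < self.T:
                raise ParameterError(
                    "IAM/IARM need 0 < T_anc_stop < T"
                )
        if self.scenario in ("IRM", "IARM"):
            if self.T_rec_start is None or not 0 < self.T_rec_start < self.T_G:
                raise ParameterError(
                    "IRM/IARM need 0 < T_rec_start < T_G"
                )
        if self.mu < 0:
            raise ParameterError("mu must be non-negative")
        if self.gen_time <= 0:
            raise ParameterError("gen_time must be positive")


@dataclass
class LocusSpec:
    """Sampling design of independent short loci.

    ``samples_per_pop`` maps population label to the *haplotype* count
    sampled there; order fixes haplotype column order in the output.
    """

    n_loci: int = 200
    locus_length: int = 2_000
    spacing: int = 125_000
    samples_per_pop: dict = field(
        default_factory=lambda: {"JS": 10, "PO": 10}
    )

    def __post_init__(self):
        if self.locus_length <= 0:
            raise ParameterError("locus_length must be positive")
        if self.spacing < self.locus_length:
            raise ParameterError("spacing must be >= locus_length")
        if self.n_loci <= 0:
            raise ParameterError("n_loci must be positive")
        for pop, n in self.samples_per_pop.items():
            if n <= 0:
                raise ParameterError(f"samples_per_pop[{pop!r}] must be > 0")
            if n % 2:
                raise ParameterError(
                    f"samples_per_pop[{pop!r}] counts haplotypes and must "
                    "be even (two per diploid individual)"
                )


# ---------------------------------------------------------------------------
# demography construction
# ---------------------------------------------------------------------------

#: outgroup split time as a multiple of T (polarisation lineage)
OUTGROUP_SPLIT_FACTOR = 5.0
#: Atlantic (allopatric) split time as a fraction of T, when requested
ATLANTIC_SPLIT_FRACTION = 0.5


def build_demography(
    params: DemographicParams,
    include_outgroup: bool = False,
    include_atlantic: bool = False,
) -> msprime.Demography:
    """Translate :class:`DemographicParams` into an msprime demography.

    Population 1 is the Japan Sea lineage (``JS``), population 2 the
    Pacific Ocean lineage (``PO``).  With ``include_atlantic`` an ``AT``
    lineage splits from PO at ``ATLANTIC_SPLIT_FRACTION * T``; with
    ``include_outgroup`` an ``OUT`` lineage splits from the root at
    ``OUTGROUP_SPLIT_FACTOR * T``.
    """
    params.validate()
    dem = msprime.Demography()
    if params.growth == "growth":
        # exponential growth from N_JSB at T_G to N_JS at present
        alpha = np.log(params.N_JS / params.N_JSB) / params.T_G
        dem.add_population(
            name="JS", initial_size=params.N_JS, growth_rate=alpha
        )
    else:
        dem.add_population(name="JS", initial_size=params.N_JS)
    dem.add_population(name="PO", initial_size=params.N_PO)
    dem.add_population(name="ANC", initial_size=params.N_ANC)
    if include_atlantic:
        dem.add_population(name="AT", initial_size=params.N_PO)
        dem.add_population(name="POANC", initial_size=params.N_PO)
    if include_outgroup:
        dem.add_population(name="OUT", initial_size=params.N_ANC)
        dem.add_population(name="ROOT", initial_size=params.N_ANC)

    if params.growth == "growth":
        dem.add_population_parameters_change(
            time=params.T_G, population="JS",
            initial_size=params.N_JSB, growth_rate=0.0,
        )
    elif params.growth == "bottleneck":
        dem.add_population_parameters_change(
            time=params.T_G, population="JS", initial_size=params.N_JSB
        )

    # migration epochs (backwards in time); msprime's rate M[a, b] moves
    # lineages from a to b backwards, i.e. a receives forward migrants
    # from b — exactly the backward m_ab convention used here.
    def set_mig(time, m12, m21):
        if time == 0.0:
            dem.set_migration_rate(source="JS", dest="PO", rate=m12)
            dem.set_migration_rate(source="PO", dest="JS", rate=m21)
        else:
            dem.add_migration_rate_change(
                time=time, source="JS", dest="PO", rate=m12
            )
            dem.add_migration_rate_change(
                time=time, source="PO", dest="JS", rate=m21
            )

    s = params.scenario
    if s == "IM":
        set_mig(0.0, params.m12, params.m21)
    elif s == "IAM":
        set_mig(params.T_anc_stop, params.m12, params.m21)
    elif s == "IRM":
        set_mig(0.0, params.m12, params.m21)
        set_mig(params.T_rec_start, 0.0, 0.0)
    elif s == "IARM":
        set_mig(0.0, params.m12, params.m21)
        set_mig(params.T_rec_start, 0.0, 0.0)
        set_mig(params.T_anc_stop, params.m12, params.m21)

    if include_atlantic:
        dem.add_population_split(
            time=ATLANTIC_SPLIT_FRACTION * params.T,
            derived=["PO", "AT"], ancestral="POANC",
        )
        dem.add_population_split(
            time=params.T, derived=["JS", "POANC"], ancestral="ANC"
        )
    else:
        dem.add_population_split(
            time=params.T, derived=["JS", "PO"], ancestral="ANC"
        )
    if include_outgroup:
        dem.add_population_split(
            time=OUTGROUP_SPLIT_FACTOR * params.T,
            derived=["ANC", "OUT"], ancestral="ROOT",
        )
    dem.sort_events()
    return dem


# ---------------------------------------------------------------------------
# locus simulation
# ---------------------------------------------------------------------------

def simulate_demography(
    params: DemographicParams,
    spec: LocusSpec,
    seed: int,
    include_outgroup: bool = False,
    include_atlantic: bool = False,
    recombination_rate: float = 0.0,
) -> list[HaplotypeMatrix]:
    """Simulate independent loci under a divergence scenario.

    Returns one :class:`HaplotypeMatrix` per locus with alleles coded 0
    (ancestral) / 1 (derived) relative to the simulated ancestral allele.
    Haplotype columns are grouped by population in the order of
    ``spec.samples_per_pop``.  Deterministic for a fixed seed.
    """
    params.validate()
    pops = dict(spec.samples_per_pop)
    if include_atlantic and "AT" not in pops:
        pops["AT"] = pops.get("PO", 10)
    if include_outgroup and "OUT" not in pops:
        pops["OUT"] = 2
    for pop in pops:
        if pop not in {"JS", "PO", "AT", "OUT"}:
            raise ParameterError(f"unknown population {pop!r} in spec")
    dem = build_demography(
        params,
        include_outgroup=include_outgroup or "OUT" in spec.samples_per_pop,
        include_atlantic=include_atlantic or "AT" in spec.samples_per_pop,
    )
    # haploid sample counts per population
    sample_sets = [
        msprime.SampleSet(n, population=pop, ploidy=1)
        for pop, n in pops.items()
    ]
    ss = np.random.SeedSequence(seed)
    anc_seed, mut_seed = [int(s) for s in ss.generate_state(2) % (2**31 - 2) + 1]

    reps = msprime.sim_ancestry(
        samples=sample_sets,
        demography=dem,
        sequence_length=spec.locus_length,
        recombination_rate=recombination_rate,
        num_replicates=spec.n_loci,
        random_seed=anc_seed,
        ploidy=2,
    )
    # two consecutive haplotypes form one diploid individual
    sample_of_hap = []
    pop_of_sample = {}
    for pop, n in pops.items():
        for i in range(n):
            name = f"{pop}_{i // 2}"
            sample_of_hap.append(name)
            pop_of_sample[name] = pop

    rng = np.random.default_rng(mut_seed)
    loci = []
    for k, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=params.mu,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            model=msprime.BinaryMutationModel(),
            discrete_genome=True,
        )
        if mts.num_sites:
            G = mts.genotype_matrix()  # (S, H), derived counts
            G = (G > 0).astype(np.int8)
            positions = np.array(
                [int(site.position) + 1 for site in mts.sites()],
                dtype=np.int64,
            )
            # discrete-genome recurrent hits share a position; keep first
            _, first = np.unique(positions, return_index=True)
            positions, G = positions[first], G[first]
        else:
            G = np.empty((0, len(sample_of_hap)), dtype=np.int8)
            positions = np.empty(0, dtype=np.int64)
        loci.append(
            HaplotypeMatrix(
                chrom=f"locus_{k}",
                positions=positions,
                alleles=G,
                sample_of_haplotype=list(sample_of_hap),
                pop_of_sample=dict(pop_of_sample),
                length=spec.locus_length,
            )
        )
    return loci


def concat_loci(loci, chrom: str = "chr1", spacing: int | None = None
                ) -> HaplotypeMatrix:
    """Lay independent loci onto one pseudo-chromosome.

    Locus ``k`` occupies ``[k * spacing, k * spacing + locus_length)``;
    the pseudo-chromosome models each locus as a fully callable island
    (statistics windows are normally aligned to the locus grid).
    """
    if not loci:
        raise ValueError("no loci to concatenate")
    if spacing is None:
        spacing = loci[0].length
    pos_all, all_alleles = [], []
    for k, h in enumerate(loci):
        pos_all.append(h.positions + k * spacing)
        all_alleles.append(h.alleles)
    return HaplotypeMatrix(
        chrom=chrom,
        positions=np.concatenate(pos_all),
        alleles=np.vstack(all_alleles),
        sample_of_haplotype=loci[0].sample_of_haplotype,
        pop_of_sample=loci[0].pop_of_sample,
        length=spacing * (len(loci) - 1) + loci[0].length,
    )


# ---------------------------------------------------------------------------
# five-taxon simulation with a directional pulse
# ---------------------------------------------------------------------------

def simulate_five_taxon(
    seed: int,
    n_loci: int = 100,
    locus_length: int = 5_000,
    samples_per_pop: int = 8,
    N: float = 1e4,
    T12: float = 1e4,
    T34: float = 2e4,
    T_root: float = 4e4,
    T_out: float = 2e5,
    mu: float = 1e-8,
    pulse: tuple | None = None,
    pulse_time: float = 5e3,
    pulse_prop: float = 0.9,
) -> list[HaplotypeMatrix]:
    """Simulate the symmetric five-taxon tree ((P1,P2),(P3,P4),OUT).

    The (P1, P2) split is younger than the (P3, P4) split, the
    configuration assumed by partitioned D and D_FOIL.  ``pulse``
    optionally injects one unidirectional introgression event as
    ``(donor, recipient)`` in forward time at ``pulse_time`` with
    admixture proportion ``pulse_prop``; ``("P3", "ANC12")`` targets the
    common ancestor of P1 and P2 (ancestral introgression, with
    ``pulse_time`` interpreted between the two split times).
    """
    if not 0 < T12 < T34 < T_root < T_out:
        raise ParameterError("need 0 < T12 < T34 < T_root < T_out")
    dem = msprime.Demography()
    for name in ("P1", "P2", "P3", "P4", "ANC12", "ANC34",
                 "ANCALL", "OUT", "ROOT"):
        dem.add_population(name=name, initial_size=N)
    if pulse is not None:
        donor, recipient = pulse
        # backwards in time the recipient's lineages move into the donor
        dem.add_mass_migration(
            time=pulse_time, source=recipient, dest=donor,
            proportion=pulse_prop,
        )
    dem.add_population_split(time=T12, derived=["P1", "P2"],
                             ancestral="ANC12")
    dem.add_population_split(time=T34, derived=["P3", "P4"],
                             ancestral="ANC34")
    dem.add_population_split(time=T_root, derived=["ANC12", "ANC34"],
                             ancestral="ANCALL")
    dem.add_population_split(time=T_out, derived=["ANCALL", "OUT"],
                             ancestral="ROOT")
    dem.sort_events()
    pops = ["P1", "P2", "P3", "P4"]
    samples = [msprime.SampleSet(samples_per_pop, population=p, ploidy=1)
               for p in pops] + [msprime.SampleSet(2, population="OUT",
                                                   ploidy=1)]
    ss = np.random.SeedSequence(seed)
    anc_seed, mut_seed = [int(s) for s in ss.generate_state(2) % (2**31 - 2) + 1]
    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=locus_length,
        num_replicates=n_loci, random_seed=anc_seed, ploidy=2,
    )
    if samples_per_pop % 2:
        raise ParameterError("samples_per_pop counts haplotypes; use even")
    sample_of_hap = []
    pop_of_sample = {}
    for p in pops:
        for i in range(samples_per_pop):
            name = f"{p}_{i // 2}"
            sample_of_hap.append(name)
            pop_of_sample[name] = p
    sample_of_hap += ["OUT_0", "OUT_0"]
    pop_of_sample["OUT_0"] = "OUT"
    rng = np.random.default_rng(mut_seed)
    loci = []
    for k, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=int(rng.integers(1, 2**31 - 1)),
            model=msprime.BinaryMutationModel(),
        )
        if mts.num_sites:
            G = (mts.genotype_matrix() > 0).astype(np.int8)
            positions = np.array(
                [int(site.position) + 1 for site in mts.sites()],
                dtype=np.int64,
            )
            _, first = np.unique(positions, return_index=True)
            positions, G = positions[first], G[first]
        else:
            G = np.empty((0, len(sample_of_hap)), dtype=np.int8)
            positions = np.empty(0, dtype=np.int64)
        loci.append(HaplotypeMatrix(
            chrom=f"locus_{k}", positions=positions, alleles=G,
            sample_of_haplotype=list(sample_of_hap),
            pop_of_sample=dict(pop_of_sample), length=locus_length,
        ))
    return loci


# ---------------------------------------------------------------------------
# hybrid pedigrees
# ---------------------------------------------------------------------------

def simulate_hybrid_genotypes(p_A, p_B, cls: str, n: int, seed: int
                              ) -> np.ndarray:
    """Draw diploid genotypes for a hybrid class at unlinked loci.

    ``p_A``/``p_B`` are per-locus frequencies of the A-species allele
    (allele code 0 = species-B allele, 1 = species-A allele) in the two
    parental gene pools.  Classes follow the standard crossing pedigree:
    F1 = one gamete from each parental pool; F2 = two gametes from
    independent F1 parents; BC_A = F1 x parentA (and mirrored for B).

    Returns an ``(n, n_loci, 2)`` int8 array of allele codes.
    """
    p_A = np.asarray(p_A, dtype=float)
    p_B = np.asarray(p_B, dtype=float)
    if p_A.shape != p_B.shape:
        raise ValueError("p_A and p_B must have the same locus count")
    if np.any((p_A < 0) | (p_A > 1) | (p_B < 0) | (p_B > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if cls not in HYBRID_CLASSES:
        raise ValueError(f"unknown hybrid class {cls!r}")
    rng = np.random.default_rng(seed)
    L = p_A.size

    def gamete_A():
        return (rng.random((n, L)) < p_A).astype(np.int8)

    def gamete_B():
        return (rng.random((n, L)) < p_B).astype(np.int8)

    def gamete_F1():
        # an F1 carries one A-pool and one B-pool allele per locus; its
        # gamete picks either copy with probability 1/2 (unlinked loci)
        a, b = gamete_A(), gamete_B()
        pick = rng.random((n, L)) < 0.5
        return np.where(pick, a, b)

    if cls == "parentA":
        g = np.stack([gamete_A(), gamete_A()], axis=-1)
    elif cls == "parentB":
        g = np.stack([gamete_B(), gamete_B()], axis=-1)
    elif cls == "F1":
        g = np.stack([gamete_A(), gamete_B()], axis=-1)
    elif cls == "F2":
        g = np.stack([gamete_F1(), gamete_F1()], axis=-1)
    elif cls == "BC_A":
        g = np.stack([gamete_F1(), gamete_A()], axis=-1)
    else:  # BC_B
        g = np.stack([gamete_F1(), gamete_B()], axis=-1)
    return g


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def _write_vcf(path, haps: HaplotypeMatrix) -> None:
    samples = list(dict.fromkeys(haps.sample_of_haplotype))
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={haps.chrom},length={haps.length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    col_of_sample = {}
    for col, s in enumerate(haps.sample_of_haplotype):
        col_of_sample.setdefault(s, []).append(col)
    for i, pos in enumerate(haps.positions):
        row = haps.alleles[i]
        gts = []
        for s in samples:
            c0, c1 = col_of_sample[s]
            a0 = "." if row[c0] == MISSING else str(int(row[c0]))
            a1 = "." if row[c1] == MISSING else str(int(row[c1]))
            gts.append(f"{a0}|{a1}")
        lines.append(
            f"{haps.chrom}\t{int(pos)}\t.\tA\tT\t100\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def make_fixture_dataset(params: DemographicParams, spec: LocusSpec,
                         seed: int, outdir) -> dict:
    """Write a self-consistent fixture dataset and return its manifest.

    Files written: a phased multi-sample VCF with the loci laid onto one
    pseudo-chromosome, a sample->population map, a linear recombination
    map, and a gene BED tiling every third locus.  All files round-trip
    through :mod:`sticklescan.gio` readers.
    """
    os.makedirs(outdir, exist_ok=True)
    loci = simulate_demography(params, spec, seed)
    haps = concat_loci(loci, spacing=spec.spacing)
    vcf = os.path.join(outdir, "dataset.vcf")
    popmap = os.path.join(outdir, "popmap.tsv")
    rmap = os.path.join(outdir, "recomb_map.tsv")
    bed = os.path.join(outdir, "genes.bed")
    try:
        _write_vcf(vcf, haps)
        samples = list(dict.fromkeys(haps.sample_of_haplotype))
        with open(popmap, "w") as fh:
            for s in samples:
                fh.write(f"{s}\t{haps.pop_of_sample[s]}\n")
        with open(rmap, "w") as fh:
            fh.write("chrom\tpos_bp\tcum_cM\n")
            # linear 3 cM/Mb map, two anchoring markers
            fh.write(f"{haps.chrom}\t0\t0.0\n")
            fh.write(f"{haps.chrom}\t{haps.length}\t"
                     f"{3.0 * haps.length / 1e6:.6f}\n")
        with open(bed, "w") as fh:
            for k in range(0, spec.n_loci, 3):
                s = k * spec.spacing
                fh.write(f"{haps.chrom}\t{s}\t{s + spec.locus_length}\t"
                         f"gene_{k}\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture file: {exc}") from exc
    return {
        "vcf": vcf,
        "popmap": popmap,
        "recomb_map": rmap,
        "genes_bed": bed,
        "chrom": haps.chrom,
        "chrom_length": haps.length,
        "n_sites": int(haps.n_sites),
        "n_samples": len(set(haps.sample_of_haplotype)),
        "seed": seed,
    }
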