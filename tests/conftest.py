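import numpy as np
import pytest

from sticklescan.gio import HaplotypeMatrix


def make_haps(alleles, pops, length=None, positions=None, chrom="chr1"):
    """Build a HaplotypeMatrix from a literal allele table.

    ``alleles``: (sites x haplotypes) list/array; ``pops``: per-haplotype
    population labels (each haplotype becomes its own sample).
    """
    A = np.asarray(alleles, dtype=np.int8)
    n_sites, n_haps = A.shape if A.ndim == 2 else (0, len(pops))
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    samples = [f"{p}_{i}" for i, p in enumerate(pops)]
    return HaplotypeMatrix(
        chrom=chrom,
        positions=np.asarray(positions),
        alleles=A.reshape(n_sites, n_haps),
        sample_of_haplotype=samples,
        pop_of_sample={s: p for s, p in zip(samples, pops)},
        length=length if length is not None else max(n_sites, 1),
    )


@pytest.fixture(scope="session")
def im_loci():
    """A small IM+bottleneck locus set reused across tests."""
    from sticklescan import simdata

    params = simdata.DemographicParams()
    spec = simdata.LocusSpec(
        n_loci=15, locus_length=2_000,
        samples_per_pop={"JS": 8, "PO": 8},
    )
    return simdata.simulate_demography(params, spec, seed=11)


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """A written VCF/popmap/map/BED dataset and its manifest."""
    from sticklescan import simdata

    outdir = tmp_path_factory.mktemp("fixture")
    params = simdata.DemographicParams()
    spec = simdata.LocusSpec(
        n_loci=10, locus_length=2_000,
        samples_per_pop={"JS": 8, "PO": 8},
    )
    manifest = simdata.make_fixture_dataset(params, spec, seed=3,
                                            outdir=str(outdir))
    return manifest
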