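import numpy as np
import pytest

from clinprs import simulate


@pytest.fixture(scope="session")
def cohort():
    """A moderately structured two-subpopulation reference cohort reused by
    adjustment and pipeline tests."""
    spec = simulate.CohortSpec(n_per_subpop=(400, 400), n_variants=250,
                               fst=0.1, seed=11)
    return simulate.simulate_cohort(spec)


@pytest.fixture
def vcf_writer(tmp_path):
    """Factory writing a small plain-text VCF; returns its path.

    ``records`` rows: (chrom, pos, ref, alt, [per-sample 'GT' or 'GT:DS']).
    """

    def write(records, samples=("S1",), fmt="GT", name="toy.vcf"):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n')
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="d">\n')
            chroms = sorted({r[0] for r in records})
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            for chrom, pos, ref, alt, *calls in records:
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t"
                         + "\t".join(calls) + "\n")
        return path

    return write


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
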