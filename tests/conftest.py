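import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from founderhap.variant_io import Genotype, MarkerTrack

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=60,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_track(
    positions,
    genotypes,
    sample_id="s1",
    chrom="chr1",
    alt=None,
    depth=30,
):
    """Build a MarkerTrack from parallel position/genotype sequences.

    ``genotypes`` may be Genotype members, ints, or the letters
    'r'/'h'/'a' (hom_ref/het/hom_alt). ``alt`` defaults to 'C' everywhere.
    """
    letter = {"r": Genotype.HOM_REF, "h": Genotype.HET, "a": Genotype.HOM_ALT}
    gts = [letter[g] if isinstance(g, str) else Genotype(g) for g in genotypes]
    n = len(positions)
    if alt is None:
        alt = ["C"] * n
    return MarkerTrack(
        sample_id=sample_id,
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        genotypes=np.asarray([int(g) for g in gts], dtype=np.int8),
        ref_alleles=np.array(["A"] * n, dtype=object),
        alt_alleles=np.array(list(alt), dtype=object),
        depths=np.full(n, depth, dtype=np.int32),
        quals=np.full(n, np.nan),
    )


@pytest.fixture
def worked_example_vcf(tmp_path):
    from founderhap.simulate import write_worked_example_vcf

    path = tmp_path / "worked_example.vcf"
    manifest = write_worked_example_vcf(path)
    return path, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
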