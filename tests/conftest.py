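import itertools

import pytest

from eightplex.panel import GenotypeCall, SampleGenotypes, get_snp, panel_rsids


def make_sample(genotypes: dict[str, str], sample_id: str = "S1") -> SampleGenotypes:
    """Build a sample from {"rs12913832": "AG", ...}; omitted SNPs are MISSING."""
    s = SampleGenotypes(sample_id=sample_id)
    for rsid, g in genotypes.items():
        s.calls[rsid] = GenotypeCall(rsid, tuple(sorted(g)))
    for rsid in panel_rsids():
        s.calls.setdefault(rsid, GenotypeCall.missing(rsid))
    return s


def genotype_options(rsid: str) -> list[tuple[str, str]]:
    """The three unordered genotypes possible at a panel SNP."""
    a, b = get_snp(rsid).alleles
    return [(a, a), (a, b), (b, b)]


def enumerate_complete(rsids: tuple[str, ...]):
    """Yield every complete genotype assignment over the given SNPs."""
    options = [genotype_options(r) for r in rsids]
    for combo in itertools.product(*options):
        yield make_sample({r: "".join(g) for r, g in zip(rsids, combo)})


@pytest.fixture
def sample_factory():
    return make_sample
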