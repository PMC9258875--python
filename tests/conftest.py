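import pytest
from hypothesis import settings

from famvar.pedigree import Individual, Pedigree
from famvar.variants import GenotypeCall, VariantSite

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_site(chrom="1", pos=100, ref="A", alt="G"):
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt)


def make_calls(dosages, depth=50, alt_reads=None):
    """Build sample->GenotypeCall from sample->dosage (None = missing)."""
    calls = {}
    for sid, d in dosages.items():
        if d is None:
            alleles = ("missing", "missing")
            ar = 0 if alt_reads is None else alt_reads.get(sid, 0)
        else:
            alleles = [("ref", "ref"), ("ref", "alt"), ("alt", "alt")][d]
            default_ar = {0: 0, 1: depth // 2, 2: depth}[d]
            ar = default_ar if alt_reads is None else alt_reads.get(sid, default_ar)
        calls[sid] = GenotypeCall(
            sample_id=sid,
            alleles=tuple(alleles),
            total_depth=depth,
            allele_depths=(depth - ar, ar),
        )
    return calls


def trio_pedigree(child_affected=True, father_affected=False, mother_affected=False):
    ped = Pedigree(family_id="T")
    aff = lambda b: "affected" if b else "unaffected"
    ped.add(Individual("dad", "T", sex="male", affection=aff(father_affected)))
    ped.add(Individual("mom", "T", sex="female", affection=aff(mother_affected)))
    ped.add(Individual("kid", "T", father_id="dad", mother_id="mom",
                       affection=aff(child_affected)))
    ped.validate()
    return ped


@pytest.fixture(scope="session")
def study_pedigrees():
    from famvar.fixtures import load_study_pedigrees

    return load_study_pedigrees()


@pytest.fixture(scope="session")
def study_candidates():
    from famvar.fixtures import load_study_candidates

    return load_study_candidates()


@pytest.fixture(scope="session")
def study_knowledge():
    from famvar.fixtures import load_study_gene_evidence

    return load_study_gene_evidence()
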