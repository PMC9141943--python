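import pytest

from pulascreen import simcohort as sc


@pytest.fixture(scope="session")
def locus():
    """Full-size (4842 bp) simulator locus with planted motifs and primers."""
    return sc.make_locus(seed=1)


@pytest.fixture(scope="session")
def small_locus():
    """A compact locus for simulation-heavy tests (CDS 300 codons)."""
    return sc.make_locus(cds_length_codons=300, flank_bp=100, seed=5)


@pytest.fixture(scope="session")
def elements():
    seqs, families = sc.make_transposase_set(seed=8)
    return seqs, families


@pytest.fixture(scope="session")
def haplotypes(locus, elements):
    seqs, _ = elements
    specs = sc.preset_haplotypes(locus, element_id=sorted(seqs)[0])
    return {hid: sc.build_haplotype(locus, spec, seqs)
            for hid, spec in specs.items()}


@pytest.fixture(scope="session")
def small_haplotypes(small_locus, elements):
    seqs, _ = elements
    specs = sc.preset_haplotypes(small_locus, element_id=sorted(seqs)[0])
    return {hid: sc.build_haplotype(small_locus, spec, seqs)
            for hid, spec in specs.items()}
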