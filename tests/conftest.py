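import pytest

from gcrescue import synthetic as syn


@pytest.fixture(scope="session")
def scaffold_protein():
    """Default adaptor-like scaffold (230 aa, motif panel planted)."""
    return syn.make_lat_like_protein(seed=11)


@pytest.fixture(scope="session")
def gc_rich_cds(scaffold_protein):
    """GC-rich CDS of the scaffold (target 0.72)."""
    return syn.reverse_translate_gc_biased(scaffold_protein, 0.72, seed=12)


@pytest.fixture(scope="session")
def planted_gene():
    """600-nt planted gene: 199-aa scaffold protein and its 72%-GC CDS.

    Docking tyrosines are shifted to fit the shorter protein.
    """
    params = syn.LatScaffoldParams(protein_length=199,
                                   docking_tyrosine_positions=(132, 171, 191, 196))
    protein = syn.make_lat_like_protein(params, seed=21)
    cds = syn.reverse_translate_gc_biased(protein, 0.72, seed=22)
    return protein, cds


@pytest.fixture(scope="session")
def ortholog_family(scaffold_protein):
    """Six orthologs evolved along the default vertebrate-like tree with the
    motif panel held invariant."""
    invariant = {1, 26, 29, 131, 132, 133, 134, 135, 171, 173, 191, 193, 226, 228}
    fam = syn.evolve_orthologs(scaffold_protein, syn.DEFAULT_ORTHOLOG_TREE,
                               invariant_sites=invariant, seed=13)
    return fam
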