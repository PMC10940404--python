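import pytest

from hrtract import SimConfig, builtin_locus, simulate_cohort

MINIMAL_CONFIG = """
name: minimal
region_length: 3500
haplotypes: [hap1]
flank: 120
anchor_5prime: -50
anchor_3prime: 3540
mutation_marker: mut
l2_marker: L2
reporter_marker: rep
sequence_seed: 3
markers:
  - {id: L1, kind: insertion, position: 300, role: linker,
     vector: GGTACCTAGGCTTAAGTCGACGCATGCA}
  - {id: mut, kind: substitution, position: 1200, role: mutation,
     vector: A, genomic: {hap1: G}}
  - {id: L2, kind: insertion, position: 2000, role: linker,
     vector: TTAATTAACCGCGGTACGTAGCTAGCGGCCGCT}
  - {id: rep, kind: insertion, position: 3000, role: reporter,
     vector: GAGGGCAGAGGAAGTCTTCTAACATGCGGTGACGTGGAGG}
"""


@pytest.fixture(scope="session")
def s134c():
    return builtin_locus("s134c")


@pytest.fixture(scope="session")
def r106w():
    return builtin_locus("r106w")


@pytest.fixture(scope="session")
def r282x():
    return builtin_locus("r282x")


@pytest.fixture(scope="session")
def all_loci(s134c, r106w, r282x):
    return {"s134c": s134c, "r106w": r106w, "r282x": r282x}


@pytest.fixture(scope="session")
def edited_cohort(s134c):
    """Error-free fully-edited S134C cohort reused across read-level tests."""
    cfg = SimConfig(n_clones=120, editing_efficiency=1.0, seed=11,
                    reporter_amplicon_dropout=0.0)
    return simulate_cohort(s134c, cfg)
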