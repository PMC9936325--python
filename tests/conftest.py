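import pytest

from sdswitch.reference import Biotype, MatureArm, PrecursorRecord, ReferenceSet
from sdswitch.simulate import SimConfig, simulate


def naive_find(refset: ReferenceSet, query: str) -> list[tuple[str, int]]:
    """Independent brute-force substring scan (the alignment oracle)."""
    if not (16 <= len(query) <= 32) or set(query) - set("ACGT"):
        return []
    hits = []
    for rec in refset:
        start = 0
        while True:
            pos = rec.sequence.find(query, start)
            if pos < 0:
                break
            hits.append((rec.id, pos))
            start = pos + 1
    return sorted(hits)


@pytest.fixture
def toy_refset() -> ReferenceSet:
    """Three matures, one hairpin with arms, two snoRNAs; hand-built."""
    sno1 = (
        "TGCATGCAAGTCCTAGGATCGTACGTACGGTACCAGTTGACCTAGGCATCAGTTACGGA"
        "TCCGATCGGATACCGTTAGCATGCGTATTGACG"
    )
    sno2 = (
        "GGATTCTAGCCGGATTCAGCATGGCATCGATCCAGTTCAGGATCCGGTTAACGGATGCA"
        "TGGCCATTAGGACCTTAGGCATTAGCC"
    )
    hp = "ACGGTTCAGCATGGACTTCAGATTACCGGATGCTAGCTTACCAGGTTCAGCATGACTTGACAT"
    rs = ReferenceSet(
        [
            PrecursorRecord("mir-a", Biotype.MIRNA_MATURE, "TAGCTTATCAGACTGATGTTGA"),
            PrecursorRecord("mir-b", Biotype.MIRNA_MATURE, "TGAGGTAGTAGGTTGTATAGTT"),
            PrecursorRecord("mir-c", Biotype.MIRNA_MATURE, "ACTGGACTTGGAGTCAGAAGGC"),
            PrecursorRecord(
                "hairpin-1",
                Biotype.MIRNA_HAIRPIN,
                hp,
                mature_annotations=(
                    MatureArm("hairpin-1-5p", 0, 22),
                    MatureArm("hairpin-1-3p", 41, 63),
                ),
            ),
            PrecursorRecord("SNORD18", Biotype.SNORNA, sno1),
            PrecursorRecord("SNORA31", Biotype.SNORNA, sno2),
        ]
    )
    rs.build_index()
    return rs


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small but complete simulated study (reference + WT/KO libraries)."""
    out = tmp_path_factory.mktemp("sim")
    config = SimConfig(seed=7, n_mirna=30, n_snorna=15, reads_per_library=20_000)
    refset, result = simulate(config, out)
    return refset, result, config
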