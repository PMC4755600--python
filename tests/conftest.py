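"""Shared fixtures: published MT sequences and synthetic defaults."""

import pytest

from modmt.records import ProteinRecord

#: MT sequences of the classic fungal families, as published (one per
#: family); the Neurospora crassa MT is the 26-residue paradigm whose
#: 7-Cys arrangement defines the tandem building block.
FUNGAL_MT_SEQUENCES = {
    "Ncrassa_MT": "MGDCGCSGASSCNCGSGCSCSNCGSK",
    "Cglabrata_MT1": "MANDCKCPNGCSCPNCANGGCQCGDKCECKKQSCHGCGEQCKCGSHGSSCHGSCGCGDKCECK",
    "Cglabrata_MT2": "MPEQVNCQYDCHCSNCACENTCNCCAKPACACTNSASNECSCQTCKCQTCKC",
    "Ylipolytica_MT3": "MEFTTAMLGASLISTTSTQSKHNLVNNCCCSSSTSESSMPASCACTKCGCKTCKC",
    "Scerevisiae_Cup1": "MFSELINFQNEGHECQCQCGSCKNNEQCQKSCSCPTGCNSDDKCPCGNKSEETKKSCCSGK",
    "Scerevisiae_Crs5": "MTVKICDCEGECCKDSCHCGSTCLPSCSGGEKCKCDHSTGSPQCKSCGEKCKCETTCTCEKSKCNCEKC",
}


@pytest.fixture(scope="session")
def fungal_mts() -> dict[str, ProteinRecord]:
    return {
        name: ProteinRecord(name, seq, source="in_paper")
        for name, seq in FUNGAL_MT_SEQUENCES.items()
    }


@pytest.fixture(scope="session")
def ncrassa(fungal_mts) -> ProteinRecord:
    return fungal_mts["Ncrassa_MT"]
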