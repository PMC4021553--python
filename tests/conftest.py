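from pathlib import Path

import pytest

from protfeat.scales import AminoAcidScale, builtin_uncorrelated, normalize_scale
from protfeat.seqdata import Labeling, ProteinRecord, ProteinSet

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def aaindex_path() -> Path:
    return DATA_DIR / "aaindex_sample.txt"


@pytest.fixture()
def small_pset() -> ProteinSet:
    """Six handcrafted proteins with ORF, SS and SA auxiliaries."""
    recs = []
    seqs = [
        ("p1", "MKVLAACDEF"),
        ("p2", "GHIKLMNPQR"),
        ("p3", "STVWYACDEG"),
        ("p4", "AAAAAKKKKK"),
        ("p5", "MNPQRSTVWY"),
        ("p6", "CDEFGHIKLM"),
    ]
    # one uniformly chosen codon per residue is enough for feature tests
    codon = {
        "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
        "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
        "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
        "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    }
    for pid, aa in seqs:
        recs.append(ProteinRecord(
            id=pid, aa_seq=aa,
            orf_seq="".join(codon[a] for a in aa),
            ss_seq=("HEC" * len(aa))[:len(aa)],
            sa_seq=("BE" * len(aa))[:len(aa)],
        ))
    lab = Labeling(
        name="toy",
        assignments={"p1": "high", "p2": "low", "p3": "high",
                     "p4": "low", "p5": "high", "p6": "low"},
        class_names=["high", "low"],
    )
    return ProteinSet(records=recs, labelings=[lab])


@pytest.fixture(scope="session")
def kd_scale() -> AminoAcidScale:
    """Normalized Kyte-Doolittle hydropathy scale from the built-in set."""
    return normalize_scale(builtin_uncorrelated().get("KYTJ820101"))
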