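"""Residue and codon alphabets shared across the package.

All feature code indexes the strict 20-letter amino-acid alphabet in
alphabetical order; ambiguity codes are rejected at load time.
"""

from itertools import product

#: The 20 standard amino acids, alphabetically ordered.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard one-letter codes rejected on input.
AA_AMBIGUOUS = set("BJOUXZ")

#: Nucleotides allowed in ORF sequences.
NUC4 = "ACGT"

#: Secondary-structure states: helix, strand, coil.
SS3 = "HEC"

#: Solvent-accessibility states: buried, exposed.
SA2 = "BE"

#: The 64 codons in alphabetical order.
CODONS64 = tuple("".join(c) for c in product(NUC4, repeat=3))

# Standard genetic code; '*' marks stop codons, which form their own
# synonymous family for codon-usage purposes.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: codons grouped by encoded amino acid (stop = '*').
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
SYNONYMOUS_FAMILIES = {
    aa: tuple(sorted(c for c, a in GENETIC_CODE.items() if a == aa))
    for aa in SYNONYMOUS_FAMILIES
}


def validate_sequence(seq: str, kind: str, seq_id: str = "?") -> None:
    """Check ``seq`` against the alphabet for ``kind``.

    ``kind`` is one of ``protein``, ``orf``, ``ss``, ``sa``.  Raises
    :class:`ValueError` naming the offending character and its 1-based
    position.
    """
    alphabets = {"protein": set(AA20), "orf": set(NUC4), "ss": set(SS3), "sa": set(SA2)}
    try:
        allowed = alphabets[kind]
    except KeyError:
        raise ValueError(f"unknown sequence kind: {kind!r}")
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            extra = ""
            if kind == "protein" and ch in AA_AMBIGUOUS:
                extra = " (ambiguous amino-acid codes are not supported)"
            raise ValueError(
                f"illegal character {ch!r} at position {pos} "
                f"in {kind} sequence of {seq_id!r}{extra}"
            )
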