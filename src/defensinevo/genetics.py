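"""Standard nuclear genetic code and small codon utilities.

The code table is owned by the package (rather than delegated to a sequence
library) because the Nei–Gojobori machinery enumerates single-base codon
neighbours and substitution pathways directly against it, and because
translation here maps any ambiguity code (including the '?' placeholders that
SNP-bearing genome translations produce) to 'X' rather than raising.
"""

from __future__ import annotations

BASES = "ACGT"

GENETIC_CODE: dict[str, str] = {
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

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))

#: IUPAC nucleotide symbols accepted in coding input (plus '-' gaps and '?').
IUPAC_DNA = frozenset("ACGTURYSWKMBDHVN")
GAP_CHARS = frozenset("-")

# Most-used human codon per amino acid; used for deterministic
# back-translation of template proteins in the synthetic generator.
PREFERRED_CODON: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_unambiguous(codon: str) -> bool:
    """True for a gap-free codon made only of A/C/G/T."""
    return len(codon) == 3 and all(b in BASES for b in codon)


def translate_codon(codon: str) -> str:
    """Translate one codon; ambiguity codes, '?' or gaps yield 'X'.

    A codon that is entirely gaps yields '-' so alignment columns survive
    translation.
    """
    codon = codon.upper().replace("U", "T")
    if codon in GENETIC_CODE:
        return GENETIC_CODE[codon]
    if all(b in GAP_CHARS for b in codon):
        return "-"
    return "X"


def translate(seq: str) -> str:
    """Translate an in-frame DNA string codon by codon (stops become '*')."""
    seq = seq.upper().replace("U", "T")
    n = len(seq) // 3
    return "".join(translate_codon(seq[3 * i : 3 * i + 3]) for i in range(n))


def codon_neighbors(codon: str):
    """Yield the 9 single-base mutants of a codon."""
    for pos in range(3):
        for base in BASES:
            if base != codon[pos]:
                yield pos, codon[:pos] + base + codon[pos + 1 :]


def validate_dna(seq: str, *, allow_gaps: bool = True) -> str:
    """Uppercase and check a DNA string; raise ValueError on empty/invalid."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper().replace("U", "T")
    allowed = IUPAC_DNA | (GAP_CHARS if allow_gaps else frozenset()) | {"?"}
    bad = sorted(set(seq) - allowed)
    if bad:
        raise ValueError(f"non-IUPAC symbol(s) in sequence: {''.join(bad)}")
    return seq
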