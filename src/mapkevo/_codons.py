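"""Standard genetic code tables and small codon helpers shared across modules."""

from __future__ import annotations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, '*' for stop, standard genetic code
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(_standard.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS

def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon]


def is_transition(a: str, b: str) -> bool:
    """True if the single-base change a->b is a transition (purine<->purine or
    pyrimidine<->pyrimidine)."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def codon_neighbors(codon: str, position: int) -> list[str]:
    """All 3 single-base variants of ``codon`` at ``position`` (0-based)."""
    out = []
    for base in NUCLEOTIDES:
        if base != codon[position]:
            out.append(codon[:position] + base + codon[position + 1 :])
    return out


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in NUCLEOTIDES for b in codon)
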