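"""Standard genetic code helpers shared by the generator, search and Ka/Ks code."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: codon -> single-letter amino acid, with '*' for the three stops
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TABLE[_stop] = "*"

#: amino acid -> tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)


def translate_codon(codon: str) -> str:
    """Amino acid for one codon; 'X' when the codon contains a non-ACGT base."""
    return CODON_TABLE.get(codon, "X")


def translate_cds(cds: str, trim_stop: bool = True) -> str:
    """Frame-0 translation of a CDS; trailing '*' removed when trim_stop."""
    aa = "".join(translate_codon(cds[i:i + 3]) for i in range(0, len(cds) - 2, 3))
    if trim_stop and aa.endswith("*"):
        aa = aa[:-1]
    return aa


def codon_neighbors(codon: str) -> list[str]:
    """All nine single-nucleotide neighbors of a codon."""
    out = []
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                out.append(codon[:pos] + b + codon[pos + 1:])
    return out


def synonymous_neighbors(codon: str) -> list[str]:
    aa = CODON_TABLE[codon]
    return [c for c in codon_neighbors(codon) if CODON_TABLE[c] == aa]


def nonsynonymous_neighbors(codon: str, allow_stop: bool = False) -> list[str]:
    """Single-nt neighbors coding a different amino acid (stops excluded by default)."""
    aa = CODON_TABLE[codon]
    out = []
    for c in codon_neighbors(codon):
        caa = CODON_TABLE[c]
        if caa != aa and (allow_stop or caa != "*"):
            out.append(c)
    return out
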