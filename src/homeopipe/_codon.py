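"""Standard genetic-code lookups shared by the simulator and molevol.

Tables are derived once from Biopython's standard (NCBI table 1) codon table.
"""
from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid, with '*' for stop codons
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: the 61 sense codons of the standard code
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def translate_codon(codon: str) -> str:
    """Amino acid for one codon ('*' for stop). Raises KeyError on ambiguity."""
    return CODON_TO_AA[codon]


@lru_cache(maxsize=None)
def syn_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position fraction of the three possible single-base changes that are
    synonymous, for a sense codon.

    Changes that create a stop codon count as nonsynonymous, following the
    usual NG86 site-counting convention.
    """
    aa = CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TO_AA[alt] == aa:
                syn += 1
        out.append(syn / 3.0)
    return tuple(out)


def codon_syn_sites(codon: str) -> float:
    """NG86 synonymous site count s for one codon (n = 3 − s)."""
    return sum(syn_fractions(codon))
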