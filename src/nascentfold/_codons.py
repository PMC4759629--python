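"""Codon alphabet helpers shared across modules.

All codons are normalized internally to the RNA alphabet (ACGU); DNA input
(ACGT) is accepted everywhere and converted on entry.
"""
from __future__ import annotations

import itertools

from Bio.Data.CodonTable import unambiguous_rna_by_id

_STANDARD_TABLE = unambiguous_rna_by_id[1]

RNA_BASES = "ACGU"
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(RNA_BASES, repeat=3)
)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STOP_CODONS
)

#: codon -> one-letter amino acid, standard genetic code, sense codons only
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)

#: amino acid -> sorted tuple of synonymous codons
SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMS.setdefault(_aa, ())
    SYNONYMS[_aa] = SYNONYMS[_aa] + (_codon,)


class AlphabetError(ValueError):
    """A sequence or codon contains characters outside ACGT/ACGU."""


class CodingFrameError(ValueError):
    """A CDS whose length is not a multiple of three."""


def normalize_codon(codon: str) -> str:
    """Normalize a 3-letter codon to the upper-case RNA alphabet."""
    c = codon.strip().upper().replace("T", "U")
    if len(c) != 3 or any(b not in RNA_BASES for b in c):
        raise AlphabetError(f"invalid codon {codon!r}")
    return c


def split_codons(cds: str) -> list[str]:
    """Split a CDS into normalized RNA codons, validating frame and alphabet."""
    seq = "".join(cds.split()).upper().replace("T", "U")
    if len(seq) % 3 != 0:
        raise CodingFrameError(
            f"CDS length {len(seq)} is not a multiple of 3"
        )
    if len(seq) == 0:
        raise CodingFrameError("empty CDS")
    bad = set(seq) - set(RNA_BASES)
    if bad:
        raise AlphabetError(f"invalid characters in CDS: {sorted(bad)}")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def translate(cds: str) -> str:
    """Translate a CDS (standard code) up to but excluding the first stop."""
    aas = []
    for codon in split_codons(cds):
        if codon in STOP_CODONS:
            break
        aas.append(CODON_TO_AA[codon])
    return "".join(aas)
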