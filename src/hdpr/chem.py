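"""In-silico tryptic digestion and monoisotopic peptide masses at arbitrary 13C levels.

Peptide masses are computed by element counting: the monoisotopic mass of the
intact (neutral) peptide is the sum of its atoms' monoisotopic masses, and a
partial 13C incorporation of ``p`` atom percent adds ``p/100 * C * 1.003355`` Da,
where ``C`` is the peptide's carbon count and 1.003355 Da is the 13C-12C mass
difference. Computing masses this way makes any incorporation level a linear
function of the 0 % mass, which is what the downstream slope calibration relies
on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: Monoisotopic atomic masses (Da) of the light isotopes used throughout.
ELEMENT_MASSES = {
    "C": 12.000000,
    "H": 1.007825,
    "N": 14.003074,
    "O": 15.994915,
    "S": 31.972071,
}

#: Nominal (integer) masses of the same isotopes, used for exact band offsets.
NOMINAL_MASSES = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32}

#: Mass added per carbon atom when 12C is replaced by 13C (Da).
C13_MASS_SHIFT = 1.003355

#: Monoisotopic residue compositions (C, H, N, O, S) of the 20 canonical
#: amino acids, i.e. the amino acid minus one water.
RESIDUE_FORMULAS = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

WATER = (0, 2, 0, 1, 0)  # H2O added once per intact peptide

_TRYPSIN_SITE = re.compile(r"(?<=[KR])(?!P)")


class EmptyReferenceError(ValueError):
    """No peptide survived the reference filters."""


@dataclass(frozen=True)
class ElementCounts:
    """Atom inventory of an intact peptide (one water included)."""

    C: int
    H: int
    N: int
    O: int
    S: int = 0

    def __post_init__(self) -> None:
        for name in ("C", "H", "N", "O", "S"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} count")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.C, self.H, self.N, self.O, self.S)


@dataclass(frozen=True)
class PeptideRecord:
    """A tryptic peptide with its composition and light (0 atom % 13C) mass."""

    sequence: str
    elements: ElementCounts
    mass_light: float

    @property
    def length(self) -> int:
        return len(self.sequence)

    def mass_at(self, incorporation: float) -> float:
        """Monoisotopic mass (Da) at ``incorporation`` atom % 13C."""
        if not 0.0 <= incorporation <= 100.0:
            raise ValueError("incorporation must be within [0, 100] atom %")
        return self.mass_light + incorporation / 100.0 * self.elements.C * C13_MASS_SHIFT


def tryptic_digest(protein_sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Digest a protein with the trypsin rule: cleave after K or R, not before P.

    With ``missed_cleavages = 0`` the returned peptides partition the input
    (their concatenation reproduces it, in order). Higher values additionally
    return the joins of up to that many adjacent fragments.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if not protein_sequence:
        return []
    fragments = [f for f in _TRYPSIN_SITE.split(protein_sequence) if f]
    if missed_cleavages == 0:
        return fragments
    peptides = list(fragments)
    for mc in range(1, missed_cleavages + 1):
        for i in range(len(fragments) - mc):
            peptides.append("".join(fragments[i : i + mc + 1]))
    return peptides


def residue_composition(sequence: str) -> ElementCounts:
    """Element counts of the intact peptide: residue formulas plus one water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    c, h, n, o, s = WATER
    for ch in sequence:
        try:
            rc, rh, rn, ro, rs = RESIDUE_FORMULAS[ch]
        except KeyError:
            raise ValueError(f"unknown residue code {ch!r} in sequence") from None
        c += rc
        h += rh
        n += rn
        o += ro
        s += rs
    return ElementCounts(C=c, H=h, N=n, O=o, S=s)


def monoisotopic_mass(elements: ElementCounts, incorporation: float = 0.0) -> float:
    """Monoisotopic mass in Da at a given atom % 13C incorporation.

    mass = 12.000000*C + 1.007825*H + 14.003074*N + 15.994915*O + 31.972071*S
           + (incorporation/100) * C * 1.003355
    """
    if not 0.0 <= incorporation <= 100.0:
        raise ValueError("incorporation must be within [0, 100] atom %")
    c, h, n, o, s = elements.as_tuple()
    mass = (
        ELEMENT_MASSES["C"] * c
        + ELEMENT_MASSES["H"] * h
        + ELEMENT_MASSES["N"] * n
        + ELEMENT_MASSES["O"] * o
        + ELEMENT_MASSES["S"] * s
    )
    return mass + incorporation / 100.0 * c * C13_MASS_SHIFT


def nominal_mass(elements: ElementCounts, incorporation: float = 0.0) -> float:
    """Integer-isotope mass; at 100 % 13C each carbon weighs a nominal 13."""
    c, h, n, o, s = elements.as_tuple()
    base = 12 * c + 1 * h + 14 * n + 16 * o + 32 * s
    return base + incorporation / 100.0 * c


def peptide_record(sequence: str) -> PeptideRecord:
    elements = residue_composition(sequence)
    return PeptideRecord(sequence, elements, monoisotopic_mass(elements, 0.0))


def _iter_fasta(source) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs from a FASTA path, handle, or record iterable."""
    from Bio import SeqIO

    if isinstance(source, (str, Path)):
        with open(source) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                yield rec.id, str(rec.seq)
        return
    for rec in source:
        if isinstance(rec, tuple):
            yield rec
        else:  # Bio.SeqRecord
            yield rec.id, str(rec.seq)


def build_reference_peptides(
    fasta_records,
    mz_min: float = 300.0,
    mz_max: float = 6000.0,
    len_min: int = 2,
    len_max: int = 40,
    missed_cleavages: int = 0,
) -> list[PeptideRecord]:
    """Digest every protein and keep peptides passing the length and mass window.

    The mass filter applies to the light (0 atom %) mass, mirroring a reference
    built from an unlabeled proteome. Duplicate peptide sequences arising from
    different proteins are kept as separate entries. Proteins containing
    non-canonical residue codes are skipped with a warning; ``*`` stop
    characters are stripped.
    """
    kept: list[PeptideRecord] = []
    n_proteins = 0
    for name, seq in _iter_fasta(fasta_records):
        n_proteins += 1
        if "*" in seq:
            logger.warning("stripping '*' stop character(s) from %s", name)
            seq = seq.replace("*", "")
        seq = seq.upper()
        bad = set(seq) - set(RESIDUE_FORMULAS)
        if bad:
            logger.warning(
                "skipping protein %s: non-canonical residue(s) %s",
                name,
                "".join(sorted(bad)),
            )
            continue
        for pep in tryptic_digest(seq, missed_cleavages=missed_cleavages):
            if not len_min <= len(pep) <= len_max:
                continue
            elements = residue_composition(pep)
            mass = monoisotopic_mass(elements, 0.0)
            if mz_min <= mass <= mz_max:
                kept.append(PeptideRecord(pep, elements, mass))
    if n_proteins == 0:
        raise EmptyReferenceError("no parseable FASTA record in input")
    if not kept:
        raise EmptyReferenceError(
            "empty reference: no peptide passed the length/mass filters"
        )
    logger.info("reference: %d peptide entries from %d proteins", len(kept), n_proteins)
    return kept
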