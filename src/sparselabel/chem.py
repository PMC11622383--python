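"""Peptide chemistry: compositions, sparse-label injection, digestion, m/z.

Sparse labels are carried as pseudo-elements (``C13label``, ``N15label``)
inside an :class:`ElementalComposition`: injecting a label moves one atom
from the natural-abundance element into the corresponding single-isotope
pseudo-element, so the total atom count is conserved and every downstream
pattern simulation sees the label as its own 100%-abundance element.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

from sparselabel import data

__all__ = [
    "IsotopeTable",
    "ElementalComposition",
    "Peptide",
    "peptide_composition",
    "apply_labels",
    "digest",
    "monoisotopic_mass",
    "mz",
    "read_fasta",
]

_LABEL_PSEUDO = {"C": "C13label", "N": "N15label"}


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element isotope masses and abundances.

    ``entries`` maps an element symbol to an ordered list of
    ``(mass_da, abundance_fraction)`` pairs, ascending in mass.
    Pseudo-elements used for enforced labels have exactly one isotope
    at abundance 1.
    """

    entries: Mapping[str, list[tuple[float, float]]] = field(
        default_factory=lambda: dict(data.ISOTOPES)
    )

    def __post_init__(self) -> None:
        for element, isotopes in self.entries.items():
            if not isotopes:
                raise ValueError(f"element {element!r} has no isotopes")
            masses = [m for m, _ in isotopes]
            abundances = [a for _, a in isotopes]
            if any(m <= 0 for m in masses):
                raise ValueError(f"element {element!r} has a non-positive mass")
            if masses != sorted(masses) or len(set(masses)) != len(masses):
                raise ValueError(
                    f"element {element!r}: isotope masses must be strictly ascending"
                )
            if abs(sum(abundances) - 1.0) > 1e-6:
                raise ValueError(
                    f"element {element!r}: abundances sum to {sum(abundances)!r}, not 1"
                )

    def monoisotopic(self, element: str) -> float:
        """Mass of the lightest isotope of *element*."""
        return self.entries[element][0][0]

    def __contains__(self, element: str) -> bool:
        return element in self.entries


#: module-level default table (IUPAC 2013 values, see :mod:`sparselabel.data`)
DEFAULT_TABLE = IsotopeTable()


@dataclass(frozen=True)
class ElementalComposition:
    """Nonnegative integer atom counts per element, incl. pseudo-elements."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for element, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for element {element!r}: {n}")
            if element not in DEFAULT_TABLE:
                raise ValueError(f"unknown element {element!r}")
            if n > 0:
                clean[element] = int(n)
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalComposition(merged)

    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def formula(self) -> str:
        """Hill-ish formula string, pseudo-elements last."""
        order = ["C", "H", "N", "O", "S", "C13label", "N15label"]
        parts = []
        for element in order:
            n = self[element]
            if n:
                parts.append(f"{element}{n}" if n > 1 else element)
        return "".join(parts)


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with fixed H-/-OH termini."""

    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for i, letter in enumerate(self.sequence):
            if letter not in data.RESIDUE_FORMULAS:
                raise ValueError(
                    f"unknown residue {letter!r} at position {i + 1} "
                    f"in {self.sequence!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def peptide_composition(
    peptide: Peptide | str,
    fixed_modifications: Mapping[str, Mapping[str, int]] | None = None,
) -> ElementalComposition:
    """Elemental composition of a peptide: residue formulas plus one water.

    Parameters
    ----------
    peptide:
        Sequence over the 20 one-letter codes.
    fixed_modifications:
        Optional map residue letter -> extra formula added per occurrence
        (e.g. carbamidomethyl-Cys ``{"C": {"C": 2, "H": 3, "N": 1, "O": 1}}``).
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    counts: dict[str, int] = {"H": 2, "O": 1}  # terminal water
    for letter in peptide.sequence:
        for element, n in data.RESIDUE_FORMULAS[letter].items():
            counts[element] = counts.get(element, 0) + n
        if fixed_modifications and letter in fixed_modifications:
            for element, n in fixed_modifications[letter].items():
                counts[element] = counts.get(element, 0) + n
    return ElementalComposition(counts)


def apply_labels(
    comp: ElementalComposition, n13C: int = 0, n15N: int = 0
) -> ElementalComposition:
    """Move *n13C* carbons and *n15N* nitrogens into enforced-label slots.

    Atom totals are conserved: ``C + C13label`` and ``N + N15label`` are
    unchanged.  The monoisotopic mass increases by exactly
    ``n13C * 1.0033548 + n15N * 0.9970349`` Da.
    """
    if n13C < 0 or n15N < 0:
        raise ValueError("label counts must be nonnegative")
    counts = dict(comp.counts)
    for element, n in (("C", n13C), ("N", n15N)):
        if n == 0:
            continue
        available = counts.get(element, 0)
        if n > available:
            raise ValueError(
                f"cannot place {n} labels on {element}: only {available} "
                f"{element} atoms available"
            )
        counts[element] = available - n
        pseudo = _LABEL_PSEUDO[element]
        counts[pseudo] = counts.get(pseudo, 0) + n
    return ElementalComposition(counts)


def monoisotopic_mass(
    comp: ElementalComposition, table: IsotopeTable = DEFAULT_TABLE
) -> float:
    """Sum of lightest-isotope masses (pseudo-elements count as their label)."""
    return sum(n * table.monoisotopic(el) for el, n in comp.counts.items())


def mz(
    comp: ElementalComposition | float, charge: int, table: IsotopeTable = DEFAULT_TABLE
) -> float:
    """m/z of a composition (or neutral mass) under the protonation convention."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    mass = comp if isinstance(comp, (int, float)) else monoisotopic_mass(comp, table)
    return (mass + charge * data.PROTON_MASS) / charge


def _cleavage_sites(sequence: str) -> list[int]:
    """Indices after which trypsin cuts (C-terminal to K/R, not before P)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: str, enzyme: str = "trypsin", missed_cleavages: int = 0
) -> list[Peptide]:
    """Enzymatic digest of a protein sequence.

    Only the trypsin rule is implemented: cleave C-terminal to K/R except
    before P.  Peptides with up to *missed_cleavages* internal sites are
    included, in order of appearance (all forms starting at one position
    are emitted shortest-first).
    """
    if enzyme != "trypsin":
        raise ValueError(f"unsupported enzyme {enzyme!r}")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    Peptide(protein)  # alphabet validation
    bounds = [0, *_cleavage_sites(protein), len(protein)]
    pieces = [protein[a:b] for a, b in zip(bounds, bounds[1:])]
    peptides: list[Peptide] = []
    for start in range(len(pieces)):
        for extra in range(missed_cleavages + 1):
            stop = start + extra + 1
            if stop > len(pieces):
                break
            peptides.append(Peptide("".join(pieces[start:stop])))
    return peptides


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {header: sequence} map."""
    records: dict[str, str] = {}
    header: str | None = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records[header] = "".join(chunks)
                header = line[1:].split()[0] if line[1:] else f"seq{len(records) + 1}"
                chunks = []
            else:
                if header is None:
                    raise ValueError("FASTA file does not start with a header line")
                chunks.append(re.sub(r"[\s*]", "", line.upper()))
    if header is not None:
        records[header] = "".join(chunks)
    return records


def iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    yield from read_fasta(path).items()
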