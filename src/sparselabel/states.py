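"""Labeling schemes and enumeration of intermediate labeling states.

A :class:`LabelScheme` gives, per amino acid, the number of enforced 15N
and 13C labels and how they partition into independently omittable units
(metabolic scrambling can strip a unit as a block: e.g. the alpha-amino
15N of Val can be lost on its own, while its five 13C come and go
together).  :func:`enumerate_states` walks every include/omit combination
of the units across a peptide's labeled residues and collects the
distinct (total 15N, total 13C) pairs: positional isomers are isobaric
and indistinguishable in MS1, so states are identified by totals only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from sparselabel.chem import Peptide

__all__ = [
    "LabelScheme",
    "LabelingState",
    "StateSet",
    "enumerate_states",
    "find_collisions",
    "load_scheme",
]


@dataclass(frozen=True)
class ResidueRule:
    """Label content of one amino acid: counts and omittable units.

    ``units`` lists block sizes; each block can be independently omitted.
    Blocks are assigned to 15N first, then 13C, in order; a block may
    straddle both (a jointly-removed [15N,13Cn] unit).
    """

    n15N: int
    n13C: int
    units: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n15N < 0 or self.n13C < 0:
            raise ValueError("label counts must be nonnegative")
        if sum(self.units) != self.n15N + self.n13C:
            raise ValueError(
                f"unit sizes {list(self.units)} must sum to n15N + n13C "
                f"= {self.n15N + self.n13C}"
            )

    def unit_contributions(self) -> list[tuple[int, int]]:
        """Per-unit (15N, 13C) contribution, allocating 15N before 13C."""
        out = []
        remaining_n = self.n15N
        for size in self.units:
            d_n = min(size, remaining_n)
            remaining_n -= d_n
            out.append((d_n, size - d_n))
        return out


@dataclass(frozen=True)
class LabelScheme:
    """Map residue letter -> :class:`ResidueRule`."""

    rules: dict[str, ResidueRule]

    @classmethod
    def from_dict(cls, raw: dict) -> "LabelScheme":
        """Build from plain-dict config, e.g.
        ``{"V": {"n15N": 1, "n13C": 5, "units": [1, 5]}}``."""
        rules = {}
        for letter, entry in raw.items():
            n15N = int(entry.get("n15N", 0))
            n13C = int(entry.get("n13C", 0))
            units = entry.get("units")
            if units is None:
                units = ([1] * n15N) + ([n13C] if n13C else [])
            rules[letter] = ResidueRule(n15N, n13C, tuple(int(u) for u in units))
        return cls(rules)

    def peptide_maxima(self, peptide: Peptide | str) -> tuple[int, int]:
        """Total (15N, 13C) of the fully labeled peptide."""
        seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
        n = sum(self.rules[aa].n15N for aa in seq if aa in self.rules)
        c = sum(self.rules[aa].n13C for aa in seq if aa in self.rules)
        return n, c

    def peptide_units(self, peptide: Peptide | str) -> list[tuple[int, int]]:
        """All omittable units across the peptide, as (15N, 13C) pairs."""
        seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
        units: list[tuple[int, int]] = []
        for aa in seq:
            if aa in self.rules:
                units.extend(self.rules[aa].unit_contributions())
        return units


@dataclass(frozen=True)
class LabelingState:
    """One labeling state: totals of added 15N and 13C."""

    n15N: int
    n13C: int
    extra: bool = False  # user-added beyond the scheme's reachable set

    def __post_init__(self) -> None:
        if self.n15N < 0 or self.n13C < 0:
            raise ValueError("label counts must be nonnegative")

    @property
    def neutron_count(self) -> int:
        return self.n15N + self.n13C

    @property
    def descriptor(self) -> str:
        if self.n15N == 0 and self.n13C == 0:
            return "unlabeled"
        parts = []
        if self.n15N:
            parts.append(f"15N{self.n15N if self.n15N > 1 else ''}")
        if self.n13C:
            parts.append(f"13C{self.n13C if self.n13C > 1 else ''}")
        return "[" + ", ".join(parts) + "]"

    def key(self) -> tuple[int, int]:
        return (self.n15N, self.n13C)


def neutron_count(state: LabelingState) -> int:
    """Total added heavy labels (added neutrons) of a state."""
    return state.neutron_count


@dataclass(frozen=True)
class StateSet:
    """Ordered collection of distinct labeling states.

    Sorted by neutron count ascending; ties keep insertion order (the
    enumeration inserts higher-15N states first, so at equal neutron
    count the lower-mass state comes first).
    """

    states: tuple[LabelingState, ...]

    def __post_init__(self) -> None:
        keys = [s.key() for s in self.states]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate labeling states")
        if (0, 0) not in keys:
            raise ValueError("state set must contain the unlabeled state")
        counts = [s.neutron_count for s in self.states]
        if counts != sorted(counts):
            raise ValueError("states must be ordered by neutron count")

    def __iter__(self):
        return iter(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i: int) -> LabelingState:
        return self.states[i]

    @property
    def max_neutrons(self) -> int:
        return self.states[-1].neutron_count


def enumerate_states(
    peptide: Peptide | str,
    scheme: LabelScheme,
    extras: list[LabelingState] | None = None,
) -> StateSet:
    """All labeling states reachable by include/omit choices of the
    scheme's units on *peptide*, plus optional user-declared extras.

    Extras duplicating a reachable (15N, 13C) pair are silently merged.
    """
    reachable: set[tuple[int, int]] = {(0, 0)}
    for d_n, d_c in scheme.peptide_units(peptide):
        reachable |= {(n + d_n, c + d_c) for n, c in reachable}
    pairs = {(n, c): False for n, c in reachable}
    for extra in extras or []:
        pairs.setdefault(extra.key(), True)
    ordered = sorted(pairs, key=lambda p: (p[0] + p[1], -p[0]))
    return StateSet(
        tuple(LabelingState(n, c, extra=pairs[(n, c)]) for n, c in ordered)
    )


def find_collisions(states: StateSet) -> list[list[LabelingState]]:
    """Groups of >= 2 states sharing a neutron count.

    Within a group, states are ordered by 15N descending: more 15N means
    a lower mass defect, hence lower exact mass at the same neutron count.
    """
    by_count: dict[int, list[LabelingState]] = {}
    for state in states:
        by_count.setdefault(state.neutron_count, []).append(state)
    groups = []
    for count in sorted(by_count):
        group = by_count[count]
        if len(group) >= 2:
            groups.append(sorted(group, key=lambda s: -s.n15N))
    return groups


def load_scheme(path: str | Path) -> tuple[LabelScheme, list[LabelingState]]:
    """Load a JSON scheme file; returns (scheme, extras).

    Format::

        {"V": {"n15N": 1, "n13C": 5, "units": [1, 5]},
         "L": {"n15N": 1, "n13C": 0, "units": [1]},
         "extras": [{"n15N": 2, "n13C": 5}]}
    """
    with open(path) as handle:
        raw = json.load(handle)
    extras = [
        LabelingState(int(e.get("n15N", 0)), int(e.get("n13C", 0)), extra=True)
        for e in raw.pop("extras", [])
    ]
    return LabelScheme.from_dict(raw), extras
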