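"""Label-aware peptide mass fingerprinting and B/Y fragment matching.

The PMF search checks each peptide's unlabeled and fully labeled
monoisotopic m/z (per charge) against a centroid masslist.  The fragment
tools generate every B and Y ion at all charges up to the precursor's,
carrying the label content of the residues each fragment spans, and match
them to a masslist within a ppm tolerance (CID only; B/Y series).

Fragment chemistry (standard b/y definitions, protonation convention):
``b_i = (sum of first i residue masses + z * proton) / z`` and
``y_i = (sum of last i residue masses + water + z * proton) / z``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from sparselabel import data
from sparselabel.chem import (
    ElementalComposition,
    Peptide,
    apply_labels,
    monoisotopic_mass,
    peptide_composition,
)
from sparselabel.states import LabelScheme

__all__ = [
    "PmfMatch",
    "FragmentIon",
    "pmf_search",
    "generate_fragments",
    "match_fragments",
    "read_asc",
    "read_xy",
]


@dataclass(frozen=True)
class PmfMatch:
    peptide: str
    state: str  # "unlabeled" | "labeled"
    charge: int
    theoretical_mz: float
    observed_mz: float
    error_ppm: float


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "B" | "Y"
    index: int
    charge: int
    sequence: str
    composition: ElementalComposition
    n15N: int
    n13C: int
    mz: float

    @property
    def name(self) -> str:
        label = f"+[15N{self.n15N},13C{self.n13C}]" if self.n15N or self.n13C else ""
        return f"{self.series}{self.index}^{self.charge}+{label}"


def read_asc(path: str | Path) -> np.ndarray:
    """Read a centroid masslist: whitespace/comma-separated ``m/z [intensity]``
    lines; ``#`` and ``;`` comment lines ignored.  Returns an (n, 2) array
    (intensity 0 where absent)."""
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.split("#")[0].split(";")[0].strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            mz_value = float(fields[0])
            intensity = float(fields[1]) if len(fields) > 1 else 0.0
            rows.append((mz_value, intensity))
    return np.array(rows).reshape(-1, 2)


def read_xy(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column full-profile spectrum; returns (mz, intensity)."""
    arr = np.loadtxt(path)
    return arr[:, 0], arr[:, 1]


def _mz_of(comp: ElementalComposition, charge: int) -> float:
    return (monoisotopic_mass(comp) + charge * data.PROTON_MASS) / charge


def pmf_search(
    masslist: np.ndarray,
    peptides: list[Peptide | str],
    scheme: LabelScheme,
    tol_ppm: float = 5.0,
    charges: list[int] | None = None,
) -> pd.DataFrame:
    """Search a masslist for the unlabeled and fully labeled monoisotopic
    m/z of each peptide.

    Returns a DataFrame with one row per match (peptide, state, charge,
    theoretical and observed m/z, signed ppm error).  Peptides without
    labeled residues are searched only as unlabeled.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    charges = charges or [1]
    masslist = np.asarray(masslist, dtype=float).reshape(-1, 2)
    if len(masslist) == 0:
        warnings.warn("empty masslist; no matches possible", stacklevel=2)
    observed = masslist[:, 0] if len(masslist) else np.empty(0)
    matches: list[PmfMatch] = []
    for pep in peptides:
        pep = pep if isinstance(pep, Peptide) else Peptide(pep)
        comp = peptide_composition(pep)
        max_n, max_c = scheme.peptide_maxima(pep)
        variants = [("unlabeled", comp)]
        if max_n or max_c:
            variants.append(("labeled", apply_labels(comp, n13C=max_c, n15N=max_n)))
        for state, variant in variants:
            for z in charges:
                theo = _mz_of(variant, z)
                if len(observed) == 0:
                    continue
                errs = (observed - theo) / theo * 1e6
                inside = np.flatnonzero(np.abs(errs) <= tol_ppm)
                if len(inside) == 0:
                    continue
                best = inside[np.argmin(np.abs(errs[inside]))]
                matches.append(
                    PmfMatch(
                        peptide=pep.sequence,
                        state=state,
                        charge=z,
                        theoretical_mz=theo,
                        observed_mz=float(observed[best]),
                        error_ppm=float(errs[best]),
                    )
                )
    return pd.DataFrame([m.__dict__ for m in matches],
                        columns=["peptide", "state", "charge", "theoretical_mz",
                                 "observed_mz", "error_ppm"])


def _span_labels(sequence: str, scheme: LabelScheme) -> tuple[int, int]:
    n = sum(scheme.rules[aa].n15N for aa in sequence if aa in scheme.rules)
    c = sum(scheme.rules[aa].n13C for aa in sequence if aa in scheme.rules)
    return n, c


def generate_fragments(
    peptide: Peptide | str,
    scheme: LabelScheme | None = None,
    precursor_charge: int = 1,
) -> list[FragmentIon]:
    """All B and Y fragment ions of *peptide*, charges 1..precursor_charge.

    For each fragment, the unlabeled ion is emitted and, when the spanned
    residues carry labels under *scheme*, the fully labeled ion as well.
    """
    if precursor_charge < 1:
        raise ValueError("precursor_charge must be >= 1")
    pep = peptide if isinstance(peptide, Peptide) else Peptide(peptide)
    seq = pep.sequence
    fragments: list[FragmentIon] = []
    water = {"H": 2, "O": 1}
    for series in ("B", "Y"):
        for index in range(1, len(seq)):
            sub = seq[:index] if series == "B" else seq[-index:]
            counts: dict[str, int] = dict(water) if series == "Y" else {}
            for aa in sub:
                for element, k in data.RESIDUE_FORMULAS[aa].items():
                    counts[element] = counts.get(element, 0) + k
            comp = ElementalComposition(counts)
            label_n, label_c = _span_labels(sub, scheme) if scheme else (0, 0)
            variants = [(comp, 0, 0)]
            if label_n or label_c:
                variants.append(
                    (apply_labels(comp, n13C=label_c, n15N=label_n), label_n, label_c)
                )
            for variant, n15, c13 in variants:
                for z in range(1, precursor_charge + 1):
                    fragments.append(
                        FragmentIon(
                            series=series,
                            index=index,
                            charge=z,
                            sequence=sub,
                            composition=variant,
                            n15N=n15,
                            n13C=c13,
                            mz=_mz_of(variant, z),
                        )
                    )
    return fragments


def match_fragments(
    masslist: np.ndarray,
    fragments: list[FragmentIon],
    tol_ppm: float = 5.0,
) -> pd.DataFrame:
    """Match fragment ions to a centroid masslist within *tol_ppm*.

    One row per (series, index, charge): flags whether the labeled, the
    unlabeled, or both variants matched, with observed m/z and signed ppm
    error per variant (NaN where unmatched) and the inferred label counts.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    masslist = np.asarray(masslist, dtype=float).reshape(-1, 2)
    observed = masslist[:, 0] if len(masslist) else np.empty(0)

    def nearest(theo: float) -> tuple[float, float]:
        if len(observed) == 0:
            return np.nan, np.nan
        errs = (observed - theo) / theo * 1e6
        inside = np.flatnonzero(np.abs(errs) <= tol_ppm)
        if len(inside) == 0:
            return np.nan, np.nan
        best = inside[np.argmin(np.abs(errs[inside]))]
        return float(observed[best]), float(errs[best])

    keys: dict[tuple[str, int, int], dict] = {}
    for frag in fragments:
        key = (frag.series, frag.index, frag.charge)
        row = keys.setdefault(
            key,
            {
                "series": frag.series,
                "index": frag.index,
                "charge": frag.charge,
                "sequence": frag.sequence,
                "n15N": 0,
                "n13C": 0,
                "unlabeled_mz": np.nan,
                "unlabeled_obs": np.nan,
                "unlabeled_ppm": np.nan,
                "labeled_mz": np.nan,
                "labeled_obs": np.nan,
                "labeled_ppm": np.nan,
            },
        )
        kind = "labeled" if (frag.n15N or frag.n13C) else "unlabeled"
        obs_mz, ppm = nearest(frag.mz)
        row[f"{kind}_mz"] = frag.mz
        row[f"{kind}_obs"] = obs_mz
        row[f"{kind}_ppm"] = ppm
        if kind == "labeled":
            row["n15N"] = frag.n15N
            row["n13C"] = frag.n13C

    rows = []
    for row in keys.values():
        matched_unlabeled = not np.isnan(row["unlabeled_ppm"])
        matched_labeled = not np.isnan(row["labeled_ppm"])
        if matched_unlabeled and matched_labeled:
            row["match"] = "both"
        elif matched_labeled:
            row["match"] = "labeled"
        elif matched_unlabeled:
            row["match"] = "unlabeled"
        else:
            row["match"] = "none"
        # inferred labels: present only if the labeled variant was seen
        row["inferred_n15N"] = row["n15N"] if matched_labeled else 0
        row["inferred_n13C"] = row["n13C"] if matched_labeled else 0
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values(["series", "index", "charge"]).reset_index(drop=True)
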