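"""Isotope-pattern computation and Gaussian profile rendering.

Two independent routes produce patterns:

* :func:`simulate_pattern` — per-element convolution with pruning
  (``method="convolution"``, works in nominal-aggregated and
  fine-structure mode) or a fast FFT-convolution route over
  added-neutron number (``method="fft"``, nominal mode only).
* :func:`brute_force_pattern` — exact multinomial enumeration of
  isotopologues, used as a test oracle for small compositions.

Enforced-label pseudo-elements have a single isotope, so they shift every
centroid by a constant mass and leave the abundance vector untouched.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from sparselabel import data
from sparselabel.chem import DEFAULT_TABLE, ElementalComposition, IsotopeTable

__all__ = [
    "IsotopePattern",
    "Profile",
    "simulate_pattern",
    "brute_force_pattern",
    "render_profile",
    "write_xy",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...
_MASS_QUANTUM = 1e-5  # Da; centroid-merge bin width in fine-structure mode


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided isotope pattern of a neutral composition.

    ``masses`` are neutral masses in Da, ascending; ``abundances`` are
    fractions summing to 1; ``neutrons`` is the added-neutron number of
    each centroid relative to the monoisotopic peak.
    """

    masses: np.ndarray
    abundances: np.ndarray
    neutrons: np.ndarray
    mode: str  # "nominal" | "fine"

    def __post_init__(self) -> None:
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(self, "abundances", np.asarray(self.abundances, dtype=float))
        object.__setattr__(self, "neutrons", np.asarray(self.neutrons, dtype=int))
        if np.any(np.diff(self.masses) <= 0):
            raise ValueError("centroid masses must be strictly ascending")
        if np.any(self.abundances < 0):
            raise ValueError("centroid abundances must be nonnegative")

    @property
    def monoisotopic_mass(self) -> float:
        return float(self.masses[0])

    def __len__(self) -> int:
        return len(self.masses)

    def aggregate_nominal(self) -> "IsotopePattern":
        """Collapse fine structure to one abundance-weighted centroid per
        added-neutron number."""
        if self.mode == "nominal":
            return self
        order: dict[int, int] = {}
        probs: list[float] = []
        moments: list[float] = []
        for mass, ab, shift in zip(self.masses, self.abundances, self.neutrons):
            k = int(shift)
            if k not in order:
                order[k] = len(probs)
                probs.append(0.0)
                moments.append(0.0)
            probs[order[k]] += ab
            moments[order[k]] += ab * mass
        shifts = sorted(order)
        idx = [order[k] for k in shifts]
        p = np.array([probs[i] for i in idx])
        m = np.array([moments[i] for i in idx]) / p
        return IsotopePattern(m, p / p.sum(), np.array(shifts), "nominal")

    def scaled(self, factor: float) -> "IsotopePattern":
        out = IsotopePattern.__new__(IsotopePattern)
        object.__setattr__(out, "masses", self.masses)
        object.__setattr__(out, "abundances", self.abundances * factor)
        object.__setattr__(out, "neutrons", self.neutrons)
        object.__setattr__(out, "mode", self.mode)
        return out


@dataclass
class Profile:
    """Continuous rendering of a pattern on a uniform m/z grid."""

    start: float
    spacing: float
    intensity: np.ndarray
    charge: int = 1
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.intensity = np.asarray(self.intensity, dtype=float)

    @property
    def mz(self) -> np.ndarray:
        return self.start + self.spacing * np.arange(len(self.intensity))


# ---------------------------------------------------------------------------
# convolution route


def _single_atom(table: IsotopeTable, element: str) -> list[tuple[int, float, float]]:
    isotopes = table.entries[element]
    m0 = isotopes[0][0]
    return [(int(round(m - m0)), m, a) for m, a in isotopes]


def _convolve(d1, d2, floor):
    """Convolve two {(shift, mass-bin): (prob, prob*mass)} distributions."""
    out: dict[tuple[int, int], list[float]] = {}
    for (s1, _), (p1, pm1) in d1.items():
        m1 = pm1 / p1
        for (s2, _), (p2, pm2) in d2.items():
            p = p1 * p2
            if p < floor:
                continue
            m = m1 + pm2 / p2
            key = (s1 + s2, int(round(m / _MASS_QUANTUM)))
            if key in out:
                acc = out[key]
                acc[0] += p
                acc[1] += p * m
            else:
                out[key] = [p, p * m]
    return out


def _n_atoms(single, n: int, floor):
    """n-fold self-convolution of a single-atom distribution."""
    base = {
        (s, int(round(m / _MASS_QUANTUM))): [a, a * m] for s, m, a in single if a > 0
    }
    result = None
    power = base
    while n:
        if n & 1:
            result = power if result is None else _convolve(result, power, floor)
        n >>= 1
        if n:
            power = _convolve(power, power, floor)
    return result


def _finalize(dist, mode: str, prune: float) -> IsotopePattern:
    shifts = np.array([k[0] for k in dist])
    probs = np.array([v[0] for v in dist.values()])
    masses = np.array([v[1] for v in dist.values()]) / probs
    order = np.argsort(masses, kind="stable")
    pattern = IsotopePattern(
        masses[order], probs[order] / probs.sum(), shifts[order], "fine"
    )
    if mode == "nominal":
        pattern = pattern.aggregate_nominal()
    keep = pattern.abundances >= prune
    kept = pattern.abundances[keep]
    return IsotopePattern(
        pattern.masses[keep], kept / kept.sum(), pattern.neutrons[keep], pattern.mode
    )


def _convolution_pattern(
    comp: ElementalComposition, mode: str, prune: float, table: IsotopeTable
) -> IsotopePattern:
    floor = min(prune, 1e-8) * 1e-3
    dist = None
    for element, n in sorted(comp.counts.items()):
        part = _n_atoms(_single_atom(table, element), n, floor)
        dist = part if dist is None else _convolve(dist, part, floor)
    return _finalize(dist, mode, prune)


# ---------------------------------------------------------------------------
# FFT route (nominal-aggregated only)


def _fft_pair(pair1, pair2):
    p1, m1 = pair1
    p2, m2 = pair2
    p = fftconvolve(p1, p2)
    m = fftconvolve(m1, p2) + fftconvolve(p1, m2)
    p[p < 0] = 0.0
    return p, m


def _fft_power(pair, n: int):
    result = None
    power = pair
    while n:
        if n & 1:
            result = power if result is None else _fft_pair(result, power)
        n >>= 1
        if n:
            power = _fft_pair(power, power)
    return result


def _fft_pattern(
    comp: ElementalComposition, prune: float, table: IsotopeTable
) -> IsotopePattern:
    total = None
    for element, n in sorted(comp.counts.items()):
        single = _single_atom(table, element)
        size = max(s for s, _, _ in single) + 1
        p1 = np.zeros(size)
        m1 = np.zeros(size)
        for s, m, a in single:
            p1[s] += a
            m1[s] += a * m
        pair = _fft_power((p1, m1), n)
        total = pair if total is None else _fft_pair(total, pair)
    probs, moments = total
    keep = probs >= prune
    shifts = np.flatnonzero(keep)
    p = probs[keep]
    masses = moments[keep] / p
    return IsotopePattern(masses, p / p.sum(), shifts, "nominal")


def simulate_pattern(
    comp: ElementalComposition,
    mode: str = "nominal",
    prune_threshold: float | None = None,
    method: str = "convolution",
    table: IsotopeTable = DEFAULT_TABLE,
) -> IsotopePattern:
    """Isotope pattern of *comp*.

    Parameters
    ----------
    mode:
        ``"nominal"`` aggregates centroids by added-neutron number
        (abundance-weighted mean mass); ``"fine"`` resolves distinct
        isotopologue compositions (isotopic fine structure).
    prune_threshold:
        Centroids below this abundance fraction are dropped and the rest
        renormalized.  Defaults: 1e-5 nominal, 1e-8 fine.
    method:
        ``"convolution"`` (reference) or ``"fft"`` (nominal mode only).
    """
    if comp.total_atoms() == 0:
        raise ValueError("empty composition")
    if mode not in ("nominal", "fine"):
        raise ValueError(f"unknown mode {mode!r}")
    if prune_threshold is None:
        prune_threshold = 1e-5 if mode == "nominal" else 1e-8
    if method == "fft":
        if mode != "nominal":
            raise ValueError("fft method supports nominal mode only")
        return _fft_pattern(comp, prune_threshold, table)
    if method != "convolution":
        raise ValueError(f"unknown method {method!r}")
    return _convolution_pattern(comp, mode, prune_threshold, table)


# ---------------------------------------------------------------------------
# brute-force oracle


def _element_isotopologues(table, element, n, floor):
    """Exact per-element isotopologue list via multinomial enumeration."""
    isotopes = table.entries[element]
    k = len(isotopes)
    out = []
    for split in itertools.combinations_with_replacement(range(k), n):
        counts = [0] * k
        for i in split:
            counts[i] += 1
        coef = math.factorial(n)
        prob = 1.0
        mass = 0.0
        for c, (m, a) in zip(counts, isotopes):
            coef //= math.factorial(c)
            prob *= a**c
            mass += c * m
        prob *= coef
        if prob >= floor:
            shift = sum(
                c * int(round(m - isotopes[0][0])) for c, (m, _) in zip(counts, isotopes)
            )
            out.append((shift, mass, prob))
    return out


def brute_force_pattern(
    comp: ElementalComposition,
    prune_threshold: float = 1e-8,
    mode: str = "fine",
    table: IsotopeTable = DEFAULT_TABLE,
) -> IsotopePattern:
    """Exact multinomial enumeration of all isotopologues (test oracle).

    Guarded to compositions of at most 300 atoms.
    """
    if comp.total_atoms() == 0:
        raise ValueError("empty composition")
    if comp.total_atoms() > 300:
        raise ValueError(
            f"brute-force enumeration limited to 300 atoms, got {comp.total_atoms()}"
        )
    floor = min(prune_threshold, 1e-8) * 1e-3
    per_element = [
        _element_isotopologues(table, element, n, floor)
        for element, n in sorted(comp.counts.items())
    ]
    dist: dict[tuple[int, int], list[float]] = {}
    for combo in itertools.product(*per_element):
        prob = 1.0
        mass = 0.0
        shift = 0
        for s, m, p in combo:
            prob *= p
            mass += m
            shift += s
        if prob < floor:
            continue
        key = (shift, int(round(mass / _MASS_QUANTUM)))
        if key in dist:
            acc = dist[key]
            acc[0] += prob
            acc[1] += prob * mass
        else:
            dist[key] = [prob, prob * mass]
    return _finalize(dist, mode, prune_threshold)


# ---------------------------------------------------------------------------
# profile rendering


def render_profile(
    pattern: IsotopePattern,
    charge: int = 1,
    fwhm: float = 0.01,
    points_per_da: float | None = None,
    grid: np.ndarray | None = None,
    pad: float | None = None,
) -> Profile:
    """Render a pattern as a sum of Gaussians on a uniform m/z grid.

    Each centroid contributes a Gaussian of area proportional to its
    abundance, with the given full width at half maximum (in m/z units).
    If *grid* is supplied the profile is evaluated on it; otherwise a grid
    covering the pattern plus *pad* (default ``10 * fwhm``) is built at
    *points_per_da* points per Da (default 1000 nominal / 10000 fine).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    centers = (pattern.masses + charge * data.PROTON_MASS) / charge
    warnings: list[str] = []
    if grid is None:
        if points_per_da is None:
            points_per_da = 10000.0 if pattern.mode == "fine" else 1000.0
        if points_per_da < 100:
            raise ValueError("points_per_da must be >= 100")
        spacing = 1.0 / points_per_da
        if pad is None:
            pad = 10.0 * fwhm
        start = math.floor((centers[0] - pad) / spacing) * spacing
        stop = centers[-1] + pad
        x = start + spacing * np.arange(int(round((stop - start) / spacing)) + 1)
    else:
        x = np.asarray(grid, dtype=float)
        spacing = float(x[1] - x[0])
        start = float(x[0])
    if fwhm / spacing < 4.0:
        warnings.append(
            f"grid too coarse: {fwhm / spacing:.2f} points across fwhm (< 4); "
            "peak shapes will be distorted"
        )
    sigma = fwhm / _FWHM_PER_SIGMA
    height = pattern.abundances / (sigma * math.sqrt(2.0 * math.pi))
    y = np.zeros_like(x)
    half_window = 8.0 * sigma
    for mu, h in zip(centers, height):
        lo = np.searchsorted(x, mu - half_window)
        hi = np.searchsorted(x, mu + half_window)
        if lo >= hi:
            continue
        y[lo:hi] += h * np.exp(-0.5 * ((x[lo:hi] - mu) / sigma) ** 2)
    return Profile(start=start, spacing=spacing, intensity=y, charge=charge,
                   warnings=warnings)


def write_xy(profile: Profile, path: str | Path) -> None:
    """Write a profile as two whitespace-separated columns (m/z, intensity)."""
    np.savetxt(path, np.column_stack([profile.mz, profile.intensity]), fmt="%.6f %.8g")
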