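"""Synthetic FTICR-like spectra with known ground truth.

Profiles are sums of Gaussian peaks at a stated resolving power, mixed
from simulated labeling-state patterns with known percentage weights,
plus seeded additive Gaussian noise and an optional constant baseline.
Used throughout the test suite in place of instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sparselabel import data
from sparselabel.chem import Peptide, apply_labels, peptide_composition
from sparselabel.fitting import ObservedSpectrum, fit_multi_state, measure_fwhm
from sparselabel.isotopes import IsotopePattern, Profile, render_profile, simulate_pattern
from sparselabel.states import LabelScheme, StateSet, enumerate_states, find_collisions

__all__ = ["SynthSpec", "generate_spectrum", "state_patterns", "recovery_suite"]

#: unit-resolution and fine-structure instrument settings
DEFAULT_RESOLVING_POWER = 80_000.0
FINE_RESOLVING_POWER = 1_400_000.0
REFERENCE_MZ = 1000.0


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic spectrum."""

    peptide: str
    scheme: LabelScheme
    weights: tuple[float, ...]  # percent per state, sum 100
    charge: int = 1
    resolving_power: float = DEFAULT_RESOLVING_POWER
    reference_mz: float = REFERENCE_MZ
    points_per_da: float = 1000.0
    noise_sigma: float = 0.0  # fraction of max intensity
    baseline: float = 0.0  # fraction of max intensity
    seed: int = 0
    mode: str = "nominal"

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 100.0) > 1e-9:
            raise ValueError(f"weights sum to {sum(self.weights)!r}, not 100")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be nonnegative")
        if self.resolving_power <= 0:
            raise ValueError("resolving power must be positive")


def state_patterns(
    peptide: str | Peptide,
    states: StateSet,
    mode: str = "nominal",
    prune_threshold: float | None = None,
) -> list[IsotopePattern]:
    """Simulated pattern for each labeling state of *peptide*."""
    base = peptide_composition(peptide)
    return [
        simulate_pattern(
            apply_labels(base, n13C=s.n13C, n15N=s.n15N),
            mode=mode,
            prune_threshold=prune_threshold,
        )
        for s in states
    ]


def generate_spectrum(
    spec: SynthSpec, states: StateSet | None = None
) -> tuple[ObservedSpectrum, dict]:
    """Render a mixed labeling-state spectrum plus its ground-truth record.

    fwhm is ``m/R`` at the unlabeled monoisotopic m/z and is held constant
    over the narrow fit window.
    """
    if states is None:
        states = enumerate_states(spec.peptide, spec.scheme)
    if len(spec.weights) != len(states):
        raise ValueError(
            f"{len(spec.weights)} weights for {len(states)} states"
        )
    patterns = state_patterns(spec.peptide, states, mode=spec.mode)
    mono_mz = (patterns[0].monoisotopic_mass + spec.charge * data.PROTON_MASS) / spec.charge
    fwhm = mono_mz / spec.resolving_power

    grid_profile = render_profile(
        patterns[0], charge=spec.charge, fwhm=fwhm,
        points_per_da=spec.points_per_da, pad=2.0,
    )
    heaviest = render_profile(
        patterns[-1], charge=spec.charge, fwhm=fwhm,
        points_per_da=spec.points_per_da, pad=2.0,
    )
    n_points = int(round((heaviest.mz[-1] - grid_profile.start) / grid_profile.spacing)) + 1
    grid = grid_profile.start + grid_profile.spacing * np.arange(n_points)

    intensity = np.zeros_like(grid)
    for weight, pattern in zip(spec.weights, patterns):
        if weight == 0:
            continue
        component = render_profile(pattern, charge=spec.charge, fwhm=fwhm, grid=grid)
        intensity += (weight / 100.0) * component.intensity

    peak = intensity.max()
    rng = np.random.default_rng(spec.seed)
    if spec.baseline:
        intensity = intensity + spec.baseline * peak
    if spec.noise_sigma:
        intensity = intensity + rng.normal(0.0, spec.noise_sigma * peak, size=len(grid))
    intensity = np.clip(intensity, 0.0, None)

    truth = {
        "peptide": str(spec.peptide),
        "states": [s.descriptor for s in states],
        "weights": list(spec.weights),
        "charge": spec.charge,
        "fwhm": fwhm,
        "resolving_power": spec.resolving_power,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "mode": spec.mode,
    }
    return ObservedSpectrum(grid, intensity), truth


def _random_weights(rng: np.random.Generator, states: StateSet) -> np.ndarray:
    """Random percent weights, zeroed on states that lose a first-occurrence
    isobaric collision (those are unrecoverable at unit resolution)."""
    raw = rng.dirichlet(np.ones(len(states))) * 100.0
    order = {s.key(): i for i, s in enumerate(states)}
    for group in find_collisions(states):
        first = min(group, key=lambda s: order[s.key()])
        for state in group:
            if state.key() != first.key():
                raw[order[state.key()]] = 0.0
    return raw / raw.sum() * 100.0


def recovery_suite(
    n_trials: int = 200,
    seed: int = 0,
    noise_levels: tuple[float, ...] = (0.0,),
    peptides: tuple[str, ...] = ("EEDPIHLR", "FEGDTLVNR", "SAMPEGYVQER"),
    schemes: dict[str, LabelScheme] | None = None,
    mode: str = "nominal",
) -> pd.DataFrame:
    """Fit randomly weighted synthetic mixtures and score weight recovery.

    Returns one row per (trial, noise level) with the max and mean absolute
    per-state weight error of :func:`fit_multi_state`.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if schemes is None:
        schemes = {
            "VIL": LabelScheme.from_dict(data.VIL_SCHEME),
            "KGS": LabelScheme.from_dict(data.KGS_SCHEME),
        }
    rng = np.random.default_rng(seed)
    rows = []
    for trial in range(n_trials):
        peptide = peptides[int(rng.integers(len(peptides)))]
        scheme_name = list(schemes)[int(rng.integers(len(schemes)))]
        scheme = schemes[scheme_name]
        states = enumerate_states(peptide, scheme)
        weights = _random_weights(rng, states)
        for noise in noise_levels:
            spec = SynthSpec(
                peptide=peptide,
                scheme=scheme,
                weights=tuple(weights),
                noise_sigma=noise,
                seed=int(rng.integers(2**31)),
                resolving_power=(
                    DEFAULT_RESOLVING_POWER if mode == "nominal" else FINE_RESOLVING_POWER
                ),
                points_per_da=1000.0 if mode == "nominal" else 10000.0,
                mode=mode,
            )
            obs, truth = generate_spectrum(spec, states)
            patterns = state_patterns(peptide, states, mode=mode)
            result = fit_multi_state(
                obs, states, patterns, fwhm=truth["fwhm"], charge=spec.charge
            )
            errors = np.abs(result.weights - weights)
            rows.append(
                {
                    "trial": trial,
                    "peptide": peptide,
                    "scheme": scheme_name,
                    "noise_sigma": noise,
                    "n_states": len(states),
                    "max_error": float(errors.max()),
                    "mean_error": float(errors.mean()),
                }
            )
    return pd.DataFrame(rows)
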