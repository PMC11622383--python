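"""Percent-incorporation fitting of simulated patterns to observed spectra.

Two fitting routes are provided.  :func:`fit_two_state` grid-searches the
mixing coefficient of a two-component (unlabeled/fully-labeled) linear
combination by RMSE.  :func:`fit_multi_state` implements the greedy
sequential procedure for many overlapping states: find the lowest-mass
state present, scale it to its nearest observed peak, then raise each
subsequent state's coefficient until the combined model matches the
observed intensity at that state's monoisotopic position, and finally
normalize the coefficients to percentages summing to 100.  The coefficient
"raising" is solved analytically — the coefficient matching the target
intensity has a closed form — which is deterministic and equivalent to
literal iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from sparselabel import data
from sparselabel.chem import ElementalComposition, apply_labels, mz
from sparselabel.isotopes import IsotopePattern, Profile, render_profile
from sparselabel.states import LabelingState, StateSet, find_collisions

__all__ = [
    "ObservedSpectrum",
    "FitResult",
    "fit_two_state",
    "fit_multi_state",
    "measure_fwhm",
    "calibrate_single_point",
    "mass_defect_discriminate",
]


@dataclass(frozen=True)
class ObservedSpectrum:
    """An observed spectrum: m/z and intensity arrays (profile or centroid)."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same shape")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")

    @classmethod
    def from_profile(cls, profile: Profile) -> "ObservedSpectrum":
        return cls(profile.mz, profile.intensity)

    def rescaled_mz(self, factor: float) -> "ObservedSpectrum":
        return ObservedSpectrum(self.mz * factor, self.intensity)


@dataclass
class FitResult:
    """Outcome of an incorporation fit."""

    descriptors: list[str]
    weights: np.ndarray  # percent, sums to 100
    coefficients: np.ndarray  # raw scaling coefficients
    rmse: float
    model: Profile
    fwhm: float
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 100.0) > 1e-6:
            raise ValueError(f"weights sum to {self.weights.sum()!r}, not 100")

    def as_dict(self) -> dict:
        return {
            "states": {d: float(w) for d, w in zip(self.descriptors, self.weights)},
            "rmse": float(self.rmse),
            "fwhm": float(self.fwhm),
            "diagnostics": list(self.diagnostics),
        }


def _local_maxima(y: np.ndarray) -> np.ndarray:
    interior = (y[1:-1] >= y[:-2]) & (y[1:-1] > y[2:]) & (y[1:-1] > 0)
    return np.flatnonzero(interior) + 1


def _nearest_peak(
    spec: ObservedSpectrum, position: float, tolerance: float
) -> int | None:
    """Grid index of the observed local maximum nearest *position*, or None."""
    maxima = _local_maxima(spec.intensity)
    if len(maxima) == 0:
        return None
    candidates = maxima[np.abs(spec.mz[maxima] - position) <= tolerance]
    if len(candidates) == 0:
        return None
    return int(candidates[np.argmin(np.abs(spec.mz[candidates] - position))])


def _refine_apex(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic-interpolated (position, height) of the apex at index i."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    spacing = x[i + 1] - x[i]
    return float(x[i] + delta * spacing), float(y1 - 0.25 * (y0 - y2) * delta)


def fit_two_state(
    obs: ObservedSpectrum,
    unlabeled: Profile,
    labeled: Profile,
    step: float = 0.1,
) -> FitResult:
    """Grid-search the labeled fraction B (percent) minimizing RMSE.

    The model ``(1 - B/100) * unlabeled + (B/100) * labeled`` is scaled to
    the data by least squares at each grid point; the best-fitting B is
    the percent incorporation.
    """
    if step <= 0 or (round(100.0 / step) * step - 100.0) > 1e-9:
        raise ValueError("step must be positive and divide 100")
    grid = unlabeled.mz
    if labeled.intensity.shape != unlabeled.intensity.shape or not np.allclose(
        labeled.mz, grid
    ):
        raise ValueError("unlabeled and labeled profiles must share a grid")
    y = np.interp(grid, obs.mz, obs.intensity, left=0.0, right=0.0)
    if not np.any(y > 0):
        raise ValueError("observed spectrum has zero intensity on the fit window")
    u, v = unlabeled.intensity, labeled.intensity
    best_b, best_rmse, best_model = 0.0, math.inf, u
    for b in np.arange(0.0, 100.0 + step / 2, step):
        model = (1.0 - b / 100.0) * u + (b / 100.0) * v
        norm = float(model @ model)
        scale = float(model @ y) / norm if norm > 0 else 0.0
        resid = y - scale * model
        rmse = math.sqrt(float(resid @ resid) / len(y))
        if rmse < best_rmse:
            best_b, best_rmse, best_model = float(b), rmse, scale * model
    weights = np.array([100.0 - best_b, best_b])
    return FitResult(
        descriptors=["unlabeled", "labeled"],
        weights=weights,
        coefficients=weights / 100.0,
        rmse=best_rmse,
        model=Profile(
            start=float(grid[0]),
            spacing=float(grid[1] - grid[0]),
            intensity=best_model,
            charge=unlabeled.charge,
        ),
        fwhm=float("nan"),
    )


def fit_multi_state(
    obs: ObservedSpectrum,
    states: StateSet,
    patterns: list[IsotopePattern],
    fwhm: float,
    charge: int = 1,
    collision_mode: str = "first_occurrence",
    presence_snr: float = 3.0,
    match_tolerance: float | None = None,
) -> FitResult:
    """Greedy sequential multi-state fit (states in neutron-count order).

    Parameters
    ----------
    patterns:
        One simulated pattern per state, in the same order as *states*.
    fwhm:
        Peak width (m/z units) at which patterns are rendered; normally
        taken from :func:`measure_fwhm` on the data being fit.
    collision_mode:
        ``"first_occurrence"`` assigns all intensity at a shared neutron
        count to the first state in the list and skips the rest with a
        warning; ``"mass_defect"`` fits every state at its exact
        monoisotopic position (requires resolution/calibration that
        separates the mass defects).
    """
    if len(patterns) != len(states):
        raise ValueError("need exactly one pattern per state")
    grid = obs.mz
    spacing = float(np.median(np.diff(grid)))
    if not np.allclose(np.diff(grid), spacing, rtol=1e-6, atol=spacing * 1e-6):
        raise ValueError("multi-state fitting requires a uniform-grid profile")
    rendered = [
        render_profile(p, charge=charge, fwhm=fwhm, grid=grid).intensity
        for p in patterns
    ]
    positions = [
        (p.monoisotopic_mass + charge * data.PROTON_MASS) / charge for p in patterns
    ]
    if match_tolerance is None:
        # at unit resolution a state's monoisotopic peak merges with the
        # same-nominal-mass isotope peaks of lighter states; the cluster
        # apex can sit up to ~1 fwhm from the state's exact position
        match_tolerance = max(fwhm, 5e-6 * positions[0])

    # fit window: 2 fwhm around the union of simulated centroids
    last_centroid = max(
        (p.masses[-1] + charge * data.PROTON_MASS) / charge for p in patterns
    )
    lo = np.searchsorted(grid, positions[0] - 2 * fwhm)
    hi = np.searchsorted(grid, last_centroid + 2 * fwhm)
    if hi <= lo or not np.any(obs.intensity[lo:hi] > 0):
        raise ValueError("observed spectrum has zero intensity on the fit window")
    noise_floor = float(np.median(np.abs(obs.intensity[lo:hi])))

    skip_after_first: set[tuple[int, int]] = set()
    if collision_mode == "first_occurrence":
        for group in find_collisions(states):
            # first occurrence = position in the state list, not mass order
            order = {s.key(): i for i, s in enumerate(states)}
            first = min(group, key=lambda s: order[s.key()])
            skip_after_first |= {s.key() for s in group if s.key() != first.key()}
    elif collision_mode != "mass_defect":
        raise ValueError(f"unknown collision_mode {collision_mode!r}")

    coeffs = np.zeros(len(states))
    combined = np.zeros_like(grid)
    diagnostics: list[str] = []
    anchored = False
    for i, state in enumerate(states):
        if state.key() in skip_after_first:
            diagnostics.append(
                f"skipped isobaric state {state.descriptor} "
                f"(neutron count {state.neutron_count} already assigned)"
            )
            continue
        idx = _nearest_peak(obs, positions[i], match_tolerance)
        if idx is None:
            diagnostics.append(
                f"no observed peak within {match_tolerance:.4g} m/z of "
                f"{state.descriptor} at {positions[i]:.4f}; weight set to 0"
            )
            continue
        target = float(obs.intensity[idx])
        if not anchored:
            if target < presence_snr * noise_floor:
                continue  # state not present; keep scanning for the anchor
            anchored = True
        height = rendered[i][idx]
        if height <= 0:
            diagnostics.append(
                f"state {state.descriptor} has no model intensity at its "
                "matched peak; weight set to 0"
            )
            continue
        coeffs[i] = max(0.0, (target - combined[idx]) / height)
        combined = combined + coeffs[i] * rendered[i]

    total = coeffs.sum()
    if total <= 0:
        raise ValueError("no labeling state matched the observed spectrum")
    weights = coeffs / total * 100.0
    resid = obs.intensity[lo:hi] - combined[lo:hi]
    rmse = math.sqrt(float(resid @ resid) / (hi - lo))
    return FitResult(
        descriptors=[s.descriptor for s in states],
        weights=weights,
        coefficients=coeffs,
        rmse=rmse,
        model=Profile(
            start=float(grid[0]), spacing=spacing, intensity=combined, charge=charge
        ),
        fwhm=fwhm,
        diagnostics=diagnostics,
    )


def plot_overlay(
    obs: ObservedSpectrum,
    result: FitResult,
    components: list[Profile] | None = None,
    path=None,
):
    """Overlay the observed spectrum, the combined model and (optionally)
    per-state component profiles.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(obs.mz, obs.intensity, color="tab:blue", lw=0.8, label="observed")
    ax.plot(result.model.mz, result.model.intensity, color="tab:orange",
            lw=1.2, label="combined fit")
    if components:
        for descriptor, weight, component in zip(
            result.descriptors, result.weights, components
        ):
            if weight <= 0:
                continue
            ax.plot(component.mz, component.intensity, ls="--", lw=0.8,
                    label=f"{descriptor} ({weight:.1f}%)")
    ax.set_xlabel("m/z")
    ax.set_ylabel("intensity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def measure_fwhm(obs: ObservedSpectrum, peak_mz: float, search: float = 0.5) -> float:
    """Full width at half maximum (linear-interpolated) of the peak nearest
    *peak_mz*, in m/z units."""
    idx = _nearest_peak(obs, peak_mz, search)
    if idx is None:
        raise ValueError(f"no peak within {search} m/z of {peak_mz}")
    x, y = obs.mz, obs.intensity
    half = y[idx] / 2.0
    left = None
    for j in range(idx, 0, -1):
        if y[j - 1] <= half:
            frac = (y[j] - half) / (y[j] - y[j - 1])
            left = x[j] - frac * (x[j] - x[j - 1])
            break
    right = None
    for j in range(idx, len(x) - 1):
        if y[j + 1] <= half:
            frac = (y[j] - half) / (y[j] - y[j + 1])
            right = x[j] + frac * (x[j + 1] - x[j])
            break
    if left is None or right is None:
        raise ValueError(f"peak at {x[idx]:.4f} has no half-height crossing")
    return float(right - left)


def calibrate_single_point(
    obs: ObservedSpectrum, reference_mz: float, tol_ppm: float = 50.0
) -> ObservedSpectrum:
    """Single-point internal calibration: rescale all m/z so the peak near
    *reference_mz* lands exactly on it (multiplicative correction)."""
    tolerance = reference_mz * tol_ppm * 1e-6
    idx = _nearest_peak(obs, reference_mz, tolerance)
    if idx is None:
        raise ValueError(
            f"no peak within {tol_ppm} ppm of reference m/z {reference_mz}"
        )
    apex, _ = _refine_apex(obs.mz, obs.intensity, idx)
    return obs.rescaled_mz(reference_mz / apex)


def mass_defect_discriminate(
    obs: ObservedSpectrum,
    base_comp: ElementalComposition,
    candidates: list[LabelingState],
    charge: int = 1,
    tolerance: float = 0.05,
) -> dict[str, float | None]:
    """Mass error (ppm) of each isobaric candidate against the observed apex.

    All candidates must share a neutron count; each candidate's labeled
    monoisotopic m/z is compared with the parabolic-refined apex of the
    corresponding isotope peak in the (calibrated) data.  The candidate
    with the smallest absolute error is preferred; candidates whose peak
    is absent map to ``None`` (indeterminate).
    """
    counts = {c.neutron_count for c in candidates}
    if len(counts) != 1:
        raise ValueError("candidates must share one neutron count")
    errors: dict[str, float | None] = {}
    for cand in candidates:
        labeled = apply_labels(base_comp, n13C=cand.n13C, n15N=cand.n15N)
        theo = mz(labeled, charge)
        idx = _nearest_peak(obs, theo, tolerance)
        if idx is None:
            errors[cand.descriptor] = None
            continue
        apex, _ = _refine_apex(obs.mz, obs.intensity, idx)
        errors[cand.descriptor] = (apex - theo) / theo * 1e6
    return errors
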