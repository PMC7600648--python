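"""Orbitrap resolvability of the canavanine / A+2 isotopologue conflict.

A peptide carrying one canavanine in place of Arg sits 27.3 mDa below the
A+2 isotopologue of the unmodified peptide.  Whether an Orbitrap can
separate the two at MS1 depends on the peak width at the measured m/z:
the Gaussian full width at 10% of maximum (FWTM) is

    FWTM = 1.822 * (m/z) / R_eff,      R_eff = R * sqrt(200 / (m/z))

where ``R`` is the resolution setting (FWHM resolving power specified at
m/z 200; Orbitrap resolving power decays as 1/sqrt(m/z)) and
1.822 = sqrt(ln 10 / ln 2) converts FWHM to FWTM for a Gaussian.  A
variant pair is called resolved when the FWTM is smaller than the
conflict spacing 27.3 mDa divided by the charge.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem import diagnostic_deltas

__all__ = [
    "FWTM_FACTOR",
    "REFERENCE_MZ",
    "CONFLICT_GAP",
    "DEFAULT_GRID",
    "UNRESOLVABLE",
    "ResolutionModel",
    "PeptideIon",
    "IsotopeEnvelope",
    "ResolvabilityCurve",
    "fwtm",
    "conflict_spacing",
    "is_resolved",
    "required_resolution",
    "fraction_resolved_curve",
    "fine_isotope_envelope",
    "render_overlap",
]

#: Gaussian FWTM / FWHM ratio, sqrt(ln 10 / ln 2).
FWTM_FACTOR = 1.822

#: m/z at which the resolution setting is specified.
REFERENCE_MZ = 200.0

#: Spacing between the A+2 isotopologue and the canavanine variant, Da.
CONFLICT_GAP = diagnostic_deltas()["conflict_gap"]

#: Resolution-setting grid: 1e4 .. 1e6 in steps of 1e4.
DEFAULT_GRID: np.ndarray = np.arange(1, 101) * 1.0e4

#: Sentinel returned when no grid setting resolves an ion.
UNRESOLVABLE = math.inf


@dataclass(frozen=True)
class ResolutionModel:
    """Gaussian peak-shape model tied to an Orbitrap resolution setting."""

    resolution_setting: float
    fwtm_factor: float = FWTM_FACTOR
    reference_mz: float = REFERENCE_MZ

    def __post_init__(self) -> None:
        if self.resolution_setting <= 0:
            raise ValueError("resolution_setting must be positive")


@dataclass(frozen=True)
class PeptideIon:
    """An observed peptide ion: m/z, charge and (optionally) sequence."""

    mz: float
    charge: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.mz <= 1.0:
            raise ValueError(f"non-physical m/z: {self.mz}")


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Centroided isotopologue masses with normalized relative abundances."""

    centroids: tuple[float, ...]
    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.centroids) != len(self.abundances):
            raise ValueError("centroids and abundances differ in length")
        if len(self.centroids) == 0:
            raise ValueError("empty envelope")
        if any(b <= a for a, b in zip(self.centroids, self.centroids[1:])):
            raise ValueError("centroids must be strictly increasing")
        total = sum(self.abundances)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")

    def shifted(self, delta: float) -> "IsotopeEnvelope":
        return IsotopeEnvelope(
            tuple(c + delta for c in self.centroids), self.abundances
        )


@dataclass(frozen=True)
class ResolvabilityCurve:
    """Fraction of an ion population resolved across a resolution grid."""

    grid: np.ndarray
    fraction: np.ndarray
    setting_50: float = field(default=UNRESOLVABLE)
    setting_95: float = field(default=UNRESOLVABLE)


def fwtm(mz: float, model: ResolutionModel) -> float:
    """Peak full width at 10% maximum (Da) at a given m/z."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    r_eff = model.resolution_setting * math.sqrt(model.reference_mz / mz)
    return model.fwtm_factor * mz / r_eff


def conflict_spacing(charge: int) -> float:
    """Expected m/z distance between the conflicting peaks at a charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return CONFLICT_GAP / charge


def is_resolved(ion: PeptideIon, model: ResolutionModel) -> bool:
    """True iff the peak width is strictly below the conflict spacing."""
    return fwtm(ion.mz, model) < conflict_spacing(ion.charge)


def required_resolution(
    ion: PeptideIon, grid: Sequence[float] | np.ndarray = DEFAULT_GRID
) -> float:
    """Smallest grid setting resolving the ion, or ``UNRESOLVABLE``."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty resolution grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("resolution grid must be strictly ascending")
    for setting in grid:
        if is_resolved(ion, ResolutionModel(float(setting))):
            return float(setting)
    return UNRESOLVABLE


def fraction_resolved_curve(
    ions: Sequence[PeptideIon], grid: Sequence[float] | np.ndarray = DEFAULT_GRID
) -> ResolvabilityCurve:
    """Fraction of ions resolved at each grid setting, with quantiles.

    The reported quantile settings are the smallest grid settings at
    which at least 50% / 95% of the ions are resolved.
    """
    if len(ions) == 0:
        raise ValueError("empty ion list")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("resolution grid must be non-empty and ascending")
    mz = np.array([ion.mz for ion in ions])
    z = np.array([ion.charge for ion in ions])
    # vectorized strict-inequality test: FWTM(mz; R) < gap/z
    widths = FWTM_FACTOR * mz / np.sqrt(REFERENCE_MZ / mz)  # per-ion R*spacing
    spacing = CONFLICT_GAP / z
    thresholds = widths / spacing  # exact R at which FWTM == spacing
    fraction = (thresholds[None, :] < grid[:, None]).mean(axis=1)

    def quantile_setting(q: float) -> float:
        idx = np.nonzero(fraction >= q)[0]
        return float(grid[idx[0]]) if idx.size else UNRESOLVABLE

    return ResolvabilityCurve(
        grid=grid,
        fraction=fraction,
        setting_50=quantile_setting(0.50),
        setting_95=quantile_setting(0.95),
    )


# Natural isotopic abundances by nominal mass increment (A, A+1, A+2, ...).
_NATURAL_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

# isotope-label keys map onto their element for envelope purposes;
# pure heavy labels (13C, 15N) contribute no natural spread.
_LABEL_TO_ELEMENT = {"12C": "C", "1H": "H", "14N": "N", "16O": "O", "32S": "S"}

#: Average nominal isotopologue spacing used to place centroids, Da.
_ISOTOPE_SPACING = 1.0033


def fine_isotope_envelope(
    composition: Mapping[str, int], n_peaks: int = 5, monoisotopic_mass: float = 0.0
) -> IsotopeEnvelope:
    """Isotopologue distribution of a composition by nominal increment.

    Fine structure (13C vs 15N splits within one nominal increment) is
    aggregated: the A+2 conflict the labeling design addresses operates
    at the nominal-isotopologue level.  Element counts may be given as
    plain element symbols (``C``) or base-isotope labels (``12C``); heavy
    labels (``13C``, ``15N``) shift the monoisotopic mass but add no
    natural spread.

    Centroids are placed at ``monoisotopic_mass + k * 1.0033``.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if not composition:
        raise ValueError("empty composition")
    dist = np.array([1.0])
    for key, count in composition.items():
        if count < 0:
            raise ValueError(f"negative count for {key!r}")
        element = _LABEL_TO_ELEMENT.get(key, key)
        if element not in _NATURAL_ABUNDANCES:
            continue  # pure heavy label or exotic isotope: no spread
        single = np.array(_NATURAL_ABUNDANCES[element])
        for _ in range(count):
            dist = np.convolve(dist, single)
    dist = dist[:n_peaks]
    dist = dist / dist.sum()
    centroids = tuple(monoisotopic_mass + k * _ISOTOPE_SPACING for k in range(len(dist)))
    return IsotopeEnvelope(centroids, tuple(dist))


def render_overlap(
    env_a: IsotopeEnvelope,
    env_b: IsotopeEnvelope,
    model: ResolutionModel,
    charge: int,
    n_points: int = 4000,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Sum-of-Gaussians MS1 profile of two envelopes and a resolved flag.

    Envelope centroids are neutral masses; they are converted to m/z at
    the given charge.  The flag is True when a local minimum of the
    summed profile exists between the closest pair of centroids from the
    two envelopes (the conflicting peaks).

    Returns ``(mz_axis, profile, resolved)``.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    from .chem import PROTON_MASS

    mz_a = np.array(env_a.centroids) / charge + PROTON_MASS
    mz_b = np.array(env_b.centroids) / charge + PROTON_MASS
    ab_a = np.array(env_a.abundances)
    ab_b = np.array(env_b.abundances)

    # closest cross-envelope centroid pair = the conflicting peaks
    d = np.abs(mz_a[:, None] - mz_b[None, :])
    i, j = np.unravel_index(np.argmin(d), d.shape)
    lo, hi = sorted((mz_a[i], mz_b[j]))

    center = 0.5 * (lo + hi)
    width = fwtm(center, model)
    sigma = width / (2.0 * math.sqrt(2.0 * math.log(10.0)))

    all_mz = np.concatenate([mz_a, mz_b])
    span_lo, span_hi = all_mz.min() - 4 * width, all_mz.max() + 4 * width
    axis = np.linspace(span_lo, span_hi, n_points)
    profile = np.zeros_like(axis)
    for centers, weights in ((mz_a, ab_a), (mz_b, ab_b)):
        for c, w in zip(centers, weights):
            profile += w * np.exp(-0.5 * ((axis - c) / sigma) ** 2)

    if hi - lo > 8 * width:
        warnings.warn(
            "envelopes occupy disjoint m/z windows; overlap is trivially resolved",
            stacklevel=2,
        )
        return axis, profile, True

    between = (axis > lo) & (axis < hi)
    resolved = False
    if between.sum() >= 3:
        seg = profile[between]
        interior = seg[1:-1]
        resolved = bool(np.any((interior < seg[:-2]) & (interior <= seg[2:])))
    return axis, profile, resolved
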