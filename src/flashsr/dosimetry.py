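"""Dose-rate arithmetic and depth-dose / lateral-profile conventions.

Converts a bending-magnet photon rate into an absorbed dose rate through the
per-photon energy deposit in a scoring voxel, and applies the 85 %-of-d_max
conventions used to read effective treatment ranges off percentage-depth-dose
(PDD) and lateral-profile curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DoseCurve",
    "DepositionGeometry",
    "EffectiveRange",
    "dose_rate",
    "normalize_pdd",
    "effective_treatment_range",
    "profile_effective_fraction",
]

EV_TO_JOULE = 1.602176634e-19


class DosimetryDomainError(ValueError):
    """Raised for inputs outside the dosimetric domain."""


@dataclass(frozen=True)
class DoseCurve:
    """A sampled 1-D dose curve: depth (PDD) or lateral position (profile).

    Coordinates are physical millimetres, 0-based at the phantom entrance
    for depth curves; doses are in arbitrary units (normalize with
    :func:`normalize_pdd` to express them as fractions of d_max).
    """

    coordinate: np.ndarray  # mm
    dose: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        coord = np.asarray(self.coordinate, dtype=float)
        dose = np.asarray(self.dose, dtype=float)
        object.__setattr__(self, "coordinate", coord)
        object.__setattr__(self, "dose", dose)
        if coord.ndim != 1 or dose.ndim != 1 or coord.size != dose.size:
            raise DosimetryDomainError("coordinate and dose must be equal-length 1-D")
        if coord.size < 3:
            raise DosimetryDomainError("a dose curve needs at least 3 samples")
        if np.any(np.diff(coord) <= 0):
            raise DosimetryDomainError("coordinates must be strictly ascending")
        if np.any(dose < 0):
            raise DosimetryDomainError("doses must be nonnegative")

    @classmethod
    def from_csv(cls, path) -> "DoseCurve":
        frame = pd.read_csv(path)
        if frame.shape[1] < 2:
            raise DosimetryDomainError("curve CSV needs two columns")
        return cls(frame.iloc[:, 0].to_numpy(), frame.iloc[:, 1].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"coordinate_mm": self.coordinate, "dose": self.dose}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class DepositionGeometry:
    """Scoring-voxel geometry of the dose-rate equation.

    ``per_photon_energy_deposit`` (eV) is the mean energy one source photon
    leaves in the voxel of volume ``scoring_volume`` (m^3) filled with a
    medium of density ``medium_density`` (kg/m^3).
    """

    per_photon_energy_deposit: float  # eV
    scoring_volume: float  # m^3
    medium_density: float = 1000.0  # kg/m^3, water

    def __post_init__(self) -> None:
        if self.per_photon_energy_deposit < 0:
            raise DosimetryDomainError("per-photon deposit must be nonnegative (eV)")
        if self.scoring_volume <= 0 or self.medium_density <= 0:
            raise DosimetryDomainError("scoring volume and density must be positive")

    @property
    def mass(self) -> float:
        """Voxel mass in kg."""
        return self.scoring_volume * self.medium_density


@dataclass(frozen=True)
class EffectiveRange:
    """Contiguous super-threshold interval around the curve maximum."""

    start: float  # mm
    end: float  # mm
    clamped_low: bool = False  # curve never fell below threshold on the left
    clamped_high: bool = False
    other_lobes: tuple = field(default_factory=tuple)  # (start, end) of other peaks

    @property
    def width(self) -> float:
        return self.end - self.start


def dose_rate(geometry: DepositionGeometry, photon_rate: float) -> float:
    """Mean absorbed dose rate in Gy/s.

    ``Dr = e[eV] * q_e * N / (V * rho)``: energy deposited per second
    divided by the voxel mass, with Gy = J/kg.
    """
    if photon_rate < 0:
        raise DosimetryDomainError("photon_rate must be nonnegative")
    return (
        geometry.per_photon_energy_deposit * EV_TO_JOULE * photon_rate
    ) / geometry.mass


def normalize_pdd(curve: DoseCurve) -> DoseCurve:
    """Divide doses by d_max so the maximum is exactly 1."""
    d_max = float(np.max(curve.dose))
    if d_max <= 0:
        raise DosimetryDomainError("cannot normalize an all-zero curve")
    return replace(curve, dose=curve.dose / d_max)


def _crossing(x0, y0, x1, y1, level) -> float:
    """Linear-interpolated coordinate where the segment crosses `level`."""
    if y1 == y0:
        return x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def _superthreshold_intervals(curve: DoseCurve, level: float):
    """All contiguous intervals with dose >= level, interpolated boundaries."""
    coord, dose = curve.coordinate, curve.dose
    above = dose >= level
    intervals = []
    i = 0
    n = coord.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if i == 0:
            start, clamp_lo = coord[0], True
        else:
            start = _crossing(coord[i - 1], dose[i - 1], coord[i], dose[i], level)
            clamp_lo = False
        if j == n - 1:
            end, clamp_hi = coord[-1], True
        else:
            end = _crossing(coord[j], dose[j], coord[j + 1], dose[j + 1], level)
            clamp_hi = False
        intervals.append((start, end, clamp_lo, clamp_hi, i, j))
        i = j + 1
    return intervals


def effective_treatment_range(
    curve: DoseCurve, threshold_fraction: float = 0.85
) -> EffectiveRange:
    """Depth band where the dose stays above ``threshold_fraction * d_max``.

    The boundaries of the band containing the global maximum are located by
    linear interpolation between adjacent samples.  A boundary that runs
    off the sampled support is clamped to the curve end and flagged.  On a
    multi-modal curve the other super-threshold lobes are reported
    separately in ``other_lobes``.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise DosimetryDomainError("threshold_fraction must lie in (0, 1)")
    d_max = float(np.max(curve.dose))
    if d_max <= 0:
        raise DosimetryDomainError("curve has no positive dose")
    level = threshold_fraction * d_max
    peak_index = int(np.argmax(curve.dose))
    intervals = _superthreshold_intervals(curve, level)
    main = None
    lobes = []
    for start, end, clamp_lo, clamp_hi, i, j in intervals:
        if i <= peak_index <= j:
            main = EffectiveRange(start, end, clamp_lo, clamp_hi)
        else:
            lobes.append((start, end))
    assert main is not None  # the peak itself always satisfies dose >= level
    return replace(main, other_lobes=tuple(lobes))


def profile_effective_fraction(
    curve: DoseCurve,
    window: tuple[float, float],
    threshold_fraction: float = 0.85,
) -> float:
    """Fraction of window samples with dose between threshold and d_max.

    Positions inside ``window`` (mm) count as effective when their dose
    lies in ``[threshold_fraction * d_max, d_max]``.
    """
    lo, hi = window
    if hi <= lo:
        raise DosimetryDomainError("window must have positive width")
    if lo < curve.coordinate[0] or hi > curve.coordinate[-1]:
        raise DosimetryDomainError("window must lie within the curve support")
    mask = (curve.coordinate >= lo) & (curve.coordinate <= hi)
    if not np.any(mask):
        raise DosimetryDomainError("window contains no samples")
    d_max = float(np.max(curve.dose))
    if d_max <= 0:
        raise DosimetryDomainError("curve has no positive dose")
    effective = curve.dose[mask] >= threshold_fraction * d_max
    return float(np.count_nonzero(effective) / np.count_nonzero(mask))
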