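"""Cone-channel spectral sensitivities and receptor-noise parameters.

Models the photoreceptor complement of an average UVS (ultraviolet-sensitive)
passerine: four single cones (U, S_U, M, L) mediating color vision and a
double cone (D) mediating achromatic vision.  Channel noise follows the
receptor-noise-limited (RNL) convention: the Weber fraction of each chromatic
channel scales inversely with the square root of its relative cone abundance,

    e_i = nu / sqrt(eta_i),

with ``nu`` the single-cone noise (default 0.1) and abundances defaulting to
the blue tit ratios 1 : 1.9 : 2.7 : 2.7 for U : S_U : M : L.  The double cone
carries its own Weber fraction (default 0.34) and no abundance.

Sensitivity curves are configurable area-normalized Gaussians on the
wavelength axis; they are consumed only by the synthetic scene generator and
stand in for measured spectral sensitivities, which are not tabulated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "SpectrumCurve",
    "ConeSystem",
    "default_grid",
    "gaussian_sensitivity",
    "build_cone_system",
    "channel_noise",
    "DEFAULT_PEAKS_NM",
    "DEFAULT_FWHM_NM",
    "DEFAULT_ABUNDANCES",
    "DEFAULT_WEBER_SINGLE",
    "DEFAULT_WEBER_DOUBLE",
    "DOUBLE_CONE_LABEL",
]

DOUBLE_CONE_LABEL = "D"

#: Gaussian stand-ins for the avian UVS single cones and the double cone.
DEFAULT_PEAKS_NM: dict[str, float] = {
    "U": 370.0,
    "S_U": 445.0,
    "M": 508.0,
    "L": 565.0,
    "D": 560.0,
}
DEFAULT_FWHM_NM: dict[str, float] = {
    "U": 40.0,
    "S_U": 50.0,
    "M": 60.0,
    "L": 70.0,
    "D": 110.0,
}
#: Blue tit relative cone abundances, U : S_U : M : L.
DEFAULT_ABUNDANCES: dict[str, float] = {"U": 1.0, "S_U": 1.9, "M": 2.7, "L": 2.7}
#: Weber fraction of a single chromatic cone channel.
DEFAULT_WEBER_SINGLE = 0.1
#: Weber fraction of the achromatic double-cone channel.
DEFAULT_WEBER_DOUBLE = 0.34


def default_grid() -> np.ndarray:
    """Default wavelength grid: 300-700 nm in 1-nm steps."""
    return np.arange(300.0, 701.0, 1.0)


@dataclass(frozen=True)
class SpectrumCurve:
    """A non-negative function of wavelength sampled on an increasing grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2 or not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    @property
    def integral(self) -> float:
        """Trapezoidal integral over the grid."""
        return float(np.trapezoid(self.values, self.wavelengths_nm))

    def is_area_normalized(self, tol: float = 1e-6) -> bool:
        return abs(self.integral - 1.0) <= tol

    def area_normalized(self) -> "SpectrumCurve":
        area = self.integral
        if area <= 0:
            raise ValueError("cannot area-normalize a zero curve")
        return SpectrumCurve(self.wavelengths_nm, self.values / area)

    def interp(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation; zero outside the sampled range."""
        return np.interp(
            np.asarray(wavelengths_nm, dtype=float),
            self.wavelengths_nm,
            self.values,
            left=0.0,
            right=0.0,
        )

    @classmethod
    def flat(cls, value: float, grid: np.ndarray | None = None) -> "SpectrumCurve":
        grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
        return cls(grid, np.full(grid.shape, float(value)))


def gaussian_sensitivity(
    peak_nm: float, fwhm_nm: float, grid: np.ndarray | None = None
) -> SpectrumCurve:
    """Area-normalized Gaussian sensitivity with the given peak and FWHM.

    Raises
    ------
    ValueError
        If the peak lies outside the wavelength grid.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if not (grid[0] <= peak_nm <= grid[-1]):
        raise ValueError(
            f"peak {peak_nm} nm outside grid range [{grid[0]}, {grid[-1]}] nm"
        )
    if fwhm_nm <= 0:
        raise ValueError("fwhm_nm must be positive")
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    values = np.exp(-0.5 * ((grid - peak_nm) / sigma) ** 2)
    return SpectrumCurve(grid, values).area_normalized()


@dataclass(frozen=True)
class ConeSystem:
    """A visual system: labelled sensitivity curves, abundances, and noise.

    ``labels`` orders the channels; every label except the double cone must
    have a positive abundance.  ``weber_single`` (nu) sets the chromatic
    noise scale and ``weber_double`` (omega_D) the achromatic one.
    """

    labels: tuple[str, ...]
    sensitivities: Mapping[str, SpectrumCurve]
    abundances: Mapping[str, float]
    weber_single: float = DEFAULT_WEBER_SINGLE
    weber_double: float = DEFAULT_WEBER_DOUBLE
    double_label: str = DOUBLE_CONE_LABEL

    def __post_init__(self) -> None:
        if self.weber_single <= 0 or self.weber_double <= 0:
            raise ValueError("Weber fractions must be positive")
        for label in self.labels:
            if label not in self.sensitivities:
                raise ValueError(f"missing sensitivity curve for channel {label!r}")
        for label in self.chromatic_labels:
            if label not in self.abundances:
                raise ValueError(f"missing abundance for chromatic channel {label!r}")
            if self.abundances[label] <= 0:
                raise ValueError(f"abundance for {label!r} must be positive")
        if self.double_label in self.abundances:
            raise ValueError("double cone carries no abundance")

    @property
    def chromatic_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l != self.double_label)

    @property
    def has_double_cone(self) -> bool:
        return self.double_label in self.labels

    def grid(self) -> np.ndarray:
        return self.sensitivities[self.labels[0]].wavelengths_nm


def build_cone_system(config: Mapping | None = None) -> ConeSystem:
    """Build a :class:`ConeSystem` from a (possibly partial) configuration.

    Recognized keys: ``labels``, ``peaks_nm``, ``fwhm_nm``, ``abundances``,
    ``weber_single``, ``weber_double``, ``double_label``, ``grid``.
    Unspecified entries fall back to the UVS defaults.
    """
    cfg = dict(config or {})
    labels = tuple(cfg.get("labels", ("U", "S_U", "M", "L", "D")))
    double_label = cfg.get("double_label", DOUBLE_CONE_LABEL)
    grid = cfg.get("grid")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)

    peaks = {**DEFAULT_PEAKS_NM, **cfg.get("peaks_nm", {})}
    fwhms = {**DEFAULT_FWHM_NM, **cfg.get("fwhm_nm", {})}
    if "abundances" in cfg:
        abundances = dict(cfg["abundances"])
    else:
        abundances = {l: DEFAULT_ABUNDANCES[l] for l in labels if l != double_label}

    sensitivities = {}
    for label in labels:
        if label not in peaks or label not in fwhms:
            raise ValueError(f"no peak/FWHM configured for channel {label!r}")
        sensitivities[label] = gaussian_sensitivity(peaks[label], fwhms[label], grid)

    return ConeSystem(
        labels=labels,
        sensitivities=sensitivities,
        abundances=abundances,
        weber_single=float(cfg.get("weber_single", DEFAULT_WEBER_SINGLE)),
        weber_double=float(cfg.get("weber_double", DEFAULT_WEBER_DOUBLE)),
        double_label=double_label,
    )


def channel_noise(system: ConeSystem) -> dict[str, float]:
    """Per-channel RNL noise e_i = nu / sqrt(eta_i) for chromatic channels.

    The double cone is excluded; its Weber fraction is used directly by the
    achromatic contrast.
    """
    nu = system.weber_single
    return {
        label: nu / np.sqrt(system.abundances[label])
        for label in system.chromatic_labels
    }


def export_curve_csv(curve: SpectrumCurve, path) -> None:
    """Write a curve as two-column CSV (wavelength_nm, value)."""
    arr = np.column_stack([curve.wavelengths_nm, curve.values])
    np.savetxt(path, arr, delimiter=",", header="wavelength_nm,value", comments="")
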