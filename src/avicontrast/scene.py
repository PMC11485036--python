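"""Seeded synthetic multispectral scenes with ground-truth region masks.

Emulates the statistical structure of field photographs of a small jumping
spider posed on oak leaf litter: a desaturated, long-wavelength-rich litter
background, an elongated spider leg carrying a red patch (whose reflectance
ramp shifts toward orange/yellow at an oblique viewing angle), an adjoining
simulated black ornament of very low flat reflectance, a 20%-reflective gray
standard square, a constant sensor dark offset with unilluminated bottom
rows, and optional per-pixel multiplicative noise.

Noise-free pixel values in channel c for material m are proportional to

    integral( reflectance_m(lambda) * illuminant(lambda) * sens_c(lambda) )

with a per-channel exposure constant chosen so the gray standard sits at
half of full scale, plus the dark offset.  Rendering is a pure function of
(SceneSpec, ConeSystem).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .spectral import ConeSystem, SpectrumCurve, default_grid

__all__ = [
    "SceneSpec",
    "MultispectralStack",
    "ROISet",
    "red_reflectance",
    "leaf_litter_reflectance",
    "black_reflectance",
    "gray_standard_reflectance",
    "render_scene",
    "material_channel_signal",
]

ANGLE_CLASSES = ("perpendicular", "oblique")

# Logistic ramp parameters (base, plateau, inflection nm, width nm) for the
# red ornament at the two viewing angles.  The oblique pose shifts the
# inflection to shorter wavelengths and lowers the plateau, reproducing the
# orange/yellow appearance of legs angled away from the viewer.
_RED_RAMP = {
    "perpendicular": (0.02, 0.40, 615.0, 12.0),
    "oblique": (0.03, 0.30, 575.0, 14.0),
}


def red_reflectance(angle_class: str, grid: np.ndarray | None = None) -> SpectrumCurve:
    """Sigmoid reflectance ramp of the red leg ornament.

    ``perpendicular``: low below ~580 nm rising to a high plateau above
    ~620 nm.  ``oblique``: inflection shifted toward shorter wavelengths and
    plateau reduced, giving higher mid-wavelength reflectance.
    """
    if angle_class not in ANGLE_CLASSES:
        raise ValueError(
            f"unknown angle_class {angle_class!r}; expected one of {ANGLE_CLASSES}"
        )
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    base, plateau, mid, width = _RED_RAMP[angle_class]
    vals = base + (plateau - base) / (1.0 + np.exp(-(grid - mid) / width))
    return SpectrumCurve(grid, np.clip(vals, 0.0, 1.0))


def leaf_litter_reflectance(
    seed: int, grid: np.ndarray | None = None, perturbation: float = 1.0
) -> SpectrumCurve:
    """Desaturated, gently rising leaf-litter reflectance for one leaf.

    The template rises linearly from 0.05 at 400 nm to 0.35 at 700 nm (with a
    shallow UV tail), the desaturated long-wavelength-rich shape typical of
    dry oak litter.  A seeded brightness offset and spectral tilt perturb
    the template per leaf; the result stays within +-30% of the template and
    keeps its non-decreasing trend over 400-700 nm.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    template = np.where(
        grid < 400.0,
        0.035 + 0.015 * (grid - 300.0) / 100.0,
        0.05 + 0.30 * np.clip((grid - 400.0) / 300.0, 0.0, 1.0),
    )
    rng = np.random.default_rng(seed)
    gain = np.clip(rng.normal(0.0, 0.15), -0.25, 0.25)
    tilt = np.clip(rng.normal(0.0, 0.15), -0.30, 0.30)
    factor = 1.0 + perturbation * (gain + tilt * (grid - 500.0) / 200.0)
    factor = np.clip(factor, 0.70, 1.30)
    return SpectrumCurve(grid, np.clip(template * factor, 0.0, 1.0))


def black_reflectance(level: float = 0.015, grid: np.ndarray | None = None) -> SpectrumCurve:
    """Flat, very low reflectance of the simulated black ornament (~1-2%)."""
    return SpectrumCurve.flat(level, grid)


def gray_standard_reflectance(level: float = 0.20, grid: np.ndarray | None = None) -> SpectrumCurve:
    """Flat reflectance of the diffuse gray standard (default 20%)."""
    return SpectrumCurve.flat(level, grid)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; the seed fully determines output."""

    shape: tuple[int, int] = (256, 256)
    pixel_pitch_mm: float = 0.05
    dark_rows: int = 8
    include_oblique: bool = True
    gray_reflectance: float = 0.20
    black_reflectance: float = 0.015
    dark_offset: float = 0.02
    noise_sd: float = 0.02
    block_texture_sd: float = 0.06
    block_tilt_sd: float = 0.08
    block_px: int = 32
    seed: int = 0
    background: SpectrumCurve | None = None
    illuminant: SpectrumCurve | None = None

    def __post_init__(self) -> None:
        if self.dark_rows < 1 or self.dark_rows >= self.shape[0]:
            raise ValueError("dark_rows must be >= 1 and smaller than image height")
        for name in ("gray_reflectance", "black_reflectance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.block_texture_sd < 0 or self.block_tilt_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")


@dataclass
class MultispectralStack:
    """Per-cone-channel pixel grids plus acquisition metadata.

    ``dark_rows`` counts unilluminated rows at the bottom of the frame.
    ``steps`` records the processing provenance, enforced by the excitation
    pipeline.
    """

    channels: dict[str, np.ndarray]
    pixel_pitch_mm: float
    dark_rows: int
    steps: tuple[str, ...] = ("rendered",)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share dimensions")
        (self.shape,) = shapes

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def illuminated_slice(self) -> slice:
        """Row slice of the illuminated (non-dark) part of the frame."""
        return slice(0, self.shape[0] - self.dark_rows)

    def with_channels(self, channels: dict[str, np.ndarray], step: str) -> "MultispectralStack":
        return MultispectralStack(
            channels=channels,
            pixel_pitch_mm=self.pixel_pitch_mm,
            dark_rows=self.dark_rows,
            steps=self.steps + (step,),
            meta=dict(self.meta),
        )


@dataclass
class ROISet:
    """Named boolean masks over the scene's pixel grid.

    Required names: ``background``, ``gray_standard``, ``black_simulated``,
    and at least one of ``red_perpendicular`` / ``red_oblique``.  Masks are
    mutually disjoint; the background excludes target and standard pixels.
    """

    masks: dict[str, np.ndarray]

    REQUIRED = ("background", "gray_standard", "black_simulated")

    def __post_init__(self) -> None:
        for name in self.REQUIRED:
            if name not in self.masks:
                raise ValueError(f"missing required mask {name!r}")
        if not ("red_perpendicular" in self.masks or "red_oblique" in self.masks):
            raise ValueError("need at least one red mask (perpendicular or oblique)")
        total = np.zeros_like(next(iter(self.masks.values())), dtype=int)
        for arr in self.masks.values():
            total += arr.astype(int)
        if np.any(total > 1):
            raise ValueError("ROI masks must be mutually disjoint")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.masks)


def material_channel_signal(
    reflectance: SpectrumCurve, illuminant: SpectrumCurve, sensitivity: SpectrumCurve
) -> float:
    """Noise-free channel response: trapezoidal integral of R * I * S."""
    grid = sensitivity.wavelengths_nm
    product = reflectance.interp(grid) * illuminant.interp(grid) * sensitivity.values
    return float(np.trapezoid(product, grid))


def _scene_layout(spec: SceneSpec) -> dict[str, np.ndarray]:
    """Rectangular material masks for the default scene geometry.

    The ornamented leg is an elongated horizontal bar (~4 mm across ~80 px at
    the default pitch) carrying the red patch with the simulated black
    ornament adjoining it; the gray standard is a square near the top-left
    corner; everything else illuminated is litter background.
    """
    h, w = spec.shape
    lit_h = h - spec.dark_rows
    if lit_h < 64 or w < 192:
        raise ValueError("image too small for the default target layout")

    def rect(r0, r1, c0, c1):
        m = np.zeros(spec.shape, dtype=bool)
        m[r0:r1, c0:c1] = True
        return m

    # scale the fixed layout onto the requested frame
    def sr(frac):  # row coordinate
        return int(round(frac * lit_h))

    def sc(frac):  # column coordinate
        return int(round(frac * w))

    masks = {
        "gray_standard": rect(sr(0.05), sr(0.20), sc(0.05), sc(0.20)),
        "red_perpendicular": rect(sr(0.42), sr(0.50), sc(0.25), sc(0.55)),
        "black_simulated": rect(sr(0.42), sr(0.50), sc(0.55), sc(0.67)),
    }
    if spec.include_oblique:
        masks["red_oblique"] = rect(sr(0.60), sr(0.68), sc(0.25), sc(0.55))
    occupied = np.zeros(spec.shape, dtype=bool)
    for m in masks.values():
        occupied |= m
    background = ~occupied
    background[lit_h:, :] = False
    masks["background"] = background
    return masks


def render_scene(spec: SceneSpec, system: ConeSystem) -> tuple[MultispectralStack, ROISet]:
    """Render a synthetic multispectral stack and its ground-truth masks.

    Deterministic given ``spec.seed``.  Per-channel exposure places the gray
    standard at 0.5 of full scale; the dark offset is added everywhere and is
    the only content of the dark rows.  Multiplicative mean-one lognormal
    noise (sd ``noise_sd``) acts on the photon signal.  The litter background
    is a mosaic of leaf fragments: each block perturbs the scene's leaf curve
    with a brightness jitter (sd ``block_texture_sd``) and a spectral tilt
    (sd ``block_tilt_sd``), so background patches vary both achromatically
    and chromatically, as patches of real litter do.
    """
    grid = system.grid()
    illuminant = spec.illuminant or SpectrumCurve.flat(1.0, grid)
    background = spec.background or leaf_litter_reflectance(spec.seed, grid)

    materials: dict[str, SpectrumCurve] = {
        "background": background,
        "gray_standard": gray_standard_reflectance(spec.gray_reflectance, grid),
        "black_simulated": black_reflectance(spec.black_reflectance, grid),
        "red_perpendicular": red_reflectance("perpendicular", grid),
    }
    if spec.include_oblique:
        materials["red_oblique"] = red_reflectance("oblique", grid)

    masks = _scene_layout(spec)
    if spec.include_oblique and "red_oblique" not in masks:
        raise ValueError("layout could not place the oblique target")

    signals = {
        name: {
            c: material_channel_signal(refl, illuminant, system.sensitivities[c])
            for c in system.labels
        }
        for name, refl in materials.items()
    }
    gray = signals["gray_standard"]
    exposure = {c: 0.5 / gray[c] for c in system.labels}

    h, w = spec.shape
    lit = slice(0, h - spec.dark_rows)
    rng = np.random.default_rng(spec.seed)

    # leaf-fragment mosaic: per-block background signal per channel
    bg_signal = {c: np.full(spec.shape, signals["background"][c]) for c in system.labels}
    if spec.block_texture_sd > 0 or spec.block_tilt_sd > 0:
        nbr = -(-h // spec.block_px)
        nbc = -(-w // spec.block_px)
        gains = np.clip(
            rng.normal(0.0, spec.block_texture_sd, size=(nbr, nbc)), -0.25, 0.25
        )
        tilts = np.clip(
            rng.normal(0.0, spec.block_tilt_sd, size=(nbr, nbc)), -0.1, 0.1
        )
        tilt_curve = (grid - 500.0) / 200.0
        for c in system.labels:
            sens = system.sensitivities[c]
            block_sig = np.empty((nbr, nbc))
            for i in range(nbr):
                for j in range(nbc):
                    factor = np.clip(
                        1.0 + gains[i, j] + tilts[i, j] * tilt_curve, 0.7, 1.3
                    )
                    frag = SpectrumCurve(
                        grid, np.clip(background.values * factor, 0.0, 1.0)
                    )
                    block_sig[i, j] = material_channel_signal(frag, illuminant, sens)
            bg_signal[c] = np.kron(
                block_sig, np.ones((spec.block_px, spec.block_px))
            )[:h, :w]

    # per-pixel lognormal sensor noise, one field per channel
    noise_fields = {}
    for c in system.labels:
        if spec.noise_sd > 0:
            sd = spec.noise_sd
            noise_fields[c] = np.exp(rng.normal(-0.5 * sd**2, sd, size=spec.shape))
        else:
            noise_fields[c] = None

    channels: dict[str, np.ndarray] = {}
    for c in system.labels:
        signal = np.zeros(spec.shape)
        signal[masks["background"]] = (exposure[c] * bg_signal[c])[masks["background"]]
        for name in ("gray_standard", "black_simulated", "red_perpendicular", "red_oblique"):
            if name in masks:
                signal[masks[name]] = exposure[c] * signals[name][c]
        signal[h - spec.dark_rows :, :] = 0.0
        if noise_fields[c] is not None:
            signal *= noise_fields[c]
        channels[c] = signal + spec.dark_offset

    stack = MultispectralStack(
        channels=channels,
        pixel_pitch_mm=spec.pixel_pitch_mm,
        dark_rows=spec.dark_rows,
        steps=("rendered",),
        meta={
            "seed": spec.seed,
            "dark_offset": spec.dark_offset,
            "noise_sd": spec.noise_sd,
            "channel_order": list(system.labels),
        },
    )
    return stack, ROISet(masks)
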