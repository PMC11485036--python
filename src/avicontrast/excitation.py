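"""Raw stack -> cone excitation processing chain.

The chain mirrors standard multispectral calibrated-photography workflows:

1. ``subtract_dark`` — estimate the sensor dark level from unilluminated
   rows and subtract it from every pixel (negatives clipped to zero).
2. ``normalize_to_standard`` — divide by the mean over a gray-standard mask,
   yielding relative quantum catches p (standard region ~ 1); or
   ``adapt_to_background`` — von Kries chromatic adaptation, dividing each
   channel by its mean over the illuminated frame (or a supplied mask).
3. ``naka_rushton`` — saturating nonlinearity E = p / (p + 1), mapping
   catches to excitations in [0, 1).

Step order is enforced through the stack's provenance record: running a
step out of order, or twice, raises.  ROI statistics use channelwise
medians; background comparison patches are 3x3 squares laid on an even grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scene import MultispectralStack

__all__ = [
    "ExcitationStack",
    "PatchSet",
    "subtract_dark",
    "normalize_to_standard",
    "adapt_to_background",
    "naka_rushton",
    "roi_median_excitation",
    "sample_background_patches",
    "patch_medians",
    "render_false_color",
]

_NORM_STEPS = ("normalized:standard", "adapted:background")


@dataclass
class ExcitationStack:
    """Nonlinear cone-excitation images, every pixel in [0, 1)."""

    channels: dict[str, np.ndarray]
    mode: str  # "standard" | "background"
    pixel_pitch_mm: float
    dark_rows: int
    steps: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share dimensions")
        (self.shape,) = shapes
        for label, arr in self.channels.items():
            if np.any(arr < 0) or np.any(arr >= 1):
                raise ValueError(f"excitations in channel {label!r} outside [0, 1)")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def illuminated_slice(self) -> slice:
        return slice(0, self.shape[0] - self.dark_rows)

    def with_channels(self, channels: dict[str, np.ndarray], step: str) -> "ExcitationStack":
        return ExcitationStack(
            channels=channels,
            mode=self.mode,
            pixel_pitch_mm=self.pixel_pitch_mm,
            dark_rows=self.dark_rows,
            steps=self.steps + (step,),
            meta=dict(self.meta),
        )


def subtract_dark(stack: MultispectralStack) -> MultispectralStack:
    """Subtract the per-channel mean of the unilluminated rows everywhere.

    Negative results are clipped to zero.  The dark rows stay in the frame
    but are flagged consumed so the correction cannot run twice.
    """
    if "dark_subtracted" in stack.steps:
        raise ValueError("dark correction already applied")
    if stack.dark_rows < 1:
        raise ValueError(
            "stack has no dark rows; supply an explicit offset by constructing "
            "a stack with dark rows or pre-subtracting"
        )
    dark = slice(stack.shape[0] - stack.dark_rows, stack.shape[0])
    out = {}
    for label, arr in stack.channels.items():
        level = float(arr[dark, :].mean())
        out[label] = np.clip(arr - level, 0.0, None)
    new = stack.with_channels(out, "dark_subtracted")
    new.meta["dark_levels"] = {
        label: float(stack.channels[label][dark, :].mean()) for label in stack.channels
    }
    return new


def _require_dark_subtracted(stack: MultispectralStack) -> None:
    if "dark_subtracted" not in stack.steps:
        raise ValueError("dark correction must run before normalization")
    for step in _NORM_STEPS:
        if step in stack.steps:
            raise ValueError(f"stack already normalized ({step})")


def normalize_to_standard(
    stack: MultispectralStack,
    standard_mask: np.ndarray,
    standard_reflectance: float = 0.20,
) -> MultispectralStack:
    """Relative quantum catches: divide each channel by its gray-standard mean.

    The standard region maps to ~1 per channel; ``standard_reflectance`` is
    recorded for optional absolute scaling downstream.
    """
    _require_dark_subtracted(stack)
    standard_mask = np.asarray(standard_mask, dtype=bool)
    if not standard_mask.any():
        raise ValueError("standard mask is empty")
    out = {}
    for label, arr in stack.channels.items():
        mean = float(arr[standard_mask].mean())
        if mean <= 0:
            raise ValueError(f"gray-standard mean is zero in channel {label!r}")
        out[label] = arr / mean
    new = stack.with_channels(out, "normalized:standard")
    new.meta["standard_reflectance"] = standard_reflectance
    return new


def adapt_to_background(
    stack: MultispectralStack, adaptation_mask: np.ndarray | None = None
) -> MultispectralStack:
    """von Kries chromatic adaptation against the scene itself.

    Each channel is divided by its mean over the illuminated frame (default,
    spider pixels included) or over ``adaptation_mask`` when supplied (e.g.
    to adapt to background-only pixels).  Output channel means equal 1 under
    the default.
    """
    _require_dark_subtracted(stack)
    lit = stack.illuminated_slice()
    out = {}
    for label, arr in stack.channels.items():
        region = arr[adaptation_mask] if adaptation_mask is not None else arr[lit, :]
        mean = float(region.mean())
        if mean <= 0:
            raise ValueError(f"zero adaptation mean in channel {label!r}")
        out[label] = arr / mean
    return stack.with_channels(out, "adapted:background")


def naka_rushton(stack: MultispectralStack) -> ExcitationStack:
    """Saturating receptor nonlinearity E = p / (p + 1), elementwise."""
    applied = [s for s in _NORM_STEPS if s in stack.steps]
    if not applied:
        raise ValueError("normalize or adapt before the receptor nonlinearity")
    out = {}
    for label, arr in stack.channels.items():
        if np.any(arr < 0):
            raise ValueError(
                f"negative quantum catches in channel {label!r}; "
                "was the dark correction applied?"
            )
        out[label] = arr / (arr + 1.0)
    mode = "standard" if applied[0] == "normalized:standard" else "background"
    return ExcitationStack(
        channels=out,
        mode=mode,
        pixel_pitch_mm=stack.pixel_pitch_mm,
        dark_rows=stack.dark_rows,
        steps=stack.steps + ("naka_rushton",),
        meta=dict(stack.meta),
    )


def roi_median_excitation(stack: ExcitationStack, mask: np.ndarray) -> dict[str, float]:
    """Channelwise median excitation over a boolean region mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return {label: float(np.median(arr[mask])) for label, arr in stack.channels.items()}


@dataclass
class PatchSet:
    """Evenly spaced square background patches (default 3x3 px)."""

    centers: list[tuple[int, int]]
    size: int = 3
    medians: list[dict[str, float]] | None = None

    def __len__(self) -> int:
        return len(self.centers)

    def mask_for(self, index: int, shape: tuple[int, int]) -> np.ndarray:
        r, c = self.centers[index]
        half = self.size // 2
        m = np.zeros(shape, dtype=bool)
        m[r - half : r + half + 1, c - half : c + half + 1] = True
        return m


def sample_background_patches(
    background_mask: np.ndarray,
    n_target: int = 20,
    tol: int = 3,
    size: int = 3,
    seed: int = 0,
    stack: ExcitationStack | None = None,
) -> PatchSet:
    """Select ~``n_target`` (+-``tol``) even, disjoint patches inside a mask.

    Candidate centers sit on a uniform grid over the mask's bounding box; the
    grid pitch is searched (coarse to fine) until the number of patches fully
    inside the mask falls within tolerance.  If the first feasible pitch
    overshoots, a seeded subsample brings the count down to ``n_target``.
    Deterministic given (mask, seed).
    """
    mask = np.asarray(background_mask, dtype=bool)
    if mask.sum() < n_target * size * size:
        raise ValueError(
            f"background mask ({int(mask.sum())} px) too small for "
            f"{n_target} patches of {size}x{size}"
        )
    rows, cols = np.nonzero(mask)
    r0, r1, c0, c1 = rows.min(), rows.max(), cols.min(), cols.max()
    half = size // 2

    def accepted(pitch: int) -> list[tuple[int, int]]:
        centers = []
        for r in range(r0 + pitch // 2, r1 + 1, pitch):
            for c in range(c0 + pitch // 2, c1 + 1, pitch):
                rr = slice(r - half, r + half + 1)
                cc = slice(c - half, c + half + 1)
                if r - half < 0 or c - half < 0:
                    continue
                sub = mask[rr, cc]
                if sub.shape == (size, size) and sub.all():
                    centers.append((r, c))
        return centers

    max_pitch = max(r1 - r0, c1 - c0) + 1
    best: list[tuple[int, int]] = []
    chosen = None
    for pitch in range(max_pitch, size - 1, -1):
        cand = accepted(pitch)
        if len(cand) > len(best):
            best = cand
        if len(cand) >= n_target - tol:
            chosen = cand
            break
    if chosen is None:
        raise ValueError(
            f"could not place {n_target - tol} patches; achievable maximum "
            f"is {len(best)}"
        )
    if len(chosen) > n_target + tol:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(chosen), size=n_target, replace=False))
        chosen = [chosen[i] for i in idx]

    patches = PatchSet(centers=chosen, size=size)
    if stack is not None:
        patches.medians = patch_medians(patches, stack)
    return patches


def patch_medians(patches: PatchSet, stack: ExcitationStack) -> list[dict[str, float]]:
    """Per-patch channelwise median excitations."""
    out = []
    for i in range(len(patches)):
        mask = patches.mask_for(i, stack.shape)
        out.append(roi_median_excitation(stack, mask))
    return out


def render_false_color(stack: ExcitationStack) -> tuple[np.ndarray, float]:
    """False-color display image: (R, G, B) = (L, M, S_U) excitations.

    Returns the image scaled so its maximum is 1, together with the scale
    factor applied.
    """
    for label in ("L", "M", "S_U"):
        if label not in stack.channels:
            raise ValueError(f"false-color rendering needs channel {label!r}")
    img = np.stack(
        [stack.channels["L"], stack.channels["M"], stack.channels["S_U"]], axis=-1
    )
    peak = float(img.max())
    scale = 1.0 / peak if peak > 0 else 1.0
    return img * scale, scale
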