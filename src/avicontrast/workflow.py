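"""End-to-end experiment orchestration and group comparisons.

``run_imaging_experiment`` replays the imaging study on synthetic scenes:
for each spider x leaf combination it renders a scene, runs the excitation
chain (dark subtraction, background chromatic adaptation, Naka-Rushton),
samples ~20 background patches, computes RNL contrasts for the red
(perpendicular and, for a subset of spiders, oblique) and simulated-black
targets at native resolution and at acuity-limited "predator" resolution
for each viewing distance, and optionally repeats the black target with
boosted excitations.  Every stage seed derives from the master seed, so a
run is fully reproducible from (config, seed).

``cluster_bootstrap_diff`` compares groups of contrast values by
resampling leaves (the natural cluster: each scene's background) with
replacement — an assumption-light alternative to mixed-effects modeling
for grouped, heteroscedastic contrast data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acuity import ViewingGeometry, apply_acuity_blur
from .contrast import boost_excitations, contrast_table, records_to_frame
from .excitation import (
    adapt_to_background,
    naka_rushton,
    patch_medians,
    roi_median_excitation,
    sample_background_patches,
    subtract_dark,
)
from .scene import SceneSpec, render_scene
from .spectral import ConeSystem, build_cone_system

__all__ = [
    "ExperimentConfig",
    "ComparisonResult",
    "run_imaging_experiment",
    "cluster_bootstrap_diff",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Replication structure and processing options of an imaging run.

    Defaults mirror the field study's design: 13 spiders photographed on up
    to 3 leaves each, 7 of them posed with both perpendicular and oblique
    legs; ~20 background patches per image; native resolution plus an
    11-cpd viewer at 20/30/40 cm.
    """

    n_spiders: int = 13
    leaves_per_spider: int = 3
    n_oblique_spiders: int = 7
    scene: SceneSpec = field(default_factory=SceneSpec)
    acuity_cpd: float = 11.0
    distances_cm: tuple[float, ...] = (20.0, 30.0, 40.0)
    n_patches: int = 20
    patch_tol: int = 3
    patch_size: int = 3
    boost_factors: tuple[float, ...] = ()
    cone_config: dict | None = None

    def __post_init__(self) -> None:
        if self.n_spiders < 1 or self.leaves_per_spider < 1:
            raise ValueError("replication counts must be >= 1")
        if not (0 <= self.n_oblique_spiders <= self.n_spiders):
            raise ValueError("n_oblique_spiders must not exceed n_spiders")


@dataclass(frozen=True)
class ComparisonResult:
    """Cluster-bootstrap group difference with a percentile 95% CI."""

    contrast_type: str
    effect: str
    difference: float
    ci_low: float
    ci_high: float
    n_clusters: int
    n_boot: int

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.difference <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must contain the point estimate")

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def _scene_targets(config, rois, spider_has_oblique):
    names = [("red_perpendicular", "red", "perpendicular"),
             ("black_simulated", "black_simulated", "perpendicular")]
    if spider_has_oblique and "red_oblique" in rois:
        names.append(("red_oblique", "red", "oblique"))
    return names


def run_imaging_experiment(
    config: ExperimentConfig, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Run the full synthetic imaging experiment.

    Returns a tidy contrast table (one row per target x patch x resolution x
    boost) and a run manifest with all derived seeds.  Deterministic given
    (config, seed).
    """
    system = build_cone_system(config.cone_config)
    master = np.random.SeedSequence(seed)
    rows: list[dict] = []
    manifest: dict = {"master_seed": seed, "scenes": [], "config": repr(config)}

    for spider in range(config.n_spiders):
        has_oblique = spider < config.n_oblique_spiders
        for leaf in range(config.leaves_per_spider):
            (scene_seed,) = master.spawn(1)
            scene_seed_int = int(scene_seed.generate_state(1)[0] % (2**31))
            spec = replace(
                config.scene, seed=scene_seed_int, include_oblique=has_oblique
            )
            stage = f"spider {spider} / leaf {leaf}"
            try:
                stack, rois = render_scene(spec, system)
                dark = subtract_dark(stack)
                adapted = adapt_to_background(dark)
                exc = naka_rushton(adapted)
                patches = sample_background_patches(
                    rois["background"],
                    n_target=config.n_patches,
                    tol=config.patch_tol,
                    size=config.patch_size,
                    seed=scene_seed_int,
                    stack=exc,
                )
            except Exception as err:  # pragma: no cover - defensive
                raise RuntimeError(f"stage failed at {stage}: {err}") from err

            leaf_id = f"s{spider:02d}l{leaf}"
            stacks = {("native", None): exc}
            for dist in config.distances_cm:
                geom = ViewingGeometry(
                    acuity_cpd=config.acuity_cpd,
                    distance_cm=dist,
                    pixel_pitch_mm=spec.pixel_pitch_mm,
                )
                stacks[("predator", dist)] = apply_acuity_blur(exc, geom)

            for (res_class, dist), res_stack in stacks.items():
                res_patches = patches
                if res_stack is not exc:
                    res_patches = replace_medians(patches, res_stack)
                targets = []
                for mask_name, color, angle in _scene_targets(config, rois, has_oblique):
                    med = roi_median_excitation(res_stack, rois[mask_name])
                    targets.append((mask_name, color, angle, med, 1.0))
                    if color == "black_simulated":
                        for factor in config.boost_factors:
                            targets.append(
                                (mask_name, color, angle,
                                 boost_excitations(med, factor), factor)
                            )
                for mask_name, color, angle, med, factor in targets:
                    recs = contrast_table(
                        [(mask_name, color, angle, med)],
                        res_patches,
                        system,
                        resolution_class=res_class,
                    )
                    for r in recs:
                        rows.append(
                            {
                                "spider_id": f"s{spider:02d}",
                                "leaf_id": leaf_id,
                                "patch_id": r.patch_id,
                                "color_class": r.color_class,
                                "angle_class": r.angle_class,
                                "resolution_class": r.resolution_class,
                                "distance_cm": dist,
                                "boost_factor": factor,
                                "chromatic": r.chromatic,
                                "achromatic": r.achromatic,
                            }
                        )
            manifest["scenes"].append(
                {
                    "spider": spider,
                    "leaf": leaf,
                    "leaf_id": leaf_id,
                    "seed": scene_seed_int,
                    "n_patches": len(patches),
                    "oblique": has_oblique,
                }
            )

    table = pd.DataFrame(rows)
    manifest["n_rows"] = len(table)
    return table, manifest


def replace_medians(patches, stack):
    """Patch set with medians recomputed on another (e.g. blurred) stack."""
    from .excitation import PatchSet

    new = PatchSet(centers=list(patches.centers), size=patches.size)
    new.medians = patch_medians(new, stack)
    return new


def cluster_bootstrap_diff(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    group_pair: tuple[str, str],
    cluster_col: str = "leaf_id",
    n_boot: int = 2000,
    seed: int = 0,
    contrast_type: str | None = None,
    effect: str = "",
) -> ComparisonResult:
    """Group mean difference with a leaf-cluster percentile bootstrap.

    The difference is mean(group_pair[0]) - mean(group_pair[1]).  Clusters
    (leaves) are resampled with replacement; each replicate recomputes the
    pooled group means over the resampled clusters.
    """
    a, b = group_pair
    df = table[table[group_col].isin(group_pair)][[group_col, cluster_col, value_col]]
    df = df.dropna(subset=[value_col])
    for g in group_pair:
        if not (df[group_col] == g).any():
            raise ValueError(f"group {g!r} absent from table")
    clusters = sorted(df[cluster_col].unique())
    if len(clusters) < 2:
        raise ValueError("cluster bootstrap needs >= 2 clusters")

    # per-cluster sufficient statistics: (sum, count) per group
    agg = df.groupby([cluster_col, group_col])[value_col].agg(["sum", "count"])
    sums = np.zeros((len(clusters), 2))
    counts = np.zeros((len(clusters), 2))
    for ci, cl in enumerate(clusters):
        for gi, g in enumerate(group_pair):
            if (cl, g) in agg.index:
                sums[ci, gi] = agg.loc[(cl, g), "sum"]
                counts[ci, gi] = agg.loc[(cl, g), "count"]

    def diff_from(idx: np.ndarray) -> float:
        s = sums[idx].sum(axis=0)
        n = counts[idx].sum(axis=0)
        if (n == 0).any():
            return np.nan
        return float(s[0] / n[0] - s[1] / n[1])

    point = diff_from(np.arange(len(clusters)))
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        reps[i] = diff_from(rng.integers(0, len(clusters), size=len(clusters)))
    reps = reps[~np.isnan(reps)]
    lo, hi = np.percentile(reps, [2.5, 97.5])
    lo, hi = min(lo, point), max(hi, point)
    return ComparisonResult(
        contrast_type=contrast_type or value_col,
        effect=effect,
        difference=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_clusters=len(clusters),
        n_boot=n_boot,
    )
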