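"""End-to-end lung parenchyma segmentation pipeline.

Stages: ROI extraction → GSLIC superpixels → GA-seeded neural forest
clustering → region identification → coarse mask assembly → refinement.
The pipeline is a pure function of (input stack, config, seed); the GA is
the only stochastic stage and draws from one seeded generator.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import clustering, identify, metrics, refine, superpixels
from .stackio import ImageStack, MaskStack, StackValidationError

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

# K = 1000 superpixels on the 300×360 ROI of a 512×512 slice; other frame
# sizes scale K with the ROI pixel count.
REFERENCE_K = 1000
REFERENCE_ROI_PIXELS = 300 * 360


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the method's published setting."""

    roi_rect: tuple[int, int, int, int] | None = None
    superpixels: int | None = None      # K; derived from ROI size when None
    delta: float = 10.0                 # GSLIC spatial weight δ
    residual: float = 1e-4              # GSLIC convergence threshold E
    window: int = 3                     # gradient window n
    n_clusters: int = 4
    generations: int = 800              # GA max generations T
    crossover: float = 0.7              # τ
    mutation: float = 0.001             # η
    ga_tol: float = 1e-4                # μ
    pop_size: int = 20
    smooth_radius: int | None = None    # 2 px at 512, scaled
    seed: int = 0

    def validate(self) -> None:
        if self.delta <= 0:
            raise StackValidationError("delta must be > 0")
        if self.residual < 0 or self.ga_tol < 0:
            raise StackValidationError("thresholds must be >= 0")
        if self.window < 1 or self.window % 2 == 0:
            raise StackValidationError("gradient window must be odd and >= 1")
        if not (0 <= self.crossover <= 1 and 0 <= self.mutation <= 1):
            raise StackValidationError("GA probabilities must lie in [0, 1]")
        if self.pop_size < 2:
            raise StackValidationError("GA population must be >= 2")
        if self.n_clusters != 4:
            raise StackValidationError("identification requires exactly 4 clusters")


@dataclass
class PipelineResult:
    final: MaskStack
    coarse: MaskStack
    labeling: identify.RegionLabeling
    spmap: superpixels.SuperpixelMap = field(repr=False)
    cluster_sets: list = field(repr=False, default=None)  # type: ignore[assignment]
    report: dict = field(default_factory=dict)


def run_pipeline(
    stack: ImageStack,
    config: PipelineConfig | None = None,
    reference: MaskStack | None = None,
) -> PipelineResult:
    """Segment a stack; optionally score the result against a reference."""
    config = config or PipelineConfig()
    config.validate()

    roi = superpixels.extract_roi(stack, config.roi_rect)
    K = config.superpixels
    if K is None:
        K = max(16, round(REFERENCE_K * roi.height * roi.width / REFERENCE_ROI_PIXELS))
    logger.info("ROI %dx%d, K=%d superpixels per slice", roi.width, roi.height, K)

    spmap = superpixels.segment_stack(
        roi, K=K, delta=config.delta, E=config.residual, n=config.window
    )
    logger.info(
        "GSLIC: %d superpixels, per-slice iterations %s",
        spmap.n_superpixels,
        spmap.iterations,
    )

    rng = np.random.default_rng(config.seed)
    sets = clustering.cluster_superpixels(
        spmap,
        K=config.n_clusters,
        T=config.generations,
        crossover=config.crossover,
        mutation=config.mutation,
        tol=config.ga_tol,
        pop_size=config.pop_size,
        rng=rng,
    )

    member_features = [spmap.features[s] for s in sets]
    labeling = identify.identify_regions(member_features)
    coarse = identify.assemble_masks(
        (sets[labeling.left_lung], sets[labeling.right_lung]), spmap
    )
    final = refine.refine_stack(coarse, radius=config.smooth_radius)

    report = {
        "seed": config.seed,
        "superpixels_per_slice_target": K,
        "grid_step": spmap.S,
        "n_superpixels": spmap.n_superpixels,
        "gslic_iterations": list(spmap.iterations),
        "cluster_sizes": [int(len(s)) for s in sets],
        "roles": {
            role: int(getattr(labeling, role)) for role in identify.ROLES
        },
        "config": asdict(config),
    }
    if reference is not None:
        report["metrics"] = {
            "volume_overlap_pct": metrics.volume_overlap(reference, final),
            "jaccard": metrics.jaccard(reference, final),
            "pri": metrics.pri(reference.data, final.data),
            "voi_bits": metrics.voi(reference.data, final.data),
        }
    return PipelineResult(
        final=final,
        coarse=coarse,
        labeling=labeling,
        spmap=spmap,
        cluster_sets=sets,
        report=report,
    )
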