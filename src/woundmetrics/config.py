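"""Shared configuration, logging, and error types.

All tunables of the measurement pipeline live in :class:`PipelineConfig` so a
single object can be recorded in every report and round-tripped through the
visit store.  Units are millimetres and pixels throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields


logger = logging.getLogger("woundmetrics")
if not logger.handlers:  # library default: quiet unless the app configures it
    logger.addHandler(logging.NullHandler())


def configure_logging(level: str = "INFO") -> None:
    """Attach a basic stderr handler (used by the CLI)."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("woundmetrics")
    root.setLevel(level.upper())
    root.addHandler(handler)


class WoundMetricsError(Exception):
    """Base class for all package errors."""


class DomainError(WoundMetricsError):
    """Inputs violate a documented precondition (bad geometry, empty mask...)."""


class DegenerateInputError(DomainError):
    """Input has no usable structure (rank-deficient, zero variance...)."""


class RefinementError(WoundMetricsError):
    """Contour refinement produced no usable region."""


class StoreError(WoundMetricsError):
    """Visit-store failure (duplicate key, missing record, corrupt asset)."""


@dataclass
class PipelineConfig:
    """Tunable parameters of the measurement pipeline.

    Attributes
    ----------
    skin_expand_factor
        Target ratio of (wound + surrounding-skin) area to wound area when
        growing the skin reference band.  1.5 reproduces a 50% expansion of
        the segmented region.
    chanvese_mu, chanvese_lambda1, chanvese_lambda2, chanvese_max_iter, chanvese_tol
        Region-based active-contour (Chan-Vese) parameters used to refine the
        user's coarse wound outline on the grayscale image.
    som_grid
        Requested SOM mesh resolution (rows, cols).  The pipeline clamps each
        side to ``floor(sqrt(n_points))`` so the map never has more nodes
        than training samples.
    som_epochs, som_lr, som_lr_final, som_radius_final
        SOM ordering-phase schedule: epochs of shuffled full passes,
        exponentially decaying learning rate and Gaussian neighborhood
        radius.
    som_conv_epochs, som_conv_radius, som_conv_lr
        SOM convergence phase: extra passes at a fixed small radius and
        rate that settle each node onto its own cell's local mean.
    boundary_smooth_sigma
        Circular Gaussian smoothing (in boundary samples) applied to the
        lifted 3D perimeter polyline before summing segment lengths; removes
        digital staircase bias and uncorrelated depth-noise inflation.
    alpha_mm
        2D alpha-shape radius for the projected area.  ``None`` selects twice
        the median nearest-neighbour spacing of the projected points.
    slic_pixels_per_segment, slic_compactness
        Superpixel granularity (wound pixels per superpixel) and SLIC
        compactness for tissue classification.
    ncc_threshold
        Minimum normalized cross-correlation for a stereo match to be valid.
    """

    skin_expand_factor: float = 1.5
    chanvese_mu: float = 0.05
    chanvese_lambda1: float = 1.0
    chanvese_lambda2: float = 1.0
    chanvese_max_iter: int = 500
    chanvese_tol: float = 1e-3
    som_grid: tuple[int, int] = (64, 64)
    som_epochs: int = 10
    som_lr: float = 0.5
    som_lr_final: float = 0.01
    som_radius_final: float = 1.0
    som_conv_epochs: int = 3
    som_conv_radius: float = 0.5
    som_conv_lr: float = 0.05
    boundary_smooth_sigma: float = 1.0
    alpha_mm: float | None = None
    slic_pixels_per_segment: int = 200
    slic_compactness: float = 10.0
    ncc_threshold: float = 0.7

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in names}
        if "som_grid" in kwargs:
            kwargs["som_grid"] = tuple(kwargs["som_grid"])
        return cls(**kwargs)
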