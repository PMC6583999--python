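"""Central numeric configuration.

All tolerances and pipeline defaults live in one frozen record so that every
module agrees on what "equal", "on the plane" or "converged" means.  Lengths
are millimetres throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace


@dataclass(frozen=True)
class Config:
    """Package-wide tolerances and defaults (mm unless noted)."""

    #: geometric identity tolerance (involution, point-on-plane checks)
    geom_tol: float = 1e-9
    #: registration convergence tolerance on RMS improvement
    reg_tol: float = 1e-6
    #: duplicate-vertex merge tolerance at mesh load time
    vertex_merge_tol: float = 1e-6

    #: default Hounsfield threshold for cortical bone segmentation
    hu_threshold: float = 226.0
    #: connected components smaller than this many voxels are discarded
    min_voxels: int = 50

    #: fracture-line resampling step
    resample_step: float = 0.5
    #: a line point is "adjacent" to another fragment within this distance
    adjacency_tol: float = 2.0
    #: articular region = vertices within this band of the fitted cup sphere
    sphere_band: float = 2.5
    #: boundary points closer than this to the intact articular rim are not
    #: fracture points (they are the joint margin, present before injury)
    rim_exclusion_tol: float = 1.5

    #: ICP surface sample size (source side)
    icp_samples: int = 5000
    #: dense target sampling used for closest-point queries
    icp_target_samples: int = 60000
    icp_max_iter: int = 60
    #: registrations worse than this RMS are flagged "unreduced"
    rms_max: float = 2.0

    #: gap-area rasterization fallback step
    raster_step: float = 0.1
    #: 2D slice emulator default thickness (max clinical CT slice thickness)
    slice_thickness: float = 2.0

    #: phantom mesh target edge length
    phantom_edge: float = 0.5

    seed: int = 0

    def with_(self, **kw) -> "Config":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT = Config()
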