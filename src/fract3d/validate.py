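"""Phantom validation study: end-to-end accuracy against known ground truth.

Mirrors a physical validation experiment: fracture a cup whose displacements
are known exactly, run the complete measurement pipeline (mirror template,
ICP virtual reduction, fracture-line extraction, profile summarization) and
compare the measured maximum gap and step-off against the truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import DEFAULT, Config
from .io import FragmentSet
from .metrics import (SphericalCupRegion, dedupe_interior, displacement_profile,
                      extract_fracture_lines, summarize)
from .phantom import PhantomSpec, make_phantom
from .reduction import build_mirror_template, reduce_fragments

log = logging.getLogger(__name__)


@dataclass
class PhantomRun:
    seed: int
    measured_max_gap: float
    measured_max_step_off: float
    true_max_gap: float
    true_max_step_off: float

    @property
    def gap_deviation(self) -> float:
        return abs(self.measured_max_gap - self.true_max_gap)

    @property
    def step_deviation(self) -> float:
        return abs(self.measured_max_step_off - self.true_max_step_off)


def run_phantom_end_to_end(seed: int, config: Config = DEFAULT,
                           **spec_kwargs) -> PhantomRun:
    """Generate one phantom and push it through the full measurement chain."""
    ph = make_phantom(PhantomSpec(seed=seed, **spec_kwargs))
    template = build_mirror_template(ph.intact, ph.symmetry_plane)
    reduction = reduce_fragments(ph.pre, template, config)
    region = SphericalCupRegion.fit(template, band=config.sphere_band)
    meshes = []
    for fid, mesh in ph.pre:
        rm = mesh.copy()
        rm.apply_transform(reduction.transforms[fid].to_matrix())
        rm.metadata["fragment_id"] = fid
        meshes.append(rm)
    reduced = FragmentSet(meshes=meshes, fragment_ids=list(ph.pre.fragment_ids))
    lines = extract_fracture_lines(reduced, region, template, config)
    profiles = dedupe_interior([
        displacement_profile(
            ln, reduction.displaced_pose(ln.fragment_id),
            reduction.displaced_pose(ln.adjacent_fragment_id)
            if ln.adjacent_fragment_id else None,
            region,
        )
        for ln in lines
    ])
    s = summarize(profiles)
    return PhantomRun(
        seed=seed,
        measured_max_gap=s.max_gap,
        measured_max_step_off=s.max_step_off,
        true_max_gap=ph.truth.max_gap,
        true_max_step_off=ph.truth.max_step_off,
    )


def validation_study(seeds, config: Config = DEFAULT, **spec_kwargs) -> dict:
    """Run the end-to-end pipeline over several seeded phantoms.

    Returns the per-phantom runs and the maximum absolute deviation of the
    measured maximum gap / step-off from ground truth (mm).
    """
    runs = [run_phantom_end_to_end(s, config, **spec_kwargs) for s in seeds]
    max_dev = max(max(r.gap_deviation, r.step_deviation) for r in runs)
    return {
        "runs": runs,
        "max_abs_deviation_mm": float(max_dev),
        "max_gap_deviation_mm": float(max(r.gap_deviation for r in runs)),
        "max_step_deviation_mm": float(max(r.step_deviation for r in runs)),
        "n": len(runs),
    }
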