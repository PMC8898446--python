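"""End-to-end reconstruction: contour stack in, watertight triangle mesh out.

Stages run in order: validation, branching resolution, keyhole removal,
minimal-area tiling of each consecutive slice pair, and sealing of the first
and last contours.  Each stage is available separately from its own module;
this driver only sequences them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .contour_model import ContourStack, validate_stack
from .mesh import SurfaceMesh, assemble
from .preprocess import KeyholeReport, remove_stack_keyholes, resolve_branching
from .sealing import CapTriangulation, seal_cap
from .tiling import TilingPath, tile_stack


@dataclass
class ReconstructionResult:
    """The mesh plus the intermediate products of every stage."""

    mesh: SurfaceMesh
    tilings: List[TilingPath]
    caps: List[CapTriangulation]
    keyhole_reports: List[KeyholeReport] = field(default_factory=list)


def reconstruct(
    stack: ContourStack,
    normalize: bool = True,
    keyhole_threshold: Optional[float] = None,
    seal: bool = True,
    start: str = "closest",
) -> ReconstructionResult:
    """Run the full pipeline on a validated contour stack.

    Parameters
    ----------
    stack : ordered contour stack (strictly increasing z).
    normalize : optimize tile areas on normalized contours (recommended;
        protects offset sections from collapsing into double cones).
    keyhole_threshold : conflict distance in mm; ``None`` chooses
        1.5x the median edge length per contour.
    seal : close the first and last contours with planar caps.
    start : ``"closest"`` or ``"exhaustive"`` start-span strategy.

    Raises
    ------
    ValueError
        If the stack fails validation.
    """
    problems = validate_stack(stack)
    if problems:
        raise ValueError("invalid contour stack: " + "; ".join(problems))
    branched = resolve_branching(stack)
    cleaned, reports = remove_stack_keyholes(branched, threshold=keyhole_threshold)
    tilings = tile_stack(cleaned, normalize=normalize, start=start)
    caps: List[CapTriangulation] = []
    if seal:
        for c in cleaned.slices[0].contours:
            caps.append(seal_cap(c, "down"))
        for c in cleaned.slices[-1].contours:
            caps.append(seal_cap(c, "up"))
    mesh = assemble(cleaned, tilings, caps)
    return ReconstructionResult(mesh=mesh, tilings=tilings, caps=caps,
                                keyhole_reports=reports)
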