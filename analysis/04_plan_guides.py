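#!/usr/bin/env python
"""Reverse-sequence planning: osteotomize, reposition, place PSI drill holes
on the planned anatomy, transpose the moving-segment holes backward, and
build drilling/cutting guides on the pre-op anatomy.

Verifies the hole-matching contract: holes drilled through the guides line
up with the PSI pattern only under the planned repositioning.
"""

import json
from pathlib import Path

from zygoplan.phantom import PhantomParams, default_hole_requests, generate_phantom
from zygoplan.planning import make_plan, verify_plan
from zygoplan.registration import recover_malunion_alignment

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    case = generate_phantom(PhantomParams(seed=SEED))
    _, _, fine = recover_malunion_alignment(
        case.preop_mesh,
        case.segment_outer_surface(),
        case.landmarks_preop,
        case.segment_landmark_names,
        seed=SEED,
    )
    plan, _, _ = make_plan(
        case.preop_mesh,
        fine.transform,
        case.osteotomy_preop,
        default_hole_requests(case, fine.transform),
        precut=(case.moving_preop, case.stable),
        build_guide_meshes=True,
    )
    plan.to_json(OUT / "04_plan.json", mesh_dir=OUT / "04_plan_meshes")
    report = verify_plan(plan, tol_mm=1e-9)
    (OUT / "04_verification.json").write_text(json.dumps(report, indent=2))
    print(f"plan: {len(plan.holes_planned)} holes "
          f"({sum(h.role == 'moving' for h in plan.holes_planned)} moving), "
          f"{len(plan.guides)} guides, {len(plan.psi_footprints)} PSI footprints")
    print(f"verification pass: {report['pass']}, "
          f"max hole deviation {report['max_deviation_mm']:.2e} mm")
    assert report["pass"]


if __name__ == "__main__":
    main()
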