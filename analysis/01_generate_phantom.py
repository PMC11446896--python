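#!/usr/bin/env python
"""Build the study phantom: a skull-like surface with a known malunion.

Writes the case directory (meshes, landmarks, ground truth) plus a
soft-tissue envelope under results/case/ and prints the case summary.
"""

import json
from pathlib import Path

import numpy as np

from zygoplan.geometry import write_mesh
from zygoplan.phantom import PhantomParams, generate_phantom, soft_tissue_surface

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    params = PhantomParams(seed=SEED)
    case = generate_phantom(params)
    d = case.write(OUT / "case")
    soft = soft_tissue_surface(case.preop_mesh, params.soft_tissue_thickness_mm)
    write_mesh(soft, d / "soft_pre.ply", "ply")

    t = case.ground_truth_malunion
    summary = {
        "seed": SEED,
        "intact_faces": len(case.intact_mesh.faces),
        "preop_faces": len(case.preop_mesh.faces),
        "segment_faces": len(case.moving_preop.faces),
        "malunion_translation_mm": [float(v) for v in params.malunion_translation_mm],
        "malunion_rotation_deg": params.malunion_rotation_deg,
        "malunion_displacement_at_apex_mm": float(
            np.linalg.norm(
                t.apply(case.landmarks_intact.get("zygoma_apex", "right"))
                - case.landmarks_intact.get("zygoma_apex", "right")
            )
        ),
        "landmarks": len(case.landmarks_preop),
    }
    (OUT / "01_phantom.json").write_text(json.dumps(summary, indent=2))
    print("phantom case written to", d)
    for k, v in summary.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
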