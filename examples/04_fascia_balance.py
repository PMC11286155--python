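"""Find the minimum temporal-fascia force that balances the zygomatic arch.

The masseter pulls the arch inferiorly; the temporal fascia, inserting on
the arch's superior border, resists that deflection.  Exploiting
linearity, the balancing force follows from one baseline solve and one
unit-fascia sensitivity solve (s* = -u0/du at the arch mid-span).
Runs the calibrated default 48-month surrogate (~1 minute).
"""

import json

from cranioload import SkullParams, SkullModel, build_skull_mesh, solve_tff

forces = {"temporalis": 87.0, "masseter": 69.6, "medial_pterygoid": 58.9}

mesh = build_skull_mesh(SkullParams(age_months=48))
model = SkullModel(mesh)
system = model.system(1)  # bilateral molar bite constraints

res = solve_tff(
    mesh,
    system,
    model.muscle_loads(forces),
    model.unit_loads("temporal_fascia"),
    forces,
)
print(json.dumps(res.to_dict(age_months=48, mode="bilateral_molar"), indent=2))
print(f"\nThe arch needs {res.tff_per_side_N:.1f} N of fascia force per side "
      f"to null its mid-span inferior deflection — "
      f"{res.ratio_masseter_pct:.0f}% of the applied masseter force and "
      f"{res.ratio_temporalis_pct:.0f}% of the temporalis force.")
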