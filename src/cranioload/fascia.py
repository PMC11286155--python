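"""Temporal-fascia force balancing.

The temporal fascia inserts along the superior border of the zygomatic
arch and counteracts the masseter's inferior pull on the arch.  Its force
is not measurable in infants, so it is *estimated*: the minimum fascia
force (TFF) that removes the inferior deflection of the arch mid-span
under the muscle loads.  Because the model is linear, the balancing scale
is found from one baseline solve and one unit-fascia sensitivity solve,
s* = -u0 / du, instead of an iterative search; a bisection search over the
scale is used as an independent oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegeneracyError, DomainError
from .fem import FactorizedSystem
from .mesh import LabelledTetMesh


@dataclass(frozen=True)
class BalanceCriterion:
    """Zero inferior (-z) displacement at each arch mid-span control node."""

    tolerance_mm: float = 1e-6
    control_sets: tuple[str, str] = ("arch_mid_L", "arch_mid_R")


@dataclass
class FasciaSolveResult:
    """Balanced temporal-fascia force and its ratios to the jaw muscles."""

    tff_per_side_N: float
    scale: float
    ratio_masseter_pct: float
    ratio_temporalis_pct: float
    residual_mm: float
    per_arch_scale: dict[str, float]
    warning: str | None = None

    def to_dict(self, age_months: float | None = None, mode: str | None = None) -> dict:
        return {
            "age": age_months,
            "tff_N_per_side": self.tff_per_side_N,
            "ratio_masseter_pct": self.ratio_masseter_pct,
            "ratio_temporalis_pct": self.ratio_temporalis_pct,
            "residual_mm": self.residual_mm,
            "mode": mode,
        }


def _control_uz(mesh: LabelledTetMesh, u: np.ndarray, criterion: BalanceCriterion) -> dict:
    out = {}
    for name in criterion.control_sets:
        node = int(mesh.node_sets[name][0])
        out[name] = float(u[node, 2])
    return out


def solve_tff(
    mesh: LabelledTetMesh,
    system: FactorizedSystem,
    muscle_loads: np.ndarray,
    fascia_unit_loads: np.ndarray,
    muscle_forces_per_side: dict[str, float],
    criterion: BalanceCriterion | None = None,
    verify: bool = True,
) -> FasciaSolveResult:
    """Minimum fascia force that balances both zygomatic arches.

    ``fascia_unit_loads`` must be the nodal load case of a fascia vector
    set with **1 N per side** total, so the returned scale *is* the TFF per
    side in newtons.  Both arches must satisfy the criterion; the larger
    required scale is used.  If the arch mid-span is not deflected
    inferiorly at all, TFF = 0 is returned with a warning.
    """
    criterion = criterion or BalanceCriterion()
    base = system.solve(muscle_loads)
    sens = system.solve(fascia_unit_loads)
    u0 = _control_uz(mesh, base.u, criterion)
    du = _control_uz(mesh, sens.u, criterion)

    per_arch = {}
    warning = None
    for name in criterion.control_sets:
        if u0[name] >= 0.0:
            per_arch[name] = 0.0
            warning = f"{name}: arch not deflected inferiorly (u0={u0[name]:.3g} mm)"
            continue
        if abs(du[name]) < 1e-15:
            raise DegeneracyError(
                f"{name}: fascia load cannot move the control node (du ~ 0)"
            )
        per_arch[name] = max(0.0, -u0[name] / du[name])
    s = max(per_arch.values())

    residual = 0.0
    if verify and s > 0:
        check = system.solve(muscle_loads + s * fascia_unit_loads)
        uz = _control_uz(mesh, check.u, criterion)
        governing = max(per_arch, key=per_arch.get)
        residual = abs(uz[governing])
        if residual > criterion.tolerance_mm:
            raise DegeneracyError(
                f"balance verification failed: |uz|={residual:.3e} mm at {governing}"
            )

    f_mas = muscle_forces_per_side.get("masseter", np.nan)
    f_tmp = muscle_forces_per_side.get("temporalis", np.nan)
    return FasciaSolveResult(
        tff_per_side_N=s,
        scale=s,
        ratio_masseter_pct=100.0 * s / f_mas,
        ratio_temporalis_pct=100.0 * s / f_tmp,
        residual_mm=residual,
        per_arch_scale=per_arch,
        warning=warning,
    )


def scale_tff_by_arch_length(
    tff_ref_N: float, arch_length_ref_mm: float, arch_length_target_mm: float
) -> float:
    """Transfer a balanced TFF across ages by force-per-millimetre scaling.

    TFF_target = (TFF_ref / L_ref) x L_target, mirroring the published
    procedure of scaling fascia forces with effective arch length.
    """
    if arch_length_ref_mm <= 0 or arch_length_target_mm <= 0:
        raise DomainError("arch lengths must be positive")
    return tff_ref_N / arch_length_ref_mm * arch_length_target_mm
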