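"""Bite simulations: loads, constraints, solves and extraction.

For each (age, bite mode, fascia flag) the pipeline builds per-age muscle
forces from the growth model, assembles the landmark-based force vectors,
optionally adds the balanced temporal-fascia load, constrains the bite
points and both TMJs against displacement in all directions, solves the
elastic problem and reports the bite force (reaction at the bite
constraints), per-side TMJ reactions and von Mises strain/stress at nine
facial probe locations.  A rigid-body equilibrium oracle cross-checks the
force balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fascia as fascia_mod
from .anatomy import SkullParams, SuturePatencySchedule, build_skull_mesh
from .errors import DomainError, NodeSetLookupError
from .fem import (
    AgeMaterialModel,
    ConstraintSet,
    FactorizedSystem,
    FieldResult,
    Solution,
    assemble,
    element_materials,
    strain_stress,
)
from .mesh import LabelledTetMesh
from .muscle import GrowthModel, MuscleConstants, build_vectors, vectors_to_loads

BITE_MODES = (1, 2, 3)
ERUPTION_AGE_MONTHS = 12.0  # bite points move from alveolar margin to cusps

FACIAL_LABELS = ("facial", "zygomatic_arch_L", "zygomatic_arch_R")
CALVARIAL_LABELS = ("frontal", "parietal", "occipital")


def bite_node_sets(mesh: LabelledTetMesh, mode: int, age_months: float) -> dict[str, np.ndarray]:
    """Constrained bite node sets for a mode, eruption-aware.

    Before ~12 months the bite points sit on the alveolar ridge margin;
    after eruption on the raised cusp nodes.
    """
    if mode not in BITE_MODES:
        raise DomainError(f"unknown bite mode {mode}")
    pre = "_pre" if age_months < ERUPTION_AGE_MONTHS else ""
    if mode == 1:
        names = [f"bite_molar{pre}_L", f"bite_molar{pre}_R"]
    elif mode == 2:
        names = [f"bite_incisor{pre}"]
    else:
        names = [f"bite_molar{pre}_L"]
    out = {}
    for n in names:
        if n not in mesh.node_sets:
            raise NodeSetLookupError(f"mesh lacks node set {n!r}")
        out[n] = mesh.node_sets[n]
    return out


def constraints_for_mode(mesh: LabelledTetMesh, mode: int, age_months: float) -> ConstraintSet:
    bite = bite_node_sets(mesh, mode, age_months)
    roles: dict[int, str] = {}
    nodes: list[int] = []
    for ns in bite.values():
        for n in ns:
            roles[int(n)] = "bite"
            nodes.append(int(n))
    for side in ("L", "R"):
        for n in mesh.node_sets[f"tmj_{side}"]:
            roles[int(n)] = "tmj"
            nodes.append(int(n))
    return ConstraintSet(nodes=np.asarray(nodes), roles=roles)


class SkullModel:
    """One age's surrogate with cached stiffness, factorizations and
    unit load cases (the model is linear, so muscle loads are assembled
    from per-muscle unit-force load cases)."""

    def __init__(
        self,
        mesh: LabelledTetMesh,
        material_model: AgeMaterialModel | None = None,
        constants: MuscleConstants | None = None,
    ):
        self.mesh = mesh
        self.age = float(mesh.metadata["age_months"])
        self.material_model = material_model or AgeMaterialModel()
        self.constants = constants or MuscleConstants()
        self.E, self.nu = element_materials(mesh, self.age, self.material_model)
        self._K = None
        self._systems: dict[int, FactorizedSystem] = {}
        self._unit_loads: dict[str, np.ndarray] = {}
        self._vol_by_node = None

    @property
    def K(self):
        if self._K is None:
            self._K = assemble(self.mesh, self.E, self.nu)
        return self._K

    def system(self, mode: int) -> FactorizedSystem:
        if mode not in self._systems:
            # keep a single factorization: each holds ~0.5 GB of LU factors
            self._systems.clear()
            cons = constraints_for_mode(self.mesh, mode, self.age)
            self._systems[mode] = FactorizedSystem(self.K, cons, self.mesh.nodes)
        return self._systems[mode]

    def unit_loads(self, tag: str) -> np.ndarray:
        """Nodal loads for 1 N per side of one muscle (or the fascia)."""
        if tag not in self._unit_loads:
            if tag == "temporal_fascia":
                vs = build_vectors(
                    self.mesh, {}, self.constants,
                    include_fascia=True, fascia_force_per_side=1.0,
                )
            else:
                vs = build_vectors(self.mesh, {tag: 1.0}, self.constants)
            self._unit_loads[tag] = vectors_to_loads(self.mesh, vs)
        return self._unit_loads[tag]

    def muscle_loads(self, forces_per_side: dict[str, float]) -> np.ndarray:
        f = np.zeros((self.mesh.n_nodes, 3))
        for m, val in forces_per_side.items():
            f = f + val * self.unit_loads(m)
        return f


@dataclass
class BiteResult:
    """Outputs of one (age, mode, fascia) bite simulation."""

    age_months: float
    mode: int
    with_fascia: bool
    bite_force_N: float          # sum of reaction-vector magnitudes, bite nodes
    bite_force_z_N: float        # occlusal (z) component sum
    bite_left_N: float
    bite_right_N: float
    tmj_left_N: float            # magnitude of the per-side summed reaction
    tmj_right_N: float
    muscle_forces_N: dict[str, float]
    tff_per_side_N: float
    fascia_result: fascia_mod.FasciaSolveResult | None
    probe_table: pd.DataFrame
    field_summary: dict[str, float]
    solution: Solution = field(repr=False, default=None)
    fields: FieldResult = field(repr=False, default=None)


def probe_fields(
    mesh: LabelledTetMesh, fields: FieldResult, probe_ids=range(1, 10)
) -> pd.DataFrame:
    """Nodal von Mises values at the facial probes.

    The nodal value is the volume-weighted average of the adjoining
    elements' element values.  Includes the mirror-image node's strain so
    left/right asymmetry can be quantified.
    """
    vol = mesh.volumes()
    mirror = mesh.mirror_node_map()
    rows = []
    for pid in probe_ids:
        key = f"probe_{pid}"
        if key not in mesh.node_sets:
            raise NodeSetLookupError(f"mesh lacks probe {pid}")
        node = int(mesh.node_sets[key][0])

        def nodal(n, arr):
            els = np.flatnonzero((mesh.tets == n).any(axis=1))
            w = vol[els]
            return float(np.average(arr[els], weights=w))

        rows.append(
            (
                pid,
                nodal(node, fields.vm_strain),
                nodal(node, fields.vm_stress),
                nodal(int(mirror[node]), fields.vm_strain),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["probe", "vm_strain_microstrain", "vm_stress_MPa",
                 "vm_strain_mirror_microstrain"],
    )


def _group_reaction(sol: Solution, nodes: np.ndarray) -> np.ndarray:
    return sol.reactions[np.asarray(nodes, dtype=int)].sum(axis=0)


def _field_summary(mesh: LabelledTetMesh, fields: FieldResult) -> dict[str, float]:
    vol = mesh.volumes()
    facial = mesh.elements_with_label(*FACIAL_LABELS)
    calv = mesh.elements_with_label(*CALVARIAL_LABELS)

    def wmedian(idx):
        v = fields.vm_strain[idx]
        order = np.argsort(v)
        cw = np.cumsum(vol[idx][order])
        return float(v[order][np.searchsorted(cw, 0.5 * cw[-1])])

    return {
        "median_facial_vm_strain": wmedian(facial),
        "median_calvarial_vm_strain": wmedian(calv),
        "peak_facial_vm_strain": float(fields.vm_strain[facial].max()),
        "peak_facial_vm_stress": float(fields.vm_stress[facial].max()),
    }


def run_bite(
    model: SkullModel,
    mode: int,
    with_fascia: bool,
    growth: GrowthModel | None = None,
    muscle_forces: dict[str, float] | None = None,
    keep_fields: bool = False,
) -> BiteResult:
    """Solve one bite load case and extract forces and probe fields.

    Muscle forces come from ``growth`` evaluated at the model's age unless
    ``muscle_forces`` (N per side) is given explicitly.  With
    ``with_fascia`` the balanced temporal-fascia force is determined first
    (affine solve on the same factorized system) and added.
    """
    if muscle_forces is None:
        if growth is None:
            raise DomainError("either a growth model or explicit forces are required")
        muscle_forces = growth.forces_at(model.age)
    system = model.system(mode)
    f_muscle = model.muscle_loads(muscle_forces)

    tff = 0.0
    fas_res = None
    if with_fascia:
        f_unit = model.unit_loads("temporal_fascia")
        fas_res = fascia_mod.solve_tff(
            model.mesh, system, f_muscle, f_unit, muscle_forces
        )
        tff = fas_res.tff_per_side_N
        loads = f_muscle + tff * f_unit
    else:
        loads = f_muscle

    sol = system.solve(loads)
    fields = strain_stress(model.mesh, model.E, model.nu, sol)

    bite_sets = bite_node_sets(model.mesh, mode, model.age)
    per_node_mag = {
        name: float(np.linalg.norm(sol.reactions[np.asarray(ns, int)], axis=1).sum())
        for name, ns in bite_sets.items()
    }
    bite_nodes = np.concatenate([np.asarray(v, int) for v in bite_sets.values()])
    bite_force = float(np.linalg.norm(sol.reactions[bite_nodes], axis=1).sum())
    bite_z = float(sol.reactions[bite_nodes, 2].sum())
    left = sum(v for k, v in per_node_mag.items() if "_L" in k)
    right = sum(v for k, v in per_node_mag.items() if "_R" in k)
    if mode == 2:  # incisor set spans both sides; split by node x sign
        inc = np.asarray(next(iter(bite_sets.values())), int)
        mags = np.linalg.norm(sol.reactions[inc], axis=1)
        left = float(mags[model.mesh.nodes[inc, 0] > 0].sum())
        right = float(mags[model.mesh.nodes[inc, 0] < 0].sum())

    return BiteResult(
        age_months=model.age,
        mode=mode,
        with_fascia=with_fascia,
        bite_force_N=bite_force,
        bite_force_z_N=bite_z,
        bite_left_N=left,
        bite_right_N=right,
        tmj_left_N=float(np.linalg.norm(_group_reaction(sol, model.mesh.node_sets["tmj_L"]))),
        tmj_right_N=float(np.linalg.norm(_group_reaction(sol, model.mesh.node_sets["tmj_R"]))),
        muscle_forces_N=dict(muscle_forces),
        tff_per_side_N=tff,
        fascia_result=fas_res,
        probe_table=probe_fields(model.mesh, fields),
        field_summary=_field_summary(model.mesh, fields),
        solution=sol if keep_fields else None,
        fields=fields if keep_fields else None,
    )


@dataclass
class ResultTable:
    """Factorial sweep results: one row per run plus per-age derived ratios."""

    runs: pd.DataFrame
    summary: pd.DataFrame
    results: dict = field(default_factory=dict, repr=False)


def run_series(
    ages=(3, 6, 12, 24, 36, 48),
    modes=BITE_MODES,
    fascia_flags=(False, True),
    growth: GrowthModel | None = None,
    skull_params: SkullParams | None = None,
    schedule: SuturePatencySchedule | None = None,
    material_model: AgeMaterialModel | None = None,
    constants: MuscleConstants | None = None,
) -> ResultTable:
    """Full factorial sweep over (age, mode, fascia flag).

    Failed cells are recorded with their error and do not abort the sweep.
    The summary table carries, per age: the mode2/mode1 bite-force ratio,
    the per-mode fascia bite-force reduction and the TFF/muscle ratios.
    """
    if growth is None:
        raise DomainError("run_series needs a growth model")
    base = skull_params or SkullParams()
    rows = []
    results: dict = {}
    for age in ages:
        try:
            mesh = build_skull_mesh(
                SkullParams(**{**base.__dict__, "age_months": float(age)}), schedule
            )
            model = SkullModel(mesh, material_model, constants)
        except Exception as exc:  # geometry failure poisons the whole age
            for mode in modes:
                for flag in fascia_flags:
                    rows.append({"age_months": age, "mode": mode,
                                 "with_fascia": flag, "error": repr(exc)})
            continue
        for mode in modes:
            for flag in fascia_flags:
                try:
                    r = run_bite(model, mode, flag, growth)
                    results[(age, mode, flag)] = r
                    rows.append(
                        {
                            "age_months": age,
                            "mode": mode,
                            "with_fascia": flag,
                            "bite_force_N": r.bite_force_N,
                            "bite_force_z_N": r.bite_force_z_N,
                            "tmj_left_N": r.tmj_left_N,
                            "tmj_right_N": r.tmj_right_N,
                            "tff_per_side_N": r.tff_per_side_N,
                            **{f"force_{k}_N": v for k, v in r.muscle_forces_N.items()},
                            **r.field_summary,
                            "error": None,
                        }
                    )
                except Exception as exc:
                    rows.append({"age_months": age, "mode": mode,
                                 "with_fascia": flag, "error": repr(exc)})
    runs = pd.DataFrame(rows)
    summary = _summarize(runs)
    return ResultTable(runs=runs, summary=summary, results=results)


def _summarize(runs: pd.DataFrame) -> pd.DataFrame:
    out = []
    if runs.empty or "bite_force_N" not in runs.columns:
        return pd.DataFrame(
            columns=["age_months", "mode2_over_mode1_pct", "fascia_reduction_mode1_pct",
                     "tff_ratio_masseter_pct", "tff_ratio_temporalis_pct"])
    for age, grp in runs[runs["error"].isna()].groupby("age_months"):
        def bite(mode, flag):
            sel = grp[(grp["mode"] == mode) & (grp["with_fascia"] == flag)]
            return float(sel["bite_force_N"].iloc[0]) if len(sel) else np.nan

        row = {"age_months": age}
        b1, b2 = bite(1, False), bite(2, False)
        row["mode2_over_mode1_pct"] = 100.0 * b2 / b1 if b1 else np.nan
        for mode in (1, 2, 3):
            b_no, b_yes = bite(mode, False), bite(mode, True)
            row[f"fascia_reduction_mode{mode}_pct"] = (
                100.0 * (b_no - b_yes) / b_no if np.isfinite(b_no) and b_no else np.nan
            )
        wf = grp[grp["with_fascia"]]
        if len(wf) and "tff_per_side_N" in wf:
            tff = float(wf["tff_per_side_N"].iloc[0])
            row["tff_per_side_N"] = tff
            fm = wf["force_masseter_N"].iloc[0] if "force_masseter_N" in wf else np.nan
            ft = wf["force_temporalis_N"].iloc[0] if "force_temporalis_N" in wf else np.nan
            row["tff_ratio_masseter_pct"] = 100.0 * tff / fm
            row["tff_ratio_temporalis_pct"] = 100.0 * tff / ft
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# rigid-body equilibrium oracle
# ---------------------------------------------------------------------------


def rigid_equilibrium_oracle(
    mesh: LabelledTetMesh,
    loads: np.ndarray,
    mode: int,
    age_months: float | None = None,
) -> dict:
    """Rigid-body statics prediction of bite and TMJ resultants.

    Treats the skull as rigid with point supports at the bite-point
    centroid(s) and per-side TMJ centroids.  Bite reactions are assumed
    purely occlusal (z); TMJ reactions are full 3-vectors.  The 6
    force/moment balance equations are solved by (min-norm) least squares
    — exactly determined for the symmetric bilateral modes, per the
    published lever interpretation.  Used to cross-check FEM totals and to
    calibrate the default geometry.
    """
    age = age_months if age_months is not None else float(mesh.metadata["age_months"])
    bite_sets = bite_node_sets(mesh, mode, age)
    groups = [(name, mesh.nodes[np.asarray(ns, int)].mean(axis=0))
              for name, ns in bite_sets.items()]
    tmj = [(f"tmj_{s}", mesh.nodes[np.asarray(mesh.node_sets[f"tmj_{s}"], int)].mean(axis=0))
           for s in ("L", "R")]

    f = np.asarray(loads, dtype=float)
    F_app = f.sum(axis=0)
    M_app = np.cross(mesh.nodes, f).sum(axis=0)

    cols = []
    meta = []
    ez = np.array([0.0, 0.0, 1.0])
    for name, p in groups:
        cols.append(np.concatenate([ez, np.cross(p, ez)]))
        meta.append((name, "z"))
    for name, p in tmj:
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = 1.0
            cols.append(np.concatenate([e, np.cross(p, e)]))
            meta.append((name, "xyz"[ax]))
    A = np.column_stack(cols)
    b = -np.concatenate([F_app, M_app])
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = A @ sol - b

    reactions: dict[str, np.ndarray] = {}
    for (name, ax), val in zip(meta, sol):
        r = reactions.setdefault(name, np.zeros(3))
        r["xyz".index(ax)] += val
    bite_total = float(sum(abs(reactions[name][2]) for name, _ in groups))
    return {
        "reactions": reactions,
        "bite_force_N": bite_total,
        "tmj_left_N": float(np.linalg.norm(reactions["tmj_L"])),
        "tmj_right_N": float(np.linalg.norm(reactions["tmj_R"])),
        "equation_residual": float(np.linalg.norm(resid)),
    }


def equilibrium_residual(mesh: LabelledTetMesh, loads: np.ndarray, sol: Solution) -> float:
    """Relative force+moment balance residual of an FEM run (Newton check)."""
    f = np.asarray(loads, float)
    total_f = f.sum(axis=0) + sol.reactions.sum(axis=0)
    total_m = (np.cross(mesh.nodes, f) + np.cross(mesh.nodes, sol.reactions)).sum(axis=0)
    scale = np.linalg.norm(f) + 1e-30
    mscale = np.linalg.norm(np.cross(mesh.nodes, f)) + 1e-30
    return float(np.linalg.norm(total_f) / scale + np.linalg.norm(total_m) / mscale)


def save_results(table: ResultTable, out_dir, mesh: LabelledTetMesh | None = None):
    """Write the sweep to disk: runs/summary CSVs, per-run probe CSV, and
    (when result objects are retained) VTU field files."""
    from pathlib import Path

    from .vtu import write_fields_vtu

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.runs.to_csv(out / "runs.csv", index=False)
    table.summary.to_csv(out / "summary.csv", index=False)
    probes = []
    for (age, mode, flag), r in table.results.items():
        t = r.probe_table.copy()
        t.insert(0, "age_months", age)
        t.insert(1, "mode", mode)
        t.insert(2, "with_fascia", flag)
        probes.append(t)
    if probes:
        pd.concat(probes, ignore_index=True).to_csv(out / "probes.csv", index=False)
    if mesh is not None:
        for (age, mode, flag), r in table.results.items():
            if r.fields is not None:
                write_fields_vtu(
                    mesh, r.fields, r.solution,
                    out / f"fields_age{age}_mode{mode}_{'tff' if flag else 'notff'}.vtu",
                )
    return out
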