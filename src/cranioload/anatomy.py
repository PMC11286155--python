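"""Synthetic craniofacial anatomy.

The clinical CT reconstructions behind the original analysis are not
public, so this module generates every input the pipeline needs:

* a parametric, age-scaled *skull surrogate* — an ellipsoidal calvarial
  shell, a skull-base plate, a facial plate with an alveolar/palatal
  ridge, and tubular zygomatic arches — voxelized from signed-distance
  primitives and split into tetrahedra, carrying bone/suture region
  labels, 42 muscle landmarks, bite points, TMJ nodes and 9 facial
  probe points;
* a synthetic cohort of per-individual muscle cross-sectional areas
  (CSAs) with configurable growth trajectories and multiplicative
  lognormal noise;
* labelled voxel masks of simple solids for exercising the CSA
  sectioning protocol.

The surrogate is stylized: only the topology and the lever geometry
(muscle attachments, bite points and joints relative to one another)
matter for the mechanics, not anatomical realism.  It is exactly
mirror-symmetric about the mid-sagittal plane by construction (one half
is voxelized and reflected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import PchipInterpolator

from .errors import DomainError, ResolutionError
from .mesh import REGION_LABELS, SUTURE_LABELS, LabelledTetMesh

MUSCLES = ("temporalis", "masseter", "medial_pterygoid")

#: Mean per-side muscle forces (N) at 3 and 48 months used to anchor the
#: synthetic CSA cohort (CSA anchor = force / 37 N cm^-2).
ANCHOR_FORCES_N = {
    "temporalis": (30.9, 87.0),
    "masseter": (25.6, 69.6),
    "medial_pterygoid": (23.1, 58.9),
}

MUSCLE_STRESS_FACTOR = 37.0  # N / cm^2

_AGE_MIN, _AGE_MAX = 3.0, 48.0


def head_scale(age_months: float) -> float:
    """Linear head-dimension scale relative to the 48-month reference.

    Rises quickly in the first year and slows later (square-root law),
    from ~0.78 at 3 months to 1.0 at 48 months, mimicking head growth.
    """
    a = np.clip(age_months, _AGE_MIN, _AGE_MAX)
    return 0.78 + 0.22 * np.sqrt((a - _AGE_MIN) / (_AGE_MAX - _AGE_MIN))


# ---------------------------------------------------------------------------
# skull surrogate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SkullParams:
    """Parameters of the surrogate skull at the 48-month reference scale.

    All lengths are mm at 48 months; the builder rescales them to the
    requested age (facial height uses the extra ``facial_growth_exponent``
    so the face grows faster in height than in width).  The default values
    are the calibrated reference geometry: they were fixed once, using the
    rigid-body lever oracle and scaled finite-element runs, so that the
    surrogate reproduces the published force *ratios* (incisor/molar bite
    ratio, fascia/masseter balance), and are frozen here.
    """

    age_months: float = 48.0
    ax: float = 55.0          # calvaria semi-axis, x (half breadth)
    ay: float = 70.0          # calvaria semi-axis, y (half length)
    az: float = 50.0          # calvaria semi-axis, z (half height)
    shell_thickness: float = 7.0
    face_height: float = 60.0
    face_width: float = 60.0
    face_depth: float = 10.0
    palate_depth: float = 28.0
    palate_width: float = 52.0
    arch_radius: float = 3.0
    arch_post_x: float = 32.0   # posterior arch attachment (on shell)
    arch_post_y: float = -10.0
    arch_z: float = -13.0
    base_shrink: float = 0.80   # base-plate footprint vs calvaria outline
    arch_bulge: float = 10.0    # lateral bow component of the free span
    arch_sag: float = 0.0       # inferior bow component
    suture_width: float = 2.0   # at 3 months, scaled with age
    voxel_pitch: float = 3.0    # at 48 months, scaled with age
    facial_growth_exponent: float = 1.25
    # calibrated load/constraint geometry (fractions along natural spans)
    molar_y_frac: float = 0.74      # molar bite point, fraction of face y
    molar_x: float = 20.0
    tmj_x: float = 27.0
    tmj_dy: float = 3.0
    masseter_spans: tuple[float, float, float] = (0.03, 0.15, 0.28)
    fascia_spans: tuple[float, float, float] = (0.38, 0.48, 0.58)
    seed: int = 0

    def validate(self) -> None:
        lengths = (
            self.ax, self.ay, self.az, self.shell_thickness, self.face_height,
            self.face_width, self.face_depth, self.palate_depth,
            self.palate_width, self.arch_radius, self.suture_width,
            self.voxel_pitch,
        )
        if any(v <= 0 for v in lengths):
            raise DomainError("all lengths must be positive")
        if not (_AGE_MIN <= self.age_months <= _AGE_MAX):
            raise DomainError(
                f"age {self.age_months} months outside model domain [3, 48]"
            )
        if self.suture_width >= min(self.face_depth, self.shell_thickness) * 4:
            raise DomainError("suture band width too large for the plates")
        if self.shell_thickness < 2.0 * self.voxel_pitch:
            raise ResolutionError(
                "voxel pitch too coarse: shell must be >= 2 voxels thick "
                f"(thickness {self.shell_thickness} mm, pitch {self.voxel_pitch} mm)"
            )


@dataclass(frozen=True)
class SuturePatencySchedule:
    """Which suture bands are still patent (compliant) at each age.

    ``stages`` maps an age breakpoint (months) to the set of active suture
    labels from that age on; the active set at an age is the entry of the
    largest breakpoint not exceeding it.  Later sets must be subsets of
    earlier ones (sutures only ever close).
    """

    stages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ages = sorted(self.stages)
        if not ages:
            raise DomainError("schedule needs at least one stage")
        for a, b in zip(ages, ages[1:]):
            if not set(self.stages[b]) <= set(self.stages[a]):
                raise DomainError("suture patency must be monotone (closing only)")
        for s in self.stages.values():
            unknown = set(s) - set(SUTURE_LABELS)
            if unknown:
                raise DomainError(f"unknown suture labels {sorted(unknown)}")

    def active(self, age_months: float) -> frozenset:
        ages = sorted(self.stages)
        if age_months < ages[0]:
            raise DomainError(f"age {age_months} before first schedule stage")
        current = ages[0]
        for a in ages:
            if a <= age_months:
                current = a
        return frozenset(self.stages[current])


def default_schedule() -> SuturePatencySchedule:
    """Patency stages of the reference models.

    3 months: facial, calvarial and skull-base joints all open; 6 months:
    calvarial sutures and fontanelle only; 12 months: anterior fontanelle
    only; 24 months on: none.
    """
    calvarial = {"metopic", "coronal", "sagittal", "lambdoid", "anterior_fontanelle"}
    return SuturePatencySchedule(
        stages={
            3: calvarial | {"facial_suture", "base_joint"},
            6: set(calvarial),
            12: {"anterior_fontanelle"},
            24: set(),
        }
    )


@dataclass(frozen=True)
class _Dims:
    """Age-scaled geometry derived from :class:`SkullParams`."""

    s: float
    sf: float
    pitch: float
    ax: float
    ay: float
    az: float
    cz: float
    th: float
    yf0: float
    yf1: float
    zf0: float
    zf1: float
    wf: float
    wp: float
    yp0: float
    zp1: float
    zb0: float
    zb1: float
    base_shrink: float
    arch_r: float
    arch_a: np.ndarray
    arch_b: np.ndarray
    arch_c: np.ndarray      # Bezier control point (lateral bow)
    arch_poly: np.ndarray   # sampled centreline, anterior -> posterior
    arch_len: float
    y_cor: float
    y_lam: float
    w_sut: float


def _dims(p: SkullParams) -> _Dims:
    s = head_scale(p.age_months)
    sf = s ** p.facial_growth_exponent
    pitch = p.voxel_pitch * s
    ax, ay, az = p.ax * s, p.ay * s, p.az * s
    cz = 0.6 * az
    th = p.shell_thickness * s
    yf1 = ay
    yf0 = yf1 - p.face_depth * s
    zf1 = cz + 0.16 * az
    zf0 = zf1 - p.face_height * sf
    zb1 = cz - 0.58 * az
    zb0 = zb1 - 8.0 * s
    arch_a = np.array([p.face_width * s / 2.0, yf0, p.arch_z * s])
    arch_b = np.array([p.arch_post_x * s, p.arch_post_y * s, p.arch_z * s])
    # the free span bows laterally (temporal-fossa gap) so the strut stands
    # clear of the calvarial shell instead of running inside its wall
    arch_c = 0.5 * (arch_a + arch_b) + np.array(
        [p.arch_bulge * s, 0.0, -p.arch_sag * s]
    )
    t = np.linspace(0.0, 1.0, 41)[:, None]
    arch_poly = (1 - t) ** 2 * arch_a + 2 * t * (1 - t) * arch_c + t**2 * arch_b
    arch_len = float(np.linalg.norm(np.diff(arch_poly, axis=0), axis=1).sum())
    w_sut = max(p.suture_width * s / head_scale(3.0), 1.2 * pitch)
    return _Dims(
        s=s, sf=sf, pitch=pitch, ax=ax, ay=ay, az=az, cz=cz, th=th,
        yf0=yf0, yf1=yf1, zf0=zf0, zf1=zf1,
        wf=p.face_width * s, wp=p.palate_width * s,
        yp0=yf1 - p.palate_depth * s, zp1=zf0 + 6.0 * s,
        zb0=zb0, zb1=zb1, base_shrink=p.base_shrink,
        arch_r=p.arch_radius * s, arch_a=arch_a, arch_b=arch_b,
        arch_c=arch_c, arch_poly=arch_poly, arch_len=arch_len,
        y_cor=0.21 * ay, y_lam=-0.50 * ay, w_sut=w_sut,
    )


# 5-tet decomposition of a unit cube; two parities so neighbouring cubes
# share face diagonals.  Corner c has offsets (c&1, c>>1&1, c>>2&1).
_TETS_EVEN = np.array(
    [[0, 3, 5, 6], [1, 0, 3, 5], [2, 3, 0, 6], [4, 5, 6, 0], [7, 6, 5, 3]]
)
_TETS_ODD = _TETS_EVEN ^ 1


def _orient_cube_tets() -> tuple[np.ndarray, np.ndarray]:
    corners = np.array([[c & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)], float)

    def fix(tets):
        tets = tets.copy()
        for t in tets:
            a, b, c = (corners[t[1]] - corners[t[0]], corners[t[2]] - corners[t[0]],
                       corners[t[3]] - corners[t[0]])
            if np.dot(a, np.cross(b, c)) < 0:
                t[2], t[3] = t[3], t[2]
        return tets

    return fix(_TETS_EVEN), fix(_TETS_ODD)


_TETS_EVEN_OK, _TETS_ODD_OK = _orient_cube_tets()


def _polyline_distance(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each point to a sampled centreline (segment-wise)."""
    best = np.full(pts.shape[0], np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
        d = np.linalg.norm(pts - (a + t[:, None] * ab), axis=1)
        np.minimum(best, d, out=best)
    return best


def build_skull_mesh(
    params: SkullParams, schedule: SuturePatencySchedule | None = None
) -> LabelledTetMesh:
    """Voxelize the age-scaled surrogate and label it.

    One half (x >= 0) is voxelized on a uniform grid, cube cells are split
    into five tetrahedra, and the half is reflected about the mid-sagittal
    plane, so the mesh is exactly bilaterally symmetric.  Suture bands not
    active at ``params.age_months`` under ``schedule`` are labelled as the
    underlying bone.
    """
    params.validate()
    if schedule is None:
        schedule = default_schedule()
    active = schedule.active(params.age_months)
    d = _dims(params)
    p = d.pitch

    # half-grid cell centres (x >= 0)
    xmax = d.ax + 2 * p
    ymin, ymax = -(d.ay + 2 * p), d.yf1 + 2 * p
    zmin, zmax = d.zf0 - 2 * p, d.cz + d.az + 2 * p
    nx = int(np.ceil(xmax / p))
    ny = int(np.ceil((ymax - ymin) / p))
    nz = int(np.ceil((zmax - zmin) / p))
    xi = (np.arange(nx) + 0.5) * p
    yj = ymin + (np.arange(ny) + 0.5) * p
    zk = zmin + (np.arange(nz) + 0.5) * p
    X, Y, Z = np.meshgrid(xi, yj, zk, indexing="ij")

    r_out = (X / d.ax) ** 2 + (Y / d.ay) ** 2 + ((Z - d.cz) / d.az) ** 2
    ai, bi, ci = d.ax - d.th, d.ay - d.th, d.az - d.th
    r_in = (X / ai) ** 2 + (Y / bi) ** 2 + ((Z - d.cz) / ci) ** 2
    shell = (r_out <= 1.0) & (r_in >= 1.0)
    r_base = (X / (d.base_shrink * d.ax)) ** 2 + (Y / (d.base_shrink * d.ay)) ** 2 \
        + ((Z - d.cz) / d.az) ** 2
    base = (r_base <= 1.0) & (Z >= d.zb0) & (Z <= d.zb1)
    plate = (
        (np.abs(X) <= d.wf / 2) & (Y >= d.yf0) & (Y <= d.yf1)
        & (Z >= d.zf0) & (Z <= d.zf1)
    )
    palate = (
        (np.abs(X) <= d.wp / 2) & (Y >= d.yp0) & (Y <= d.yf1)
        & (Z >= d.zf0) & (Z <= d.zp1)
    )
    # solid zygomatic body buttressing the anterior arch root
    zyg = (
        (np.abs(X) >= d.wf / 2 - 8 * d.s) & (np.abs(X) <= d.wf / 2 + 2 * d.s)
        & (Y >= d.yf0 - 4 * d.s) & (Y <= d.yf1)
        & (Z >= d.arch_a[2] - 8 * d.s) & (Z <= d.arch_a[2] + 8 * d.s)
    )
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    arch = (_polyline_distance(pts, d.arch_poly) <= d.arch_r).reshape(X.shape)

    occ = shell | base | plate | palate | zyg | arch
    if not occ.any():
        raise ResolutionError("voxelization produced an empty surrogate")
    lab_grid, n_comp = ndimage.label(occ)
    if n_comp > 1:  # drop stray voxel clusters (keep the skull)
        counts = np.bincount(lab_grid.ravel())
        counts[0] = 0
        occ = lab_grid == np.argmax(counts)

    # bone labels (priority: arch > face > base plate > shell split)
    code = {name: i for i, name in enumerate(REGION_LABELS)}
    lab = np.full(X.shape, -1, dtype=np.int32)
    in_shell = occ & shell
    lab[in_shell & (Z < d.zb1)] = code["skull_base"]
    lab[in_shell & (Z >= d.zb1) & (Y >= d.y_cor)] = code["frontal"]
    lab[in_shell & (Z >= d.zb1) & (Y < d.y_cor) & (Y > d.y_lam)] = code["parietal"]
    lab[in_shell & (Z >= d.zb1) & (Y <= d.y_lam)] = code["occipital"]
    lab[occ & base & (lab < 0)] = code["skull_base"]
    lab[occ & (plate | palate | zyg)] = code["facial"]
    lab[occ & arch] = code["zygomatic_arch_L"]  # half-grid (x >= 0) is the left side
    lab[occ & (lab < 0)] = code["parietal"]  # rare corner voxels at junctions

    # suture bands override the bone they run through, when patent
    w2 = d.w_sut / 2.0
    calv = occ & in_shell & (Z >= d.zb1)
    basal = occ & ((in_shell & (Z < d.zb1)) | (base & ~in_shell))
    facial_m = occ & (plate | palate | zyg) & ~arch
    z_top = d.cz + d.az * np.sqrt(max(0.0, 1.0 - (d.y_cor / d.ay) ** 2))
    font = (
        (X ** 2 + (Y - d.y_cor) ** 2 + (Z - z_top) ** 2) <= (9.0 * d.s) ** 2
    )
    z_fs = d.zf1 - 0.45 * (d.zf1 - d.zf0)
    sutures = {
        "metopic": calv & (np.abs(X) <= w2) & (Y >= d.y_cor),
        "sagittal": calv & (np.abs(X) <= w2) & (Y < d.y_cor) & (Y > d.y_lam),
        "coronal": calv & (np.abs(Y - d.y_cor) <= w2),
        "lambdoid": calv & (np.abs(Y - d.y_lam) <= w2),
        "anterior_fontanelle": calv & font,
        "facial_suture": facial_m
        & ((np.abs(Z - z_fs) <= w2) | ((np.abs(X) <= w2) & (Z <= z_fs))),
        "base_joint": basal & (np.abs(Y + 0.15 * d.ay) <= w2),
    }
    for name in SUTURE_LABELS:  # fontanelle last: it overrides crossing sutures
        if name in active:
            lab[sutures[name]] = code[name]

    nodes, tets, region = _tets_from_cells(occ, lab, p, ymin, zmin)
    mesh = LabelledTetMesh(nodes=nodes, tets=tets, region=region)
    _attach_named_sets(mesh, params, d)
    mesh.metadata.update(
        age_months=params.age_months,
        seed=params.seed,
        voxel_pitch=p,
        scale=d.s,
        active_sutures=sorted(active),
        arch_length=d.arch_len,
    )
    mesh.validate()
    return mesh


def _tets_from_cells(occ, lab, p, ymin, zmin):
    """Split occupied cells into tets and reflect the half about x = 0."""
    ii, jj, kk = np.nonzero(occ)
    ncell = ii.size
    nyn, nzn = occ.shape[1] + 1, occ.shape[2] + 1

    def corner_id(i, j, k):
        return (i * nyn + j) * nzn + k

    offs = np.array([[c & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)])
    cid = np.stack(
        [corner_id(ii + dx, jj + dy, kk + dz) for dx, dy, dz in offs], axis=1
    )
    used, inv = np.unique(cid, return_inverse=True)
    cell_nodes = inv.reshape(ncell, 8)
    gi = used // (nyn * nzn)
    gj = (used // nzn) % nyn
    gk = used % nzn
    nodes = np.column_stack([gi * p, ymin + gj * p, zmin + gk * p]).astype(float)

    parity = (ii + jj + kk) % 2
    tets = np.empty((ncell, 5, 4), dtype=np.int64)
    for par, table in ((0, _TETS_EVEN_OK), (1, _TETS_ODD_OK)):
        sel = parity == par
        tets[sel] = cell_nodes[sel][:, table]
    tets = tets.reshape(-1, 4)
    region = np.repeat(lab[ii, jj, kk], 5).astype(np.int32)

    # reflect: nodes with x > 0 get mirrored twins, the x = 0 plane is shared
    off_plane = nodes[:, 0] > 0
    n_half = nodes.shape[0]
    twin = np.arange(n_half)
    twin[off_plane] = n_half + np.arange(off_plane.sum())
    mirrored = nodes[off_plane].copy()
    mirrored[:, 0] = -mirrored[:, 0]
    all_nodes = np.vstack([nodes, mirrored])
    mtets = twin[tets][:, [0, 1, 3, 2]]  # reflection flips orientation
    all_tets = np.vstack([tets, mtets])
    mregion = region.copy()
    code_l = REGION_LABELS.index("zygomatic_arch_L")
    code_r = REGION_LABELS.index("zygomatic_arch_R")
    mregion[mregion == code_l] = code_r
    return all_nodes, all_tets, np.concatenate([region, mregion])


def _arch_point(d: _Dims, t: float, dz: float = 0.0) -> np.ndarray:
    pt = (1 - t) ** 2 * d.arch_a + 2 * t * (1 - t) * d.arch_c + t**2 * d.arch_b
    return pt + np.array([0.0, 0.0, dz])


def landmark_table(params: SkullParams) -> pd.DataFrame:
    """The 42 landmark coordinates (mm) for the age-scaled surrogate.

    Ids follow the published numbering: temporalis 1-12, masseter 13-24,
    medial pterygoid 25-36, temporal fascia 37-42; within each muscle the
    order is left origins, left insertions, right origins, right
    insertions (fascia: left then right upper targets).  Insertion
    landmarks lie on the unmodelled mandible and are not mesh nodes.
    """
    d = _dims(params)
    s, sf = d.s, d.sf

    def wall(y, z):  # point on the shell mid-surface at given (y, z)
        a2, b2, c2 = d.ax - d.th / 2, d.ay - d.th / 2, d.az - d.th / 2
        r = 1.0 - (y / b2) ** 2 - ((z - d.cz) / c2) ** 2
        return np.array([a2 * np.sqrt(max(r, 0.0)), y, z])

    z_ins = d.zf0 - 26.0 * s  # mandible depth below the bite plane
    tmp_ori = [wall(18 * s, d.cz + 5 * s), wall(-2 * s, d.cz + 12 * s),
               wall(-20 * s, d.cz + 2 * s)]
    tmp_ins = [np.array([34 * s, 37 * s, d.zf0 - 10 * s]),
               np.array([34 * s, 33 * s, d.zf0 - 10 * s]),
               np.array([33 * s, 29 * s, d.zf0 - 8 * s])]
    mas_ori = [_arch_point(d, t, -d.arch_r) for t in params.masseter_spans]
    mas_ins = [np.array([36 * s, 22 * s, z_ins]),
               np.array([36 * s, 17 * s, z_ins]),
               np.array([36 * s, 12 * s, z_ins])]
    ptg_ori = [np.array([10 * s, 26 * s, d.zb0]),
               np.array([14 * s, 22 * s, d.zb0]),
               np.array([18 * s, 18 * s, d.zb0])]
    ptg_ins = [np.array([30 * s, 18 * s, z_ins]),
               np.array([30 * s, 14 * s, z_ins]),
               np.array([29 * s, 10 * s, z_ins])]
    fas_tgt = [wall(30 * s, d.cz + 0.30 * d.az),
               wall(20 * s, d.cz + 0.34 * d.az),
               wall(10 * s, d.cz + 0.30 * d.az)]

    rows = []
    # left block then right block per muscle: origins, insertions (+x is
    # subject-left)
    for group, ori, ins, base_id in (
        ("temporalis", tmp_ori, tmp_ins, 1),
        ("masseter", mas_ori, mas_ins, 13),
        ("medial_pterygoid", ptg_ori, ptg_ins, 25),
    ):
        lid = base_id
        for side, sign in (("L", 1.0), ("R", -1.0)):
            for role, pts in (("origin", ori), ("insertion", ins)):
                for pt in pts:
                    q = pt.copy()
                    q[0] = sign * abs(q[0])
                    rows.append((lid, group, role, side, *q))
                    lid += 1
    lid = 37
    for side, sign in (("L", 1.0), ("R", -1.0)):
        for pt in fas_tgt:
            q = pt.copy()
            q[0] = sign * abs(q[0])
            rows.append((lid, "temporal_fascia", "target", side, *q))
            lid += 1
    df = pd.DataFrame(rows, columns=["id", "group", "role", "side", "x", "y", "z"])
    return df.sort_values("id").reset_index(drop=True)


def _attach_named_sets(mesh: LabelledTetMesh, params: SkullParams, d: _Dims) -> None:
    s = d.s
    lm = landmark_table(params)
    mesh.landmarks = lm[["x", "y", "z"]].to_numpy()
    mirror = mesh.mirror_node_map()
    # left-side landmark nodes by nearest search; right side as exact mirror
    # images so attachment patches are bilaterally identical
    on_mesh = (lm["role"] == "origin") | (lm["group"] == "temporal_fascia")
    idx = np.full(42, -1, dtype=np.int64)
    for i in np.flatnonzero((on_mesh & (lm["side"] == "L")).to_numpy()):
        left = mesh.nearest_node(mesh.landmarks[i])
        idx[i] = left
        offset = 3 if lm.loc[i, "group"] == "temporal_fascia" else 6
        idx[i + offset] = mirror[left]
    mesh.landmark_nodes = idx

    def right_then_left(name, targets, labels):
        right = np.array(
            sorted({mesh.nearest_node(t, labels) for t in targets}), dtype=np.int64
        )
        mesh.node_sets[name + "_R"] = right
        mesh.node_sets[name + "_L"] = np.sort(mirror[right])

    facial = ("facial",)
    arch_l = ("zygomatic_arch_L",)
    y_mol = d.yf1 * params.molar_y_frac
    right_then_left(
        "bite_molar", [np.array([-params.molar_x * s, y_mol, d.zf0])], facial
    )
    right_then_left(
        "bite_molar_pre",
        [np.array([-params.molar_x * s, y_mol, d.zf0 + 4 * s])],
        facial,
    )
    right_then_left(
        "tmj",
        [
            np.array([-params.tmj_x * s, params.tmj_dy * s, d.zb0]),
            np.array([-params.tmj_x * s, -params.tmj_dy * s, d.zb0]),
        ],
        ("skull_base",),
    )
    inc_r = mesh.nearest_node(np.array([-3 * s, d.yf1 - 2 * s, d.zf0]), facial)
    mesh.node_sets["bite_incisor"] = np.sort(np.unique([inc_r, mirror[inc_r]]))
    inc_r_pre = mesh.nearest_node(
        np.array([-3 * s, d.yf1 - 2 * s, d.zf0 + 4 * s]), facial
    )
    mesh.node_sets["bite_incisor_pre"] = np.sort(np.unique([inc_r_pre, mirror[inc_r_pre]]))

    mid_l = mesh.nearest_node(_arch_point(d, 0.5), arch_l)
    mesh.node_sets["arch_mid_L"] = np.array([mid_l])
    mesh.node_sets["arch_mid_R"] = np.array([mirror[mid_l]])
    fas_l = np.array(
        sorted({
            mesh.nearest_node(_arch_point(d, t, d.arch_r), arch_l)
            for t in params.fascia_spans
        }),
        dtype=np.int64,
    )
    mesh.node_sets["fascia_ori_L"] = fas_l
    mesh.node_sets["fascia_ori_R"] = np.sort(mirror[fas_l])

    # nine facial probe locations (left side where lateral); all must sit
    # on facial or zygomatic elements
    probe_targets = {
        1: ([25 * s, d.yf0 + 2 * s, d.zf1 - 6 * s], facial),      # lat. inf. forehead
        2: ([0.0, d.yf1 - 2 * s, d.zf1 - 10 * s], facial),        # nasion
        3: ([10 * s, d.yf1 - 2 * s, d.zf0 + 16 * s], facial),     # alare
        4: ([16 * s, d.yf1 - 3 * s, d.zf0 + 30 * s], facial),     # frontal proc. maxilla
        5: ([24 * s, d.yf1 - 4 * s, d.zf0 + 8 * s], facial),      # lat. proc. maxilla
        6: ([14 * s, d.yf0 + 2 * s, d.zf1 - 16 * s], facial),     # inf. orbital roof
        7: ([27 * s, d.yf0 + 2 * s, d.zf1 - 20 * s], facial),     # frontal proc. zygoma
        8: ([29 * s, d.yf0 + 1 * s, d.zf0 + 22 * s],
            ("facial", "zygomatic_arch_L")),                      # central zygoma
        9: ([0.0, d.yp0 + 10 * s, d.zf0 + 3 * s], facial),        # central palate
    }
    for pid, (target, labels) in probe_targets.items():
        mesh.node_sets[f"probe_{pid}"] = np.array(
            [mesh.nearest_node(np.asarray(target), labels)]
        )


# ---------------------------------------------------------------------------
# synthetic CSA cohort
# ---------------------------------------------------------------------------

#: Control ages (months) of the cohort growth-curve family.
CURVE_CONTROL_AGES = (0.0, 3.0, 18.0, 36.0, 48.0)

#: Interior shape of each muscle's trajectory: value at age 0 as a fraction
#: of the 3-month anchor, and values at 18 / 36 months as fractions of the
#: 3->48-month rise.  The temporalis rises fast, stalls, then accelerates
#: again; masseter and medial pterygoid are closer to linear.
DEFAULT_CURVE_SHAPE = {
    "temporalis": (0.90, 0.62, 0.75),
    "masseter": (0.90, 0.40, 0.74),
    "medial_pterygoid": (0.90, 0.40, 0.74),
}


@dataclass(frozen=True)
class CohortParams:
    """Synthetic cohort of per-individual muscle CSAs.

    ``anchors_cm2`` holds per-muscle (CSA at 3 months, CSA at 48 months);
    the defaults divide the published mean per-side forces by the
    37 N cm^-2 muscle stress factor.  Noise is multiplicative lognormal
    with coefficient of variation ``cv`` (mean-preserving).
    """

    n: int = 51
    age_range: tuple[float, float] = (0.0, 48.0)
    anchors_cm2: dict = field(
        default_factory=lambda: {
            m: (lo / MUSCLE_STRESS_FACTOR, hi / MUSCLE_STRESS_FACTOR)
            for m, (lo, hi) in ANCHOR_FORCES_N.items()
        }
    )
    curve_shape: dict = field(default_factory=lambda: dict(DEFAULT_CURVE_SHAPE))
    cv: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise DomainError("cohort needs n >= 2 individuals")
        if self.cv < 0:
            raise DomainError("coefficient of variation must be >= 0")
        for m, (lo, hi) in self.anchors_cm2.items():
            if not (0 < lo < hi):
                raise DomainError(f"anchors for {m} must be positive and increasing")


def growth_curve(params: CohortParams, muscle: str) -> PchipInterpolator:
    """Monotone PCHIP CSA-vs-age curve (cm^2) through the muscle's anchors."""
    a3, a48 = params.anchors_cm2[muscle]
    f0, f18, f36 = params.curve_shape[muscle]
    rise = a48 - a3
    vals = [f0 * a3, a3, a3 + f18 * rise, a3 + f36 * rise, a48]
    return PchipInterpolator(np.asarray(CURVE_CONTROL_AGES), np.asarray(vals))


def generate_csa_cohort(params: CohortParams) -> pd.DataFrame:
    """One CSA record per individual per muscle.

    Ages are spread evenly over ``age_range`` (about one individual per
    month at the default n = 51).  Expected CSA follows the monotone
    anchor-interpolating curve; noise is seeded, multiplicative lognormal.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.age_range
    ages = np.linspace(lo, hi, params.n)
    sigma = np.sqrt(np.log1p(params.cv**2))
    rows = []
    for m in MUSCLES:
        curve = growth_curve(params, m)
        mult = (
            np.exp(rng.normal(-0.5 * sigma**2, sigma, params.n))
            if params.cv > 0
            else np.ones(params.n)
        )
        for i, (a, k) in enumerate(zip(ages, mult)):
            rows.append((i, float(a), m, float(curve(a) * k)))
    return pd.DataFrame(rows, columns=["individual_id", "age_months", "muscle", "csa_cm2"])


# ---------------------------------------------------------------------------
# muscle mask fixtures
# ---------------------------------------------------------------------------


@dataclass
class MuscleMaskVolume:
    """Boolean voxel mask of one muscle with per-axis pitch in mm."""

    mask: np.ndarray
    pitch: np.ndarray  # (3,) mm per axis
    name: str = "muscle"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.pitch = np.broadcast_to(np.asarray(self.pitch, float), (3,)).copy()
        if self.mask.ndim != 3 or not self.mask.any():
            raise DomainError("mask must be a non-empty 3-D boolean volume")
        if np.any(self.pitch <= 0):
            raise DomainError("voxel pitch must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.pitch))


def make_muscle_mask(shape: str, dims, pitch: float) -> MuscleMaskVolume:
    """Voxelize an axis-aligned solid as a stand-in muscle volume.

    ``shape`` is one of ``elliptic_cylinder`` (dims = semi-axes a, b and
    height, axis along z), ``cone`` (dims = base semi-axes a, b and
    height, apex up) or ``prism`` (dims = edge lengths lx, ly, lz).
    """
    dims = np.asarray(dims, dtype=float)
    if pitch <= 0 or np.any(dims <= 0):
        raise DomainError("dims and pitch must be positive")
    if pitch > dims.min():
        raise DomainError(
            f"pitch {pitch} mm exceeds the smallest dimension {dims.min()} mm"
        )
    if shape in ("elliptic_cylinder", "cone"):
        a, b, h = dims
        ext = np.array([2 * a, 2 * b, h])
    elif shape == "prism":
        ext = dims
    else:
        raise DomainError(f"unknown mask shape {shape!r}")
    n = np.maximum(np.ceil(ext / pitch).astype(int) + 2, 1)
    centre = (np.arange(n[0]) + 0.5) * pitch - n[0] * pitch / 2
    cy = (np.arange(n[1]) + 0.5) * pitch - n[1] * pitch / 2
    cz = (np.arange(n[2]) + 0.5) * pitch
    X, Y, Z = np.meshgrid(centre, cy, cz, indexing="ij")
    if shape == "prism":
        lx, ly, lz = dims
        m = (np.abs(X) <= lx / 2) & (np.abs(Y) <= ly / 2) & (Z <= lz)
    else:
        a, b, h = dims
        if shape == "cone":
            taper = np.clip(1.0 - Z / h, 0.0, None)
            m = ((X / (a * np.where(taper > 0, taper, np.inf))) ** 2
                 + (Y / (b * np.where(taper > 0, taper, np.inf))) ** 2 <= 1.0) & (Z <= h)
        else:
            m = ((X / a) ** 2 + (Y / b) ** 2 <= 1.0) & (Z <= h)
    if not m.any():
        raise DomainError("degenerate dims: voxelization is empty")
    return MuscleMaskVolume(mask=m, pitch=np.full(3, float(pitch)), name=shape)
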