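"""Inverse measurement of generated meshes.

Every input dimension of the generator is recovered from geometry alone and
compared against its target: diameters from cross-section ring polygons
(equivalent-area diameter 2*sqrt(A/pi)), the arch height/width and bend
radius from the recovered centerline (ring centroids), branch stations from
recovered arc lengths, and takeoff angles from branch-axis fits.  The
lattice connectivity stored with the mesh says *which* vertices form each
ring; all coordinates are read from the mesh, so a rescaled mesh fails its
length rows while passing its angle rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import trimesh

from .centerline import Centerline
from .errors import MeshError, ParameterError
from .hemo import FlowCondition, bulk_velocity, reynolds
from .meshgen import AortaModel, TriMesh, measure_wall_thickness
from .params import AortaParameterSet, ArchType

__all__ = ["MeasurementRow", "MeasurementReport", "slice_diameter",
           "arch_height_width", "branch_angle", "validate"]


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementRow:
    symbol: str
    target: float
    measured: float
    error: float       # relative for lengths, absolute (deg) for angles
    tolerance: float
    kind: str          # "rel" or "abs"
    unit: str
    passed: bool


@dataclass
class MeasurementReport:
    """Target-vs-recovered dimensions plus a mesh validity block."""

    rows: list[MeasurementRow] = field(default_factory=list)
    validity: dict[str, Any] = field(default_factory=dict)
    flow: dict[str, float] = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.rows)

    @property
    def mesh_ok(self) -> bool:
        v = self.validity
        return bool(v.get("watertight") and v.get("winding_consistent")
                    and v.get("genus", 1) == 0
                    and v.get("self_intersections", 1) == 0)

    def row(self, symbol: str) -> MeasurementRow:
        for r in self.rows:
            if r.symbol == symbol:
                return r
        raise KeyError(symbol)

    @property
    def symbols(self) -> list[str]:
        return [r.symbol for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"rows": [r.__dict__ for r in self.rows],
                   "validity": self.validity, "flow": self.flow}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def __str__(self) -> str:
        lines = [f"{'symbol':<10}{'target':>10}{'measured':>10}{'error':>10}"
                 f"{'tol':>8}  pass"]
        for r in self.rows:
            lines.append(f"{r.symbol:<10}{r.target:>10.3f}{r.measured:>10.3f}"
                         f"{r.error:>10.4f}{r.tolerance:>8.3f}  "
                         f"{'ok' if r.passed else 'FAIL'}")
        lines.append(f"mesh: {self.validity}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def _ring_pts(mesh: TriMesh, ring: list[int]) -> np.ndarray:
    return mesh.vertices[np.asarray(ring, dtype=int)]


def _polygon_equiv_diameter(pts: np.ndarray) -> float:
    """Equivalent-area diameter of a closed planar 3D polygon."""
    c = pts.mean(axis=0)
    v = pts - c
    cross = np.cross(v, np.roll(v, -1, axis=0))
    area = 0.5 * np.linalg.norm(cross.sum(axis=0))
    return 2.0 * math.sqrt(area / math.pi)


def _ring_vertex_diameter(pts: np.ndarray) -> float:
    """Diameter from mean vertex distance to the ring centroid.

    Exact for circular cross-section rings regardless of vertex count
    (the area of an inscribed polygon underestimates at low counts).
    """
    c = pts.mean(axis=0)
    return 2.0 * float(np.mean(np.linalg.norm(pts - c, axis=1)))


def _fit_line(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis through a point cloud, oriented first -> last."""
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    d = vt[0]
    if d @ (pts[-1] - pts[0]) < 0:
        d = -d
    return c, d


def _fit_circle_radius(xy: np.ndarray) -> float:
    """Algebraic (Kasa) circle fit radius in 2D."""
    A = np.column_stack([2 * xy, np.ones(len(xy))])
    b = (xy ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(math.sqrt(sol[2] + sol[0] ** 2 + sol[1] ** 2))


class _Recovered:
    """Centerline and branch geometry recovered from a structured mesh."""

    def __init__(self, mesh: TriMesh):
        if mesh.structure is None:
            raise MeshError(
                "mesh carries no lattice structure; measurement of foreign "
                "meshes supports slice_diameter only")
        st = mesh.structure
        self.mesh = mesh
        self.rings = st["rings"]
        self.landmarks: dict[str, int] = st["landmarks"]
        self.branches = {b["label"]: b for b in st.get("branches", [])}
        self.centroids = np.array([_ring_pts(mesh, r).mean(axis=0)
                                   for r in self.rings])
        seg = np.linalg.norm(np.diff(self.centroids, axis=0), axis=1)
        self.arclen = np.concatenate([[0.0], np.cumsum(seg)])

    def s_from_stj(self, ring_index: int) -> float:
        i0 = self.landmarks["STJ"]
        return float(self.arclen[ring_index] - self.arclen[i0])

    def ring_diameter(self, ring_index: int) -> float:
        return _ring_vertex_diameter(_ring_pts(self.mesh, self.rings[ring_index]))

    def tangent_at(self, ring_index: int) -> np.ndarray:
        """Centerline tangent from a local polynomial fit in arc length.

        The fit window never crosses the arch start/end junctions (where
        the curve is only C1, a window straddling the curvature jump would
        bias the derivative) and tolerates the nonuniform ring spacing left
        by station snapping.
        """
        i0 = max(ring_index - 3, 0)
        i1 = min(ring_index + 4, len(self.centroids))
        ia = self.landmarks.get("arch_start")
        ib = self.landmarks.get("arch_end")
        if ia is not None and ib is not None and ia <= ring_index <= ib:
            i0, i1 = max(i0, ia), min(i1, ib + 1)
        s = self.arclen[i0:i1] - self.arclen[ring_index]
        pts = self.centroids[i0:i1]
        deg = min(3, len(s) - 2)
        d = np.empty(3)
        for k in range(3):
            coeff = np.polyfit(s, pts[:, k], deg=deg)
            d[k] = coeff[-2]  # derivative at s = 0
        return d / np.linalg.norm(d)

    def arch_points(self) -> np.ndarray:
        i0, i1 = self.landmarks["arch_start"], self.landmarks["arch_end"]
        return self.centroids[i0:i1 + 1]

    def height_width(self) -> tuple[float, float]:
        pa = self.centroids[self.landmarks["arch_start"]]
        pe = self.centroids[self.landmarks["arch_end"]]
        apex = self.centroids[self.landmarks["arch_apex"]]
        H = float(apex[2] - pa[2])
        W = float(np.linalg.norm((pe - pa)[:2]))
        return H, W

    def descending_direction(self) -> np.ndarray:
        n = max(4, len(self.centroids) // 20)
        _, d = _fit_line(self.centroids[-n:])
        return d

    def branch_axis(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        br = self.branches[label]
        nt = br["n_transition"]
        ring_ids = br["rings"][nt:]
        if len(ring_ids) < 3:
            raise MeshError(f"branch {label!r} has too few rings to fit an axis")
        cents = np.array([_ring_pts(self.mesh, r).mean(axis=0) for r in ring_ids])
        return _fit_line(cents)

    def branch_angle(self, label: str) -> float:
        _, d = self.branch_axis(label)
        t = self.tangent_at(self.branches[label]["attach_ring"])
        return math.degrees(math.acos(float(np.clip(d @ t, -1, 1))))

    def branch_diameter(self, label: str) -> float:
        br = self.branches[label]
        return _ring_vertex_diameter(_ring_pts(self.mesh, br["rings"][-1]))


# ---------------------------------------------------------------------------
# public operators
# ---------------------------------------------------------------------------

def slice_diameter(mesh: TriMesh | trimesh.Trimesh, point: np.ndarray,
                   normal: np.ndarray, max_radius: float | None = None) -> float:
    """Equivalent-area diameter 2*sqrt(A/pi) of a planar lumen cross-section.

    ``max_radius`` restricts the cut to faces near ``point`` so a plane
    through a curved vessel does not also slice distant passages.  Raises
    when the local plane cut is empty, open, or multi-component.
    """
    tm = mesh.to_trimesh() if isinstance(mesh, TriMesh) else mesh
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    if max_radius is not None:
        cent = tm.triangles_center
        keep = np.linalg.norm(cent - point, axis=1) <= max_radius
        if not keep.any():
            raise MeshError("no faces near the slice point")
        tm = trimesh.Trimesh(vertices=tm.vertices, faces=tm.faces[keep],
                             process=False)
    segments = trimesh.intersections.mesh_plane(tm, normal, point)
    if len(segments) == 0:
        raise MeshError("slice plane does not intersect the mesh")
    loops = _chain_loops(segments)
    if len(loops) != 1:
        raise MeshError(f"slice is not a single closed lumen passage "
                        f"({len(loops)} loops found)")
    poly = loops[0]
    # project onto the plane and shoelace
    b1 = np.array([1.0, 0, 0]) if abs(normal[0]) < 0.9 else np.array([0, 1.0, 0])
    b1 = b1 - (b1 @ normal) * normal
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(normal, b1)
    uv = np.column_stack([(poly - point) @ b1, (poly - point) @ b2])
    x, y = uv[:, 0], uv[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return 2.0 * math.sqrt(area / math.pi)


def _chain_loops(segments: np.ndarray, decimals: int = 7) -> list[np.ndarray]:
    """Chain unordered segments into closed loops; open chains are errors."""
    key = lambda p: tuple(np.round(p, decimals))
    adj: dict[tuple, list[tuple[int, int]]] = {}
    for i, seg in enumerate(segments):
        for e in range(2):
            adj.setdefault(key(seg[e]), []).append((i, e))
    used = np.zeros(len(segments), dtype=bool)
    loops = []
    for start in range(len(segments)):
        if used[start]:
            continue
        pts = [segments[start][0]]
        cur_pt = segments[start][1]
        used[start] = True
        closed = False
        guard = 0
        while guard < 4 * len(segments):
            guard += 1
            if key(cur_pt) == key(pts[0]):
                closed = True
                break
            pts.append(cur_pt)
            nxt = [(i, e) for (i, e) in adj.get(key(cur_pt), []) if not used[i]]
            if not nxt:
                break
            i, e = nxt[0]
            used[i] = True
            cur_pt = segments[i][1 - e]
        if not closed:
            raise MeshError("slice produced an open (non-closed) section curve")
        loops.append(np.asarray(pts))
    return loops


def arch_height_width(obj: Centerline | AortaModel | TriMesh) -> tuple[float, float]:
    """Arch height H and width W (cm) in the arch's parasagittal plane.

    H is the apex rise above the arch-start horizontal plane; W the
    horizontal distance between ascending and descending limbs at that
    plane.
    """
    if isinstance(obj, Centerline):
        lm = obj.landmarks
        for need in ("arch_start", "arch_apex", "arch_end"):
            if need not in lm:
                raise ParameterError(f"centerline lacks landmark {need!r}")
        pa = obj.points[obj.index_at(lm["arch_start"])]
        pe = obj.points[obj.index_at(lm["arch_end"])]
        apex = obj.points[obj.index_at(lm["arch_apex"])]
        return float(apex[2] - pa[2]), float(np.linalg.norm((pe - pa)[:2]))
    mesh = obj.mesh if isinstance(obj, AortaModel) else obj
    return _Recovered(mesh).height_width()


def branch_angle(obj: AortaModel | TriMesh, branch_label: str) -> float:
    """Takeoff angle (deg) between a labeled branch axis and the aorta."""
    mesh = obj.mesh if isinstance(obj, AortaModel) else obj
    rec = _Recovered(mesh)
    if branch_label not in rec.branches:
        raise ParameterError(f"no branch labeled {branch_label!r}; "
                             f"have {sorted(rec.branches)}")
    return rec.branch_angle(branch_label)


# ---------------------------------------------------------------------------
# full validation
# ---------------------------------------------------------------------------

_BRANCH_SYMBOLS = {
    ArchType.TYPE_I: [("BA", "phi1", "alpha1"), ("LCA", "phi2", "alpha2"),
                      ("LSA", "phi3", "alpha3")],
    ArchType.TYPE_II: [("trunk", "phib1", "alphab1"), ("LSA", "phib2", "alphab2")],
}


def validate(model: AortaModel | TriMesh, params: AortaParameterSet | None = None,
             tolerance_length: float = 0.02, tolerance_angle: float = 1.0,
             check_self_intersections: bool = True,
             flow: FlowCondition | None = None) -> MeasurementReport:
    """Recover every generator input from the mesh and compare to targets.

    Lengths pass within ``tolerance_length`` (relative, default 2%), angles
    within ``tolerance_angle`` (degrees, default 1).  The report also
    carries a mesh validity block (watertightness, manifoldness, genus,
    self-intersections, minimum triangle angle).
    """
    if isinstance(model, AortaModel):
        mesh = model.mesh
        p = params or model.params
    else:
        mesh = model
        if params is None:
            raise ParameterError("validating a bare mesh requires the target "
                                 "parameter set")
        p = params
    rec = _Recovered(mesh)
    report = MeasurementReport()

    def add_len(symbol: str, target: float, measured: float, unit: str = "cm",
                tol: float | None = None) -> None:
        tol = tolerance_length if tol is None else tol
        err = abs(measured - target) / abs(target)
        report.rows.append(MeasurementRow(symbol, target, measured, err, tol,
                                          "rel", unit, bool(err <= tol)))

    def add_ang(symbol: str, target: float, measured: float,
                tol: float | None = None) -> None:
        tol = tolerance_angle if tol is None else tol
        err = abs(measured - target)
        report.rows.append(MeasurementRow(symbol, target, measured, err, tol,
                                          "abs", "deg", bool(err <= tol)))

    lm = rec.landmarks
    add_len("D1", p.D1, rec.ring_diameter(lm["STJ"]))
    add_len("D2", p.D2, rec.ring_diameter(lm["arch_apex"]))
    add_len("D3", p.D3, rec.ring_diameter(lm["mid_descending"]))
    H, W = rec.height_width()
    add_len("H", p.H, H)
    add_len("W", p.W, W)
    add_len("R", p.R, _fit_circle_radius(rec.arch_points()[:, :2]))
    add_len("L", p.L, rec.s_from_stj(lm["arch_start"]))

    # branch stations and per-branch geometry
    spec_branches = _BRANCH_SYMBOLS[p.arch_type]
    s_station = {}
    for label, _, _ in spec_branches:
        s_station[label] = rec.s_from_stj(rec.branches[label]["attach_ring"])
    first = spec_branches[0][0]
    add_len("a", p.a, s_station[first])
    if p.arch_type is ArchType.TYPE_I:
        add_len("d1", p.d1, s_station["LCA"] - s_station["BA"])
        add_len("d2", p.d2, s_station["LSA"] - s_station["LCA"])
    else:
        add_len("d3", p.d3, s_station["LSA"] - s_station["trunk"])
    for label, sym_d, sym_a in spec_branches:
        add_len(sym_d, getattr(p, sym_d), rec.branch_diameter(label))
        add_ang(sym_a, getattr(p, sym_a), rec.branch_angle(label))

    # descending and arch orientation angles
    d = rec.descending_direction()
    add_ang("beta1", p.beta1, math.degrees(math.acos(float(np.clip(-d[2], -1, 1)))))
    if abs(p.beta1) > 1e-9:
        add_ang("beta2", p.beta2, math.degrees(math.atan2(d[0], -d[1])))
    pa = rec.centroids[lm["arch_start"]]
    pe = rec.centroids[lm["arch_end"]]
    u = (pe - pa)[:2]
    add_ang("beta3", p.beta3, math.degrees(math.atan2(-u[0], -u[1])))

    # coronaries (present when a root was generated)
    if "RCA" in rec.branches:
        add_len("C1", p.C1, rec.branch_diameter("RCA") * 10.0, unit="mm")
        add_len("C2", p.C2, rec.branch_diameter("LCA_coronary") * 10.0, unit="mm")

    if isinstance(model, AortaModel) and model.shell_mesh is not None:
        th = measure_wall_thickness(model.shell_mesh) * 10.0  # cm -> mm
        add_len("shell_thickness", model.shell_thickness, float(np.mean(th)),
                unit="mm", tol=0.10)

    # mesh validity block
    tm = mesh.to_trimesh()
    v_ref = len(np.unique(mesh.faces))
    euler = int(v_ref - len(tm.edges_unique) + len(mesh.faces))
    ang = tm.face_angles
    report.validity = {
        "watertight": bool(tm.is_watertight),
        "winding_consistent": bool(tm.is_winding_consistent),
        "euler_characteristic": euler,
        "genus": int((2 - euler) // 2),
        "min_triangle_angle_deg": float(np.degrees(ang.min())),
        "n_faces": int(len(mesh.faces)),
    }
    if check_self_intersections:
        report.validity["self_intersections"] = mesh.count_self_intersections()

    if flow is not None:
        report.flow = {"Q_lpm": flow.Q, "D_mm": flow.D,
                       "bulk_velocity_ms": bulk_velocity(flow),
                       "reynolds": reynolds(flow)}
    return report
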