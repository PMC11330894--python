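"""Arc-length-parameterized aorta centerline, frames, and radius profile.

Anatomical frame: +x left, +y anterior, +z superior; the sinotubular
junction (STJ) sits at the origin with arc length 0.

The curve is assembled from four constraint blocks:

1. a straight ascending segment of length ``L`` directed superiorly;
2. an arch whose projection onto its own (parasagittal, optionally rotated
   by ``beta3``) plane is a semi-ellipse of width ``W`` and height ``H`` —
   the simplest tangent-continuous curve meeting both extents with vertical
   limbs;
3. a lateral out-of-plane bulge chosen so the transverse (axial) projection
   of the arch is exactly a circular arc of radius ``R``;
4. a short cubic blend into a straight descending limb tilted ``beta1``
   from vertical with its horizontal component rotated ``beta2`` from
   posterior toward the left.

Cross-section orientation along the curve uses rotation-minimizing frames
(double-reflection propagation) rather than Frenet frames, which flip at
inflections of 3D curves.  Frames are propagated once on a fixed fine
internal grid and interpolated to any output sampling, so they do not
depend on the requested resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleGeometryError, ParameterError
from .params import AortaParameterSet, ArchType

__all__ = ["Centerline", "FrameField", "RadiusProfile", "BranchStation",
           "build_centerline", "radius_profile", "branch_stations"]

_N_DENSE = 4096  # internal sampling for arc length and frame propagation


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameField:
    """Per-point orthonormal triads (tangent, normal, binormal)."""

    tangent: np.ndarray   # (N, 3)
    normal: np.ndarray    # (N, 3)
    binormal: np.ndarray  # (N, 3)

    def __len__(self) -> int:
        return len(self.tangent)


def _double_reflection_rmf(points: np.ndarray, tangents: np.ndarray,
                           n0: np.ndarray) -> np.ndarray:
    """Propagate a normal along the curve with minimal rotation.

    Double-reflection method: each step reflects the frame across the
    bisecting planes of the point and tangent pairs, which cancels the
    torsion-induced spin that makes Frenet frames unusable here.
    """
    n = len(points)
    normals = np.empty((n, 3))
    r = n0 - np.dot(n0, tangents[0]) * tangents[0]
    normals[0] = r / np.linalg.norm(r)
    for i in range(n - 1):
        v1 = points[i + 1] - points[i]
        c1 = float(v1 @ v1)
        if c1 < 1e-30:
            normals[i + 1] = normals[i]
            continue
        rl = normals[i] - (2.0 / c1) * (v1 @ normals[i]) * v1
        tl = tangents[i] - (2.0 / c1) * (v1 @ tangents[i]) * v1
        v2 = tangents[i + 1] - tl
        c2 = float(v2 @ v2)
        if c2 < 1e-30:
            normals[i + 1] = rl
        else:
            normals[i + 1] = rl - (2.0 / c2) * (v2 @ rl) * v2
        # re-orthonormalize against drift
        nv = normals[i + 1] - (normals[i + 1] @ tangents[i + 1]) * tangents[i + 1]
        normals[i + 1] = nv / np.linalg.norm(nv)
    return normals


# ---------------------------------------------------------------------------
# centerline container
# ---------------------------------------------------------------------------

@dataclass
class Centerline:
    """Sampled 3D centerline with arc length, tangents, frames, landmarks.

    ``landmarks`` maps names (``STJ``, ``arch_start``, ``arch_apex``,
    ``arch_end``, ``mid_descending``, ``outlet`` and branch stations) to arc
    lengths; sample points are snapped onto landmark stations during
    construction so each landmark has an exact sample index.
    """

    points: np.ndarray                  # (N, 3) cm
    arclen: np.ndarray                  # (N,) cm, strictly increasing, 0 at STJ
    tangent: np.ndarray                 # (N, 3) unit
    landmarks: dict[str, float] = field(default_factory=dict)
    # dense reference grid for resolution-independent frames
    _dense_s: np.ndarray | None = None
    _dense_normal: np.ndarray | None = None
    _dense_tangent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arclen = np.asarray(self.arclen, dtype=float)
        self.tangent = np.asarray(self.tangent, dtype=float)
        if not np.all(np.diff(self.arclen) > 0):
            raise ParameterError("arc length must be strictly increasing")

    @classmethod
    def from_points(cls, points: np.ndarray,
                    landmarks: dict[str, float] | None = None) -> "Centerline":
        """Build a centerline from a polyline (tangents by central difference)."""
        pts = np.asarray(points, dtype=float)
        if len(pts) < 2:
            raise ParameterError("need at least two points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        tan = np.gradient(pts, s, axis=0)
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        cl = cls(points=pts, arclen=s, tangent=tan,
                 landmarks=dict(landmarks or {}))
        cl._dense_s = s
        cl._dense_tangent = tan
        ref = np.array([1.0, 0.0, 0.0])
        if abs(tan[0] @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        cl._dense_normal = _double_reflection_rmf(pts, tan, ref)
        return cl

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return float(self.arclen[-1])

    def index_at(self, s: float) -> int:
        """Index of the sample nearest to arc length ``s``."""
        return int(np.argmin(np.abs(self.arclen - s)))

    def point_at(self, s: float) -> np.ndarray:
        i = np.searchsorted(self.arclen, s)
        i = np.clip(i, 1, len(self) - 1)
        w = (s - self.arclen[i - 1]) / (self.arclen[i] - self.arclen[i - 1])
        return (1 - w) * self.points[i - 1] + w * self.points[i]

    def frames(self, s: np.ndarray | None = None) -> FrameField:
        """Rotation-minimizing frames at the given arc lengths (default: all
        sample points), interpolated from the fixed internal grid."""
        if self._dense_s is None:
            raise ParameterError("centerline carries no frame reference grid")
        sq = self.arclen if s is None else np.asarray(s, dtype=float)
        t = _interp_vectors(sq, self._dense_s, self._dense_tangent)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        n = _interp_vectors(sq, self._dense_s, self._dense_normal)
        n -= np.sum(n * t, axis=1, keepdims=True) * t
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        b = np.cross(t, n)
        return FrameField(tangent=t, normal=n, binormal=b)


def _interp_vectors(sq: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    out = np.empty((len(sq), v.shape[1]))
    for k in range(v.shape[1]):
        out[:, k] = np.interp(sq, s, v[:, k])
    return out


# ---------------------------------------------------------------------------
# radius profile
# ---------------------------------------------------------------------------

class RadiusProfile:
    """Monotone-segment radius interpolation r(s) through diameter knots.

    Piecewise-cubic Hermite (PCHIP) interpolation: between any two knots the
    radius stays inside the knot interval, so prescribed diameters are never
    overshot.
    """

    def __init__(self, knots_s: np.ndarray, knots_r: np.ndarray):
        from scipy.interpolate import PchipInterpolator
        self.knots_s = np.asarray(knots_s, dtype=float)
        self.knots_r = np.asarray(knots_r, dtype=float)
        if np.any(self.knots_r <= 0):
            raise ParameterError("radius knots must be positive")
        self._f = PchipInterpolator(self.knots_s, self.knots_r, extrapolate=False)

    def __call__(self, s: np.ndarray | float) -> np.ndarray | float:
        s_arr = np.clip(np.asarray(s, dtype=float), self.knots_s[0], self.knots_s[-1])
        r = self._f(s_arr)
        return float(r) if np.isscalar(s) else np.asarray(r)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _direction_from_betas(beta1: float, beta2: float) -> np.ndarray:
    """Final descending-limb direction: polar tilt ``beta1`` from vertical,
    horizontal component rotated ``beta2`` from posterior (-y) toward left (+x)."""
    b1, b2 = math.radians(beta1), math.radians(beta2)
    return np.array([math.sin(b1) * math.sin(b2),
                     -math.sin(b1) * math.cos(b2),
                     -math.cos(b1)])


class _AortaCurve:
    """Piecewise-analytic curve realizing the centerline constraints."""

    def __init__(self, p: AortaParameterSet, descending_length: float | None):
        self.p = p
        W, H, R, L = p.W, p.H, p.R, p.L
        if R < W / 2:
            raise InfeasibleGeometryError(
                f"transverse bend radius R={R} cm is too small to close the "
                f"arch over width W={W} cm (requires R >= W/2)")
        if H > 2 * W:
            raise InfeasibleGeometryError(
                f"arch height H={H} cm exceeds twice the width W={W} cm; "
                "the semi-elliptic arch would be implausibly elongated")
        b3 = math.radians(p.beta3)
        self.u = np.array([-math.sin(b3), -math.cos(b3), 0.0])   # arch travel
        self.nlat = np.array([math.cos(b3), -math.sin(b3), 0.0])  # lateral bulge
        self.PA = np.array([0.0, 0.0, L])                         # arch start
        self.PE = self.PA + W * self.u                            # arch end
        self.eta0 = math.sqrt(R * R - (W / 2) ** 2)
        self.d_dir = _direction_from_betas(p.beta1, p.beta2)
        self.blend_len = 0.5 * H
        self.desc_len = descending_length if descending_length is not None else H + W
        if self.desc_len <= 0:
            raise ParameterError("descending length must be positive")
        # cubic Bezier blend from vertical (-z) into the tilted direction
        down = np.array([0.0, 0.0, -1.0])
        chord = self.blend_len
        self.B0 = self.PE
        self.B1 = self.PE + down * (chord / 3.0)
        self.B3 = self.PE + (down + self.d_dir) * (chord / 2.0)
        self.B2 = self.B3 - self.d_dir * (chord / 3.0)

    # segment evaluators: local parameter q in [0, 1]
    def _eval_ascend(self, q):
        pts = np.outer(q, [0, 0, self.p.L])
        der = np.tile([0, 0, self.p.L], (len(q), 1))
        return pts, der

    def _eval_arch(self, q):
        W, H, R = self.p.W, self.p.H, self.p.R
        th = q * math.pi
        xi = (W / 2) * (1 - np.cos(th))
        ze = H * np.sin(th)
        eta = np.sqrt(R * R - (xi - W / 2) ** 2) - self.eta0
        pts = (self.PA[None, :] + np.outer(xi, self.u)
               + np.outer(eta, self.nlat) + np.outer(ze, [0, 0, 1.0]))
        dxi = (W / 2) * np.sin(th) * math.pi
        dze = H * np.cos(th) * math.pi
        deta = -(xi - W / 2) / np.sqrt(R * R - (xi - W / 2) ** 2) * dxi
        der = (np.outer(dxi, self.u) + np.outer(deta, self.nlat)
               + np.outer(dze, [0, 0, 1.0]))
        return pts, der

    def _eval_blend(self, q):
        B0, B1, B2, B3 = self.B0, self.B1, self.B2, self.B3
        q = q[:, None]
        pts = ((1 - q) ** 3 * B0 + 3 * (1 - q) ** 2 * q * B1
               + 3 * (1 - q) * q ** 2 * B2 + q ** 3 * B3)
        der = (3 * (1 - q) ** 2 * (B1 - B0) + 6 * (1 - q) * q * (B2 - B1)
               + 3 * q ** 2 * (B3 - B2))
        return pts, der

    def _eval_desc(self, q):
        pts = self.B3[None, :] + np.outer(q * self.desc_len, self.d_dir)
        der = np.tile(self.d_dir * self.desc_len, (len(q), 1))
        return pts, der

    def sample_dense(self):
        """Dense (s, points, tangents, segment-boundary arc lengths)."""
        evals = [self._eval_ascend, self._eval_arch, self._eval_blend, self._eval_desc]
        # rough segment lengths to distribute samples
        rough = [self.p.L, math.pi * (self.p.W / 2 + self.p.H) / 2 * 1.1,
                 self.blend_len, self.desc_len]
        total = sum(rough)
        pts_list, der_list, counts = [], [], []
        for ev, rl in zip(evals, rough):
            m = max(64, int(_N_DENSE * rl / total))
            q = np.linspace(0.0, 1.0, m)
            pp, dd = ev(q)
            pts_list.append(pp)
            der_list.append(dd)
            counts.append(m)
        # concatenate, dropping duplicated junction points
        pts = [pts_list[0]]
        der = [der_list[0]]
        marks = [counts[0] - 1]
        for pp, dd in zip(pts_list[1:], der_list[1:]):
            pts.append(pp[1:])
            der.append(dd[1:])
            marks.append(marks[-1] + len(pp) - 1)
        P = np.vstack(pts)
        D = np.vstack(der)
        seg = np.linalg.norm(np.diff(P, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        T = D / np.linalg.norm(D, axis=1, keepdims=True)
        bounds = [s[m] for m in marks]  # arch_start, arch_end, blend_end, outlet... order below
        return s, P, T, bounds


def build_centerline(params: AortaParameterSet, resolution: float = 6.0,
                     descending_length: float | None = None) -> Centerline:
    """Sample the aorta centerline at ``resolution`` points per cm.

    Samples are snapped onto landmark and branch stations so that every
    station coincides exactly with a sample point.
    """
    if resolution < 2:
        raise ParameterError("resolution must be at least 2 points per cm")
    curve = _AortaCurve(params, descending_length)
    s_d, P_d, T_d, bounds = curve.sample_dense()
    s_arch_start, s_arch_end, s_blend_end, s_total = bounds
    # apex: theta = pi/2 -> midpoint of the arch in theta; locate from dense z-max
    arch_mask = (s_d >= s_arch_start) & (s_d <= s_arch_end)
    s_apex = float(s_d[arch_mask][np.argmax(P_d[arch_mask, 2])])
    s_mid_desc = s_blend_end + (s_total - s_blend_end) / 2.0
    landmarks = {
        "STJ": 0.0,
        "arch_start": s_arch_start,
        "arch_apex": s_apex,
        "arch_end": s_arch_end,
        "mid_descending": s_mid_desc,
        "outlet": float(s_d[-1]),
    }
    for name, st in _stations(params, s_arch_end).items():
        landmarks[name] = st.arclen

    n_out = max(int(math.ceil(s_d[-1] * resolution)) + 1, 16)
    base = np.linspace(0.0, s_d[-1], n_out)
    spacing = s_d[-1] / (n_out - 1)
    # every landmark becomes an exact sample: merge the landmark stations
    # into the uniform grid, dropping uniform samples that would crowd one
    lms = np.array(sorted(set(landmarks.values())))
    dist = np.min(np.abs(base[:, None] - lms[None, :]), axis=1)
    s_out = np.unique(np.concatenate([base[dist > 0.35 * spacing], lms]))

    pts = _interp_vectors(s_out, s_d, P_d)
    tan = _interp_vectors(s_out, s_d, T_d)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    cl = Centerline(points=pts, arclen=s_out, tangent=tan, landmarks=landmarks)
    cl._dense_s = s_d
    cl._dense_tangent = T_d
    cl._dense_normal = _double_reflection_rmf(P_d, T_d, np.array([1.0, 0.0, 0.0]))
    return cl


def radius_profile(params: AortaParameterSet, centerline: Centerline) -> RadiusProfile:
    """Radius law r(s): D1/2 up to the arch start, D2/2 at the apex, D3/2 at
    mid-descending and beyond."""
    lm = centerline.landmarks
    for need in ("arch_start", "arch_apex", "mid_descending", "outlet"):
        if need not in lm:
            raise ParameterError(f"centerline lacks landmark {need!r}")
    s_k = [lm["STJ"], lm["arch_start"], lm["arch_apex"], lm["mid_descending"], lm["outlet"]]
    r_k = [params.D1 / 2, params.D1 / 2, params.D2 / 2, params.D3 / 2, params.D3 / 2]
    return RadiusProfile(np.array(s_k), np.array(r_k))


# ---------------------------------------------------------------------------
# branch stations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchStation:
    """Arc-length station and takeoff azimuth of one arch branch."""

    arclen: float
    azimuth: str = "superior"  # direction about the local tangent


def _stations(params: AortaParameterSet, s_arch_end: float) -> dict[str, BranchStation]:
    if params.arch_type is ArchType.TYPE_I:
        stations = {"BA": params.a,
                    "LCA": params.a + params.d1,
                    "LSA": params.a + params.d1 + params.d2}
    else:
        stations = {"trunk": params.a,
                    "LSA": params.a + params.d3}
    for name, s in stations.items():
        if s > s_arch_end:
            raise InfeasibleGeometryError(
                f"branch {name} station at s={s:.2f} cm lies beyond the arch "
                f"end (s={s_arch_end:.2f} cm)")
    return {k: BranchStation(arclen=v) for k, v in stations.items()}


def branch_stations(params: AortaParameterSet,
                    centerline: Centerline) -> dict[str, BranchStation]:
    """Branch stations along the centerline (BA/LCA/LSA or trunk/LSA)."""
    if "arch_end" not in centerline.landmarks:
        raise ParameterError("centerline lacks landmark 'arch_end'")
    return _stations(params, centerline.landmarks["arch_end"])
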