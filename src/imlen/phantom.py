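"""Synthetic aorta/coronary phantoms with known intramural geometry.

The phantom stands in for CTA-derived geometry: a capped-cylinder
"aorta" triangulated at a controllable edge length, and a planar
coronary centerline whose designed signed-distance profile is known in
closed form. The centerline starts inside the cylinder (proximal to the
ostium), crosses the wall radially, runs nearly parallel to the surface
at a small wall offset for the intramural segment, and then curves away.

Ground truth is bookkept geometrically: the ostium is the arc length at
which the centerline crosses the surface (signed distance zero) and the
intramural exit is the arc length of the distance-slope transition, so
``im_exit_arc_mm - ostium_arc_mm`` equals the designed intramural length.

The departure is modelled as a gradual curve: beyond the exit the
distance-vs-arc *slope* rises linearly from ``slope_b`` toward the
asymptotic ``slope_c`` over ``departure_scale_mm`` (default: a quarter
turn of the aortic circumference). A slope of 1 is the geometric
maximum -- distance to a fixed surface is 1-Lipschitz along any curve --
so ``slope_c <= 1`` is required for the construction to be realizable.
An abrupt constant-slope departure would make the distance derivative a
step function, which the continuous two-piece linear model cannot pin
down; the curved departure reflects both real vessel geometry and the
estimator's generative model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from imlen.breakpoint_fit import FitSettings, estimate_im_length
from imlen.errors import PhantomError
from imlen.mesh_io import Centerline, TriangleMesh

__all__ = [
    "PhantomSpec",
    "make_aorta_mesh",
    "make_coronary_centerline",
    "make_phantom",
    "designed_distance",
    "recovery_experiment",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Designed phantom geometry (all lengths in mm).

    ``im_length_mm`` is the ground-truth intramural length measured from
    the ostium (surface crossing) to the distance-slope transition.
    ``d0_mm`` is the wall offset of the intramural segment: the centerline
    runs at distance ``d0_mm`` outside the surface while intramural, and
    at depth ``d0_mm`` inside it proximal to the ostium. ``slope_b`` is
    the intramural distance slope and ``slope_c`` the asymptotic slope of
    the departed vessel (1 = leaving perpendicular to the wall, the
    Lipschitz maximum).
    """

    im_length_mm: float = 8.0
    aorta_radius_mm: float = 12.0
    aorta_height_mm: float = 40.0
    target_edge_mm: float = 0.4
    d0_mm: float = 1.0
    slope_b: float = 0.05
    slope_c: float = 1.0
    departure_scale_mm: float | None = None
    total_length_mm: float = 30.0
    centerline_spacing_mm: float = 0.4
    proximal_inset_mm: float = 2.0
    noise_sd_mm: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        for name in (
            "im_length_mm", "aorta_radius_mm", "aorta_height_mm",
            "target_edge_mm", "d0_mm", "total_length_mm",
            "centerline_spacing_mm", "proximal_inset_mm",
        ):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be positive")
        if not 0.0 < self.im_length_mm < self.total_length_mm:
            raise PhantomError("im_length_mm must lie in (0, total_length_mm)")
        if self.im_length_mm <= self.d0_mm:
            raise PhantomError("im_length_mm must exceed the wall offset d0_mm")
        if not 0.0 <= self.slope_b < 1.0:
            raise PhantomError("slope_b must be in [0, 1)")
        if self.slope_c < self.slope_b:
            raise PhantomError("slope_c must be >= slope_b")
        if self.slope_c > 1.0:
            raise PhantomError(
                "slope_c > 1 is an unreachable distance slope "
                "(distance along a curve is 1-Lipschitz)"
            )
        if self.proximal_inset_mm >= self.total_length_mm:
            raise PhantomError("proximal_inset_mm must be < total_length_mm")
        if self.noise_sd_mm < 0:
            raise PhantomError("noise_sd_mm must be >= 0")
        if self.noise_sd_mm > 0 and self.seed is None:
            raise PhantomError("a seed is mandatory when noise_sd_mm > 0")

    @property
    def departure_mm(self) -> float:
        """Arc scale of the curved departure (default: quarter circumference)."""
        if self.departure_scale_mm is not None:
            return self.departure_scale_mm
        return 0.5 * math.pi * self.aorta_radius_mm


# ---------------------------------------------------------------------------
# designed distance profile
# ---------------------------------------------------------------------------

def designed_distance(spec: PhantomSpec, s_from_ostium) -> np.ndarray:
    """Designed signed distance as a function of arc length from the ostium.

    Piecewise: depth ``-d0`` proximal to the wall crossing, a slope-1
    radial crossing on [-d0, d0], the intramural slope-``b`` regime up to
    ``im_length_mm``, then the curved departure whose slope rises
    linearly from ``b`` to ``c`` over ``departure_mm``.
    """
    s = np.asarray(s_from_ostium, dtype=np.float64)
    d0, b, c = spec.d0_mm, spec.slope_b, spec.slope_c
    Lb = spec.im_length_mm - d0  # slope-b regime length beyond the wall offset
    rate = (c - b) / spec.departure_mm if c > b else 0.0
    v_sat = (c - b) / rate if rate > 0 else np.inf

    out = np.empty_like(s)
    out[s <= -d0] = -d0
    m = (s > -d0) & (s < d0)
    out[m] = s[m]  # radial wall crossing at unit slope
    m = (s >= d0) & (s < d0 + Lb)
    out[m] = d0 + b * (s[m] - d0)
    m = s >= d0 + Lb
    v = s[m] - d0 - Lb
    quad = np.where(
        v <= v_sat,
        b * v + 0.5 * rate * v * v,
        b * v_sat + 0.5 * rate * v_sat * v_sat + c * (v - v_sat),
    ) if np.isfinite(v_sat) else b * v
    out[m] = d0 + b * Lb + quad
    return out if out.ndim else float(out)


def _distance_beyond_wall_offset(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    """Designed distance at design arc t >= 0 past the wall-offset point."""
    return designed_distance(spec, t + spec.d0_mm)


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _ring(radius: float, z: float, n: int, offset: float) -> tuple[np.ndarray, np.ndarray]:
    ang = offset + 2.0 * np.pi * np.arange(n) / n
    pts = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                           np.full(n, z, dtype=np.float64)])
    return pts, ang


def _stitch(inner_idx, inner_ang, outer_idx, outer_ang, flip: bool = False):
    """Triangulate the annulus between two concentric vertex rings.

    Walks both rings in angle order, always advancing the ring whose next
    vertex comes first; produces len(inner) + len(outer) triangles that
    use every boundary edge of each ring exactly once.
    """
    faces = []
    n1, n2 = len(inner_idx), len(outer_idx)
    if n1 == 1:  # center fan
        for j in range(n2):
            faces.append((inner_idx[0], outer_idx[(j + 1) % n2], outer_idx[j]))
    else:
        i = j = 0
        while i < n1 or j < n2:
            ai_next = inner_ang[(i + 1) % n1] + 2.0 * np.pi * ((i + 1) // n1)
            aj_next = outer_ang[(j + 1) % n2] + 2.0 * np.pi * ((j + 1) // n2)
            if j >= n2 or (i < n1 and ai_next <= aj_next):
                faces.append((inner_idx[i % n1], inner_idx[(i + 1) % n1],
                              outer_idx[j % n2]))
                i += 1
            else:
                faces.append((inner_idx[i % n1], outer_idx[(j + 1) % n2],
                              outer_idx[j % n2]))
                j += 1
    faces = np.asarray(faces, dtype=np.int64)
    return faces[:, [0, 2, 1]] if flip else faces


def make_aorta_mesh(spec: PhantomSpec) -> TriangleMesh:
    """Watertight capped cylinder, axis along z, base at z = 0.

    Triangulated with edge lengths close to ``target_edge_mm``: the wall
    is a stack of offset rings, the caps are concentric rings whose point
    counts scale with radius, stitched ring-to-ring.
    """
    R, H, e = spec.aorta_radius_mm, spec.aorta_height_mm, spec.target_edge_mm
    row = e * math.sqrt(3.0) / 2.0  # near-equilateral row spacing
    n_theta = max(8, round(2.0 * math.pi * R / e))
    n_z = max(1, round(H / row))
    n_r = max(1, round(R / row))
    dtheta = 2.0 * math.pi / n_theta

    verts: list[np.ndarray] = []
    angs: list[np.ndarray] = []
    starts: list[int] = []

    def add_ring(radius, z, n, offset):
        starts.append(sum(len(v) for v in verts))
        pts, ang = _ring(radius, z, n, offset)
        verts.append(pts)
        angs.append(ang)
        return len(starts) - 1

    def cap_count(m):
        return max(3, round(n_theta * m / n_r))

    # bottom cap interior rings (center point first), then wall, then top cap
    b_center = add_ring(0.0, 0.0, 1, 0.0)
    b_rings = [add_ring(R * m / n_r, 0.0, cap_count(m), 0.5 * (m % 2) * dtheta)
               for m in range(1, n_r)]
    wall = [add_ring(R, H * j / n_z, n_theta, 0.5 * (j % 2) * dtheta)
            for j in range(n_z + 1)]
    t_center = add_ring(0.0, H, 1, 0.0)
    t_rings = [add_ring(R * m / n_r, H, cap_count(m), 0.5 * (m % 2) * dtheta)
               for m in range(1, n_r)]

    def ring(i):
        n = len(verts[i])
        idx = np.arange(starts[i], starts[i] + n)
        return idx, angs[i]

    faces = []
    bottom = [b_center] + b_rings + [wall[0]]
    for a, b in zip(bottom[:-1], bottom[1:]):
        faces.append(_stitch(*ring(a), *ring(b), flip=False))
    for a, b in zip(wall[:-1], wall[1:]):
        faces.append(_stitch(*ring(a), *ring(b), flip=False))
    top = [t_center] + t_rings + [wall[-1]]
    for a, b in zip(top[:-1], top[1:]):
        faces.append(_stitch(*ring(a), *ring(b), flip=True))

    vertices = np.concatenate(verts)
    return TriangleMesh.from_arrays(vertices, np.concatenate(faces))


# ---------------------------------------------------------------------------
# centerline construction
# ---------------------------------------------------------------------------

def make_coronary_centerline(spec: PhantomSpec) -> tuple[Centerline, dict]:
    """Planar (single-azimuth) centerline with analytic ground truth.

    Points advance by ``centerline_spacing_mm`` of design arc in the x-z
    half-plane: radial coordinate R - d0 during the proximal inset, then
    R + designed distance beyond the ostium; the axial step is chosen so
    each chord has the designed length, ``dz = sqrt(max(ds^2 - dr^2, 0))``.
    The wall crossing is a single radial chord between the last inside
    and first outside samples, so it contributes its radial extent
    (about ``2*d0``) to the true arc length; the returned truth dict
    records the exact geometric ostium and exit arc lengths.
    """
    ds = spec.centerline_spacing_mm
    R, d0 = spec.aorta_radius_mm, spec.d0_mm
    n = int(math.floor(spec.total_length_mm / ds + 1e-9)) + 1
    s_design = np.arange(n) * ds
    inside = s_design < spec.proximal_inset_mm - 1e-12
    n_in = int(inside.sum())
    if n_in < 1:
        raise PhantomError("proximal_inset_mm leaves no centerline point inside")
    if n_in >= n - 1:
        raise PhantomError("centerline ends before exiting the aorta")

    t = s_design[n_in:] - spec.proximal_inset_mm  # design arc past the ostium point
    d_out = _distance_beyond_wall_offset(spec, t)
    r = np.concatenate([np.full(n_in, R - d0), R + d_out])

    dr = np.diff(r)
    ds_step = np.full(n - 1, ds)
    # within-regime steps must be reachable; the single crossing step may not be
    reach = np.abs(dr) <= ds + 1e-12
    if not reach[:n_in - 1].all() or not reach[n_in:].all():
        raise PhantomError("designed radial slope exceeds the arc step (unreachable)")
    dz = np.sqrt(np.maximum(ds_step**2 - dr**2, 0.0))
    z = spec.aorta_height_mm / 4.0 + np.concatenate([[0.0], np.cumsum(dz)])
    points = np.column_stack([r, np.zeros(n), z])

    if spec.noise_sd_mm > 0:
        rng = np.random.default_rng(spec.seed)
        points = points + rng.normal(0.0, spec.noise_sd_mm, size=points.shape)

    # geometric truth from the noiseless design
    chord = float(np.hypot(dr[n_in - 1], dz[n_in - 1]))
    arc_last_inside = (n_in - 1) * ds
    t_first = float(t[0])
    frac_to_zero = d0 / (d0 + d_out[0])
    ostium_arc = arc_last_inside + frac_to_zero * chord
    Lb = spec.im_length_mm - d0
    if t_first > Lb:
        raise PhantomError("first sample past the ostium already beyond the exit")
    exit_arc = arc_last_inside + chord + (Lb - t_first)
    truth = {
        "ostium_arc_mm": ostium_arc,
        "im_exit_arc_mm": exit_arc,
        "im_length_mm": exit_arc - ostium_arc,
    }
    return Centerline.from_points(points), truth


def make_phantom(spec: PhantomSpec) -> tuple[TriangleMesh, Centerline, dict]:
    """Mesh, centerline and ground-truth dict for one phantom."""
    mesh = make_aorta_mesh(spec)
    centerline, truth = make_coronary_centerline(spec)
    return mesh, centerline, truth


# ---------------------------------------------------------------------------
# recovery harness
# ---------------------------------------------------------------------------

def recovery_experiment(
    specs, settings: FitSettings | None = None
) -> pd.DataFrame:
    """Run the full estimator on each phantom and tabulate recovery errors.

    Returns a DataFrame with the designed and estimated intramural length
    and their difference per phantom; the summary RMSE is stored in
    ``df.attrs["rmse_mm"]``. Meshes are cached across specs that share
    cylinder geometry, so sweeps over seeds or intramural lengths reuse
    one surface.
    """
    mesh_cache: dict[tuple, TriangleMesh] = {}
    rows = []
    for spec in specs:
        key = (spec.aorta_radius_mm, spec.aorta_height_mm, spec.target_edge_mm)
        if key not in mesh_cache:
            mesh_cache[key] = make_aorta_mesh(spec)
        centerline, truth = make_coronary_centerline(spec)
        result = estimate_im_length(mesh_cache[key], centerline, settings)
        rows.append(
            {
                "im_length_true_mm": truth["im_length_mm"],
                "im_length_est_mm": result.im_length_mm,
                "error_mm": result.im_length_mm - truth["im_length_mm"],
                "seed": spec.seed,
                "noise_sd_mm": spec.noise_sd_mm,
                "target_edge_mm": spec.target_edge_mm,
                "centerline_spacing_mm": spec.centerline_spacing_mm,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["rmse_mm"] = float(np.sqrt(np.mean(df["error_mm"] ** 2)))
    return df
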