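"""Cell geometry and cytoskeleton architectures.

The cell is a sphere centred at the origin with an optional spherical
nucleus.  Cytoskeleton filaments are static oriented polylines; the vertex
order defines polarity (``vertices[0]`` is the minus end, ``vertices[-1]``
the plus end), so a plus-directed motor walks toward increasing arc length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import CellParams, CompartmentSpec, CytoskeletonParams


class GeometryError(ValueError):
    pass


@dataclass
class CellGeometry:
    cell_radius: float
    nucleus_center: np.ndarray
    nucleus_radius: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def contains(self, p: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True where points are inside the cell and outside the nucleus."""
        p = np.atleast_2d(p)
        inside = np.linalg.norm(p, axis=1) <= self.cell_radius - margin
        if self.nucleus_radius > 0:
            out_nuc = np.linalg.norm(p - self.nucleus_center, axis=1) >= (
                self.nucleus_radius + margin)
            inside &= out_nuc
        return inside

    def in_nucleus(self, p: np.ndarray, margin: float = 0.0) -> np.ndarray:
        p = np.atleast_2d(p)
        if self.nucleus_radius <= 0:
            return np.zeros(len(p), dtype=bool)
        return np.linalg.norm(p - self.nucleus_center, axis=1) <= (
            self.nucleus_radius - margin)


def build_cell(params: CellParams) -> CellGeometry:
    """Construct the cell; its membranes act as reflecting boundaries."""
    nc = np.asarray(params.nucleus_center, dtype=float)
    if params.nucleus_radius < 0:
        raise GeometryError("nucleus radius must be >= 0")
    if params.nucleus_radius > 0:
        if np.linalg.norm(nc) + params.nucleus_radius >= params.radius:
            raise GeometryError("nucleus must lie strictly inside the cell")
    return CellGeometry(cell_radius=params.radius, nucleus_center=nc,
                        nucleus_radius=params.nucleus_radius)


@dataclass
class Filament:
    """Oriented polyline; motors read direction from the vertex order."""

    fid: int
    vertices: np.ndarray  # (n, 3)
    ftype: str = "microtubule"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2:
            raise GeometryError("filament needs at least two vertices")
        seg = np.diff(self.vertices, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        if np.any(seglen <= 0):
            raise GeometryError("consecutive filament vertices must be distinct")
        self._seglen = seglen
        self._cum = np.concatenate(([0.0], np.cumsum(seglen)))

    @property
    def length(self) -> float:
        return float(self._cum[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Position at arc length ``s`` (clamped to [0, length])."""
        s = min(max(s, 0.0), self.length)
        i = int(np.searchsorted(self._cum, s, side="right") - 1)
        i = min(i, len(self._seglen) - 1)
        f = (s - self._cum[i]) / self._seglen[i]
        return self.vertices[i] + f * (self.vertices[i + 1] - self.vertices[i])

    def tangent_at(self, s: float) -> np.ndarray:
        s = min(max(s, 0.0), self.length)
        i = int(np.searchsorted(self._cum, s, side="right") - 1)
        i = min(i, len(self._seglen) - 1)
        d = self.vertices[i + 1] - self.vertices[i]
        return d / np.linalg.norm(d)

    def nearest(self, p: np.ndarray) -> tuple[float, float]:
        """(distance, arc length of nearest point) for a single point."""
        a = self.vertices[:-1]
        b = self.vertices[1:]
        ab = b - a
        t = np.einsum("ij,ij->i", p[None, :] - a, ab) / (self._seglen ** 2)
        t = np.clip(t, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(proj - p[None, :], axis=1)
        i = int(np.argmin(d))
        return float(d[i]), float(self._cum[i] + t[i] * self._seglen[i])


# ---------------------------------------------------------------------------
# cytoskeleton generation
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _clip_to_cell(vertices: np.ndarray, R: float) -> np.ndarray:
    """Truncate a polyline at the first vertex outside the cell sphere."""
    norms = np.linalg.norm(vertices, axis=1)
    out = np.nonzero(norms > R)[0]
    if len(out) == 0:
        return vertices
    return vertices[: max(out[0], 2)]


def _find_compartment(comps: list[CompartmentSpec], cid: Optional[str],
                      default_index: int) -> CompartmentSpec:
    if cid is None:
        return comps[default_index]
    for c in comps:
        if c.id == cid:
            return c
    raise GeometryError(f"cytoskeleton references unknown compartment {cid!r}")


def _dipole_field(p: np.ndarray, c_plus: np.ndarray, c_minus: np.ndarray) -> np.ndarray:
    d1 = p - c_plus
    d2 = p - c_minus
    return d1 / np.linalg.norm(d1) ** 3 - d2 / np.linalg.norm(d2) ** 3


def trace_field_line(seed: np.ndarray, c_plus: np.ndarray, r_target: float,
                     c_minus: np.ndarray, R_cell: float, step: float = 0.01,
                     max_steps: int = 20000) -> np.ndarray:
    """Trace a field line of two opposite point charges from ``seed``.

    Fixed-step integration along the normalized field; stops on entering the
    target sphere around ``c_minus`` or on reaching the plasma membrane.
    """
    pts = [np.asarray(seed, dtype=float)]
    p = pts[0].copy()
    for _ in range(max_steps):
        e = _dipole_field(p, c_plus, c_minus)
        n = np.linalg.norm(e)
        if n == 0:
            break
        p = p + step * e / n
        pts.append(p.copy())
        if np.linalg.norm(p - c_minus) <= r_target:
            break
        if np.linalg.norm(p) >= R_cell:
            break
    return np.array(pts)


def _decimate(vertices: np.ndarray, keep_every: int = 10) -> np.ndarray:
    """Thin a densely sampled polyline, always keeping the endpoints."""
    if len(vertices) <= 2:
        return vertices
    idx = list(range(0, len(vertices) - 1, keep_every)) + [len(vertices) - 1]
    return vertices[idx]


def generate_cytoskeleton(params: CytoskeletonParams, cell: CellGeometry,
                          compartments: list[CompartmentSpec],
                          rng: np.random.Generator) -> list[Filament]:
    """Generate one of the supported cytoskeleton architectures.

    Polarity convention for the two-compartment styles (direct/linear/dipole):
    filaments run donor -> target, so plus-directed motors carry vesicles
    from the donor compartment toward the target.  Radial/polarized rays run
    cell centre -> plasma membrane.
    """
    style = params.style
    R = cell.cell_radius
    n = params.n_filaments
    fils: list[Filament] = []

    if style == "none":
        return fils

    if style == "random":
        for i in range(n):
            start = _random_unit(rng)[0] * (R * rng.uniform(0, 0.9) ** (1 / 3))
            d = _random_unit(rng)[0]
            pts = [start]
            length = 0.0
            while length < params.length:
                # persistent random walk: small angular kick each step
                kick = rng.normal(scale=params.step / max(params.persistence, 1e-9),
                                  size=3)
                d = _unit(d + kick)
                nxt = pts[-1] + d * params.step
                if np.linalg.norm(nxt) > R:
                    break
                pts.append(nxt)
                length += params.step
            if len(pts) >= 2:
                fils.append(Filament(fid=i, vertices=_decimate(np.array(pts), 4),
                                     ftype="microtubule"))
        return fils

    if style in ("direct", "linear", "dipole"):
        if len(compartments) < 2:
            raise GeometryError(f"style {style!r} needs two compartments")
        donor = _find_compartment(compartments, params.donor, 0)
        target = _find_compartment(compartments, params.target, 1)
        c1 = np.asarray(donor.center)
        c2 = np.asarray(target.center)
        axis = _unit(c2 - c1)
        # orthonormal frame around the axis
        tmp = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(tmp, axis)) > 0.9:
            tmp = np.array([0.0, 1.0, 0.0])
        e1 = _unit(np.cross(axis, tmp))
        e2 = np.cross(axis, e1)

        if style == "direct":
            for i in range(n):
                rho = params.bundle_radius * np.sqrt(rng.uniform())
                phi = rng.uniform(0, 2 * np.pi)
                off = rho * (np.cos(phi) * e1 + np.sin(phi) * e2)
                # chord offsets must stay on both spheres
                if rho >= min(donor.radius, target.radius):
                    off = off * 0.99 * min(donor.radius, target.radius) / max(rho, 1e-12)
                    rho = np.linalg.norm(off)
                a = c1 + off + axis * np.sqrt(max(donor.radius ** 2 - rho ** 2, 0.0))
                b = c2 + off - axis * np.sqrt(max(target.radius ** 2 - rho ** 2, 0.0))
                fils.append(Filament(fid=i, vertices=np.array([a, b])))
            return fils

        if style == "linear":
            for i in range(n):
                rho = params.spread * np.sqrt(rng.uniform())
                phi = rng.uniform(0, 2 * np.pi)
                off = rho * (np.cos(phi) * e1 + np.sin(phi) * e2)
                mid = (c1 + c2) / 2 + off
                # span the cell along the axis direction through `mid`
                b_coef = np.dot(mid, axis)
                disc = b_coef ** 2 - (np.dot(mid, mid) - R ** 2)
                if disc <= 0:
                    continue
                t1 = -b_coef - np.sqrt(disc)
                t2 = -b_coef + np.sqrt(disc)
                a = mid + axis * t1 * 0.98
                b = mid + axis * t2 * 0.98
                fils.append(Filament(fid=i, vertices=np.array([a, b])))
            return fils

        # dipole: field lines of +q at donor centre, -q at target centre.
        # Seeds sit a small standoff above the donor surface: the structure
        # captures diffusing vesicles rather than touching the budding sites.
        # Lines whose excursion leaves the cell are re-seeded so the kept
        # structure focuses onto the target.
        r_stop = target.radius * 1.02
        for i in range(n):
            for _ in range(50):
                u = _random_unit(rng)[0]
                seed = c1 + u * (donor.radius + 0.25)
                pts = trace_field_line(seed, c1, r_stop, c2, R * 0.995,
                                       step=params.step / 5 if params.step
                                       else 0.01)
                if len(pts) >= 2 and np.linalg.norm(pts[-1] - c2) <= r_stop * 1.1:
                    fils.append(Filament(fid=i, vertices=_decimate(pts, 10)))
                    break
        return fils

    if style in ("radial", "polarized"):
        if style == "radial":
            dirs = _random_unit(rng, n)
        else:
            # von Mises-Fisher directions concentrated toward the pole
            kappa = max(params.polarization, 1e-9)
            mu = _unit(np.asarray(params.pole, dtype=float))
            dirs = _sample_vmf(mu, kappa, n, rng)
        start_r = cell.nucleus_radius if cell.nucleus_radius > 0 else 0.0
        for i, d in enumerate(dirs):
            a = d * start_r if start_r > 0 else np.zeros(3)
            b = d * (R * 0.995)
            fils.append(Filament(fid=i, vertices=np.array([a, b])))
        return fils

    raise GeometryError(f"unknown cytoskeleton style {style!r}")


def _sample_vmf(mu: np.ndarray, kappa: float, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Sample unit vectors from a von Mises-Fisher distribution."""
    # inverse-CDF sampling of cos(theta) for vMF on S^2
    u = rng.uniform(size=n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0, 2 * np.pi, size=n)
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(tmp, mu)) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(mu, tmp))
    e2 = np.cross(mu, e1)
    st = np.sqrt(np.clip(1 - w ** 2, 0.0, None))
    return (w[:, None] * mu[None, :]
            + st[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))


# ---------------------------------------------------------------------------
# distance queries
# ---------------------------------------------------------------------------

@dataclass
class StructureHit:
    kind: str            # 'filament' | 'membrane' | 'nucleus'
    distance: float
    normal: np.ndarray   # surface normal / direction away from structure
    filament: Optional[Filament] = None
    arc: float = 0.0


class StructureField:
    """Exact Euclidean distance queries against filaments and membranes."""

    def __init__(self, cell: CellGeometry, filaments: list[Filament]):
        self.cell = cell
        self.filaments = filaments
        if filaments:
            segs_a, segs_b, owner, arc0 = [], [], [], []
            for f in filaments:
                segs_a.append(f.vertices[:-1])
                segs_b.append(f.vertices[1:])
                owner.append(np.full(len(f.vertices) - 1, f.fid))
                arc0.append(f._cum[:-1])
            self._a = np.concatenate(segs_a)
            self._b = np.concatenate(segs_b)
            self._owner = np.concatenate(owner)
            self._arc0 = np.concatenate(arc0)
            self._ab = self._b - self._a
            self._len2 = np.einsum("ij,ij->i", self._ab, self._ab)
            self._byid = {f.fid: f for f in filaments}

    def nearest_filament(self, p: np.ndarray) -> Optional[StructureHit]:
        if not self.filaments:
            return None
        t = np.einsum("j,ij->i", p, self._ab) - np.einsum("ij,ij->i", self._a, self._ab)
        t = np.clip(t / self._len2, 0.0, 1.0)
        proj = self._a + t[:, None] * self._ab
        diff = p[None, :] - proj
        d = np.linalg.norm(diff, axis=1)
        i = int(np.argmin(d))
        fil = self._byid[int(self._owner[i])]
        arc = float(self._arc0[i] + t[i] * np.linalg.norm(self._ab[i]))
        normal = diff[i] / d[i] if d[i] > 0 else np.array([0.0, 0.0, 1.0])
        return StructureHit("filament", float(d[i]), normal, filament=fil, arc=arc)

    def filaments_within(self, p: np.ndarray, cutoff: float) -> list[StructureHit]:
        """All filaments whose nearest point lies within ``cutoff`` of ``p``."""
        if not self.filaments:
            return []
        t = np.einsum("j,ij->i", p, self._ab) - np.einsum("ij,ij->i", self._a, self._ab)
        t = np.clip(t / self._len2, 0.0, 1.0)
        proj = self._a + t[:, None] * self._ab
        diff = p[None, :] - proj
        d = np.linalg.norm(diff, axis=1)
        hits: dict[int, StructureHit] = {}
        for i in np.nonzero(d <= cutoff)[0]:
            fid = int(self._owner[i])
            if fid in hits and hits[fid].distance <= d[i]:
                continue
            fil = self._byid[fid]
            arc = float(self._arc0[i] + t[i] * np.linalg.norm(self._ab[i]))
            normal = (diff[i] / d[i]) if d[i] > 0 else np.array([0.0, 0.0, 1.0])
            hits[fid] = StructureHit("filament", float(d[i]), normal,
                                     filament=fil, arc=arc)
        return list(hits.values())

    def distance_to_structures(self, p: np.ndarray) -> StructureHit:
        """Nearest structure (filament segment, plasma membrane, or nucleus)."""
        p = np.asarray(p, dtype=float)
        rnorm = np.linalg.norm(p)
        best = StructureHit("membrane", float(self.cell.cell_radius - rnorm),
                            normal=-_unit(p) if rnorm > 0 else np.array([0.0, 0, 1.0]))
        if self.cell.nucleus_radius > 0:
            dn = p - self.cell.nucleus_center
            dist = float(np.linalg.norm(dn) - self.cell.nucleus_radius)
            if dist < best.distance:
                best = StructureHit("nucleus", dist,
                                    normal=_unit(dn) if np.linalg.norm(dn) > 0
                                    else np.array([0.0, 0, 1.0]))
        fh = self.nearest_filament(p)
        if fh is not None and fh.distance < best.distance:
            best = fh
        return best


def export_filaments(filaments: list[Filament]) -> "pd.DataFrame":
    """Polyline table: filament id, vertex index, x, y, z, polarity index."""
    import pandas as pd

    rows = []
    for f in filaments:
        for i, v in enumerate(f.vertices):
            rows.append((f.fid, i, v[0], v[1], v[2], f.ftype))
    return pd.DataFrame(rows, columns=["filament", "vertex", "x", "y", "z", "type"])
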