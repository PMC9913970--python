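"""Tumor/spheroid surface geometry, compartment classification, drift correction.

Tracked cells are assigned to three mutually exclusive compartments by signed
distance ``d`` to the tumor surface (negative inside):

* **infiltrating** — inside or on the surface (``d <= 0``);
* **approaching** — outside but closer than the approach band
  (``0 < d < band``, band default 10 um);
* **peripheral** — at or beyond the band (``d >= band``).

The boundary conventions are deterministic: a point exactly on the surface is
infiltrating, a point exactly at the band distance is peripheral ("closer
than 10 um" is strict). A whole track is labelled by the time-majority of its
per-frame labels, ties broken by infiltrating > approaching > peripheral.

Surfaces are either an analytic sphere or a closed triangle mesh; both expose
the same signed-distance contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tracks import Track, TrackSet

__all__ = [
    "SphereSurface",
    "MeshSurface",
    "SurfaceValidityError",
    "LABELS",
    "DEFAULT_APPROACH_BAND_UM",
    "classify_points",
    "classify_track",
    "compartment_counts",
    "drift_correct",
    "load_surface",
    "save_surface",
]

#: Approach band outside the surface, micrometres.
DEFAULT_APPROACH_BAND_UM = 10.0

#: Compartment labels ordered by tie-break priority.
LABELS = ("infiltrating", "approaching", "peripheral")


class SurfaceValidityError(ValueError):
    """Surface fails a validity check (non-positive radius, open mesh, ...)."""


@dataclass(frozen=True)
class SphereSurface:
    """Analytic sphere: ``signed_distance(p) = |p - center| - radius``."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise SurfaceValidityError("sphere radius must be positive")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(pts - np.asarray(self.center, dtype=float), axis=1) - self.radius
        return d if np.ndim(points) > 1 else d[0]


class MeshSurface:
    """Closed triangulated surface with signed distance by ray parity.

    The unsigned distance is the exact distance to the nearest triangle
    (vectorized point-triangle projection over all faces); the sign comes
    from an even/odd crossing count of a ray cast along +x. The mesh must be
    watertight for the inside test to be meaningful; this is checked on
    construction via edge pairing (every undirected edge shared by exactly
    two faces).
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise SurfaceValidityError("vertices must have shape (nv, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise SurfaceValidityError("faces must have shape (nf, 3)")
        if not self._is_watertight():
            raise SurfaceValidityError("mesh is not watertight (open or non-manifold edges)")
        # cache triangle vertex arrays
        self._a = self.vertices[self.faces[:, 0]]
        self._b = self.vertices[self.faces[:, 1]]
        self._c = self.vertices[self.faces[:, 2]]

    def _is_watertight(self) -> bool:
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    @classmethod
    def from_file(cls, path) -> "MeshSurface":
        """Load an OFF/PLY/STL mesh (requires trimesh)."""
        import trimesh  # optional dependency

        m = trimesh.load_mesh(str(path))
        return cls(np.asarray(m.vertices), np.asarray(m.faces))

    # -- unsigned distance: min over plane projection and clamped edges --
    @staticmethod
    def _segment_dist2(p, a, ab):
        """Squared distance from points p (np,1,3) to segments a + t*ab, t in [0,1]."""
        ab2 = np.einsum("ijk,ijk->ij", ab, ab)
        t = np.einsum("ijk,ijk->ij", p - a, ab) / np.where(ab2 > 0, ab2, 1.0)
        t = np.clip(t, 0.0, 1.0)
        diff = p - (a + t[..., None] * ab)
        return np.einsum("ijk,ijk->ij", diff, diff)

    def _unsigned_distance(self, pts: np.ndarray) -> np.ndarray:
        out = np.empty(pts.shape[0])
        # chunk over points to bound memory at n_faces * chunk
        chunk = max(1, int(2e6 / max(len(self.faces), 1)))
        for s in range(0, pts.shape[0], chunk):
            p = pts[s : s + chunk, None, :]  # (np, 1, 3)
            a, b, c = self._a[None], self._b[None], self._c[None]
            ab = b - a
            ac = c - a
            n = np.cross(ab, ac)
            n2 = np.einsum("ijk,ijk->ij", n, n)
            ap = p - a
            # barycentric coordinates of the plane projection
            dist_plane = np.einsum("ijk,ijk->ij", ap, n) / np.where(n2 > 0, np.sqrt(n2), 1.0)
            proj = p - dist_plane[..., None] * (n / np.where(n2 > 0, np.sqrt(n2), 1.0)[..., None])
            vp = proj - a
            d00 = np.einsum("ijk,ijk->ij", ab, ab)
            d01 = np.einsum("ijk,ijk->ij", ab, ac)
            d11 = np.einsum("ijk,ijk->ij", ac, ac)
            d20 = np.einsum("ijk,ijk->ij", vp, ab)
            d21 = np.einsum("ijk,ijk->ij", vp, ac)
            denom = d00 * d11 - d01 * d01
            denom_safe = np.where(np.abs(denom) > 0, denom, 1.0)
            v = (d11 * d20 - d01 * d21) / denom_safe
            w = (d00 * d21 - d01 * d20) / denom_safe
            inside = (v >= 0) & (w >= 0) & (v + w <= 1) & (np.abs(denom) > 0)
            d2 = np.where(inside, dist_plane**2, np.inf)
            d2 = np.minimum(d2, self._segment_dist2(p, a, ab))
            d2 = np.minimum(d2, self._segment_dist2(p, a, ac))
            d2 = np.minimum(d2, self._segment_dist2(p, b, c - b))
            out[s : s + chunk] = np.sqrt(np.min(d2, axis=1))
        return out

    def _contains(self, pts: np.ndarray) -> np.ndarray:
        """Even/odd parity of triangle crossings of a +x ray from each point."""
        a, b, c = self._a, self._b, self._c
        inside = np.zeros(pts.shape[0], dtype=bool)
        # Moller-Trumbore with ray direction (1, 0, 0); tiny direction jitter
        # avoids edge-degenerate hits on axis-aligned meshes.
        direction = np.array([1.0, 1.3e-7, 2.7e-7])
        e1 = b - a
        e2 = c - a
        h = np.cross(np.broadcast_to(direction, e2.shape), e2)
        det = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(det) > 1e-12
        for i, p in enumerate(pts):
            s = p - a[ok]
            u = np.einsum("ij,ij->i", s, h[ok]) / det[ok]
            q = np.cross(s, e1[ok])
            v = np.einsum("j,ij->i", direction, q) / det[ok]
            t = np.einsum("ij,ij->i", e2[ok], q) / det[ok]
            hits = (u >= 0) & (u <= 1) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
            inside[i] = bool(np.count_nonzero(hits) % 2)
        return inside

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = self._unsigned_distance(pts)
        d[self._contains(pts)] *= -1
        return d if np.ndim(points) > 1 else d[0]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_points(
    surface, points: np.ndarray, approach_band: float = DEFAULT_APPROACH_BAND_UM
) -> np.ndarray:
    """Per-point compartment labels (array of str).

    ``d <= 0`` infiltrating; ``0 < d < approach_band`` approaching;
    ``d >= approach_band`` peripheral.
    """
    d = np.atleast_1d(surface.signed_distance(np.atleast_2d(np.asarray(points, float))))
    labels = np.where(d <= 0, LABELS[0], np.where(d < approach_band, LABELS[1], LABELS[2]))
    return labels


def classify_track(
    surface, track: Track, approach_band: float = DEFAULT_APPROACH_BAND_UM
) -> str:
    """Time-majority compartment label of a track.

    Ties are broken by priority infiltrating > approaching > peripheral,
    keeping the label stable under brief excursions across the surface.
    """
    labels = classify_points(surface, track.positions, approach_band)
    counts = {lab: int(np.sum(labels == lab)) for lab in LABELS}
    return max(LABELS, key=lambda lab: (counts[lab], -LABELS.index(lab)))


def compartment_counts(
    ts: TrackSet,
    surface,
    approach_band: float = DEFAULT_APPROACH_BAND_UM,
    per: str = "track",
) -> pd.DataFrame:
    """Counts and fractions of tracks (or spots) per compartment.

    ``per="track"`` (default) counts each track once under its time-majority
    label; ``per="spot"`` counts every detection under its per-frame label.
    Returns a DataFrame indexed by label with ``count`` and ``fraction``
    columns; fractions sum to 1 (empty input gives zero counts).
    """
    if per not in ("track", "spot"):
        raise ValueError("per must be 'track' or 'spot'")
    counts = dict.fromkeys(LABELS, 0)
    if per == "track":
        for tr in ts:
            counts[classify_track(surface, tr, approach_band)] += 1
    else:
        for tr in ts:
            labels = classify_points(surface, tr.positions, approach_band)
            for lab in LABELS:
                counts[lab] += int(np.sum(labels == lab))
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "count": [counts[lab] for lab in LABELS],
            "fraction": [counts[lab] / total if total else 0.0 for lab in LABELS],
        },
        index=pd.Index(LABELS, name="compartment"),
    )


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------


def drift_correct(ts: TrackSet, reference: np.ndarray | None = None) -> TrackSet:
    """Remove global stage/tissue drift by per-frame median displacement.

    The frame-to-frame global translation is estimated as the coordinate-wise
    median displacement over all spots present in both frames (or over the
    supplied per-frame ``reference`` anchor positions, shape
    ``(n_frames, n_anchors, 3)``), then cumulatively subtracted. The median is
    robust to genuinely moving cells; because the median is translation-
    equivariant, the corrected output is invariant to any injected global
    translation field.

    A single-frame TrackSet is returned unchanged (flagged corrected).
    """
    frames = sorted({int(f) for tr in ts for f in tr.frames})
    out_tracks = [t for t in ts]
    if len(frames) < 2:
        import warnings

        warnings.warn("drift_correct: fewer than 2 frames, no-op", stacklevel=2)
        return TrackSet(
            tracks=list(out_tracks),
            field_extent=ts.field_extent,
            movie_duration_s=ts.movie_duration_s,
            drift_corrected=True,
        )
    fmin, fmax = frames[0], frames[-1]
    n_frames = fmax - fmin + 1
    step = np.zeros((n_frames, 3))  # estimated translation from frame k-1 -> k
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if ref.ndim == 2:
            ref = ref[:, None, :]
        if ref.shape[0] != n_frames:
            raise ValueError("reference must supply anchors for every frame")
        step[1:] = np.median(ref[1:] - ref[:-1], axis=1)
    else:
        disp: dict[int, list[np.ndarray]] = {k: [] for k in range(1, n_frames)}
        for tr in ts:
            idx = tr.frames - fmin
            contiguous = np.flatnonzero(np.diff(tr.frames) == 1)
            for i in contiguous:
                disp[int(idx[i + 1])].append(tr.positions[i + 1] - tr.positions[i])
        for k in range(1, n_frames):
            if disp[k]:
                step[k] = np.median(np.asarray(disp[k]), axis=0)
    cumulative = np.cumsum(step, axis=0)  # translation of frame k relative to frame fmin
    corrected = [
        tr.translated(-cumulative[tr.frames - fmin]) for tr in out_tracks
    ]
    return TrackSet(
        tracks=corrected,
        field_extent=ts.field_extent,
        movie_duration_s=ts.movie_duration_s,
        drift_corrected=True,
    )


# ---------------------------------------------------------------------------
# Surface I/O
# ---------------------------------------------------------------------------


def save_surface(surface, path) -> None:
    """Write a JSON descriptor for a sphere surface."""
    if isinstance(surface, SphereSurface):
        Path(path).write_text(
            json.dumps(
                {"type": "sphere", "center": list(surface.center), "radius": surface.radius}
            )
        )
    else:
        raise ValueError("only sphere surfaces serialize to JSON; save meshes as OFF/PLY")


def load_surface(path):
    """Load a surface from a JSON sphere descriptor or a mesh file (OFF/PLY/STL)."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        spec = json.loads(p.read_text())
        if spec.get("type") != "sphere":
            raise SurfaceValidityError(f"unknown surface type {spec.get('type')!r}")
        return SphereSurface(center=tuple(spec["center"]), radius=float(spec["radius"]))
    return MeshSurface.from_file(p)
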