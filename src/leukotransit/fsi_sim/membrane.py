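"""Closed elastic membrane discretized as Lagrangian markers.

The cell boundary is an ordered, counter-clockwise, closed polyline of
markers carrying a linearly elastic constitutive law: a stretching term
with plane-stress stiffness ``k_s = E h / (1 - nu^2)`` per unit length, a
small plate-theory bending regularization ``k_b = E h^3 / (12 (1 - nu^2))``
that suppresses sub-grid buckling, and a weak global area penalty that
counteracts the slow volume leakage inherent to regularized-delta
interpolation.  All nodal forces are gradients of a discrete elastic
energy, so the unstressed reference circle is exactly force-free and the
total force (and the area-penalty contribution in particular) sums to zero.

Each marker carries a *material* coordinate: its angle on the unstressed
reference circle.  Resampling — needed when squeezing stretches or crowds
the deformed spacing out of the delta kernel's reliable range — places new
markers uniformly in deformed arc length and interpolates the material
coordinate along the curve, so local elastic strain survives resampling to
interpolation accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["Membrane", "polygon_area", "polygon_centroid"]


def polygon_area(X: np.ndarray) -> float:
    """Signed area of a closed polyline (positive for CCW orientation)."""
    x, y = X[:, 0], X[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_centroid(X: np.ndarray) -> np.ndarray:
    """Area centroid of a closed polyline."""
    x, y = X[:, 0], X[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


class Membrane:
    """Marker-based closed membrane with a circular reference shape.

    Parameters
    ----------
    center, radius
        Reference (unstressed) circle.
    n_markers
        Initial marker count; markers start uniform in reference angle.
    k_s, k_b, k_a
        Stretching (N/m), bending (N*m) and area-penalty (Pa) stiffnesses.
    """

    def __init__(self, center, radius: float, n_markers: int, k_s: float, k_b: float, k_a: float):
        if n_markers < 8:
            raise ValueError(f"need at least 8 markers, got {n_markers}")
        self.center0 = np.asarray(center, dtype=float)
        self.radius = float(radius)
        self.k_s = float(k_s)
        self.k_b = float(k_b)
        self.k_a = float(k_a)
        theta = 2.0 * np.pi * np.arange(n_markers) / n_markers  # CCW material angle
        self.X = self.center0 + self.radius * np.column_stack(
            [np.cos(theta), np.sin(theta)]
        )
        self._set_reference(theta)

    def _set_reference(self, theta: np.ndarray) -> None:
        """Recompute reference geometry for material angles ``theta``."""
        self.theta = theta
        self.n = len(theta)
        ref = self.radius * np.column_stack([np.cos(theta), np.sin(theta)])
        # rest segment length = reference polygon chord, so the discrete
        # reference circle is exactly force-free
        dtheta = np.diff(np.append(theta, theta[0] + 2.0 * np.pi))
        self.ds0 = 2.0 * self.radius * np.sin(dtheta / 2.0)
        self.ds0_mean = float(self.ds0.mean())
        # reference second difference (discrete curvature vector)
        self.C0 = np.roll(ref, -1, axis=0) - 2.0 * ref + np.roll(ref, 1, axis=0)
        self.area0 = polygon_area(self.center0 + ref)

    # -- geometry -----------------------------------------------------------

    @property
    def segment_vectors(self) -> np.ndarray:
        return np.roll(self.X, -1, axis=0) - self.X

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors, axis=1)

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.X)

    @property
    def area(self) -> float:
        return polygon_area(self.X)

    def r_max(self) -> float:
        """Deformation extent: max marker distance from the centroid."""
        return float(np.max(np.linalg.norm(self.X - self.centroid, axis=1)))

    def outward_normals(self) -> np.ndarray:
        """Unit outward normals at markers (CCW polygon assumed)."""
        d = np.roll(self.X, -1, axis=0) - np.roll(self.X, 1, axis=0)
        n = np.column_stack([d[:, 1], -d[:, 0]])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def marker_weights(self) -> np.ndarray:
        """Arclength weight of each marker (mean of adjacent segments)."""
        L = self.segment_lengths
        return 0.5 * (L + np.roll(L, 1))

    # -- elasticity ---------------------------------------------------------

    def elastic_force(self) -> np.ndarray:
        """Nodal elastic forces (N per unit depth), -dE/dX.

        Zero in the reference configuration; doubles when the elastic
        modulus doubles at fixed shape (linear elasticity).
        """
        D = self.segment_vectors
        L = np.linalg.norm(D, axis=1)
        if np.any(L < 1e-3 * self.ds0_mean):
            k = int(np.argmin(L))
            raise FloatingPointError(
                f"degenerate membrane segment {k} (length {L[k]:.3e} m << "
                f"reference {self.ds0_mean:.3e} m); the marker distribution collapsed"
            )
        that = D / L[:, None]
        tension = self.k_s * (L / self.ds0 - 1.0)
        f = tension[:, None] * that
        force = f - np.roll(f, 1, axis=0)

        if self.k_b > 0:
            C = np.roll(self.X, -1, axis=0) - 2.0 * self.X + np.roll(self.X, 1, axis=0) - self.C0
            lap = np.roll(C, -1, axis=0) - 2.0 * C + np.roll(C, 1, axis=0)
            force -= (self.k_b / self.ds0_mean**3) * lap

        if self.k_a > 0:
            dA = self.area - self.area0
            y = self.X[:, 1]
            x = self.X[:, 0]
            grad = 0.5 * np.column_stack(
                [np.roll(y, -1) - np.roll(y, 1), np.roll(x, 1) - np.roll(x, -1)]
            )
            force -= self.k_a * (dA / self.area0) * grad

        return force

    # -- resampling ---------------------------------------------------------

    def max_spacing_ratio(self, h: float) -> float:
        return float(self.segment_lengths.max() / h)

    def min_spacing_ratio(self, h: float) -> float:
        return float(self.segment_lengths.min() / h)

    def needs_resample(self, h: float, band=(0.45, 1.9)) -> bool:
        L = self.segment_lengths
        return bool(L.min() < band[0] * h or L.max() > band[1] * h)

    def resample(self, target_spacing: float) -> None:
        """Redistribute markers uniformly in deformed arc length.

        New positions come from a periodic cubic spline of the current
        shape; each new marker inherits a material angle interpolated along
        the same curve, so the reference configuration follows the material
        and the local strain field is preserved.
        """
        for _ in range(2):  # second pass corrects chord-vs-arc parameter bias
            L = self.segment_lengths
            arc = np.concatenate([[0.0], np.cumsum(L)])  # length n+1, closed
            total = arc[-1]
            n_new = max(16, int(round(total / target_spacing)))
            Xp = np.vstack([self.X, self.X[:1]])
            shape = CubicSpline(arc, Xp, bc_type="periodic")
            # unwrap the material angle so it is monotone along the curve
            th = np.unwrap(self.theta)
            th = np.append(th, th[0] + 2.0 * np.pi)
            arc_new = total * np.arange(n_new) / n_new
            X_new = shape(arc_new)
            th_new = np.interp(arc_new, arc, th)
            self.X = X_new
            self._set_reference(np.mod(th_new, 2.0 * np.pi))
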