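"""Penalized B-spline (P-spline) building blocks.

One-dimensional smooths use a B-spline basis on equally spaced knots with a
difference penalty on adjacent coefficients (order 1 or 2).  The bivariate
spatial smooth uses the tensor product of two marginal bases, penalized by
squared first differences between each coefficient and its four nearest
neighbours on the coefficient grid.  Every penalized term can be
reparameterized into a mixed-model form — an unpenalized null-space part plus
penalized columns carrying an identity penalty with variance ``tau^2 = 1/lambda``
— which is how the fitting routine treats smooths as random-effect blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "make_knots",
    "bspline_basis",
    "difference_penalty",
    "tensor_basis",
    "spatial_penalty",
    "reparameterize",
    "SplineTerm",
    "TensorSpatialTerm",
    "ReparamTerm",
]


def make_knots(z_min: float, z_max: float, n_segments: int, degree: int = 3) -> np.ndarray:
    """Equally spaced knot vector for a degree-``degree`` B-spline basis.

    The domain ``[z_min, z_max]`` is split into ``n_segments`` equal segments
    and the knot sequence is extended by ``degree`` further equally spaced
    knots on each side, so the basis has ``n_segments + degree`` functions and
    forms a partition of unity on the whole domain.  Extending by repeating
    the spacing (rather than repeating the boundary knot value) keeps the
    Greville abscissae equally spaced, so a coefficient vector linear in the
    basis index reproduces a linear function — the property the second-order
    difference penalty relies on.
    """
    if not np.isfinite(z_min) or not np.isfinite(z_max) or z_max <= z_min:
        raise ValueError(f"invalid domain [{z_min}, {z_max}]: need z_max > z_min")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    h = (z_max - z_min) / n_segments
    return z_min + h * np.arange(-degree, n_segments + degree + 1, dtype=float)


def bspline_basis(z: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    """Evaluate the B-spline basis at points ``z`` (rows) for each basis function.

    Points must lie inside ``[knots[degree], knots[-degree-1]]``; no silent
    extrapolation.  Rows are nonnegative, sum to one, and have at most
    ``degree + 1`` nonzero entries.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    lo, hi = knots[degree], knots[-degree - 1]
    bad = ~((z >= lo) & (z <= hi)) | ~np.isfinite(z)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"point {z[idx]!r} at index {idx} outside spline domain [{lo}, {hi}]"
        )
    return BSpline.design_matrix(z, knots, degree, extrapolate=False).toarray()


def difference_penalty(n_basis: int, order: int) -> np.ndarray:
    """Penalty matrix ``K = D_v' D_v`` from order-``order`` coefficient differences.

    The quadratic form ``a' K a`` equals the sum of squared order-v differences
    of the coefficient vector; the penalty entering the likelihood is
    ``(lambda / 2) * a' K a``.  The null space has dimension ``order``
    (constants for order 1; affine index trends for order 2).
    """
    if order not in (1, 2):
        raise ValueError("difference order must be 1 or 2")
    if n_basis <= order:
        raise ValueError(f"need n_basis > order, got {n_basis} <= {order}")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


@dataclass
class SplineTerm:
    """A one-dimensional P-spline term: basis, knots and difference penalty."""

    var: str
    knots: np.ndarray
    degree: int = 3
    order: int = 2

    @classmethod
    def from_data(
        cls,
        var: str,
        values: np.ndarray,
        n_segments: int = 20,
        degree: int = 3,
        order: int = 2,
        knot_convention: str = "segments",
        pad: float = 0.0,
    ) -> "SplineTerm":
        """Build a term whose knots span the observed range of ``values``.

        ``knot_convention`` resolves how a knot count is interpreted:
        ``"segments"`` (default) treats ``n_segments`` as the number of equal
        segments, giving ``n_segments + degree`` basis functions; ``"basis"``
        treats it as the total basis dimension.
        """
        values = np.asarray(values, dtype=float)
        z_min, z_max = float(values.min()) - pad, float(values.max()) + pad
        if knot_convention == "basis":
            n_segments = n_segments - degree
        elif knot_convention != "segments":
            raise ValueError("knot_convention must be 'segments' or 'basis'")
        return cls(var=var, knots=make_knots(z_min, z_max, n_segments, degree),
                   degree=degree, order=order)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), float(self.knots[-self.degree - 1])

    def basis(self, z: np.ndarray) -> np.ndarray:
        return bspline_basis(z, self.knots, self.degree)

    def penalty(self) -> np.ndarray:
        return difference_penalty(self.n_basis, self.order)


def tensor_basis(lon: np.ndarray, lat: np.ndarray,
                 term_lon: SplineTerm, term_lat: SplineTerm) -> np.ndarray:
    """Row-wise tensor product of the two marginal bases.

    Row ``i`` is the flattened outer product of the marginal basis rows at
    ``(lon[i], lat[i])``; column ``m1 * M2 + m2`` holds
    ``B_{m1}(lon_i) * B_{m2}(lat_i)``.  Rows sum to one.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.shape != lat.shape:
        raise ValueError("lon and lat must have equal length")
    B1 = term_lon.basis(lon)
    B2 = term_lat.basis(lat)
    n = B1.shape[0]
    return (B1[:, :, None] * B2[:, None, :]).reshape(n, -1)


def spatial_penalty(M1: int, M2: int) -> np.ndarray:
    """Four-nearest-neighbour penalty on an ``M1 x M2`` coefficient grid.

    The quadratic form sums squared first differences between each grid
    coefficient and its horizontal and vertical neighbours, which is the
    Kronecker sum of the marginal first-difference penalties:
    ``kron(K1, I) + kron(I, K2)``.  Symmetric PSD; null space is the constant
    sheet.
    """
    if M1 < 2 or M2 < 2:
        raise ValueError("spatial coefficient grid needs M1, M2 >= 2")
    K1 = difference_penalty(M1, 1)
    K2 = difference_penalty(M2, 1)
    return np.kron(K1, np.eye(M2)) + np.kron(np.eye(M1), K2)


@dataclass
class TensorSpatialTerm:
    """Tensor-product spatial smooth over (longitude, latitude)."""

    term_lon: SplineTerm
    term_lat: SplineTerm

    @classmethod
    def from_data(cls, lon: np.ndarray, lat: np.ndarray, n_segments: int = 17,
                  degree: int = 3, pad: float = 1e-6) -> "TensorSpatialTerm":
        # first-order marginal penalties implement the 4-neighbour construction
        t1 = SplineTerm.from_data("lon", lon, n_segments=n_segments, degree=degree,
                                  order=1, pad=pad)
        t2 = SplineTerm.from_data("lat", lat, n_segments=n_segments, degree=degree,
                                  order=1, pad=pad)
        return cls(t1, t2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.term_lon.n_basis, self.term_lat.n_basis

    @property
    def n_basis(self) -> int:
        M1, M2 = self.shape
        return M1 * M2

    def basis(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        return tensor_basis(lon, lat, self.term_lon, self.term_lat)

    def penalty(self) -> np.ndarray:
        return spatial_penalty(*self.shape)


@dataclass
class ReparamTerm:
    """Mixed-model reparameterization of a penalized term.

    The original coefficients ``alpha`` are split as
    ``alpha = N_const c + N_keep g + U L^{-1/2} b`` where ``N_const`` spans the
    constant direction of the penalty null space (absorbed into the model
    intercept for identifiability, i.e. dropped), ``N_keep`` the remaining
    null-space directions (entering the fixed-effect block unpenalized), and
    the transformed penalized part ``b`` carries an identity penalty so that
    ``b ~ N(0, tau^2 I)`` with ``tau^2 = 1/lambda``.
    """

    name: str
    null_transform: np.ndarray   # n_basis x k, null-space directions kept
    pen_transform: np.ndarray    # n_basis x (n_basis - null_dim), U_+ L_+^{-1/2}
    null_dim: int                # penalty null-space dimension before centering

    def transform(self, basis_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map raw basis rows to (unpenalized columns, penalized columns)."""
        return basis_rows @ self.null_transform, basis_rows @ self.pen_transform

    def backtransform(self, gamma: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Recover original-basis coefficients (constant direction set to 0)."""
        return self.null_transform @ gamma + self.pen_transform @ b

    @property
    def n_pen(self) -> int:
        return self.pen_transform.shape[1]

    @property
    def n_null(self) -> int:
        return self.null_transform.shape[1]


def reparameterize(penalty: np.ndarray, name: str = "smooth",
                   null_dim: int | None = None,
                   drop_constant: bool = True) -> ReparamTerm:
    """Split a PSD difference penalty into null-space and identity-penalty parts.

    Eigen-decomposes the penalty; eigenvectors with (numerically) zero
    eigenvalue span the null space.  For difference penalties the null space
    is polynomial in the coefficient index, so it is rebuilt explicitly as
    ``[1, m, ...]`` and orthonormalized with the constant first, letting the
    constant direction be dropped cleanly (sum-to-zero centering against the
    intercept).  Penalized columns are scaled by ``1/sqrt(eigenvalue)`` so the
    transformed penalty is the identity.
    """
    K = np.asarray(penalty, dtype=float)
    q = K.shape[0]
    evals, evecs = np.linalg.eigh(K)
    tol = max(q, 10) * np.finfo(float).eps * max(evals.max(), 1.0)
    null_mask = evals < tol
    k0 = int(null_mask.sum())
    if null_dim is not None and k0 != null_dim:
        raise ValueError(f"penalty null space has dimension {k0}, expected {null_dim}")
    if k0 == q:
        raise ValueError("penalty is identically zero; nothing to reparameterize")
    # explicit polynomial null basis with the constant first, QR-orthonormalized
    m = np.arange(q, dtype=float)
    N = np.vander(m, N=k0, increasing=True)  # columns 1, m, m^2, ...
    Nq, _ = np.linalg.qr(N)
    null_keep = Nq[:, 1:] if drop_constant else Nq
    pen = evecs[:, ~null_mask] / np.sqrt(evals[~null_mask])
    return ReparamTerm(name=name, null_transform=null_keep, pen_transform=pen,
                       null_dim=k0)
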