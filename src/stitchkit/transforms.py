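"""Planar affine transforms in the SVG / TrakEM2 six-coefficient convention.

A transform ``matrix(a, b, c, d, e, f)`` maps a point ``(x, y)`` to
``(a*x + c*y + e, b*x + d*y + f)``.  Throughout the toolkit ``x`` is the
image column and ``y`` the image row, both in full-resolution pixels,
0-based — the same frame Space Ranger uses for ``pxl_col``/``pxl_row``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AffineTransform2D"]


@dataclass(frozen=True)
class AffineTransform2D:
    """Invertible 2D affine map ``(x, y) -> (a*x + c*y + e, b*x + d*y + f)``."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficients).all():
            raise ValueError("affine coefficients must be finite")
        if abs(self.determinant) < 1e-12:
            raise ValueError(
                f"singular affine transform (det={self.determinant:g})"
            )

    @property
    def coefficients(self) -> np.ndarray:
        """The six coefficients as ``[a, b, c, d, e, f]``."""
        return np.array(
            [self.a, self.b, self.c, self.d, self.e, self.f], dtype=float
        )

    @property
    def determinant(self) -> float:
        return self.a * self.d - self.b * self.c

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors ``[x, y, 1]``."""
        return np.array(
            [[self.a, self.c, self.e], [self.b, self.d, self.f], [0.0, 0.0, 1.0]]
        )

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(1.0, 0.0, 0.0, 1.0, 0.0, 0.0)

    @classmethod
    def translation(cls, e: float, f: float) -> "AffineTransform2D":
        return cls(1.0, 0.0, 0.0, 1.0, e, f)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineTransform2D":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"expected a 3x3 matrix, got shape {m.shape}")
        return cls(m[0, 0], m[1, 0], m[0, 1], m[1, 1], m[0, 2], m[1, 2])

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D.from_matrix(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return AffineTransform2D.from_matrix(self.matrix @ other.matrix)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Apply the transform to an ``(n, 2)`` array of ``(x, y)`` points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"expected (n, 2) points, got shape {pts.shape}")
        linear = np.array([[self.a, self.c], [self.b, self.d]])
        return pts @ linear.T + np.array([self.e, self.f])
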