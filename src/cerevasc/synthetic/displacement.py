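"""Displacement-field fixtures with analytic Jacobian determinants.

Three families, each carrying a closed-form determinant map so the
numerical Jacobian pipeline can be validated pointwise:

``affine``
    ``u(x) = (A - I) x + t`` — determinant ``det(A)`` everywhere.
``sinusoid``
    ``u(x) = (a sin(2 pi x / L), 0, 0)`` — determinant
    ``1 + a (2 pi / L) cos(2 pi x / L)``.
``gaussian``
    ``u(x) = a g(x)`` with a scalar Gaussian bump ``g``; the gradient is a
    rank-one update so ``det(I + a grad(g)^T) = 1 + a . grad(g)``.
"""

from __future__ import annotations

import numpy as np

from cerevasc.grids import DisplacementField, Volume

__all__ = ["generate_displacement"]


def _grid_coords(shape: tuple[int, int, int], spacing: float) -> list[np.ndarray]:
    return [
        (np.arange(n) + 0.5) * spacing for n in shape
    ]


def generate_displacement(
    kind: str,
    shape: tuple[int, int, int],
    spacing: float,
    *,
    affine: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    amplitude: float = 0.1,
    wavelength: float | None = None,
    centre: np.ndarray | None = None,
    width: float | None = None,
    direction: np.ndarray | None = None,
) -> tuple[DisplacementField, Volume]:
    """Return ``(field, analytic_jacobian_determinant)``.

    Folding configurations (non-positive determinant anywhere) are
    rejected: the fixtures stand in for diffeomorphic registration output.
    """
    xs, ys, zs = _grid_coords(shape, spacing)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    extent = np.array([n * spacing for n in shape])

    if kind == "affine":
        A = np.eye(3) if affine is None else np.asarray(affine, dtype=float)
        if A.shape != (3, 3):
            raise ValueError("affine must be 3x3")
        det = float(np.linalg.det(A))
        if det <= 0:
            raise ValueError("affine folds space (det <= 0)")
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        M = A - np.eye(3)
        u = np.empty(shape + (3,), dtype=float)
        for i in range(3):
            u[..., i] = M[i, 0] * X + M[i, 1] * Y + M[i, 2] * Z + t[i]
        det_map = np.full(shape, det)

    elif kind == "sinusoid":
        L = float(wavelength) if wavelength is not None else float(extent[0])
        k = 2.0 * np.pi / L
        if abs(amplitude) * k >= 1.0:
            raise ValueError("sinusoid folds space (|a| * 2*pi/L >= 1)")
        u = np.zeros(shape + (3,), dtype=float)
        u[..., 0] = amplitude * np.sin(k * X)
        det_map = 1.0 + amplitude * k * np.cos(k * X)

    elif kind == "gaussian":
        c = 0.5 * extent if centre is None else np.asarray(centre, dtype=float)
        s = 0.15 * float(extent.min()) if width is None else float(width)
        a = (
            np.array([amplitude, 0.0, 0.0])
            if direction is None
            else amplitude * np.asarray(direction, dtype=float)
        )
        g = np.exp(-(((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) / (2 * s**2)))
        grad = [-(W - c[i]) / s**2 * g for i, W in enumerate((X, Y, Z))]
        det_map = 1.0 + a[0] * grad[0] + a[1] * grad[1] + a[2] * grad[2]
        if det_map.min() <= 0:
            raise ValueError("gaussian warp folds space; reduce amplitude")
        u = np.stack([a[i] * g for i in range(3)], axis=-1)

    else:
        raise ValueError(f"unknown displacement kind {kind!r}")

    return (
        DisplacementField(vectors=u, spacing=spacing),
        Volume(values=det_map, spacing=spacing),
    )
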