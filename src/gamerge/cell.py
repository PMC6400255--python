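"""Unit-cell geometry: reciprocal metric tensor and resolution (d-spacing) math.

The d-spacing of a reflection h = (h, k, l) in a (possibly triclinic) cell is
d = 1 / sqrt(h^T G* h), with G* the reciprocal metric tensor.  All routines
are vectorised over arrays of Miller indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["UnitCell", "d_spacing"]


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(f"cell lengths must be positive, got {(self.a, self.b, self.c)}")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name}={ang} outside (0, 180)")
        # positive-definiteness of the direct metric tensor guards against
        # impossible angle combinations (e.g. alpha+beta+gamma near 360)
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise ValueError("cell angles do not define a valid (positive-definite) metric")

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3, Angstrom^2)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal-space metric tensor G* = G^-1 (Angstrom^-2)."""
        return np.linalg.inv(self.metric_tensor())

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @classmethod
    def from_parameters(cls, params) -> "UnitCell":
        return cls(*(float(p) for p in params))


def d_spacing(hkl, cell: UnitCell):
    """Resolution d (Angstrom) of one Miller index or an (n, 3) array of them.

    Exact for triclinic cells: d = 1/sqrt(h^T G* h).  The (0, 0, 0) index has
    no direction and is rejected.
    """
    h = np.asarray(hkl, dtype=float)
    scalar = h.ndim == 1
    h = np.atleast_2d(h)
    if h.shape[1] != 3:
        raise ValueError("Miller indices must be triples")
    if np.any(np.all(h == 0, axis=1)):
        raise ValueError("d-spacing undefined for the (0,0,0) index")
    gstar = cell.reciprocal_metric_tensor()
    inv_d2 = np.einsum("ni,ij,nj->n", h, gstar, h)
    d = 1.0 / np.sqrt(inv_d2)
    return float(d[0]) if scalar else d
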