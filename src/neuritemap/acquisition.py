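"""Acquisition schemes, diffusion-weighted volumes and gradient-table I/O.

Conventions
-----------
* b-values are in s/mm^2 and diffusivities in mm^2/s, so ``b * D`` is
  dimensionless.
* Gradient tables use the FSL dialect: ``.bval`` is a single whitespace
  separated row of b-values, ``.bvec`` is three rows (x, y, z) of direction
  components, one column per measurement.
* 4-D images are NIfTI-1 with the measurement axis last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod

from typing import Mapping

import nibabel as nib
import numpy as np

from ._directions import DIRECTIONS54

__all__ = [
    "AcquisitionScheme",
    "DWIVolume",
    "LabelMap",
    "read_dwi",
    "write_dwi",
    "read_labelmap",
    "write_labelmap",
    "default_scheme",
    "validate_design",
    "DEFAULT_B_VALUES",
]

#: The nine default shell b-values, s/mm^2.
DEFAULT_B_VALUES = (0.0, 2000.0, 3000.0, 4000.0, 5000.0, 6000.0, 8000.0, 10000.0, 15000.0)

_UNIT_TOL = 1e-6
_RENORM_TOL = 1e-3


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-measurement diffusion weightings, directions and pulse timings.

    Parameters
    ----------
    b_values : (n,) array
        Diffusion weighting per measurement, s/mm^2.
    directions : (n, 3) array
        Unit gradient directions; rows with b == 0 are unconstrained.
    big_delta : float
        Gradient pulse separation, ms.
    small_delta : float
        Gradient pulse duration, ms.
    n_averages : int
        Number of averaged acquisitions per measurement.
    """

    b_values: np.ndarray
    directions: np.ndarray
    big_delta: float = 8.0
    small_delta: float = 2.0
    n_averages: int = 1

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.b_values, dtype=float))
        g = np.atleast_2d(np.asarray(self.directions, dtype=float))
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)
        if b.ndim != 1 or g.shape != (b.size, 3):
            raise ValueError(
                f"directions shape {g.shape} does not match {b.size} b-values"
            )
        if np.any(b < 0):
            raise ValueError("negative b-value")
        if not np.any(b == 0):
            raise ValueError("scheme must contain at least one b=0 measurement")
        dwi = b > 0
        norms = np.linalg.norm(g[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("non-unit gradient direction at b > 0")
        if not (self.big_delta >= self.small_delta > 0):
            raise ValueError("require big_delta >= small_delta > 0")
        if not (isinstance(self.n_averages, (int, np.integer)) and self.n_averages >= 1):
            raise ValueError("n_averages must be a positive integer")

    def __len__(self) -> int:
        return self.b_values.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique b-values."""
        return np.unique(self.b_values)


@dataclass(frozen=True)
class DWIVolume:
    """A 4-D magnitude diffusion-weighted image bound to its scheme."""

    signal: np.ndarray
    scheme: AcquisitionScheme
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", s)
        if s.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, measurement)")
        if s.shape[3] != len(self.scheme):
            raise ValueError(
                f"measurement axis ({s.shape[3]}) does not match scheme "
                f"({len(self.scheme)})"
            )
        if np.any(np.asarray(s) < 0):
            raise ValueError("magnitude signal must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass(frozen=True)
class LabelMap:
    """Integer ROI labels on a volume grid; 0 is background."""

    labels: np.ndarray
    names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if lab.ndim != 3:
            raise ValueError("labels must be 3-D")
        object.__setattr__(self, "labels", lab)
        present = set(np.unique(lab)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without a name: {sorted(missing)}")

    @property
    def label_values(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def read_dwi(image_path, bval_path, bvec_path) -> DWIVolume:
    """Read a 4-D NIfTI plus FSL-dialect bval/bvec tables into a DWIVolume.

    Directions whose norm deviates from 1 by less than 1e-3 are
    re-normalized; larger deviations at b > 0 raise ``ValueError``.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4-D image, got {data.ndim}-D")
    bvals = np.loadtxt(str(bval_path), dtype=float).reshape(-1)
    bvecs = np.loadtxt(str(bvec_path), dtype=float)
    if bvecs.shape == (bvals.size,) and bvals.size == 3:
        bvecs = bvecs.reshape(3, 1)
    if bvecs.shape != (3, bvals.size):
        raise ValueError(
            f"{bvec_path}: expected 3x{bvals.size} table, got {bvecs.shape}"
        )
    if data.shape[3] != bvals.size:
        raise ValueError(
            f"image has {data.shape[3]} frames but tables have {bvals.size} entries"
        )
    if np.any(bvals < 0):
        raise ValueError("negative b-value in bval table")
    g = np.ascontiguousarray(bvecs.T)
    norms = np.linalg.norm(g, axis=1)
    dwi = bvals > 0
    bad = dwi & (np.abs(norms - 1.0) >= _RENORM_TOL)
    if np.any(bad):
        raise ValueError(
            f"non-unit direction(s) at b>0 beyond tolerance: rows {np.flatnonzero(bad)}"
        )
    fix = norms > 0
    g[fix] = g[fix] / norms[fix, None]
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    scheme = AcquisitionScheme(bvals, g)
    return DWIVolume(signal=data, scheme=scheme, voxel_size=voxel_size)


def write_dwi(vol: DWIVolume, image_path, bval_path, bvec_path) -> None:
    """Write a DWIVolume as NIfTI + bval/bvec; lossless round trip."""
    if prod(vol.shape) == 0:
        raise ValueError("refusing to write an empty (0-voxel) volume")
    img = nib.Nifti1Image(vol.signal.astype(np.float64), _affine(vol.voxel_size))
    img.header.set_zooms(tuple(vol.voxel_size) + (1.0,))
    nib.save(img, str(image_path))
    np.savetxt(str(bval_path), vol.scheme.b_values[None, :], fmt="%.10g")
    np.savetxt(str(bvec_path), vol.scheme.directions.T, fmt="%.17g")


def read_labelmap(image_path, names: Mapping[int, str]) -> LabelMap:
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj)
    return LabelMap(labels=np.rint(data).astype(np.int32), names=dict(names))


def write_labelmap(labelmap: LabelMap, image_path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(labelmap.labels.astype(np.int16), _affine(voxel_size))
    nib.save(img, str(image_path))


def default_scheme(n_averages: int = 4) -> AcquisitionScheme:
    """The default 54-measurement multi-shell scheme.

    Nine shells at b = 0, 2000, 3000, 4000, 5000, 6000, 8000, 10000 and
    15000 s/mm^2 with six directions each, the directions drawn from the
    packaged near-uniform 54-point set (27 antipodal pairs, three pairs per
    shell); Delta/delta = 8/2 ms.
    """
    b = np.repeat(np.asarray(DEFAULT_B_VALUES), 6)
    dirs = np.empty((54, 3))
    for shell in range(9):
        pairs = DIRECTIONS54[3 * shell : 3 * shell + 3]
        dirs[6 * shell : 6 * shell + 3] = pairs
        dirs[6 * shell + 3 : 6 * shell + 6] = -pairs
    return AcquisitionScheme(
        b_values=b, directions=dirs, big_delta=8.0, small_delta=2.0, n_averages=n_averages
    )


def _double_factorial(k: int) -> int:
    return prod(range(k, 0, -2)) if k > 0 else 1


def _sphere_monomial_average(exponents: tuple[int, int, int]) -> float:
    """Exact average of x^a y^b z^c over the unit sphere (all exponents even)."""
    a, b, c = exponents
    num = _double_factorial(a - 1) * _double_factorial(b - 1) * _double_factorial(c - 1)
    return num / _double_factorial(a + b + c + 1)


def validate_design(directions: np.ndarray, max_degree: int) -> dict[int, float]:
    """Quadrature-quality report for a direction set.

    For each even degree d <= ``max_degree`` the point-set average of every
    monomial x^a y^b z^c with a + b + c = d and all exponents even is compared
    with the exact sphere average; the worst-case relative error per degree is
    returned as ``{degree: error}``.
    """
    g = np.atleast_2d(np.asarray(directions, dtype=float))
    if g.shape[0] < 2 or g.shape[1] != 3:
        raise ValueError("need at least two 3-vectors")
    if np.any(np.abs(np.linalg.norm(g, axis=1) - 1.0) > _UNIT_TOL):
        raise ValueError("directions must be unit vectors")
    report: dict[int, float] = {}
    for degree in range(2, max_degree + 1, 2):
        worst = 0.0
        for a in range(0, degree + 1, 2):
            for b in range(0, degree + 1 - a, 2):
                c = degree - a - b
                if c % 2:
                    continue
                exact = _sphere_monomial_average((a, b, c))
                approx = float(
                    np.mean(g[:, 0] ** a * g[:, 1] ** b * g[:, 2] ** c)
                )
                worst = max(worst, abs(approx - exact) / exact)
        report[degree] = worst
    return report
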