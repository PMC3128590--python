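"""Voxel-wise estimation of tissue parameters from multi-shell DWI.

The nonlinear least-squares problem is solved by variable projection: for a
given triple of diffusivities (d_eff, d_long, d_trans) the model

    S = A * exp(-b * d_eff) + exp(-b * d_trans) * sum_lm c_lm * k_l * Y_lm

is linear in A = s0*(1-nu) and c_lm = s0*nu*f_lm, so the inner problem is an
ordinary linear least squares and only the three diffusivities are optimized
nonlinearly (d_trans is parameterized as ratio * d_long to keep
0 <= d_trans <= d_long a box constraint). Because f_00 is pinned at
1/sqrt(4*pi), s0, nu and the ODF coefficients are recovered from (A, c) as

    s0*nu = c_00 * sqrt(4*pi),  s0 = A + s0*nu,  f_lm = c_lm / (s0*nu).

Fits are deterministic: measurements are put in a canonical order before
fitting (so results are invariant to measurement permutation) and the
multi-start perturbations are drawn from a seeded generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .acquisition import AcquisitionScheme, DWIVolume
from .forward import (
    F00,
    TissueParams,
    _safe_dirs,
    _sphere_quadrature,
    isotropic_odf_coeffs,
    kernel_coeffs,
    n_coeffs,
    sh_basis,
    sh_orders,
)

__all__ = ["FitConfig", "FitResult", "ParameterMaps", "dti_init", "fit_voxel", "fit_volume"]

logger = logging.getLogger(__name__)

_D_MAX = 4e-3  # mm^2/s, upper bound for all diffusivities
_DTI_B_MAX = 4000.0  # s/mm^2, shells used by the log-linear tensor fit


@dataclass(frozen=True)
class FitConfig:
    """Settings for the voxel-wise fit."""

    l_max: int = 4
    n_starts: int = 5
    seed: int = 0
    bounds: dict = field(
        default_factory=lambda: {
            "nu": (0.0, 1.0),
            "d_eff": (0.0, _D_MAX),
            "d_long": (0.0, _D_MAX),
            "d_trans": (0.0, _D_MAX),
        }
    )
    max_iterations: int = 300
    convergence_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.l_max % 2 or self.l_max < 0:
            raise ValueError("l_max must be even and nonnegative")
        if self.n_starts < 1 or self.max_iterations < 1:
            raise ValueError("n_starts and max_iterations must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        lo, hi = self.bounds["nu"]
        if lo < 0 or hi > 1:
            raise ValueError("nu bounds must lie within [0, 1]")
        for key in ("d_eff", "d_long", "d_trans"):
            lo, hi = self.bounds[key]
            if lo < 0 or hi > _D_MAX:
                raise ValueError(f"{key} bounds must lie within [0, {_D_MAX}]")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one voxel fit."""

    params: TissueParams
    residual_norm: float
    converged: bool
    n_function_evals: int
    odf_negative: bool = False


@dataclass(frozen=True)
class ParameterMaps:
    """Scalar maps assembled from voxel-wise fits (NaN outside the mask)."""

    neurite_density: np.ndarray
    mean_diffusivity: np.ndarray
    converged: np.ndarray
    residual_norm: np.ndarray | None = None


def dti_init(signal: np.ndarray, scheme: AcquisitionScheme) -> tuple[TissueParams, float]:
    """Log-linear tensor fit on the b <= 4000 s/mm^2 shells.

    Returns an initial :class:`TissueParams` (nu0 = min(1, FA), d_long0 /
    d_trans0 = extreme eigenvalues, d_eff0 = MD, isotropic ODF) together with
    the mean diffusivity (trace / 3).
    """
    s = np.asarray(signal, dtype=float)
    keep = (scheme.b_values <= _DTI_B_MAX) & (s > 0)
    if np.count_nonzero(s) == 0:
        raise ValueError("all-zero signal")
    b = scheme.b_values[keep]
    g = _safe_dirs(scheme)[keep]
    design = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    if design.shape[0] < 7 or np.linalg.matrix_rank(design) < 7:
        raise ValueError("need >= 7 measurements spanning >= 6 non-collinear directions")
    coef, *_ = np.linalg.lstsq(design, np.log(s[keep]), rcond=None)
    s0 = float(np.exp(coef[0]))
    dxx, dyy, dzz, dxy, dxz, dyz = coef[1:]
    tensor = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    evals = np.linalg.eigvalsh(tensor)  # ascending
    md = float(evals.mean())
    dev = evals - md
    denom = float(np.sum(evals**2))
    fa = float(np.sqrt(1.5 * np.sum(dev**2) / denom)) if denom > 0 else 0.0
    params = TissueParams(
        s0=s0,
        nu=min(1.0, max(0.0, fa)),
        d_eff=float(np.clip(md, 0.0, _D_MAX)),
        d_long=float(np.clip(evals[2], 1e-6, _D_MAX)),
        d_trans=float(np.clip(evals[0], 0.0, np.clip(evals[2], 1e-6, _D_MAX))),
        odf_coeffs=isotropic_odf_coeffs(4),
    )
    return params, md


class _VoxelProblem:
    """Cached per-scheme quantities plus the variable-projection residual."""

    def __init__(self, signal: np.ndarray, scheme: AcquisitionScheme, config: FitConfig):
        # canonical measurement order -> permutation-invariant results
        order = np.lexsort(
            (
                scheme.directions[:, 2],
                scheme.directions[:, 1],
                scheme.directions[:, 0],
                scheme.b_values,
            )
        )
        self.b = scheme.b_values[order]
        self.y = np.asarray(signal, dtype=float)[order]
        dirs = _safe_dirs(scheme)[order]
        self.Y = sh_basis(dirs, config.l_max)
        self.l_of_col = np.array([l // 2 for l, _ in sh_orders(config.l_max)])
        self.n_c = n_coeffs(config.l_max)

    def design(self, x: np.ndarray) -> np.ndarray:
        d_eff, d_long, ratio = x
        d_trans = ratio * d_long
        alpha = self.b * (d_long - d_trans)
        k = kernel_coeffs(alpha, l_max=2 * self.l_of_col.max() if self.n_c > 1 else 0)
        m = np.empty((self.b.size, 1 + self.n_c))
        m[:, 0] = np.exp(-self.b * d_eff)
        m[:, 1:] = (
            np.exp(-self.b * d_trans)[:, None] * self.Y * k[:, self.l_of_col]
        )
        return m

    def solve_linear(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inner linear solve with A >= 0 and c_00 >= 0.

        Unconstrained lstsq first; if either sign constraint is violated,
        re-solve the (at most three) active-set candidates with the offending
        column(s) pinned to zero and keep the feasible minimum.
        """
        m = self.design(x)
        c, *_ = np.linalg.lstsq(m, self.y, rcond=None)
        if c[0] >= 0 and c[1] >= 0:
            return c, m @ c - self.y
        best_c, best_r, best_norm = None, None, np.inf
        for drop in ((0,), (1,), (0, 1)):
            keep = [i for i in range(m.shape[1]) if i not in drop]
            sub, *_ = np.linalg.lstsq(m[:, keep], self.y, rcond=None)
            cand = np.zeros(m.shape[1])
            cand[keep] = sub
            if cand[0] < 0 or cand[1] < 0:
                continue
            r = m @ cand - self.y
            norm = float(r @ r)
            if norm < best_norm:
                best_c, best_r, best_norm = cand, r, norm
        return best_c, best_r

    def residual(self, x: np.ndarray) -> np.ndarray:
        return self.solve_linear(x)[1]


def _extract_params(c: np.ndarray, x: np.ndarray, config: FitConfig) -> TissueParams:
    d_eff, d_long, ratio = x
    d_trans = ratio * d_long
    a = max(float(c[0]), 0.0)
    s0_nu = max(float(c[1]) * np.sqrt(4.0 * np.pi), 0.0)
    s0 = a + s0_nu
    if s0 <= 0:
        return TissueParams(0.0, 0.0, d_eff, d_long, d_trans, isotropic_odf_coeffs(config.l_max))
    nu = float(np.clip(s0_nu / s0, *config.bounds["nu"]))
    if s0_nu > 0:
        f = np.asarray(c[1:], dtype=float) / s0_nu
        f[0] = F00  # exact by construction; pin against rounding
    else:
        f = isotropic_odf_coeffs(config.l_max)
    return TissueParams(s0=s0, nu=nu, d_eff=d_eff, d_long=d_long, d_trans=d_trans, odf_coeffs=f)


_ODF_CHECK_PTS, _ = _sphere_quadrature(500)


def fit_voxel(signal: np.ndarray, scheme: AcquisitionScheme, config: FitConfig | None = None) -> FitResult:
    """Fit the two-compartment model to one voxel's measurements.

    Runs a bound-constrained least-squares solve from the tensor-fit start
    plus ``n_starts - 1`` seeded perturbed starts and returns the
    lowest-residual solution. Deterministic given ``config.seed``.
    """
    config = config or FitConfig()
    s = np.asarray(signal, dtype=float)
    if s.shape != (len(scheme),):
        raise ValueError("signal length does not match scheme")
    if not np.all(np.isfinite(s)) or np.any(s < 0):
        raise ValueError("signal must be finite and nonnegative")
    problem = _VoxelProblem(s, scheme, config)

    try:
        init, _ = dti_init(s, scheme)
        x0 = np.array(
            [
                init.d_eff,
                max(init.d_long, 1e-5),
                init.d_trans / max(init.d_long, 1e-5),
            ]
        )
    except ValueError:
        x0 = np.array([1e-3, 1.5e-3, 0.1])
    lo = np.array([config.bounds["d_eff"][0], 1e-6, 0.0])
    hi = np.array([config.bounds["d_eff"][1], config.bounds["d_long"][1], 1.0])
    x0 = np.clip(x0, lo, hi)

    rng = np.random.default_rng(config.seed)
    starts = [x0]
    for _ in range(config.n_starts - 1):
        pert = x0 * rng.uniform(0.8, 1.2, size=3)  # +-20% multiplicative
        starts.append(np.clip(pert, lo, hi))

    best = None
    n_evals = 0
    any_converged = False
    for start in starts:
        res = least_squares(
            problem.residual,
            start,
            bounds=(lo, hi),
            method="trf",
            x_scale=[1e-3, 1e-3, 1.0],
            xtol=config.convergence_tol,
            ftol=config.convergence_tol,
            gtol=config.convergence_tol,
            max_nfev=config.max_iterations * 4,
        )
        n_evals += res.nfev
        any_converged |= res.status > 0
        if best is None or res.cost < best.cost:
            best = res
    c, r = problem.solve_linear(best.x)
    params = _extract_params(c, best.x, config)
    odf = sh_basis(_ODF_CHECK_PTS, config.l_max) @ params.odf_coeffs
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(r)),
        converged=bool(any_converged),
        n_function_evals=int(n_evals),
        odf_negative=bool(odf.min() < -1e-3),
    )


def fit_volume(vol: DWIVolume, mask: np.ndarray, config: FitConfig | None = None) -> ParameterMaps:
    """Apply :func:`fit_voxel` within ``mask`` and assemble parameter maps.

    Out-of-mask voxels are NaN in the maps and False in the convergence
    mask. A voxel whose signal is invalid (NaN / all-zero) is flagged
    unconverged without affecting its neighbours.
    """
    config = config or FitConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume {vol.shape}")
    nd = np.full(vol.shape, np.nan)
    md = np.full(vol.shape, np.nan)
    rn = np.full(vol.shape, np.nan)
    conv = np.zeros(vol.shape, dtype=bool)
    for z in range(vol.shape[2]):
        idx = np.argwhere(mask[:, :, z])
        for i, j in idx:
            sig = vol.signal[i, j, z]
            try:
                _, md_val = dti_init(sig, vol.scheme)
                result = fit_voxel(sig, vol.scheme, config)
            except ValueError:
                continue  # flagged unconverged via conv=False
            nd[i, j, z] = result.params.nu
            md[i, j, z] = md_val
            rn[i, j, z] = result.residual_norm
            conv[i, j, z] = result.converged
        if idx.size:
            logger.info("fit_volume: slice %d/%d (%d voxels)", z + 1, vol.shape[2], len(idx))
    return ParameterMaps(neurite_density=nd, mean_diffusivity=md, converged=conv, residual_norm=rn)
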