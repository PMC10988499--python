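"""Steady-state oxygen diffusion-consumption model on trapping regions.

Model
-----
Within each capillary domain the tissue PO2 field P (mmHg) obeys

    D * alpha * laplacian(P) = M0 * P / (P50 + P)

with Michaelis-Menten consumption saturating at ``M0``
(mL O2 / mL tissue / s). Boundary conditions:

* Dirichlet ``P = P_cap`` on the capillary lumen (grid cells whose
  centre lies within ``r_cap`` of the capillary site);
* zero flux across the domain boundary (the trapping-region
  assumption: each capillary supplies only its own domain, so no
  oxygen crosses domain borders).

Each domain is solved independently on a uniform Cartesian raster
(5-point Laplacian, reflective ghost cells for no-flux). The
Michaelis-Menten nonlinearity is handled by Picard iteration with a
lagged denominator: each sweep solves the linear sparse system

    D * alpha * laplacian(P_new) - (M0 / (P50 + P_old)) * P_new = 0

by a direct factorisation, iterated until max|P_new - P_old| falls
below 1e-6 mmHg.

The zero-order limit (P50 -> 0, all P > 0) on a disc admits the
Krogh-Erlang closed-form radial profile, used as the validation
oracle for the solver.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
import shapely
from shapely.geometry import Polygon

from .datatypes import CapillaryMap, DomainTessellation, OxygenField, ValidationError
from .tessellation import assign_pixels_bruteforce

logger = logging.getLogger(__name__)

MAX_PICARD_ITER = 500
PICARD_TOL = 1e-6  # mmHg, max |delta P| between sweeps


@dataclass(frozen=True)
class OxygenParams:
    """Physical parameters of the diffusion-consumption model.

    Defaults are literature-magnitude values for mammalian skeletal
    muscle; all are exposed because modelled PO2 is sensitive to them.

    Attributes
    ----------
    D : float
        Tissue O2 diffusivity, um^2/s.
    alpha : float
        O2 solubility, mL O2 / mL tissue / mmHg.
    M0 : float
        Maximal O2 consumption, mL O2 / mL tissue / s. Zero is allowed
        (no consumption; P identically P_cap).
    P50 : float
        Michaelis constant of consumption, mmHg.
    P_cap : float
        Capillary-surface PO2 (Dirichlet value), mmHg.
    r_cap : float
        Capillary lumen radius, um.
    hypoxia_threshold : float
        PO2 below which tissue counts as hypoxic, mmHg.
    mode : str
        "rest" or "exercise"; a bookkeeping tag for the M0 regime.
    """

    D: float = 2400.0
    alpha: float = 3.89e-5
    M0: float = 1e-4
    P50: float = 0.5
    P_cap: float = 40.0
    r_cap: float = 2.5
    hypoxia_threshold: float = 1.0
    mode: str = "rest"

    def __post_init__(self) -> None:
        for name in ("D", "alpha", "P50", "P_cap", "r_cap"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.M0 < 0:
            raise ValidationError("M0 must be non-negative")
        if self.hypoxia_threshold < 0:
            raise ValidationError("hypoxia_threshold must be non-negative")
        if self.P_cap <= self.hypoxia_threshold:
            raise ValidationError("P_cap must exceed the hypoxia threshold")


#: Resting-consumption preset.
REST_PARAMS = OxygenParams(M0=1e-4, mode="rest")
#: High-consumption preset representative of intense exercise.
EXERCISE_PARAMS = OxygenParams(M0=1.5e-3, mode="exercise")


class ConvergenceError(RuntimeError):
    """Picard iteration failed to reach tolerance."""


def _solve_masked(
    mask: np.ndarray,
    lumen: np.ndarray,
    params: OxygenParams,
    h: float,
) -> np.ndarray:
    """Solve the PDE on an arbitrary raster mask.

    ``mask`` marks cells belonging to the domain (tissue + lumen);
    ``lumen`` marks Dirichlet cells (subset of mask). Cells outside
    the mask are no-flux: a missing neighbour simply drops out of the
    Laplacian stencil (reflective ghost cell). Returns the PO2 grid
    with NaN outside the mask.
    """
    ny, nx = mask.shape
    idx = -np.ones(mask.shape, dtype=np.int64)
    cells = np.flatnonzero(mask.ravel())
    idx.ravel()[cells] = np.arange(cells.size)
    N = cells.size
    if N == 0:
        raise ValidationError("empty domain mask")
    lum = lumen.ravel()[cells]
    if not lum.any():
        raise ValidationError("domain contains no capillary lumen cell")

    Dalpha_h2 = params.D * params.alpha / h**2

    # neighbour connectivity among masked cells
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    iy, ix = np.unravel_index(cells, mask.shape)
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ny_, nx_ = iy + dy, ix + dx
        ok = (ny_ >= 0) & (ny_ < ny) & (nx_ >= 0) & (nx_ < nx)
        nb = np.full(N, -1, dtype=np.int64)
        nb[ok] = idx[ny_[ok], nx_[ok]]
        has = nb >= 0
        ii.append(np.arange(N)[has])
        jj.append(nb[has])
    rows = np.concatenate(ii)
    cols = np.concatenate(jj)
    deg = np.bincount(rows, minlength=N).astype(float)

    # Laplacian with reflective boundaries: L P = sum(P_nb) - deg * P
    off = sparse.coo_matrix(
        (np.full(rows.size, Dalpha_h2), (rows, cols)), shape=(N, N)
    ).tocsr()

    P = np.full(N, params.P_cap)
    n_clamped_total = 0
    for iteration in range(MAX_PICARD_ITER):
        react = params.M0 / (params.P50 + P)  # lagged MM denominator
        diag = -Dalpha_h2 * deg - react
        A = off + sparse.diags(diag)
        b = np.zeros(N)
        # Dirichlet rows: P = P_cap on lumen
        A = A.tolil()
        for k in np.flatnonzero(lum):
            A.rows[k] = [k]
            A.data[k] = [1.0]
        b[lum] = params.P_cap
        P_new = spsolve(A.tocsr(), b)
        neg = P_new < 0
        if neg.any():
            n_clamped_total += int(neg.sum())
            logger.warning(
                "clamped %d negative PO2 cells during Picard sweep %d",
                int(neg.sum()),
                iteration,
            )
            P_new = np.where(neg, 0.0, P_new)
        delta = float(np.max(np.abs(P_new - P)))
        P = P_new
        if delta < PICARD_TOL:
            break
    else:
        raise ConvergenceError(
            f"Picard iteration did not converge in {MAX_PICARD_ITER} sweeps "
            f"(final max |dP| = {delta:.3e} mmHg)"
        )

    out = np.full(mask.shape, np.nan)
    out.ravel()[cells] = P + 0.0  # normalise any -0.0 from the direct solve
    return out


def solve_domain(
    domain: Polygon,
    capillary: np.ndarray,
    params: OxygenParams,
    h: float = 1.0,
) -> np.ndarray:
    """Solve the oxygen model on one trapping region.

    The polygon is rasterised on a grid of step ``h`` spanning its
    bounding box (cell centres inside the polygon belong to the
    domain); cells within ``r_cap`` of the capillary are the Dirichlet
    lumen. Returns the PO2 subgrid (NaN outside the domain); lumen
    cells carry ``P_cap``.
    """
    if h > params.r_cap:
        raise ValidationError("grid step h must not exceed r_cap")
    cx, cy = float(capillary[0]), float(capillary[1])
    if not domain.buffer(1e-9).contains(shapely.points(cx, cy)):
        raise ValidationError("capillary point must lie inside its domain")
    minx, miny, maxx, maxy = domain.bounds
    nx = max(1, int(np.ceil((maxx - minx) / h)))
    ny = max(1, int(np.ceil((maxy - miny) / h)))
    xc = minx + (np.arange(nx) + 0.5) * h
    yc = miny + (np.arange(ny) + 0.5) * h
    XX, YY = np.meshgrid(xc, yc)
    mask = shapely.contains_xy(domain, XX.ravel(), YY.ravel()).reshape(ny, nx)
    lumen = ((XX - cx) ** 2 + (YY - cy) ** 2 <= params.r_cap**2) & mask
    if not lumen.any():
        # very coarse grid relative to r_cap: use the nearest in-domain cell
        d2 = np.where(mask, (XX - cx) ** 2 + (YY - cy) ** 2, np.inf)
        lumen = d2 == d2.min()
    return _solve_masked(mask, lumen, params, h)


def krogh_erlang_reference(
    r: np.ndarray | float, R: float, params: OxygenParams
) -> np.ndarray | float:
    """Krogh-Erlang radial PO2 profile for zero-order consumption.

    For a single capillary of radius ``r_cap`` supplying a disc of
    outer radius ``R`` with uniform consumption ``M0``:

        P(r) = P_cap + (M0 / (2 D alpha)) * [(r^2 - r_cap^2)/2
                                             - R^2 ln(r / r_cap)]

    Valid while P stays positive; a negative P(R) means the zero-order
    form breaks down (anoxic rim) and raises an error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < params.r_cap - 1e-12) or np.any(r > R + 1e-12):
        raise ValidationError("r must satisfy r_cap <= r <= R")
    coef = params.M0 / (2.0 * params.D * params.alpha)
    P = params.P_cap + coef * (
        (r**2 - params.r_cap**2) / 2.0 - R**2 * np.log(r / params.r_cap)
    )
    P_rim = params.P_cap + coef * (
        (R**2 - params.r_cap**2) / 2.0 - R**2 * np.log(R / params.r_cap)
    )
    if P_rim < 0:
        raise ValidationError(
            "zero-order profile reaches negative PO2 at the rim (anoxic "
            "core); the closed form is invalid for these parameters"
        )
    return float(P) if P.ndim == 0 else P


def solve_frame(
    tess: DomainTessellation,
    cmap: CapillaryMap,
    params: OxygenParams,
    h: float = 1.0,
) -> OxygenField:
    """Solve every trapping region and assemble the full-frame PO2 field.

    The frame raster is partitioned by nearest-capillary assignment
    (identical to the domain tessellation up to raster resolution), and
    the PDE is solved independently on each domain's cells. Summary
    statistics are taken over tissue cells only (capillary-lumen cells
    excluded).
    """
    if tess.n_domains != cmap.n_capillaries:
        raise ValidationError("tessellation does not match the capillary map")
    labels = assign_pixels_bruteforce(cmap, h)
    ny, nx = labels.shape
    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h
    XX, YY = np.meshgrid(xc, yc)
    grid = np.full(labels.shape, np.nan)
    lumen_all = np.zeros(labels.shape, dtype=bool)
    for i in range(cmap.n_capillaries):
        mask = labels == i
        if not mask.any():
            # domain smaller than one raster cell at this h; its tissue
            # is absorbed by the neighbouring domains' cells
            logger.warning("domain %d has no raster cells at h=%g; skipped", i, h)
            continue
        cx, cy = cmap.capillaries[i]
        lumen = ((XX - cx) ** 2 + (YY - cy) ** 2 <= params.r_cap**2) & mask
        if not lumen.any():
            d2 = np.where(mask, (XX - cx) ** 2 + (YY - cy) ** 2, np.inf)
            lumen = d2 == d2.min()
        try:
            sub = _solve_masked(mask, lumen, params, h)
        except (ConvergenceError, ValidationError) as exc:
            raise type(exc)(f"domain {i}: {exc}") from exc
        grid[mask] = sub[mask]
        lumen_all |= lumen

    tissue = ~lumen_all
    field_labels = labels.copy()
    field_labels[lumen_all] = -1
    vals = grid[tissue]
    mean_po2 = float(np.mean(vals))
    min_po2 = float(np.min(vals))
    hypo = 100.0 * float(np.mean(vals < params.hypoxia_threshold))
    return OxygenField(
        grid=grid,
        labels=field_labels,
        h=h,
        mean_PO2=mean_po2,
        min_PO2=min_po2,
        hypoxic_fraction=hypo,
        hypoxia_threshold=params.hypoxia_threshold,
    )


def hypoxic_fraction(field: OxygenField, threshold: Optional[float] = None) -> float:
    """Percent of tissue area with PO2 below ``threshold`` (mmHg)."""
    thr = field.hypoxia_threshold if threshold is None else threshold
    vals = field.grid[field.tissue_mask]
    if vals.size == 0:
        raise ValidationError("field has no tissue cells")
    return 100.0 * float(np.mean(vals < thr))


def params_for_mode(mode: str, **overrides) -> OxygenParams:
    """Preset parameters for ``rest`` or ``exercise`` consumption."""
    base = {"rest": REST_PARAMS, "exercise": EXERCISE_PARAMS}.get(mode)
    if base is None:
        raise ValidationError(f"unknown mode {mode!r}")
    return replace(base, **overrides) if overrides else base
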