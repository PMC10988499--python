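"""Global and local capillary supply indices.

Global indices (counting-frame level):

* ``CD`` — capillary density, capillaries per mm^2 of section.
* ``C:F`` — capillary-to-fibre ratio, capillaries per counted fibre.
* ``CSA`` — mean fibre cross-sectional area (um^2).

Fibres are counted with an unbiased (Gundersen) counting frame: a
fibre profile is counted if it lies in the frame and does not touch
the forbidden lines (the left and bottom frame edges); profiles
crossing the right or top edge are included. This makes the expected
count proportional to frame area regardless of fibre size.

Local indices (capillary level), computed from the domain tessellation:

* ``CDA`` — capillary domain area, the area of tissue nearer to one
  capillary than to any other (um^2).
* ``logSD`` — the sample standard deviation of ln(CDA), a
  dimensionless index of capillary-spacing heterogeneity. The log
  base only rescales logSD by a constant; natural log is used here.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon

from .datatypes import (
    CapillaryMap,
    DomainTessellation,
    SupplyIndices,
    ValidationError,
)

#: Default CDA histogram bin edges: 100 um^2 bins from 0 to 3000 um^2.
DEFAULT_CDA_BIN_EDGES = np.arange(0.0, 3100.0, 100.0)


def count_fibres_unbiased(
    fibres: Sequence[Polygon], frame_width: float, frame_height: float
) -> np.ndarray:
    """Indices of fibres accepted by the forbidden-line counting rule.

    A fibre is counted iff it intersects the frame interior and does
    not touch the left (x = 0) or bottom (y = 0) frame edge.
    """
    left = LineString([(0, 0), (0, frame_height)])
    bottom = LineString([(0, 0), (frame_width, 0)])
    from shapely.geometry import box

    frame = box(0.0, 0.0, frame_width, frame_height)
    kept = [
        k
        for k, poly in enumerate(fibres)
        if poly.intersects(frame)
        and not poly.intersects(left)
        and not poly.intersects(bottom)
    ]
    return np.asarray(kept, dtype=int)


def compute_global_indices(cmap: CapillaryMap) -> SupplyIndices:
    """Capillary density, and C:F / mean CSA when fibre outlines exist.

    CD uses the raw capillary count over the frame area; C:F and CSA
    use the forbidden-line fibre count, with CSA taken as the mean
    whole-polygon area of the counted fibres.
    """
    if cmap.n_capillaries < 1:
        raise ValidationError("global indices need at least one capillary")
    cd = cmap.n_capillaries / cmap.frame_area_mm2
    cf = csa = None
    if cmap.fibres:
        kept = count_fibres_unbiased(
            cmap.fibres, cmap.frame_width, cmap.frame_height
        )
        if kept.size > 0:
            cf = cmap.n_capillaries / kept.size
            csa = float(np.mean([cmap.fibres[k].area for k in kept]))
    return SupplyIndices(CD=cd, CF=cf, CSA=csa, region_label=cmap.region_label)


def compute_local_indices(
    tess: DomainTessellation,
    bins: Optional[np.ndarray] = None,
    exclude_boundary_domains: bool = False,
) -> SupplyIndices:
    """Mean capillary domain area, logSD heterogeneity and CDA histogram.

    With ``exclude_boundary_domains`` the frame-edge-touching domains
    are dropped from the statistics to reduce edge bias; by default all
    domains are included, which preserves the identity
    ``CDA_mean = frame_area / n_capillaries = 1/CD``.
    """
    areas = tess.interior() if exclude_boundary_domains else tess.areas
    if areas.size == 0:
        raise ValidationError("no domains left after boundary exclusion")
    cda_mean = float(np.mean(areas))
    logsd = float(np.std(np.log(areas), ddof=1)) if areas.size >= 2 else None
    edges = DEFAULT_CDA_BIN_EDGES if bins is None else np.asarray(bins, float)
    counts, edges = np.histogram(areas, bins=edges)
    cd = tess.n_domains / (tess.frame_area_um2 * 1e-6)
    return SupplyIndices(
        CD=cd,
        CDA_mean=cda_mean,
        logSD=logsd,
        domain_hist=(counts, edges),
    )


_RATIO_FIELDS = ("CF", "CD", "CSA", "CDA_mean", "logSD", "mean_PO2")


def core_cortex_ratio(core: SupplyIndices, cortex: SupplyIndices) -> dict[str, float]:
    """Element-wise core/cortex ratio of supply indices.

    Normalising core by cortex expresses the whole-muscle phenotype
    shift in one number per index; values move toward 1 as the two
    compartments converge. Indices absent from either input are
    skipped; a zero cortex value is an error.
    """
    out: dict[str, float] = {}
    for name in _RATIO_FIELDS:
        a, b = getattr(core, name), getattr(cortex, name)
        if a is None or b is None:
            continue
        if b == 0:
            raise ValidationError(f"cortex {name} is zero; ratio undefined")
        out[name] = a / b
    if not out:
        raise ValidationError("no common indices to form ratios")
    return out


def percent_change(control: float, treated: float) -> tuple[float, int]:
    """Percent change of a treated group mean relative to control.

    Returns ``(full_precision, nearest_integer)`` of
    ``100 * (treated - control) / control``.
    """
    if control <= 0:
        raise ValidationError("control value must be positive")
    pct = 100.0 * (treated - control) / control
    return pct, int(round(pct))
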