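"""Core data containers for capillary-domain analysis.

All spatial quantities are in micrometres in a frame-local coordinate
system with the origin at the bottom-left corner of the rectangular
sampling frame. The default sampling frame is a square of area
0.145 mm^2 (side ~380.79 um), matching the region-of-interest size used
in quantitative muscle histology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

#: Default sampling-frame area in mm^2.
DEFAULT_FRAME_AREA_MM2 = 0.145

#: Side length (um) of the default square sampling frame.
DEFAULT_FRAME_SIDE_UM = float(np.sqrt(DEFAULT_FRAME_AREA_MM2 * 1e6))

VALID_REGIONS = ("core", "cortex", "whole")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class CapillaryMap:
    """Capillary point pattern (and optional fibre outlines) in one frame.

    Parameters
    ----------
    frame_width, frame_height:
        Frame dimensions in um.
    capillaries:
        Array of shape (n, 2) with capillary (x, y) positions in um.
    fibres:
        Optional list of simple shapely polygons outlining muscle fibres.
    fibre_types:
        Optional fibre-type label per polygon (e.g. "I", "IIa", "IIb").
    region_label:
        One of ``core`` (oxidative), ``cortex`` (glycolytic) or ``whole``.
    """

    frame_width: float
    frame_height: float
    capillaries: np.ndarray
    fibres: Optional[list[Polygon]] = None
    fibre_types: Optional[list[Optional[str]]] = None
    region_label: str = "whole"
    animal_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValidationError("frame dimensions must be positive")
        pts = np.asarray(self.capillaries, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(
                f"capillaries must be an (n, 2) array, got shape {pts.shape}"
            )
        self.capillaries = pts
        x, y = pts[:, 0], pts[:, 1]
        bad = np.flatnonzero(
            (x < 0) | (x > self.frame_width) | (y < 0) | (y > self.frame_height)
        )
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"capillary row {i} at ({x[i]:g}, {y[i]:g}) lies outside the "
                f"frame [0, {self.frame_width:g}] x [0, {self.frame_height:g}]"
            )
        if pts.shape[0] > 1:
            uniq = np.unique(pts, axis=0)
            if uniq.shape[0] != pts.shape[0]:
                raise ValidationError(
                    "duplicate capillary points; tessellation requires "
                    "pairwise-distinct sites"
                )
        if self.region_label not in VALID_REGIONS:
            raise ValidationError(
                f"region_label must be one of {VALID_REGIONS}, "
                f"got {self.region_label!r}"
            )
        if self.fibres is not None:
            for k, poly in enumerate(self.fibres):
                if not poly.is_valid or poly.area <= 0:
                    raise ValidationError(
                        f"fibre polygon {k} is not a simple polygon with "
                        "positive area"
                    )
            if self.fibre_types is not None and len(self.fibre_types) != len(
                self.fibres
            ):
                raise ValidationError("fibre_types length must match fibres")

    @property
    def n_capillaries(self) -> int:
        return int(self.capillaries.shape[0])

    @property
    def frame_area_um2(self) -> float:
        return float(self.frame_width * self.frame_height)

    @property
    def frame_area_mm2(self) -> float:
        return self.frame_area_um2 * 1e-6


@dataclass
class TensionTrace:
    """Uniformly sampled isometric tension recording.

    ``stimulation_window`` is the (start, end) of the stimulation
    protocol in seconds; twitches are expected inside it.
    """

    time: np.ndarray
    tension: np.ndarray
    stimulation_window: tuple[float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.tension, dtype=float)
        if t.size == 0 or t.size != y.size:
            raise ValidationError("time and tension must be non-empty, equal length")
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValidationError("tension trace must be uniformly sampled")
        if np.any(y < 0):
            raise ValidationError("tension must be non-negative")
        a, b = self.stimulation_window
        if not (a < b):
            raise ValidationError("stimulation window start must precede end")
        self.time, self.tension = t, y

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else 0.0


@dataclass
class FlowTrace:
    """Arterial blood-flow recording (ml/min), optionally with pressure (mmHg)."""

    time: np.ndarray
    flow: np.ndarray
    stimulation_window: tuple[float, float]
    pressure: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        q = np.asarray(self.flow, dtype=float)
        if t.size == 0 or t.size != q.size:
            raise ValidationError("time and flow must be non-empty, equal length")
        if np.any(q < 0):
            raise ValidationError("flow must be non-negative")
        if self.pressure is not None:
            p = np.asarray(self.pressure, dtype=float)
            if p.size != t.size:
                raise ValidationError("pressure must match flow sampling")
            if np.any(p <= 0):
                raise ValidationError("pressure must be positive throughout")
            self.pressure = p
        a, b = self.stimulation_window
        if not (a < b):
            raise ValidationError("stimulation window start must precede end")
        self.time, self.flow = t, q

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else 0.0


@dataclass
class MetaboliteMatrix:
    """Samples x compounds intensity matrix with group labels."""

    intensities: np.ndarray
    sample_groups: list[str]
    compound_ids: list[str]
    sample_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        m = np.asarray(self.intensities, dtype=float)
        if m.ndim != 2:
            raise ValidationError("intensities must be 2-D (samples x compounds)")
        if np.any(m < 0) or np.any(~np.isfinite(m)):
            raise ValidationError("intensities must be finite and non-negative")
        if len(self.sample_groups) != m.shape[0]:
            raise ValidationError("one group label required per sample")
        if any(g is None or g == "" for g in self.sample_groups):
            raise ValidationError("missing group labels")
        if len(self.compound_ids) != m.shape[1]:
            raise ValidationError("one compound id required per column")
        if self.sample_ids is not None and len(self.sample_ids) != m.shape[0]:
            raise ValidationError("sample_ids length must match samples")
        self.intensities = m

    @property
    def n_samples(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def n_compounds(self) -> int:
        return int(self.intensities.shape[1])

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray([g == group for g in self.sample_groups], dtype=bool)


@dataclass(frozen=True)
class CompoundRecord:
    """Authenticated-standard reference for compound identification."""

    compound_id: str
    theoretical_mass: float  # Da
    retention_time: float  # seconds
    isotope_match: float = 100.0  # percent similarity to theoretical pattern

    def __post_init__(self) -> None:
        if self.theoretical_mass <= 0:
            raise ValidationError("theoretical mass must be positive")
        if not (0 <= self.isotope_match <= 100):
            raise ValidationError("isotope match must lie in [0, 100]")


@dataclass(frozen=True)
class FeatureRecord:
    """Measured LC-MS feature to be matched against a compound record."""

    feature_id: str
    measured_mass: float  # Da
    retention_time: float  # seconds
    isotope_match: float = 0.0  # percent

    def __post_init__(self) -> None:
        if self.measured_mass <= 0:
            raise ValidationError("measured mass must be positive")
        if not (0 <= self.isotope_match <= 100):
            raise ValidationError("isotope match must lie in [0, 100]")


@dataclass
class DomainTessellation:
    """Per-capillary trapping-region polygons clipped to the frame."""

    domains: list[Polygon]
    areas: np.ndarray
    boundary_flags: np.ndarray
    source_index: np.ndarray
    frame_width: float
    frame_height: float

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def frame_area_um2(self) -> float:
        return float(self.frame_width * self.frame_height)

    def interior(self) -> np.ndarray:
        """Areas of domains that do not touch the frame boundary."""
        return self.areas[~self.boundary_flags]


@dataclass
class SupplyIndices:
    """Global and local capillary supply indices for one frame or region.

    ``CF`` and ``CSA`` are None when no fibre outlines were supplied;
    ``logSD`` is None when fewer than two domains are available.
    """

    CD: float  # capillaries per mm^2
    CF: Optional[float] = None  # capillary-to-fibre ratio
    CSA: Optional[float] = None  # mean fibre cross-sectional area, um^2
    CDA_mean: Optional[float] = None  # mean capillary domain area, um^2
    logSD: Optional[float] = None  # SD of ln(domain area)
    domain_hist: Optional[tuple[np.ndarray, np.ndarray]] = None  # (counts, edges)
    mean_PO2: Optional[float] = None  # mmHg, from the oxygen model
    region_label: str = "whole"


@dataclass
class FatigueResult:
    """Fatigue-index summary of a stimulated tension trace."""

    FI: float  # final/peak tension ratio
    FI_percent: float  # the same ratio x 100
    peak_tension: float
    final_tension: float
    peak_window_indices: np.ndarray  # the 5 twitch-peak sample indices used for peak
    final_window_indices: np.ndarray  # the last 5 twitch-peak sample indices


@dataclass
class HyperaemiaResult:
    """Functional-hyperaemia summary of a flow (and optional pressure) trace."""

    relative_conductance: np.ndarray  # conductance / baseline conductance
    hyperaemia_ratio: float  # peak / resting blood flow
    baseline_flow: float
    peak_flow: float
    used_pressure: bool


@dataclass
class OxygenField:
    """Gridded steady-state PO2 solution over a sampling frame."""

    grid: np.ndarray  # PO2 in mmHg; NaN outside tissue (lumen cells)
    labels: np.ndarray  # nearest-capillary domain index per cell; -1 = lumen
    h: float  # grid step, um
    mean_PO2: float
    min_PO2: float
    hypoxic_fraction: float  # percent of tissue area below threshold
    hypoxia_threshold: float

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels >= 0


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""

    F: float
    df: tuple[int, int]
    p: float
    tukey: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


@dataclass
class VolcanoRow:
    """One compound's fold change and significance in a two-group comparison."""

    compound_id: str
    log2_fold_change: float
    raw_p: float
    fdr_adjusted_p: float
    flagged: bool = False  # True when a zero group mean made the fold change undefined
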