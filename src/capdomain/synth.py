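"""Synthetic-data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here with
known parameters, so each stage is testable end-to-end without any
external data:

* muscle cross-sections (fibre mosaics + capillary point patterns)
  emulating the oxidative **core** (high capillary density, smaller
  fibres) and glycolytic **cortex** (low density, larger fibres) of
  rat tibialis anterior, on 0.145 mm^2 sampling frames;
* twitch-train tension traces with a planted fatigue index;
* blood-flow traces with a planted peak/resting hyperaemia ratio and
  stimulation-frequency-dependent time-to-peak kinetics;
* log-normal metabolite intensity matrices with planted fold changes.

All generators are deterministic given their seed.

Cross-section construction: fibre centres sit on a hexagonal
(triangular) lattice scaled so the mean Voronoi-cell area equals the
requested fibre CSA, perturbed by Gaussian jitter (a fraction of the
lattice spacing). Fibre outlines are the Voronoi cells of the
centres, and capillaries are placed at fibre-boundary triple points
(Voronoi vertices) — the anatomical position of capillaries in the
interstitium between fibres — then thinned by Bernoulli sampling so
the expected capillary count matches the target capillary density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .datatypes import (
    CapillaryMap,
    FlowTrace,
    MetaboliteMatrix,
    TensionTrace,
    ValidationError,
)


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeSpec:
    """Parameters of one synthetic cross-section phenotype.

    ``jitter`` is the SD of the Gaussian lattice perturbation as a
    fraction of the lattice spacing; it is the single control of
    spatial heterogeneity (capillary-spacing logSD rises with it).
    ``target_CD`` may be None to keep every triple point (no thinning).
    """

    target_CD: Optional[float]  # capillaries per mm^2
    fibre_CSA_mean: float  # um^2
    jitter: float = 0.3  # fraction of lattice spacing
    frame_area_mm2: float = 0.145
    region_label: str = "whole"

    def __post_init__(self) -> None:
        if self.target_CD is not None and self.target_CD <= 0:
            raise ValidationError("target_CD must be positive")
        if self.fibre_CSA_mean <= 0:
            raise ValidationError("fibre_CSA_mean must be positive")
        if not (0 <= self.jitter <= 1):
            raise ValidationError("jitter must lie in [0, 1]")
        if self.frame_area_mm2 <= 0:
            raise ValidationError("frame_area_mm2 must be positive")

    @property
    def frame_side_um(self) -> float:
        return float(np.sqrt(self.frame_area_mm2 * 1e6))


# Control-phenotype presets. Capillary densities are the control group
# means for the two compartments (984 / 533 per mm^2); mean fibre CSA
# is derived from the control capillary-to-fibre ratios via
# CSA ~ (C:F) / CD, giving ~1870 um^2 (core) and ~2758 um^2 (cortex).
CORE_PRESET = PhenotypeSpec(
    target_CD=984.0, fibre_CSA_mean=1.84 / 984.0 * 1e6, region_label="core"
)
CORTEX_PRESET = PhenotypeSpec(
    target_CD=533.0, fibre_CSA_mean=1.47 / 533.0 * 1e6, region_label="cortex"
)

GROUPS = ("CT", "4Hz", "10Hz(3)", "10Hz", "40Hz")


def _default_effect_folds() -> dict[str, dict[str, float]]:
    # planted metabolite fold changes per stimulated group, following the
    # reported group effects (e.g. kynurenic acid doubling at 10 Hz,
    # glutamate +50% at 10 Hz, oxaloacetate -20/-25%)
    return {
        "4Hz": {
            "carnitine": 1.5,
            "TMABA": 1.2,
            "beta-alanine": 1.25,
            "anserine": 2.0,
            "1-methylhistidine": 2.0,
            "oxaloacetate": 0.8,
        },
        "10Hz(3)": {
            "lysine": 0.5,
            "malate": 1.2,
            "kynurenic acid": 2.0,
            "anserine": 2.0,
            "1-methylhistidine": 2.0,
        },
        "10Hz": {
            "kynurenic acid": 2.0,
            "glutamate": 1.5,
            "anserine": 2.0,
            "1-methylhistidine": 2.0,
            "oxaloacetate": 0.8,
        },
        "40Hz": {
            "beta-alanine": 1.25,
            "anserine": 2.0,
            "1-methylhistidine": 2.0,
            "oxaloacetate": 0.75,
        },
    }


@dataclass(frozen=True)
class EffectSpec:
    """Per-group planted effects for the stimulated phenotypes.

    Multipliers scale the control (CT) value of each quantity;
    metabolite folds are compound -> fold per group. Defaults mirror
    the reported group-level changes: cortex capillary density rising
    by 73/110/55% at 4/10/40 Hz, fatigue-index group means of
    0.47/0.58/0.75/0.82, and selected metabolite fold changes.
    """

    cd_multiplier: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "core": {
                "CT": 1.0,
                "4Hz": 1.0,
                "10Hz(3)": 1.0,
                "10Hz": 1360.0 / 984.0,
                "40Hz": 1.0,
            },
            "cortex": {
                "CT": 1.0,
                "4Hz": 921.0 / 533.0,
                "10Hz(3)": 1.0,
                "10Hz": 1120.0 / 533.0,
                "40Hz": 829.0 / 533.0,
            },
        }
    )
    csa_multiplier: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "core": {g: 1.0 for g in GROUPS},
            "cortex": {
                "CT": 1.0,
                "4Hz": 1.0,
                "10Hz(3)": 1.0,
                "10Hz": 0.81,
                "40Hz": 0.91,
            },
        }
    )
    metabolite_folds: dict[str, dict[str, float]] = field(
        default_factory=_default_effect_folds
    )
    fi_targets: dict[str, float] = field(
        default_factory=lambda: {
            "CT": 0.47,
            "4Hz": 0.58,
            "10Hz(3)": 0.75,
            "10Hz": 0.75,
            "40Hz": 0.82,
        }
    )
    hyperaemia_targets: dict[str, float] = field(
        default_factory=lambda: {g: 3.0 for g in GROUPS}
    )

    def __post_init__(self) -> None:
        for d in (self.cd_multiplier, self.csa_multiplier):
            for region in d.values():
                if any(v <= 0 for v in region.values()):
                    raise ValidationError("multipliers must be positive")
        for folds in self.metabolite_folds.values():
            if any(v <= 0 for v in folds.values()):
                raise ValidationError("metabolite folds must be positive")


DEFAULT_EFFECTS = EffectSpec()


# ---------------------------------------------------------------------------
# cross-sections
# ---------------------------------------------------------------------------

def _hex_lattice(spacing: float, lo: float, hi: float) -> np.ndarray:
    """Triangular-lattice points covering [lo, hi]^2."""
    dy = spacing * np.sqrt(3.0) / 2.0
    rows = int(np.ceil((hi - lo) / dy)) + 1
    cols = int(np.ceil((hi - lo) / spacing)) + 2
    pts = []
    for r in range(rows):
        y = lo + r * dy
        xoff = 0.5 * spacing if r % 2 else 0.0
        for c in range(cols):
            pts.append((lo + xoff + c * spacing, y))
    return np.asarray(pts)


def _ridge_midpoints(vor: Voronoi, side: float) -> np.ndarray:
    """Midpoints of finite Voronoi ridges (fibre-boundary edges) in frame."""
    pairs = np.asarray(
        [rv for rv in vor.ridge_vertices if -1 not in rv], dtype=int
    )
    if pairs.size == 0:
        return np.empty((0, 2))
    mids = 0.5 * (vor.vertices[pairs[:, 0]] + vor.vertices[pairs[:, 1]])
    keep = (
        (mids[:, 0] >= 0) & (mids[:, 0] <= side)
        & (mids[:, 1] >= 0) & (mids[:, 1] <= side)
    )
    return np.unique(mids[keep], axis=0)


def generate_cross_section(
    spec: PhenotypeSpec,
    seed: int,
    animal_id: str = "",
    group_label: str = "",
) -> CapillaryMap:
    """Synthetic fibre mosaic and capillary point pattern for one frame.

    Deterministic given (spec, seed). Raises when ``target_CD`` asks
    for more capillaries than there are fibre-boundary triple points.
    """
    rng = np.random.default_rng(seed)
    side = spec.frame_side_um
    # triangular lattice whose Voronoi (hexagonal) cells have the target
    # mean area: area = sqrt(3)/2 * a^2  =>  a = sqrt(2*CSA/sqrt(3))
    a = float(np.sqrt(2.0 * spec.fibre_CSA_mean / np.sqrt(3.0)))
    margin = 3.0 * a
    centres = _hex_lattice(a, -margin, side + margin)
    centres = centres + rng.normal(0.0, spec.jitter * a, size=centres.shape)

    vor = Voronoi(centres)
    frame = box(0.0, 0.0, side, side)

    fibres: list[Polygon] = []
    for i in range(len(centres)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            continue  # unbounded margin cell
        poly = Polygon(vor.vertices[region])
        if poly.is_valid and poly.area > 0 and poly.intersects(frame):
            fibres.append(poly)

    verts = vor.vertices
    inside = (
        (verts[:, 0] >= 0)
        & (verts[:, 0] <= side)
        & (verts[:, 1] >= 0)
        & (verts[:, 1] <= side)
    )
    candidates = np.unique(verts[inside], axis=0)
    if spec.target_CD is None:
        caps = candidates
    else:
        expected = spec.target_CD * spec.frame_area_mm2
        if expected <= candidates.shape[0]:
            keep = rng.random(candidates.shape[0]) < expected / candidates.shape[0]
            caps = candidates[keep]
        else:
            # densely capillarised phenotypes exceed one capillary per
            # triple point; draw the excess from fibre-boundary edge
            # midpoints, which are still interstitial positions
            mids = _ridge_midpoints(vor, side)
            deficit = expected - candidates.shape[0]
            if mids.shape[0] == 0 or deficit > mids.shape[0]:
                raise ValidationError(
                    f"target_CD {spec.target_CD:g}/mm^2 needs {expected:.0f} "
                    f"capillaries but only {candidates.shape[0]} triple points"
                    f" and {mids.shape[0]} edge midpoints exist; reduce "
                    "target_CD or fibre size"
                )
            keepm = rng.random(mids.shape[0]) < deficit / mids.shape[0]
            caps = np.unique(np.vstack([candidates, mids[keepm]]), axis=0)

    return CapillaryMap(
        frame_width=side,
        frame_height=side,
        capillaries=caps,
        fibres=fibres,
        region_label=spec.region_label,
        animal_id=animal_id,
        group_label=group_label,
    )


def phenotype_for_group(
    base: PhenotypeSpec, group: str, effects: EffectSpec = DEFAULT_EFFECTS
) -> PhenotypeSpec:
    """Apply a group's planted CD / CSA multipliers to a control spec.

    Multipliers are compartment-specific (the glycolytic cortex
    remodels far more than the oxidative core); a spec whose region is
    not listed falls back to the cortex multipliers.
    """
    region = base.region_label if base.region_label in effects.cd_multiplier \
        else "cortex"
    cd = base.target_CD
    if cd is not None:
        cd = cd * effects.cd_multiplier[region].get(group, 1.0)
    csa = base.fibre_CSA_mean * effects.csa_multiplier.get(region, {}).get(
        group, 1.0
    )
    return replace(base, target_CD=cd, fibre_CSA_mean=csa)


# ---------------------------------------------------------------------------
# tension traces
# ---------------------------------------------------------------------------

def generate_tension_trace(
    freq: float = 10.0,
    duration: float = 180.0,
    FI_target: float = 0.75,
    noise_sd: float = 0.02,
    seed: int = 0,
    sample_rate: float = 1000.0,
    pre_s: float = 1.0,
    post_s: float = 1.0,
) -> TensionTrace:
    """Twitch-train tension trace with a planted fatigue index.

    Raised-cosine twitches at ``freq`` Hz for ``duration`` s; twitch
    peak amplitudes decay geometrically from 1.0 (first twitch) to
    ``FI_target`` (last twitch), with multiplicative Gaussian
    amplitude noise of SD ``noise_sd``.
    """
    if not (0 < FI_target <= 1):
        raise ValidationError("FI_target must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    total = pre_s + duration + post_s
    t = np.arange(0.0, total, dt)
    y = np.zeros_like(t)
    n_twitch = int(np.floor(duration * freq))
    width = min(0.08, 0.8 / freq)  # s, shorter than the inter-twitch interval
    half = width / 2.0
    for k in range(n_twitch):
        if n_twitch > 1:
            amp = FI_target ** (k / (n_twitch - 1))
        else:
            amp = 1.0
        amp *= max(0.0, 1.0 + rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
        tc = pre_s + k / freq + half
        lo = max(0, int(np.floor((tc - half) / dt)))
        hi = min(t.size, int(np.ceil((tc + half) / dt)) + 1)
        seg = t[lo:hi]
        y[lo:hi] += amp * 0.5 * (1.0 + np.cos(np.pi * (seg - tc) / half)) * (
            np.abs(seg - tc) <= half
        )
    return TensionTrace(
        time=t, tension=y, stimulation_window=(pre_s, pre_s + duration)
    )


# ---------------------------------------------------------------------------
# flow traces
# ---------------------------------------------------------------------------

#: Time-to-peak of functional hyperaemia relative to the 3-min
#: stimulation window: peak near the window end at 4 Hz, earlier
#: (mid-window) at 10 Hz, and after stimulation ends at 40 Hz.
FLOW_KINETICS = {"4Hz": 1.0, "10Hz": 0.5, "40Hz": 1.25}


def generate_flow_trace(
    baseline: float = 1.0,
    peak_ratio: float = 3.0,
    kinetics: str = "10Hz",
    noise_sd: float = 0.0,
    seed: int = 0,
    stim_start: float = 60.0,
    stim_duration: float = 180.0,
    total: float = 480.0,
    sample_rate: float = 10.0,
    pressure: Optional[float] = 100.0,
) -> FlowTrace:
    """Blood-flow trace with a planted peak/resting hyperaemia ratio.

    Normalised logistic rise from baseline to ``baseline * peak_ratio``
    at the mode-dependent time-to-peak, then exponential return to
    baseline; optional multiplicative Gaussian noise.
    """
    if peak_ratio < 1:
        raise ValidationError("peak_ratio must be >= 1")
    if kinetics not in FLOW_KINETICS:
        raise ValidationError(f"kinetics must be one of {tuple(FLOW_KINETICS)}")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    t = np.arange(0.0, total, dt)
    peak = baseline * peak_ratio
    t_peak = stim_start + FLOW_KINETICS[kinetics] * stim_duration
    tau_rise = (t_peak - stim_start) / 8.0
    tau_decay = 60.0

    def sig(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(x - (stim_start + t_peak) / 2.0) / tau_rise))

    flow = np.full_like(t, baseline)
    rising = (t >= stim_start) & (t <= t_peak)
    s0, s1 = sig(np.array([stim_start]))[0], sig(np.array([t_peak]))[0]
    flow[rising] = baseline + (peak - baseline) * (sig(t[rising]) - s0) / (s1 - s0)
    after = t > t_peak
    flow[after] = baseline + (peak - baseline) * np.exp(-(t[after] - t_peak) / tau_decay)
    if noise_sd > 0:
        flow = flow * np.clip(1.0 + rng.normal(0.0, noise_sd, size=t.size), 0.0, None)
    p = np.full_like(t, float(pressure)) if pressure is not None else None
    return FlowTrace(
        time=t,
        flow=flow,
        stimulation_window=(stim_start, stim_start + stim_duration),
        pressure=p,
    )


# ---------------------------------------------------------------------------
# metabolomes
# ---------------------------------------------------------------------------

def generate_metabolome(
    n_per_group: int = 5,
    compounds: Optional[list[str]] = None,
    effects: EffectSpec = DEFAULT_EFFECTS,
    sigma_log: float = 0.2,
    seed: int = 0,
    groups: tuple[str, ...] = GROUPS,
    base_intensity: float = 1e6,
) -> MetaboliteMatrix:
    """Log-normal metabolite intensity matrix with planted fold changes.

    ln(intensity) ~ Normal(ln(base * fold) - sigma^2/2, sigma); the
    -sigma^2/2 correction makes the *arithmetic* group-mean ratio equal
    the planted fold. Compounds without a planted effect have fold 1
    in every group.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be at least 2")
    if compounds is None:
        named = sorted(
            {c for folds in effects.metabolite_folds.values() for c in folds}
        )
        filler = [f"compound_{k:03d}" for k in range(240 - len(named))]
        compounds = named + filler
    rng = np.random.default_rng(seed)
    # per-compound baseline spans a few orders of magnitude, as in MS data
    base = base_intensity * rng.lognormal(0.0, 1.0, size=len(compounds))
    rows, labels, ids = [], [], []
    for g in groups:
        folds = effects.metabolite_folds.get(g, {})
        mu = np.log(base * np.asarray([folds.get(c, 1.0) for c in compounds]))
        mu = mu - sigma_log**2 / 2.0
        sample = np.exp(
            rng.normal(mu, sigma_log, size=(n_per_group, len(compounds)))
        )
        rows.append(sample)
        labels.extend([g] * n_per_group)
        ids.extend([f"{g}_{i}" for i in range(n_per_group)])
    return MetaboliteMatrix(
        intensities=np.vstack(rows),
        sample_groups=labels,
        compound_ids=list(compounds),
        sample_ids=ids,
    )
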