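"""End-to-end demo pipeline wiring every analysis stage.

Generates synthetic core/cortex cross-sections for each experimental
group, tessellates them, computes supply indices and the oxygen model,
forms core:cortex ratios, analyses synthetic tension/flow traces, and
runs the metabolomics volcano comparison — writing one results
directory with CSV/JSON/GeoJSON/TIFF artifacts and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__, io
from .datatypes import SupplyIndices, ValidationError
from .function_metrics import fatigue_index, relative_conductance
from .group_stats import one_way_anova, volcano_table
from .indices import compute_global_indices, compute_local_indices, core_cortex_ratio
from .oxygen import OxygenParams, params_for_mode, solve_frame
from .synth import (
    CORE_PRESET,
    CORTEX_PRESET,
    DEFAULT_EFFECTS,
    generate_cross_section,
    generate_flow_trace,
    generate_metabolome,
    generate_tension_trace,
    phenotype_for_group,
)
from .tessellation import tessellate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Unknown keys are rejected; the effective configuration is echoed
    to the log and written alongside the outputs so every run is
    reproducible from its results directory.
    """

    out_dir: str = "capdomain_results"
    seed: int = 0
    groups: tuple[str, ...] = ("CT", "10Hz")
    n_animals: int = 2
    oxygen_mode: str = "exercise"
    oxygen_h: float = 2.0  # um grid step for the demo solve
    M0: Optional[float] = None  # override of the mode's consumption rate
    P_cap: Optional[float] = None
    hypoxia_threshold: Optional[float] = None
    n_compounds: int = 60
    n_per_group: int = 5
    sigma_log: float = 0.2
    volcano_pair: tuple[str, str] = ("CT", "10Hz")
    save_fields: bool = True

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("groups", "volcano_pair"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def oxygen_params(self) -> OxygenParams:
        overrides = {}
        if self.M0 is not None:
            overrides["M0"] = self.M0
        if self.P_cap is not None:
            overrides["P_cap"] = self.P_cap
        if self.hypoxia_threshold is not None:
            overrides["hypoxia_threshold"] = self.hypoxia_threshold
        return params_for_mode(self.oxygen_mode, **overrides)

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        if self.oxygen_h <= 0:
            raise ValidationError("oxygen_h must be positive")
        self.oxygen_params()  # raises on invalid physical parameters


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the results directory.

    Returns the manifest dictionary (also saved as ``manifest.json``).
    All randomness derives from ``config.seed``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("effective config: %s", asdict(config))
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)

    root = np.random.SeedSequence(config.seed)
    params = config.oxygen_params()
    effects = DEFAULT_EFFECTS

    stage = "histology"
    try:
        index_records: list[dict] = []
        ratio_records: list[dict] = []
        for gi, group in enumerate(config.groups):
            for animal in range(config.n_animals):
                per_region: dict[str, SupplyIndices] = {}
                for ri, (region, preset) in enumerate(
                    (("core", CORE_PRESET), ("cortex", CORTEX_PRESET))
                ):
                    seed = int(
                        np.random.SeedSequence(
                            [config.seed, 1, gi, animal, ri]
                        ).generate_state(1)[0] % (2**31)
                    )
                    spec = phenotype_for_group(preset, group, effects)
                    cmap = generate_cross_section(
                        spec, seed, animal_id=f"{group}-a{animal}", group_label=group
                    )
                    tess = tessellate(cmap)
                    g = compute_global_indices(cmap)
                    l = compute_local_indices(tess)
                    field_file = None
                    stage = "oxygen"
                    ox = solve_frame(tess, cmap, params, h=config.oxygen_h)
                    if config.save_fields and animal == 0:
                        import tifffile

                        field_file = f"po2_{group}_{region}.tiff"
                        tifffile.imwrite(
                            out / field_file,
                            ox.grid.astype(np.float32),
                        )
                    stage = "histology"
                    idx = SupplyIndices(
                        CD=g.CD,
                        CF=g.CF,
                        CSA=g.CSA,
                        CDA_mean=l.CDA_mean,
                        logSD=l.logSD,
                        domain_hist=l.domain_hist,
                        mean_PO2=ox.mean_PO2,
                        region_label=region,
                    )
                    per_region[region] = idx
                    index_records.append(
                        {
                            "group": group,
                            "animal": animal,
                            "region": region,
                            "CD_per_mm2": idx.CD,
                            "CF": idx.CF,
                            "CSA_um2": idx.CSA,
                            "CDA_um2": idx.CDA_mean,
                            "logSD": idx.logSD,
                            "mean_PO2_mmHg": idx.mean_PO2,
                            "hypoxic_fraction_pct": ox.hypoxic_fraction,
                            "po2_field": field_file,
                        }
                    )
                ratios = core_cortex_ratio(per_region["core"], per_region["cortex"])
                ratio_records.append(
                    {"group": group, "animal": animal, **ratios}
                )

        import pandas as pd

        pd.DataFrame(index_records).to_csv(out / "indices.csv", index=False)
        pd.DataFrame(ratio_records).to_csv(out / "core_cortex_ratios.csv", index=False)

        stage = "function"
        fi_rows = []
        for gi, group in enumerate(config.groups):
            for animal in range(config.n_animals):
                seed = int(
                    np.random.SeedSequence(
                        [config.seed, 2, gi, animal]
                    ).generate_state(1)[0] % (2**31)
                )
                trace = generate_tension_trace(
                    FI_target=effects.fi_targets.get(group, 0.6), seed=seed
                )
                fi = fatigue_index(trace, min_separation=0.05)
                flow = generate_flow_trace(
                    peak_ratio=effects.hyperaemia_targets.get(group, 3.0),
                    kinetics=group if group in ("4Hz", "10Hz", "40Hz") else "10Hz",
                    noise_sd=0.05,
                    seed=seed,
                )
                hyp = relative_conductance(flow)
                fi_rows.append(
                    {
                        "group": group,
                        "animal": animal,
                        "FI": fi.FI,
                        "FI_percent": fi.FI_percent,
                        "hyperaemia_ratio": hyp.hyperaemia_ratio,
                    }
                )
        fi_df = pd.DataFrame(fi_rows)
        fi_df.to_csv(out / "function_metrics.csv", index=False)

        anova_out = None
        if config.n_animals >= 2 and len(config.groups) >= 2:
            samples = [
                fi_df.loc[fi_df.group == g, "FI"].to_numpy()
                for g in config.groups
            ]
            res = one_way_anova(samples, labels=list(config.groups))
            anova_out = {
                "F": res.F,
                "df": res.df,
                "p": res.p,
                "tukey": {f"{a} vs {b}": v for (a, b), v in res.tukey.items()},
            }
            with open(out / "fi_anova.json", "w") as fh:
                json.dump(anova_out, fh, indent=2)

        stage = "metabolomics"
        seed = int(
            np.random.SeedSequence([config.seed, 3]).generate_state(1)[0] % (2**31)
        )
        named = sorted(
            {c for folds in effects.metabolite_folds.values() for c in folds}
        )
        n_cmp = max(config.n_compounds, len(named))
        compounds = named + [
            f"compound_{k:03d}" for k in range(n_cmp - len(named))
        ]
        matrix = generate_metabolome(
            n_per_group=config.n_per_group,
            compounds=compounds,
            sigma_log=config.sigma_log,
            seed=seed,
        )
        io.write_metabolite_matrix(matrix, out / "metabolome.csv")
        rows = volcano_table(matrix, *config.volcano_pair)
        pd.DataFrame(
            [
                {
                    "compound": r.compound_id,
                    "log2_fold_change": r.log2_fold_change,
                    "raw_p": r.raw_p,
                    "fdr_adjusted_p": r.fdr_adjusted_p,
                }
                for r in rows
            ]
        ).to_csv(out / "volcano.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    artifacts = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "capdomain_version": __version__,
        "seed": config.seed,
        "config_sha256": _hash_file(out / "config.json"),
        "artifacts": {name: _hash_file(out / name) for name in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
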