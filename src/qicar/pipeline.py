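"""One-command orchestration: screen -> estimator comparison -> Monte Carlo
-> held-out validation, with a provenance record.

All stage outputs are plain TSV/JSON so repeated runs with the same seed and
inputs are byte-identical and diffable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ctd_scores import DiseaseScoreSet, load_scores
from .ion_properties import PropertyTable, load_property_table
from .robustness import compare_estimators, monte_carlo, validate_on_new_ions
from .screening import run_screen
from .synthetic import SyntheticConfig, generate_properties, generate_scores

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for a full analysis run."""

    out_dir: str
    seed: int = 0
    properties_path: str | None = None
    scores_path: str | None = None
    synth: SyntheticConfig | None = None     # used when paths are absent
    alpha: float = 0.05
    correction: str = "per-cellset"
    iqr_convention: str = "divide"
    ntrim_overrides: dict = field(default_factory=dict)
    replicates: int = 1000
    validation_ions: list = field(default_factory=list)
    validation_endpoint: str = "cardiac arrhythmia"
    validation_properties: list = field(default_factory=lambda: ["AN", "sigma_p", "MP", "rho"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        synth = raw.pop("synth", None)
        if synth is not None:
            from .synthetic import CellModel
            cells = [CellModel(**c) for c in synth.pop("cells")]
            synth = SyntheticConfig(cells=cells, **synth)
        return cls(synth=synth, **raw)


def _resolve_inputs(config: RunConfig) -> tuple[PropertyTable, DiseaseScoreSet]:
    if config.properties_path and config.scores_path:
        for path in (config.properties_path, config.scores_path):
            if not Path(path).exists():
                raise FileNotFoundError(f"input not found: {path}")
        return load_property_table(config.properties_path), load_scores(config.scores_path)
    if config.synth is None:
        raise ValueError("config needs either properties_path+scores_path or a synth block")
    props = generate_properties(config.synth, config.seed)
    scores, manifest = generate_scores(props, config.synth, config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_json(out / "truth.json")
    return props, scores


def run_full_analysis(config: RunConfig) -> Path:
    """Run every stage and write its outputs under ``config.out_dir``.

    Returns the output directory; raises on any stage failure (the CLI maps
    that to a nonzero exit status).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    props, scores = _resolve_inputs(config)

    # 1. screen
    overrides = {tuple(k.split(" | ")) if isinstance(k, str) else tuple(k): v
                 for k, v in config.ntrim_overrides.items()}
    screen = run_screen(scores, props, alpha=config.alpha,
                        correction=config.correction,
                        ntrim_overrides=overrides,
                        iqr_convention=config.iqr_convention)
    screen.write(out)

    # 2. estimator comparison on every fitted cell
    comp_rows = []
    for cell in screen.fitted:
        f = cell.fit
        comp = compare_estimators(f.x, f.y, h=f.h)
        row = {"endpoint": cell.endpoint, "group": cell.group,
               "property": cell.property, "partial": comp.partial,
               "agree_exact": comp.agree_within(0.0),
               "agree_20pct": comp.agree_within(0.2)}
        row.update({f"slope_{m}": comp.slopes.get(m) for m in ("LTS", "M", "S", "MM")})
        comp_rows.append(row)
    pd.DataFrame(comp_rows).to_csv(out / "estimator_comparison.tsv", sep="\t", index=False)

    # 3. Monte Carlo on the significant cells
    mc_rows = []
    for i, cell in enumerate(screen.significant):
        f = cell.fit
        summary = monte_carlo(f.intercept, f.slope, f.scale, f.x,
                              n_outliers=f.n_trim + 1,
                              replicates=config.replicates,
                              seed=config.seed + i, h=f.h)
        mc_rows.append({"endpoint": cell.endpoint, "group": cell.group,
                        "property": cell.property,
                        "slope_mean": summary.slope_mean,
                        "slope_sd": summary.slope_sd,
                        "relative_deviation_pct": summary.relative_deviation_pct,
                        "mean_reported_se": summary.mean_reported_se,
                        "se_ratio": summary.se_ratio,
                        "n_failed": summary.n_failed})
    pd.DataFrame(mc_rows).to_csv(out / "simulation_summary.tsv", sep="\t", index=False)

    # 4. held-out validation where configured
    val_rows = []
    for cell in screen.fitted:
        if (config.validation_ions
                and cell.endpoint == config.validation_endpoint
                and cell.group == "transition"
                and cell.property in config.validation_properties):
            try:
                res = validate_on_new_ions(cell.fit, props, scores, config.validation_ions)
            except ValueError as exc:
                logger.warning("validation skipped for %s: %s", cell.property, exc)
                continue
            val_rows.append({"model": res.model, "ions": ",".join(res.ions),
                             "relative_l2_norm": res.norm,
                             "excluded": ",".join(res.excluded)})
    pd.DataFrame(val_rows).to_csv(out / "validation.tsv", sep="\t", index=False)

    provenance = {
        "version": __version__, "seed": config.seed, "alpha": config.alpha,
        "correction": config.correction, "corrected_alpha": screen.corrected_alpha,
        "iqr_convention": config.iqr_convention, "replicates": config.replicates,
        "inputs": {"properties": config.properties_path, "scores": config.scores_path,
                   "synthetic": config.synth is not None},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return out
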