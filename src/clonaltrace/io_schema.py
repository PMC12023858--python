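"""Schema validation, config handling and end-to-end orchestration.

Tidy-long CSV is the single interchange schema: measurement tables in,
isotope-result / fate-panel / contribution tables out. Every output file
starts with comment headers recording the seed and a hash of the run
configuration, so identical configurations produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expr_screen, partitioning, synthetic_data
from .isotope_core import (
    ORGANS,
    STAGE_ORDER,
    TracerSpec,
    aggregate_results,
    compute_isotope_results,
    labelled_mass,
)

__all__ = [
    "ValidationError",
    "RunConfig",
    "validate_measurements",
    "read_measurements",
    "write_table",
    "load_scenario",
    "run_all",
]

TREATMENTS = ("PL", "RL", "control")


class ValidationError(ValueError):
    """Schema violation with an itemized report."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "measurement table failed validation:\n  - " + "\n  - ".join(problems)
        )


def validate_measurements(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Validate a tidy measurement table; raise with all problems found.

    Enforces the column schema, enum domains (treatment, stage, organ),
    value ranges, the rule that nascent-leaf rows only occur at the
    leafing stage, and uniqueness of (treatment, stage, organ,
    replicate). Returns the validated table (stage as an ordered
    categorical) and an empty problem list on success.
    """
    problems: list[str] = []
    from .isotope_core import MEASUREMENT_COLUMNS

    missing = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError([f"missing columns: {sorted(missing)}"])
    for col, domain in (
        ("treatment", TREATMENTS),
        ("stage", STAGE_ORDER),
        ("organ", ORGANS),
    ):
        bad = set(table[col].unique()) - set(domain)
        if bad:
            problems.append(f"unknown {col} value(s): {sorted(map(str, bad))}")
    if (table["replicate"] < 1).any():
        problems.append("replicate numbers must be ≥ 1")
    if ((table["atom_pct_15N"] < 0) | (table["atom_pct_15N"] > 100)).any():
        problems.append("atom_pct_15N outside [0, 100]")
    if (table["tn_conc_mg_per_kg"] < 0).any():
        problems.append("negative tn_conc_mg_per_kg")
    if (table["biomass_kg"] < 0).any():
        problems.append("negative biomass_kg")
    bad_nascent = table[
        (table["organ"] == "nascent_leaf") & (table["stage"] != "LS")
    ]
    if len(bad_nascent):
        problems.append(
            f"nascent_leaf rows at stage(s) other than LS "
            f"({sorted(bad_nascent['stage'].unique())}): the nascent leaf "
            "only exists at the leafing stage"
        )
    key = ["treatment", "stage", "organ", "replicate"]
    dupes = table[table.duplicated(key, keep=False)]
    if len(dupes):
        problems.append(
            f"{len(dupes)} rows share a duplicated (treatment, stage, organ, "
            "replicate) key"
        )
    if problems:
        raise ValidationError(problems)
    out = table.copy()
    out["stage"] = pd.Categorical(out["stage"], STAGE_ORDER, ordered=True)
    return out, problems


def read_measurements(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep, comment="#")
    validated, _ = validate_measurements(table)
    return validated


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    out_dir: Path
    seed: int = 0
    tracer: TracerSpec = field(
        default_factory=lambda: synthetic_data.DEFAULT_TRACER
    )
    measurements_path: Path | None = None  # None → simulate
    p_thresh: float = 0.05
    lfc_thresh: float = 1.0
    fpkm_floor: float = 10.0
    alpha: float = 0.05
    run_screen: bool = True

    def __post_init__(self) -> None:
        for name in ("p_thresh", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def hash(self) -> str:
        payload = {
            "seed": self.seed,
            "tracer": [
                self.tracer.volume_ml,
                self.tracer.n_conc_mg_per_ml,
                self.tracer.atom_pct,
                self.tracer.compound,
            ],
            "measurements": str(self.measurements_path),
            "p": self.p_thresh,
            "lfc": self.lfc_thresh,
            "floor": self.fpkm_floor,
            "alpha": self.alpha,
            "screen": self.run_screen,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, *, seed: int, config_hash: str
) -> None:
    """Write a CSV with seed / config-hash provenance headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def load_scenario(path: str | Path) -> synthetic_data.FragmentModel:
    """Build a FragmentModel from a YAML scenario file.

    The file may override any of: ``transfer`` (list of per-stage flow
    mappings), ``dose_mg``, ``noise_cv``, ``biomass_cv``,
    ``n_replicates``, ``seed``, ``tn_conc`` / ``biomass`` (mappings
    ``stage.organ`` → value), and the tracer spec. Omitted fields fall
    back to the bundled default scenario.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model = synthetic_data.default_model(seed=int(raw.get("seed", 0)))
    if "transfer" in raw:
        model.transfer = raw["transfer"]
        model.matrices()  # validate
    for key in ("dose_mg", "noise_cv", "biomass_cv", "n_replicates"):
        if key in raw:
            setattr(model, key, type(getattr(model, key))(raw[key]))
    if "tracer" in raw:
        model.tracer = TracerSpec(**raw["tracer"])
    for pool_key in ("tn_conc", "biomass"):
        for dotted, value in (raw.get(pool_key) or {}).items():
            stage, organ = dotted.split(".")
            getattr(model, pool_key)[(stage, organ)] = float(value)
    return model


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write versioned outputs.

    simulate (unless a measurement file is given) → isotope equations →
    fate partitioning → contribution table → backflow → expression
    screen (on synthetic expression with planted signal). Deterministic
    for a fixed seed; every output carries the seed and config hash.
    """
    cfg_hash = config.hash()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.measurements_path is None:
        model = synthetic_data.default_model(seed=config.seed)
        measurements = synthetic_data.simulate_fragment(model)
        truth = synthetic_data.ground_truth(model)
    else:
        measurements = read_measurements(config.measurements_path)
        truth = None
    validate_measurements(measurements)

    dose_g = labelled_mass(config.tracer) * 1e-3
    results = compute_isotope_results(measurements, config.tracer)
    panel = partitioning.fate_panel(results, dose_g)
    contrib = partitioning.contribution_table(panel)
    backflow_pl = partitioning.backflow_series(panel, "PL")
    backflow_rl = partitioning.backflow_series(panel, "RL")

    kw = {"seed": config.seed, "config_hash": cfg_hash}
    write_table(measurements, out / "measurements.csv", **kw)
    write_table(results, out / "isotope_results.csv", **kw)
    write_table(aggregate_results(results), out / "isotope_aggregated.csv", **kw)
    write_table(panel, out / "fate_panel.csv", **kw)
    write_table(contrib, out / "contribution_table.csv", **kw)
    write_table(
        pd.concat(
            [backflow_pl.assign(treatment="PL"), backflow_rl.assign(treatment="RL")],
            ignore_index=True,
        ),
        out / "backflow.csv",
        **kw,
    )

    bundle = {
        "measurements": measurements,
        "isotope_results": results,
        "fate_panel": panel,
        "contributions": contrib,
        "backflow_PL": backflow_pl,
        "backflow_RL": backflow_rl,
        "ground_truth": truth,
        "config_hash": cfg_hash,
    }

    if config.run_screen:
        expr_cfg = synthetic_data.ExprSimConfig(seed=config.seed)
        expr = synthetic_data.generate_expression(expr_cfg)
        screen = expr_screen.run_screen(
            expr["fpkm"],
            expr["samples"],
            expr["traits"],
            p_thresh=config.p_thresh,
            lfc_thresh=config.lfc_thresh,
        )
        write_table(screen.edges, out / "screen_edges.csv", **kw)
        write_table(
            pd.DataFrame(
                {"gene": sorted(screen.trait_correlated)}
            ),
            out / "trait_correlated_genes.csv",
            **kw,
        )
        bundle["screen"] = screen
        bundle["expression"] = expr

    manifest = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "labelled_15N_mg": labelled_mass(config.tracer),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["manifest"] = manifest
    return bundle
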