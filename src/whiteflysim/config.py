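"""Configuration loading, validation, output writing, run manifests.

One structured YAML file describes a run: a ``scenario`` section
(horizon, temperatures, applications, initial population, migration,
replication) plus optional ``deb``/``tktd``/``exposure``/``plant``/
``temperature`` sections overriding the shipped defaults.  Time
series may be inline lists or CSV paths.  Every output directory gets
a manifest recording the configuration hash, master seed, and package
version so reruns are reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deb import DEBParams, Stage
from .exposure import ApplicationEvent
from .ibm import InitialGroup, ModelParams, ScenarioConfig
from .plant import PlantParams
from .temperature import TemperatureResponse
from .tktd import TKTDParams

__all__ = [
    "RunManifest",
    "default_parameter_dict",
    "default_model_params",
    "load_config",
    "read_temperature_csv",
    "read_application_csv",
    "write_outputs",
]

_SECTION_KEYS = {
    "temperature": {"whitefly", "cotton"},
    "deb": set(DEBParams.__dataclass_fields__),
    "tktd": set(TKTDParams.__dataclass_fields__),
    "exposure": {"k_dec_ref", "V_sat", "k_up", "P_max_at_sat"},
    "plant": set(PlantParams.__dataclass_fields__),
    "scenario": {
        "horizon", "temps", "temps_csv", "applications", "applications_csv",
        "initial_population", "immigration", "emigration_rate",
        "emigration_trigger_nodes", "emigration_trigger_fraction",
        "background_hazard_multiplier", "n_reps", "seed", "substeps", "f",
        "immigrant_sex", "n_reps", "disc_area_cm2", "adult_leaf_multiplier",
    },
}


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every output set."""

    config_hash: str
    master_seed: int
    tool_version: str
    parameter_defaults_version: str
    created_utc: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")

    @staticmethod
    def from_config(config_dict: dict, seed: int) -> "RunManifest":
        payload = json.dumps(config_dict, sort_keys=True, default=str)
        return RunManifest(
            config_hash=hashlib.sha256(payload.encode()).hexdigest(),
            master_seed=int(seed),
            tool_version=__version__,
            parameter_defaults_version=_defaults_hash(),
            created_utc=datetime.now(timezone.utc).isoformat(),
        )


def _defaults_text() -> str:
    return (resources.files("whiteflysim") / "params" /
            "defaults.yaml").read_text()


def _defaults_hash() -> str:
    return hashlib.sha256(_defaults_text().encode()).hexdigest()[:16]


def default_parameter_dict() -> dict:
    """The shipped parameter file as a nested dict."""
    return yaml.safe_load(_defaults_text())


def _build_temperature(block: dict) -> TemperatureResponse:
    return TemperatureResponse(**block)


def _build_deb(block: dict) -> DEBParams:
    block = dict(block)
    block["instar_lengths"] = tuple(block["instar_lengths"])
    params = DEBParams(**block)
    bad = params.validate()
    if bad:
        raise ValueError("deb: " + "; ".join(bad))
    return params


def _build_tktd(block: dict) -> TKTDParams:
    block = dict(block)
    if "exposed_stages" in block:
        block["exposed_stages"] = frozenset(
            Stage[s] if isinstance(s, str) else Stage(s)
            for s in block["exposed_stages"])
    params = TKTDParams(**block)
    bad = params.validate()
    if bad:
        raise ValueError("tktd: " + "; ".join(bad))
    return params


def default_model_params(overrides: dict | None = None) -> ModelParams:
    """Build :class:`ModelParams` from the shipped defaults, with
    optional per-section overrides (same nesting as the YAML)."""
    base = default_parameter_dict()
    if overrides:
        for section, block in overrides.items():
            if section not in _SECTION_KEYS:
                raise ValueError(f"unknown config section {section!r}")
            if isinstance(block, dict):
                base.setdefault(section, {}).update(block)
            else:
                base[section] = block
    return ModelParams(
        deb=_build_deb(base["deb"]),
        tktd=_build_tktd(base["tktd"]),
        whitefly_resp=_build_temperature(base["temperature"]["whitefly"]),
        cotton_resp=_build_temperature(base["temperature"]["cotton"]),
        plant=PlantParams(**base["plant"]),
        k_dec_ref=float(base["exposure"]["k_dec_ref"]),
    )


def read_temperature_csv(path) -> np.ndarray:
    """Daily mean temperatures from CSV (columns: day or date, t_mean_c)."""
    df = pd.read_csv(path)
    if "t_mean_c" not in df.columns:
        raise ValueError(f"{path}: missing column 't_mean_c'")
    return df["t_mean_c"].to_numpy(dtype=float)


def read_application_csv(path) -> tuple:
    """Application schedule from CSV (day, rate_g_ai_ha, water_volume_l_ha)."""
    df = pd.read_csv(path)
    missing = {"day", "rate_g_ai_ha"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    events = []
    for row in df.itertuples():
        wv = getattr(row, "water_volume_l_ha", 300.0)
        events.append(ApplicationEvent(day=int(row.day),
                                       rate=float(row.rate_g_ai_ha),
                                       water_volume=float(wv)))
    return tuple(events)


def _parse_initial_population(entries) -> tuple:
    groups = []
    for entry in entries:
        entry = dict(entry)
        stage = entry.pop("stage")
        stage = Stage[stage] if isinstance(stage, str) else Stage(stage)
        sex = entry.pop("sex", None)
        if isinstance(sex, str):
            sex = {"female": 0, "male": 1}[sex.lower()]
        groups.append(InitialGroup(
            stage=stage, count=int(entry.pop("count")),
            length_mean=entry.pop("length_mean", None),
            length_sd=float(entry.pop("length_sd", 0.0)), sex=sex))
        if entry:
            raise ValueError(
                f"initial_population: unknown keys {sorted(entry)}")
    return tuple(groups)


def load_config(path) -> tuple[ScenarioConfig, ModelParams, dict]:
    """Load and validate a run configuration.

    Returns ``(scenario, model_params, raw_dict)``.  Every unknown key
    and every cross-field violation is reported in one error.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    errors = []
    for section, block in raw.items():
        if section not in _SECTION_KEYS:
            errors.append(f"unknown section {section!r}")
            continue
        if section == "temperature":
            continue
        if not isinstance(block, dict):
            errors.append(f"section {section!r}: expected a mapping")
            continue
        unknown = set(block) - _SECTION_KEYS[section]
        if unknown:
            errors.append(f"section {section!r}: unknown keys "
                          f"{sorted(unknown)}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))

    overrides = {k: v for k, v in raw.items() if k != "scenario"}
    params = default_model_params(overrides)

    sc = dict(raw.get("scenario", {}))
    defaults = default_parameter_dict()["scenario"]
    if "temps_csv" in sc:
        temps = read_temperature_csv(path.parent / sc.pop("temps_csv"))
    else:
        temps = np.asarray(sc.pop("temps", []), dtype=float)
    if "applications_csv" in sc:
        apps = read_application_csv(path.parent / sc.pop("applications_csv"))
    else:
        apps = tuple(ApplicationEvent(
            day=int(a["day"]), rate=float(a["rate"]),
            water_volume=float(a.get("water_volume", 300.0)))
            for a in sc.pop("applications", []))
    init = _parse_initial_population(sc.pop("initial_population", []))
    sc.pop("disc_area_cm2", None)
    sc.pop("adult_leaf_multiplier", None)
    immigrant_sex = sc.pop("immigrant_sex", "female")
    if isinstance(immigrant_sex, str):
        immigrant_sex = {"female": 0, "male": 1,
                         "random": None}[immigrant_sex.lower()]
    config = ScenarioConfig(
        horizon=int(sc.pop("horizon")),
        temps=tuple(float(t) for t in temps),
        applications=apps,
        initial_population=init,
        immigration=sc.pop("immigration", 0.0),
        emigration_rate=float(sc.pop("emigration_rate", 0.0)),
        emigration_trigger_nodes=float(
            sc.pop("emigration_trigger_nodes",
                   defaults["emigration_trigger_nodes"])),
        emigration_trigger_fraction=float(
            sc.pop("emigration_trigger_fraction",
                   defaults["emigration_trigger_fraction"])),
        background_hazard_multiplier=sc.pop(
            "background_hazard_multiplier", 1.0),
        n_reps=int(sc.pop("n_reps", defaults["n_reps"])),
        seed=int(sc.pop("seed", 0)),
        substeps=int(sc.pop("substeps", defaults["substeps"])),
        f=float(sc.pop("f", 1.0)),
        immigrant_sex=immigrant_sex,
    )
    if sc:
        raise ValueError(f"{path}: scenario: unhandled keys {sorted(sc)}")
    bad = config.validate()
    if bad:
        raise ValueError(f"{path}: " + "; ".join(bad))
    return config, params, raw


_STAGE_NAMES = [s.name for s in Stage]


def trajectories_to_frame(trajectories) -> pd.DataFrame:
    """Tidy long-format frame of per-day, per-stage counts."""
    rows = []
    for traj in trajectories:
        horizon = traj.counts.shape[0]
        for day in range(horizon):
            for s in Stage:
                rows.append({
                    "replicate": traj.replicate, "day": day,
                    "stage": s.name, "count": int(traj.counts[day, int(s)]),
                    "leaf_area_cm2": traj.leaf_area[day],
                    "nodes": traj.nodes[day],
                    "exposure_c": traj.exposure[day],
                })
    columns = ["replicate", "day", "stage", "count", "leaf_area_cm2",
               "nodes", "exposure_c"]
    return pd.DataFrame(rows, columns=columns)


def summary_to_frame(summary: dict) -> pd.DataFrame:
    """Long-format quantile summary from :func:`ibm.monte_carlo`."""
    rows = []
    horizon = summary["counts_median"].shape[0]
    for day in range(horizon):
        for s in Stage:
            rows.append({
                "day": day, "stage": s.name,
                "q2_5": summary["counts_lo"][day, int(s)],
                "median": summary["counts_median"][day, int(s)],
                "q97_5": summary["counts_hi"][day, int(s)],
            })
        rows.append({"day": day, "stage": "TOTAL",
                     "q2_5": summary["totals_lo"][day],
                     "median": summary["totals_median"][day],
                     "q97_5": summary["totals_hi"][day]})
    return pd.DataFrame(rows)


def write_outputs(trajectories, summary: dict | None, out_dir,
                  config_dict: dict, seed: int) -> dict:
    """Write tidy CSVs and the run manifest; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    traj_path = out_dir / "trajectories.csv"
    if traj_path.exists():
        import warnings
        warnings.warn(f"overwriting {traj_path}", stacklevel=2)
    trajectories_to_frame(trajectories).to_csv(traj_path, index=False)
    written["trajectories"] = traj_path
    if summary is not None:
        sum_path = out_dir / "summary.csv"
        summary_to_frame(summary).to_csv(sum_path, index=False)
        written["summary"] = sum_path
    manifest = RunManifest.from_config(config_dict, seed)
    manifest.write(out_dir / "manifest.json")
    written["manifest"] = out_dir / "manifest.json"
    return written
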