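"""Readers, writers and pipeline configuration.

All tabular artifacts are long-format CSV (ragged observation windows —
cells born mid-experiment — don't fit wide matrices).  Times are in
minutes, fluorescence in background-subtracted arbitrary units.  Floats
are written with enough digits (%.17g) that every writer/reader pair
round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .population import PopulationModel
from .synthetic import CellTrajectory, StudyDataset
from .input_model import ShockSchedule

__all__ = ["read_trajectories", "write_trajectories", "read_study", "write_study",
           "RunConfig", "run_pipeline", "ParseError"]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"
TRAJ_COLUMNS = ["cell_id", "time_min", "fluorescence_au"]


class ParseError(ValueError):
    pass


def read_trajectories(path: str | Path) -> list[CellTrajectory]:
    """Read long-format trajectories (cell_id,time_min,fluorescence_au).

    Rows are grouped by cell and sorted by time; birth/end times are the
    first/last sample.  Duplicate (cell, time) rows and non-numeric
    values raise :class:`ParseError` naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cell_id": str}, float_precision="round_trip")
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("time_min", "fluorescence_au"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(bad | df[col].isna())[0]) + 2  # 1-based + header
            raise ParseError(f"{path}: non-numeric {col} at line {row}")
        df[col] = pd.to_numeric(df[col])
    dup = df.duplicated(subset=["cell_id", "time_min"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 2
        raise ParseError(f"{path}: duplicate (cell_id, time_min) at line {row}")
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(dtype=float)
        out.append(CellTrajectory(cell_id=str(cid), times=t,
                                  values=grp["fluorescence_au"].to_numpy(dtype=float),
                                  birth_time_min=float(t[0]), end_time_min=float(t[-1])))
    return out


def write_trajectories(trajectories: list[CellTrajectory], path: str | Path) -> None:
    rows = {
        "cell_id": np.concatenate([[t.cell_id] * len(t.times) for t in trajectories]),
        "time_min": np.concatenate([t.times for t in trajectories]),
        "fluorescence_au": np.concatenate([t.values for t in trajectories]),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_study(study: StudyDataset, out_dir: str | Path) -> None:
    """Write trajectories.csv, features.csv, lineage.csv, schedule.json
    and, when present, truth_params.csv + population.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trajectories(study.trajectories, out / "trajectories.csv")
    study.features.to_csv(out / "features.csv", float_format=FLOAT_FMT)
    study.lineage.to_csv(out / "lineage.csv", index=False, float_format=FLOAT_FMT)
    if study.schedule is not None:
        study.schedule.to_json(out / "schedule.json")
    if study.truth_params is not None:
        study.truth_params.to_csv(out / "truth_params.csv", float_format=FLOAT_FMT)
    if study.truth_population is not None:
        study.truth_population.to_json(out / "population.json")


def read_study(in_dir: str | Path) -> StudyDataset:
    ind = Path(in_dir)
    trajectories = read_trajectories(ind / "trajectories.csv")
    features = (pd.read_csv(ind / "features.csv", index_col="cell_id",
                             float_precision="round_trip")
                if (ind / "features.csv").exists() else
                pd.DataFrame(index=pd.Index([t.cell_id for t in trajectories],
                                            name="cell_id")))
    lineage = (pd.read_csv(ind / "lineage.csv", dtype={"daughter_id": str,
                                                       "mother_id": str},
                           float_precision="round_trip")
               if (ind / "lineage.csv").exists() else
               pd.DataFrame(columns=["daughter_id", "mother_id", "birth_time_min"]))
    schedule = (ShockSchedule.from_json(ind / "schedule.json")
                if (ind / "schedule.json").exists() else None)
    truth = (pd.read_csv(ind / "truth_params.csv", index_col="cell_id",
                          float_precision="round_trip")
             if (ind / "truth_params.csv").exists() else None)
    truth_pop = (PopulationModel.from_json(ind / "population.json")
                 if (ind / "population.json").exists() else None)
    if features.index.name is None:
        features.index.name = "cell_id"
    return StudyDataset(trajectories=trajectories, features=features, lineage=lineage,
                        schedule=schedule, truth_params=truth,
                        truth_population=truth_pop)


_KNOWN_KEYS = {
    "data_dir", "out_dir", "seed", "log_level", "qc", "saem", "naive", "map",
    "validate", "analysis", "stages", "generate",
}


@dataclass
class RunConfig:
    """Pipeline configuration (see examples/ and the CLI --config flag).

    ``stages`` selects which steps run; unknown top-level keys are
    rejected so typos fail fast.
    """

    data_dir: str | None = None
    out_dir: str = "mecell_out"
    seed: int = 0
    log_level: str = "INFO"
    generate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=lambda: {"min_hours": 5.0,
                                              "newborn_discard_hours": 2.0})
    saem: dict = field(default_factory=dict)
    naive: dict = field(default_factory=dict)
    map: dict = field(default_factory=dict)
    validate: dict = field(default_factory=lambda: {"n_virtual": 2000})
    analysis: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: ["qc", "saem", "map",
                                                       "validate", "analyze"])

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise FileNotFoundError(f"data_dir does not exist: {self.data_dir}")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages end to end.

    simulate/load → qc → fit (naive and/or SAEM) → map → validate →
    analyze.  Every artifact directory gets a ``run_info.json`` stamp
    with the config hash and seed; identical config+seed produces
    identical artifacts.
    """
    from .synthetic import StudyConfig, generate_study, apply_qc_filters
    from .naive import fit_study_naive
    from .saem import SAEMConfig, fit_saem
    from .individual import fit_map_study
    from .validation import predict_population, envelope_coverage, predict_cells, fit_error
    from .analysis import correlate_features, pca_rank, inheritance_test

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    artifacts: dict = {}

    if config.data_dir is not None:
        study = read_study(config.data_dir)
    else:
        gen_seed = int(rng.integers(0, 2**31 - 1))
        study = generate_study(StudyConfig(**config.generate), rng=gen_seed)
        write_study(study, out / "simulated")
        artifacts["simulated"] = str(out / "simulated")
    if study.schedule is None:
        raise ValueError("study has no shock schedule; cannot build the input signal")
    from .input_model import build_input
    input_signal = build_input(study.schedule)

    if "qc" in config.stages:
        study = apply_qc_filters(study, **config.qc)

    pop = None
    if "naive" in config.stages:
        naive_res = fit_study_naive(study, input_signal,
                                    rng=int(rng.integers(0, 2**31 - 1)),
                                    **config.naive)
        rows = [{"cell_id": cid, **dict(zip(("k_m", "g_m", "k_p", "g_p"),
                                            f.params.as_array())),
                 "k_mp": f.params.k_mp, "loglik": f.loglik, "converged": f.converged}
                for cid, f in naive_res.per_cell.items()]
        pd.DataFrame(rows).to_csv(out / "individual_params.csv", index=False,
                                  float_format=FLOAT_FMT)
        naive_res.pooled.to_json(out / "population_naive.json")
        artifacts["naive"] = str(out / "population_naive.json")
        pop = naive_res.pooled
    if "saem" in config.stages:
        saem_cfg = SAEMConfig(seed=int(rng.integers(0, 2**31 - 1)), **config.saem)
        pop, trace = fit_saem(study, input_signal, saem_cfg)
        pop.to_json(out / "population.json")
        pd.DataFrame({k: v for k, v in trace.scalars().items()}).to_csv(
            out / "trace.csv", index=False, float_format=FLOAT_FMT)
        artifacts["saem"] = str(out / "population.json")
    if pop is None and any(s in config.stages for s in ("map", "validate", "analyze")):
        raise ValueError("map/validate/analyze stages need a fitted population "
                         "(enable 'saem' or 'naive')")

    estimates = None
    if "map" in config.stages:
        estimates = fit_map_study(study, pop, input_signal,
                                  rng=int(rng.integers(0, 2**31 - 1)))
        rows = [{"cell_id": e.cell_id,
                 **dict(zip(("k_m", "g_m", "k_p", "g_p"), e.map_params.as_array())),
                 "k_mp": e.map_params.k_mp, "log_posterior": e.log_posterior,
                 "converged": e.converged} for e in estimates]
        pd.DataFrame(rows).to_csv(out / "map_params.csv", index=False,
                                  float_format=FLOAT_FMT)
        artifacts["map"] = str(out / "map_params.csv")

    if "validate" in config.stages:
        env = predict_population(pop, study.schedule,
                                 n=config.validate.get("n_virtual", 2000),
                                 rng=int(rng.integers(0, 2**31 - 1)), with_noise=True)
        pd.DataFrame({"time": env.times, "median": env.median,
                      "q2.5": env.lower, "q97.5": env.upper}).to_csv(
            out / "envelope.csv", index=False, float_format=FLOAT_FMT)
        report = {"coverage": envelope_coverage(study, env)}
        if estimates is not None:
            Z = np.array([e.map_params.log_array() for e in estimates])
            preds = predict_cells(study, Z, input_signal, pop.tau_min)
            report["map_fit_error_pct"] = fit_error(study, preds)
        (out / "validation.json").write_text(json.dumps(report, indent=1))
        artifacts["validation"] = report

    if "analyze" in config.stages and estimates is not None:
        Z = np.array([e.map_params.log_array() for e in estimates])
        log_params = pd.DataFrame(
            Z, index=pd.Index([e.cell_id for e in estimates], name="cell_id"),
            columns=["ln_k_m", "ln_g_m", "ln_k_p", "ln_g_p"])
        log_params["ln_k_mp"] = log_params["ln_k_m"] + log_params["ln_k_p"]
        rho, pval = correlate_features(log_params, study.features)
        summary = pca_rank(log_params[["ln_k_mp", "ln_g_m", "ln_g_p"]], study.features)
        report = {
            "spearman_rho": rho.to_dict(), "spearman_p": pval.to_dict(),
            "pca_variance_fractions": summary.variance_fractions.tolist(),
            "feature_scores": summary.feature_scores.to_dict(),
        }
        n_md = len(study.lineage)
        if n_md >= config.analysis.get("n_pairs", 40):
            inh = inheritance_test(
                np.exp(log_params[["ln_k_mp", "ln_g_m", "ln_g_p"]]
                       ).rename(columns=lambda c: c[3:]),
                study.lineage, n_pairs=config.analysis.get("n_pairs", 40),
                n_boot=config.analysis.get("n_boot", 5000),
                rng=int(rng.integers(0, 2**31 - 1)))
            report["inheritance"] = inh.per_parameter.to_dict()
        (out / "analysis_report.json").write_text(json.dumps(report, indent=1))
        artifacts["analysis"] = str(out / "analysis_report.json")

    (out / "run_info.json").write_text(json.dumps(
        {"config_hash": config.digest(), "seed": config.seed}, indent=1))
    return artifacts
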