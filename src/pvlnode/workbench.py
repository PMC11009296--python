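"""Pipeline orchestration: configuration, manifests and stage runners.

The four pipeline quadrants — dataset generation, surrogate training,
sensitivity analysis, calibration — are exposed as stage functions that
read/write a shared output directory.  Every stage writes a
``<stage>_manifest.json`` with the configuration hash, seeds and artifact
checksums, and chains to the manifest of the stage it consumed, so a whole
run is reproducible from one seed.  Re-running a stage with unchanged
inputs is a no-op unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import build_error_model, run_test_case
from .cardio0d import default_space, generate_dataset, reduced_space
from .gsa import gsa_pipeline
from .lnode import SurrogateConfig, load_surrogate, save_surrogate
from .parameters import ParameterVector
from .traces import load_dataset, save_dataset, save_dataset_hdf5
from .training import TrainingConfig, evaluate, train

__all__ = [
    "PipelineConfig", "RunManifest", "load_config",
    "cli_simulate", "cli_train", "cli_eval", "cli_gsa", "cli_calibrate",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A configuration section failed schema validation."""


def _build_section(cls, section: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    bad = set(section) - valid
    if bad:
        raise ConfigError(f"unknown field(s) {sorted(bad)} in config section {name!r}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid config section {name!r}: {e}") from e


@dataclass(frozen=True)
class SimulatorSection:
    space: str = "default"          # "default" (12 analogs) or "reduced" (8)
    n: int = 405
    n_train: int = 400
    n_beats: int = 5
    samples_per_beat: int = 200

    def resolve_space(self):
        if self.space == "default":
            return default_space()
        if self.space == "reduced":
            return reduced_space()
        raise ConfigError(f"unknown space {self.space!r} in section 'simulator'")


@dataclass(frozen=True)
class GsaSection:
    n_base: int = 1024
    second_order: bool = False
    n_bootstrap: int = 200


@dataclass(frozen=True)
class CalibrationSection:
    case: str = "T_LV"
    source: str = "simulator"
    error_mode: str = "homoscedastic"
    n_restarts: int = 4
    n_chains: int = 2
    n_warmup: int = 500
    n_samples: int = 500


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the whole pipeline."""

    simulator: SimulatorSection = field(default_factory=SimulatorSection)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    gsa: GsaSection = field(default_factory=GsaSection)
    calibration: CalibrationSection = field(default_factory=CalibrationSection)
    seed: int = 0
    units: dict = field(default_factory=lambda: {
        "pressure": "mmHg", "volume": "mL", "time": "s"})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown top-level config field(s) {sorted(bad)}")
        sections = {
            "simulator": SimulatorSection, "surrogate": SurrogateConfig,
            "training": TrainingConfig, "gsa": GsaSection,
            "calibration": CalibrationSection,
        }
        kwargs = {}
        for key, sect_cls in sections.items():
            if key in d:
                kwargs[key] = _build_section(sect_cls, d.pop(key), key)
        kwargs.update(d)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Named per-stage substream of the global seed (below 2^31)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a JSON (or YAML) pipeline config; None gives the defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return PipelineConfig.from_dict(data or {})


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for p in sorted(path.rglob("*")):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written by every stage run."""

    stage: str
    config_hash: str
    seed: int
    version: str
    timestamp: str
    artifacts: dict[str, str]
    upstream: dict[str, str] = field(default_factory=dict)

    def save(self, out: Path) -> Path:
        p = out / f"{self.stage}_manifest.json"
        p.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return p

    @classmethod
    def load(cls, out: Path, stage: str) -> "RunManifest | None":
        p = out / f"{stage}_manifest.json"
        if not p.exists():
            return None
        return cls(**json.loads(p.read_text()))


def _write_manifest(stage, cfg, out: Path, artifacts: list[Path],
                    upstream: dict[str, str] | None = None) -> RunManifest:
    man = RunManifest(
        stage=stage, config_hash=cfg.hash(), seed=cfg.seed, version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        artifacts={p.name: _checksum(p) for p in artifacts},
        upstream=upstream or {},
    )
    man.save(out)
    return man


def _fresh(stage: str, cfg: PipelineConfig, out: Path, force: bool) -> bool:
    """True if the stage's previous outputs can be reused."""
    if force:
        return False
    man = RunManifest.load(out, stage)
    if man is None or man.config_hash != cfg.hash():
        return False
    for name, want in man.artifacts.items():
        p = out / name
        if not p.exists() or _checksum(p) != want:
            return False
    logger.info("%s: outputs up to date (use force to re-run)", stage)
    return True


def _require(stage: str, out: Path, producer: str) -> RunManifest:
    man = RunManifest.load(out, stage)
    if man is None:
        raise FileNotFoundError(
            f"missing upstream artifacts for stage {stage!r}; run "
            f"`pvlnode {producer}` first"
        )
    for name, want in man.artifacts.items():
        if _checksum(out / name) != want:
            raise RuntimeError(
                f"artifact {name} changed since `pvlnode {producer}` wrote it; "
                f"re-run `pvlnode {producer}` (or pass force)"
            )
    return man


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def cli_simulate(cfg: PipelineConfig, out: str | Path, force: bool = False) -> Path:
    """Generate the simulation database (CSV directory + HDF5 bundle)."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    if _fresh("simulate", cfg, out, force):
        return out / "dataset"
    sim = cfg.simulator
    ds = generate_dataset(
        sim.resolve_space(), n=sim.n, n_beats=sim.n_beats,
        seed=cfg.stage_seed("simulate"), samples_per_beat=sim.samples_per_beat,
    )
    ds.provenance["train_test_split"] = [sim.n_train, sim.n - sim.n_train]
    save_dataset(ds, out / "dataset")
    save_dataset_hdf5(ds, out / "dataset.h5")
    _write_manifest("simulate", cfg, out, [out / "dataset", out / "dataset.h5"])
    return out / "dataset"


def cli_train(cfg: PipelineConfig, out: str | Path, force: bool = False) -> Path:
    """Train the surrogate on the simulated database."""
    out = Path(out)
    if _fresh("train", cfg, out, force):
        return out / "model.h5"
    up = _require("simulate", out, "simulate")
    ds = load_dataset(out / "dataset")
    train_ds, test_ds = ds.split(cfg.simulator.n_train)
    tcfg = dataclasses.replace(cfg.training, seed=cfg.stage_seed("train"))
    model, report = train(train_ds, test_ds, tcfg, cfg.surrogate)
    model.meta["z0_mean"] = train_ds.trace_array()[:, 0, :].mean(axis=0).tolist()
    save_surrogate(model, out / "model.h5")
    report.save(out / "fit_report.json")
    _write_manifest("train", cfg, out,
                    [out / "model.h5", out / "fit_report.json"],
                    {"simulate": up.config_hash})
    return out / "model.h5"


def cli_eval(cfg: PipelineConfig, out: str | Path, force: bool = False) -> Path:
    """Per-channel NRMSE / R^2 table of the trained surrogate on held-out data."""
    out = Path(out)
    if _fresh("eval", cfg, out, force):
        return out / "metrics.csv"
    up = _require("train", out, "train")
    model = load_surrogate(out / "model.h5")
    ds = load_dataset(out / "dataset")
    _, test_ds = ds.split(cfg.simulator.n_train)
    nrmse, r2 = evaluate(model, test_ds)
    import pandas as pd

    tab = pd.DataFrame({"channel": list(nrmse), "NRMSE": list(nrmse.values()),
                        "R2": [r2[c] for c in nrmse]})
    tab.to_csv(out / "metrics.csv", index=False)
    _write_manifest("eval", cfg, out, [out / "metrics.csv"],
                    {"train": up.config_hash})
    return out / "metrics.csv"


def cli_gsa(cfg: PipelineConfig, out: str | Path, force: bool = False) -> Path:
    """Sobol sensitivity analysis on the trained surrogate."""
    out = Path(out)
    if _fresh("gsa", cfg, out, force):
        return out / "sobol.csv"
    up = _require("train", out, "train")
    model = load_surrogate(out / "model.h5")
    g = cfg.gsa
    ix = gsa_pipeline(model, n_base=g.n_base, second_order=g.second_order,
                      seed=cfg.stage_seed("gsa"), n_bootstrap=g.n_bootstrap)
    ix.to_frame().to_csv(out / "sobol.csv", index=False)
    P = len(model.space)
    n_rows = g.n_base * (2 * P + 2 if g.second_order else P + 2)
    (out / "sobol_summary.json").write_text(json.dumps({
        "n_base": g.n_base, "n_parameters": P, "second_order": g.second_order,
        "design_rows": n_rows,
        "relevant_threshold": 0.1,
        "max_ST_per_parameter": {p: float(v) for p, v in zip(
            ix.parameter_names, np.nanmax(ix.ST, axis=0))},
    }, indent=2))
    _write_manifest("gsa", cfg, out,
                    [out / "sobol.csv", out / "sobol_summary.json"],
                    {"train": up.config_hash})
    return out / "sobol.csv"


def cli_calibrate(cfg: PipelineConfig, out: str | Path, force: bool = False,
                  case: str | None = None) -> Path:
    """MAP + NUTS calibration for one named in-silico test case."""
    out = Path(out)
    case = case or cfg.calibration.case
    stage = f"calibrate_{case}"
    if _fresh(stage, cfg, out, force):
        return out / f"calibration_{case}.csv"
    up = _require("train", out, "train")
    model = load_surrogate(out / "model.h5")
    ds = load_dataset(out / "dataset")
    _, test_ds = ds.split(cfg.simulator.n_train)
    cal = cfg.calibration
    err = build_error_model(model, test_ds, mode=cal.error_mode)
    rng = np.random.default_rng(cfg.stage_seed("calibrate"))
    truth_vals = model.space.from_unit(rng.uniform(-0.5, 0.5, len(model.space)))
    truth = ParameterVector(model.space, truth_vals)
    report = run_test_case(
        case, truth, model, err, seed=cfg.stage_seed("calibrate"),
        source=cal.source, n_restarts=cal.n_restarts, n_chains=cal.n_chains,
        n_warmup=cal.n_warmup, n_samples=cal.n_samples,
    )
    report.save(out / f"calibration_{case}")
    report.pairwise_draws().to_csv(out / f"calibration_{case}_draws.csv",
                                   index=False)
    _write_manifest(stage, cfg, out,
                    [out / f"calibration_{case}.csv",
                     out / f"calibration_{case}_draws.csv"],
                    {"train": up.config_hash})
    return out / f"calibration_{case}.csv"
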