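"""Delimited-text I/O, configuration, and the reproducible pipeline driver.

File dialect (shared by every reader/writer): comma-delimited UTF-8 text,
``.`` decimal separator, ``#`` comment lines, one header row whose column
names carry SI unit suffixes (``voltage_V,current_A``; ``time_s,current_A``;
``time_s,delta_f_Hz[,delta_D_1e6]``; ``conc_M,response_pct``).  Files store
SI base units; nm/nA/mV appear only in human-readable reports.  Write->read
round-trips are lossless at float64 precision; unknown extra columns are
preserved in the object's ``metadata``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import AptaporeError, FormatError, PreconditionError
from .iv import (CalibrationSeries, IVCurve, TimeTrace, build_calibration,
                 limit_of_detection, rectification_coefficient,
                 sensor_response)
from .qcmd import QcmdTrace, SauerbreyParams, extract_step, film_rigidity, \
    layer_height_change

__all__ = [
    "read_iv_csv", "write_iv_csv",
    "read_timetrace_csv", "write_timetrace_csv",
    "read_qcmd_csv", "write_qcmd_csv",
    "read_responses_csv", "write_responses_csv",
    "read_calibration_csv", "write_calibration_csv",
    "RunConfig", "load_config", "run_pipeline",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def _read_table(path, required: tuple, optional: tuple = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", sep=",", float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse as the expected CSV dialect: {exc}")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}' "
                              f"(found {list(df.columns)})")
    for col in required + tuple(c for c in optional if c in df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(f"{path}: non-numeric value in column '{col}' "
                              f"at data row {int(bad[0])}")
        if vals.isna().any():
            raise FormatError(f"{path}: empty cell in column '{col}' "
                              f"at data row {int(vals.index[vals.isna()][0])}")
        df[col] = vals.astype(float)
    return df


def _extra_metadata(df: pd.DataFrame, known: tuple) -> dict:
    extra = [c for c in df.columns if c not in known]
    return {"extra_columns": {c: df[c].tolist() for c in extra}} if extra else {}


def _write_frame(df: pd.DataFrame, path, comments: list | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_iv_csv(path) -> IVCurve:
    df = _read_table(path, ("voltage_V", "current_A"))
    return IVCurve(df["voltage_V"].to_numpy(), df["current_A"].to_numpy(),
                   label=str(Path(path).stem),
                   metadata=_extra_metadata(df, ("voltage_V", "current_A")))


def write_iv_csv(curve: IVCurve, path, comments: list | None = None) -> None:
    _write_frame(pd.DataFrame({"voltage_V": curve.voltage,
                               "current_A": curve.current}), path, comments)


def read_timetrace_csv(path) -> TimeTrace:
    events = ()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("# events_s:"):
            txt = line.split(":", 1)[1].strip()
            events = tuple(float(x) for x in txt.split(",")) if txt else ()
    df = _read_table(path, ("time_s", "current_A"))
    return TimeTrace(df["time_s"].to_numpy(), df["current_A"].to_numpy(),
                     events=events, label=str(Path(path).stem),
                     metadata=_extra_metadata(df, ("time_s", "current_A")))


def write_timetrace_csv(trace: TimeTrace, path) -> None:
    comments = []
    if trace.events:
        comments.append("events_s: " + ",".join(f"{e:.17g}" for e in trace.events))
    _write_frame(pd.DataFrame({"time_s": trace.time,
                               "current_A": trace.current}), path, comments)


def read_qcmd_csv(path) -> QcmdTrace:
    df = _read_table(path, ("time_s", "delta_f_Hz"), optional=("delta_D_1e6",))
    dD = df["delta_D_1e6"].to_numpy() if "delta_D_1e6" in df.columns else None
    return QcmdTrace(df["time_s"].to_numpy(), df["delta_f_Hz"].to_numpy(),
                     delta_D=dD, label=str(Path(path).stem),
                     metadata=_extra_metadata(
                         df, ("time_s", "delta_f_Hz", "delta_D_1e6")))


def write_qcmd_csv(trace: QcmdTrace, path) -> None:
    data = {"time_s": trace.time, "delta_f_Hz": trace.delta_f}
    if trace.delta_D is not None:
        data["delta_D_1e6"] = trace.delta_D
    _write_frame(pd.DataFrame(data), path)


def read_responses_csv(path) -> dict:
    """Raw replicate responses: one (conc_M, response_pct) row per replicate."""
    df = _read_table(path, ("conc_M", "response_pct"))
    out: dict = {}
    for c, r in zip(df["conc_M"], df["response_pct"]):
        out.setdefault(float(c), []).append(float(r))
    return out


def write_responses_csv(responses: dict, path) -> None:
    rows = [(c, r) for c in sorted(responses) for r in responses[c]]
    _write_frame(pd.DataFrame(rows, columns=["conc_M", "response_pct"]), path)


def read_calibration_csv(path) -> CalibrationSeries:
    df = _read_table(path, ("conc_M", "mean_pct", "sd_pct", "n"))
    return CalibrationSeries(df["conc_M"].to_numpy(), df["mean_pct"].to_numpy(),
                             df["sd_pct"].to_numpy(),
                             df["n"].to_numpy().astype(int),
                             label=str(Path(path).stem))


def write_calibration_csv(cal: CalibrationSeries, path) -> None:
    _write_frame(pd.DataFrame({
        "conc_M": cal.concentration, "mean_pct": cal.mean_response,
        "sd_pct": cal.sd_response, "n": cal.n_replicates}), path)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Declarative description of one analysis run.

    ``stages`` selects among ``iv``, ``qcmd``, ``analytic``, ``synth`` and
    ``pnp``; ``params`` carries per-stage inputs and overrides (paths,
    v_eval, Sauerbrey constants, electrolyte preset, solver tolerances).
    """

    stages: list = field(default_factory=list)
    params: dict = field(default_factory=dict)
    output_dir: str = "aptapore_out"
    seed: int = 0
    v_eval: float = 0.5
    verbose: bool = False

    def canonical_hash(self) -> str:
        blob = json.dumps(
            {"stages": self.stages, "params": self.params, "seed": self.seed,
             "v_eval": self.v_eval}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {"stages", "params", "output_dir", "seed", "v_eval", "verbose"}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def _stage_iv(cfg: RunConfig, p: dict, outdir: Path) -> dict:
    out: dict = {}
    v_eval = float(p.get("v_eval", cfg.v_eval))
    if "iv_path" in p:
        curve = read_iv_csv(p["iv_path"])
        out["rectification_coefficient"] = rectification_coefficient(curve, v_eval)
    if "baseline_path" in p and "target_path" in p:
        base = read_iv_csv(p["baseline_path"])
        tgt = read_iv_csv(p["target_path"])
        out["response_pct"] = sensor_response(base, tgt, v_eval)
    if "responses_path" in p:
        cal = build_calibration(read_responses_csv(p["responses_path"]))
        write_calibration_csv(cal, outdir / "calibration.csv")
        lod = limit_of_detection(cal)
        out["lod_M"] = lod if lod is None else float(lod)
    return out


def _stage_qcmd(cfg: RunConfig, p: dict, outdir: Path) -> dict:
    trace = read_qcmd_csv(p["trace_path"])
    params = SauerbreyParams(
        mass_sensitivity_C=float(p.get("mass_sensitivity_C", 17.7)),
        layer_density=float(p.get("layer_density", 1.02)))
    step = extract_step(trace, tuple(p["pre_window"]), tuple(p["post_window"]))
    out = {"step_Hz": step, "height_nm": layer_height_change(step, params)}
    if trace.delta_D is not None and step < 0:
        d_step = extract_step(trace, tuple(p["pre_window"]),
                              tuple(p["post_window"]), channel="delta_D")
        out["rigidity"] = film_rigidity(step, d_step)
    return out


def _stage_analytic(cfg: RunConfig, p: dict, outdir: Path) -> dict:
    from . import electrokinetics as ek
    preset = p.get("electrolyte", "PBS_1x")
    if preset != "PBS_1x":
        raise PreconditionError(f"unknown electrolyte preset '{preset}'")
    comp = ek.PBS_1X
    ionic = ek.ionic_strength(comp)
    from .pnp.model import binary_electrolyte
    species = binary_electrolyte(ionic * 1e3)
    return {
        "ionic_strength_M": ionic,
        "debye_length_nm": ek.debye_length(ionic),
        "bulk_conductivity_S_per_m": ek.bulk_conductivity(species),
    }


def _stage_synth(cfg: RunConfig, p: dict, outdir: Path) -> dict:
    from .synth import gen_iv
    curve = gen_iv(r_true=float(p.get("r_true", -0.5)),
                   R_true=float(p.get("R_true", 367e6)),
                   noise_sd=float(p.get("noise_sd", 0.0)),
                   n_points=int(p.get("n_points", 101)), seed=cfg.seed)
    path = outdir / "synthetic_iv.csv"
    write_iv_csv(curve, path)
    return {"synthetic_iv_path": str(path)}


def _stage_pnp(cfg: RunConfig, p: dict, outdir: Path) -> dict:
    from .pnp import (AptamerLayer, MeshOptions, PoreGeometry, SolverOptions,
                      binary_electrolyte, simulate_iv)
    geom = PoreGeometry(tip_radius=float(p.get("tip_radius", 4.6e-9)),
                        half_cone_angle=float(p.get("half_cone_angle", 0.13)),
                        taper_length=float(p.get("taper_length", 5e-6)))
    layer = None
    if "layer" in p:
        layer = AptamerLayer(**{k: float(v) for k, v in p["layer"].items()})
    species = binary_electrolyte(float(p.get("concentration_mol_m3", 171.5)))
    mesh = MeshOptions(n_r=int(p.get("n_r", 90)), n_theta=int(p.get("n_theta", 36)))
    opts = SolverOptions(mesh=mesh)
    voltages = p.get("voltages", [-0.5, -0.25, 0.0, 0.25, 0.5])
    curve = simulate_iv(geom, layer, species, voltages, options=opts)
    path = outdir / "pnp_iv.csv"
    write_iv_csv(curve, path)
    out = {"pnp_iv_path": str(path)}
    v_eval = float(p.get("v_eval", cfg.v_eval))
    if min(curve.voltage) <= -v_eval and max(curve.voltage) >= v_eval:
        out["rectification_coefficient"] = rectification_coefficient(curve, v_eval)
    return out


_STAGES = {"iv": _stage_iv, "qcmd": _stage_qcmd, "analytic": _stage_analytic,
           "synth": _stage_synth, "pnp": _stage_pnp}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the result bundle.

    A ``summary.json`` with a provenance block (config hash, seed, package
    version) is always written to ``config.output_dir``; a stage failure is
    recorded under ``failures`` and re-raised after partial results are
    persisted.
    """
    from . import __version__
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in config.stages if s not in _STAGES]
    if unknown:
        raise PreconditionError(f"unknown stages {unknown}; "
                                f"choose from {sorted(_STAGES)}")
    if not config.stages:
        warnings.warn("no stages requested; writing provenance only")
    bundle: dict = {"results": {}, "failures": {}, "provenance": {
        "package": "aptapore", "version": __version__,
        "config_hash": config.canonical_hash(), "seed": config.seed}}
    error: Exception | None = None
    for stage in config.stages:
        try:
            bundle["results"][stage] = _STAGES[stage](
                config, dict(config.params.get(stage, {})), outdir)
        except (AptaporeError, FileNotFoundError, KeyError) as exc:
            bundle["failures"][stage] = f"{type(exc).__name__}: {exc}"
            error = error or exc
    (outdir / "summary.json").write_text(
        json.dumps(bundle, indent=2, default=str) + "\n", encoding="utf-8")
    if error is not None:
        raise AptaporeError(
            f"stage failures: {bundle['failures']}; partial outputs in {outdir}"
        ) from error
    return bundle
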