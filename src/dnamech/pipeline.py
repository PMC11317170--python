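"""Validated analysis configuration and pipeline orchestration.

A run is described by one YAML/dict config validated against a strict
pydantic schema (unknown keys are rejected before any computation).
``run_pipeline`` executes the requested stages in dependency order —
simulate first, then curve fits, stiffness, ΔL extraction, isotherm,
kinetics and AFM — writing one JSON result per stage.  Every result
embeds the config hash and the seed, and reruns with identical config
produce byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import io as dio
from .afm_stats import ContourSample, compare_samples, contour_length
from .constants import ThermalConstants
from .equilibrium_binding import delta_length_curve, fit_isotherm
from .errors import DnamechError, FormatError
from .fec_model import EmpiricalParams, fit_empirical
from .perturbation_kinetics import (
    RatePoint,
    decompose_rates,
    fit_bell,
    fit_monoexponential,
    segment_trace,
)
from .polymer_models import PolymerParams, fit_polymer
from .stiffness import smooth_force, stiffness_curve, stiffness_peak
from .synthetic_data import (
    SimulationConfig,
    gen_afm_sample,
    gen_fec_empirical,
    gen_fec_mechanistic,
    gen_fec_polymer,
)

log = logging.getLogger("dnamech")

__version__ = "0.1.0"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateStage(_Strict):
    kind: Literal["fec_empirical", "fec_mechanistic", "fec_polymer",
                  "afm_sample"]
    out: str = "simulated.tsv"
    params: dict = {}


class FitFecStage(_Strict):
    input: str


class FitPolymerStage(_Strict):
    input: str
    model: Literal["wlc", "ewlc"] = "ewlc"
    window: Tuple[float, float] = (0.0, 20.0)


class StiffnessStage(_Strict):
    input: str
    window: int = 21
    order: int = 3
    raw: bool = False
    search_window: Optional[Tuple[float, float]] = None


class DeltaLStage(_Strict):
    treated: str
    control: str
    grid: Optional[List[float]] = None


class IsothermStage(_Strict):
    input: str  # ΔL table path, or "delta_l" for the previous stage output


class KineticsStage(_Strict):
    inputs: List[str]
    settle: Optional[float] = None


class AfmStage(_Strict):
    control: List[str]
    treated: List[str]


class AnalysisConfig(_Strict):
    """Schema of one pipeline run; unknown keys are rejected."""

    seed: int = 0
    kbt: float = 4.114
    out_dir: str = "results"
    format: Literal["tsv", "csv"] = "tsv"
    simulate: Optional[SimulateStage] = None
    fit_fec: Optional[FitFecStage] = None
    fit_polymer: Optional[FitPolymerStage] = None
    stiffness: Optional[StiffnessStage] = None
    delta_l: Optional[DeltaLStage] = None
    isotherm: Optional[IsothermStage] = None
    kinetics: Optional[KineticsStage] = None
    afm: Optional[AfmStage] = None


def load_config(path) -> AnalysisConfig:
    """Read and validate a YAML config; schema errors are FormatErrors."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        return AnalysisConfig.model_validate(raw)
    except Exception as err:  # pydantic ValidationError
        raise FormatError(f"invalid config {path}: {err}") from err


def config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _simulate(stage: SimulateStage, cfg, out_dir, fmt):
    params = dict(stage.params)
    sim = SimulationConfig(
        seed=cfg.seed,
        force_noise_sd=float(params.pop("force_noise_sd", 0.37)),
        length_noise_sd=float(params.pop("length_noise_sd", 0.005)),
    )
    out_path = out_dir / stage.out
    manifest = {"kind": stage.kind, "seed": cfg.seed, "params": stage.params}
    if stage.kind == "fec_empirical":
        p = EmpiricalParams(**{k.lower(): float(v)
                               for k, v in params.pop("empirical").items()})
        fec = gen_fec_empirical(p, sim, **params)
        dio.write_fec(fec, out_path, fmt)
    elif stage.kind == "fec_mechanistic":
        fec = gen_fec_mechanistic(cfg=sim, **params)
        dio.write_fec(fec, out_path, fmt)
    elif stage.kind == "fec_polymer":
        poly = PolymerParams(**params.pop("polymer"))
        fec = gen_fec_polymer(poly, sim, **params)
        dio.write_fec(fec, out_path, fmt)
    else:  # afm_sample
        sample = gen_afm_sample(cfg=sim, **params)
        np.savetxt(out_path, np.column_stack(
            [sample.contour_lengths, sample.end_to_end]),
            delimiter="\t", header="contour_nm\tend_to_end_nm", comments="")
    manifest["out"] = str(out_path)
    return manifest


def run_pipeline(config: AnalysisConfig, base_dir=".") -> dict:
    """Execute the configured stages; one JSON result file per stage.

    Returns the bundle of per-stage results.  A failed stage is recorded
    with its error and its dependents are skipped; independent stages
    still run.
    """
    base = Path(base_dir)
    out_dir = base / config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    c = ThermalConstants(kbt=config.kbt)
    fmt = config.format
    bundle: dict = {}
    failed: set = set()

    def record(stage_name, payload):
        payload = {"config_hash": chash, "seed": config.seed, **payload}
        bundle[stage_name] = payload
        dio.write_json(payload, out_dir / f"{stage_name}.json")
        log.info("stage %s done", stage_name)

    def guarded(stage_name, deps, fn):
        if getattr(config, stage_name) is None:
            return
        if failed & set(deps):
            record(stage_name, {"error": f"skipped: dependency failed "
                                         f"({sorted(failed & set(deps))})"})
            failed.add(stage_name)
            return
        try:
            record(stage_name, fn())
        except (DnamechError, OSError) as err:
            log.error("stage %s failed: %s", stage_name, err)
            record(stage_name, {"error": str(err)})
            failed.add(stage_name)

    def resolve(path_str):
        p = Path(path_str)
        for candidate in (p, base / p, out_dir / p):
            if candidate.exists():
                return candidate
        raise FormatError(f"input not found: {path_str}")

    guarded("simulate", (), lambda: _simulate(
        config.simulate, config, out_dir, fmt))

    def do_fit_fec():
        fec = dio.read_fec(resolve(config.fit_fec.input))
        params, diag = fit_empirical(fec)
        return {**params.as_dict(), "residual_sd": diag.residual_sd,
                "metadata": {"tmpyp_nM": fec.tmpyp, "nacl_M": fec.nacl,
                             "pulling_rate_um_s": fec.pulling_rate,
                             "direction": fec.direction, "label": fec.label}}

    guarded("fit_fec", ("simulate",), do_fit_fec)

    def do_fit_polymer():
        fec = dio.read_fec(resolve(config.fit_polymer.input))
        result = fit_polymer(fec, model=config.fit_polymer.model,
                             force_window=tuple(config.fit_polymer.window),
                             c=c)
        return result.as_dict()

    guarded("fit_polymer", ("simulate",), do_fit_polymer)

    def do_stiffness():
        fec = dio.read_fec(resolve(config.stiffness.input))
        s = config.stiffness
        if not s.raw:
            fec = smooth_force(fec, window=s.window, order=s.order)
        sc = stiffness_curve(fec)
        dio.write_stiffness_table(sc, out_dir / "stiffness.tsv", "tsv")
        peak = stiffness_peak(sc, s.search_window)
        return {"peak_position_um": peak.position_um,
                "peak_stiffness_pN_per_um": peak.value_pn_per_um,
                "at_boundary": peak.at_boundary,
                "smoothing": ("raw" if s.raw
                              else f"savgol(window={s.window}, order={s.order})")}

    guarded("stiffness", ("simulate",), do_stiffness)

    def do_delta_l():
        treated = dio.read_fec(resolve(config.delta_l.treated))
        control = dio.read_fec(resolve(config.delta_l.control))
        dl = delta_length_curve(treated, control, config.delta_l.grid)
        dio.write_delta_l(dl, out_dir / "delta_l.tsv", "tsv")
        return {"tmpyp_nM": dl.tmpyp, "n_points": int(dl.force.size),
                "force_pN": dl.force.tolist(),
                "delta_L_um": dl.delta_l.tolist(),
                "out": str(out_dir / "delta_l.tsv")}

    guarded("delta_l", ("simulate",), do_delta_l)

    def do_isotherm():
        src = config.isotherm.input
        if src == "delta_l":
            if "delta_l" not in bundle or "error" in bundle["delta_l"]:
                raise FormatError("isotherm input 'delta_l' not available")
            path = bundle["delta_l"]["out"]
        else:
            path = resolve(src)
        dl = dio.read_delta_l(path)
        params, report = fit_isotherm(dl, c)
        return {"tmpyp_nM": dl.tmpyp, "dx_eq_nm": params.dx_eq_nm,
                "n_bp": params.n, "K0_per_M": params.k0_per_m,
                "delta_L_max_um": params.delta_l_max_um,
                "residual_sd_um": report.residual_sd,
                "flags": list(report.flags)}

    guarded("isotherm", ("delta_l",), do_isotherm)

    def do_kinetics():
        per_trace = []
        k0_by_conc = []
        for path in config.kinetics.inputs:
            tr = dio.read_kinetic_trace(resolve(path))
            windows = segment_trace(tr, settle=config.kinetics.settle)
            points = []
            phases = []
            for w in windows:
                t, L, F = w.select(tr)
                if t.size < 10:
                    continue
                fit = fit_monoexponential(t, L)
                phases.append({"label": w.label, "k_obs": fit.rate,
                               "amplitude_um": fit.amplitude,
                               "unreliable": fit.unreliable})
                if not fit.unreliable:
                    points.append(RatePoint(force=float(np.median(F)),
                                            k_obs=fit.rate, se=fit.se_rate))
            entry = {"input": str(path), "tmpyp_nM": tr.tmpyp,
                     "per_phase": phases}
            if len(points) >= 3:
                bell, _ = fit_bell(points, c)
                entry["bell"] = {"k0_per_s": bell.k0, "dx_nm": bell.dx_nm}
                k0_by_conc.append((tr.tmpyp, bell.k0))
            per_trace.append(entry)
        out = {"traces": per_trace}
        if len(k0_by_conc) >= 2:
            lin, diag = decompose_rates(k0_by_conc)
            out["linear"] = {"k_on_per_nM_s": lin.k_on,
                             "k_off_per_s": lin.k_off, **diag}
        return out

    guarded("kinetics", ("simulate",), do_kinetics)

    def do_afm():
        def build(paths, label):
            contours, e2e = [], []
            for p in paths:
                m = contour_length(dio.read_contour_trace(resolve(p)))
                contours.append(m.contour_nm)
                e2e.append(m.end_to_end_nm)
            return ContourSample(np.array(contours), np.array(e2e), label)

        a = build(config.afm.control, "control")
        b = build(config.afm.treated, "treated")
        cmpres = compare_samples(a, b)
        return {"mean_control_nm": cmpres.mean_a, "sd_control_nm": cmpres.sd_a,
                "mean_treated_nm": cmpres.mean_b, "sd_treated_nm": cmpres.sd_b,
                "mean_difference_nm": cmpres.mean_difference,
                "percent_change": cmpres.percent_change,
                "welch_t": cmpres.t, "welch_df": cmpres.df, "p_value": cmpres.p}

    guarded("afm", (), do_afm)

    dio.write_json({"version": __version__, "config_hash": chash,
                    "seed": config.seed,
                    "stages": sorted(bundle)}, out_dir / "run_log.json")
    return bundle
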