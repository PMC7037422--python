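"""End-to-end run orchestration: generate -> gate -> death -> fit -> synergy
-> growth -> pcr -> report.

Stages communicate only through files under the run's output directory
(tidy CSV, JSON, TIFF), so any stage can be re-run in isolation from its
on-disk inputs and reproduces its outputs bit-identically.  Every run is
driven by a schema-validated configuration (unknown keys rejected, all
violations enumerated) and a master seed; per-sample sub-seeds are
derived from documented counters, so the whole run is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .conditions import DOSE_GRID, NMType, SampleCondition
from .cytometry import (
    DEFAULT_LOW_FRACTION_IR,
    DEFAULT_LOW_FRACTION_NI,
    EventTable,
    apply_ssc_gate,
    classify_death,
    compute_ssc_threshold,
    derive_fluor_thresholds,
)
from .doseresponse import DoseResponseData, fit_ll4
from .expression import comparison_suite, fold_changes
from .imaging import build_growth_series, growth_inhibition, growth_table
from .synergy import synergy_call, synergy_heatmap
from .synthdata import (
    default_generative_params,
    simulate_events,
    simulate_growth_images,
    simulate_pcr,
)

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "gate", "death", "fit", "synergy", "growth", "pcr", "report")


class GatingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    low_fraction_ni: float = Field(DEFAULT_LOW_FRACTION_NI, gt=0, lt=1)
    low_fraction_ir: float = Field(DEFAULT_LOW_FRACTION_IR, gt=0, lt=1)


class CountingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    smooth_sigma: float = Field(2.0, gt=0)
    min_area: int = Field(20, ge=1)
    threshold_rule: str | float = "otsu"


class GrowthConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    days: list[int] = Field(default_factory=lambda: [0, 1, 2, 3])
    n_fields: int = Field(3, ge=1)
    image_size: int = Field(320, ge=64)


class PcrConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    doses: list[float] = Field(default_factory=lambda: [0.0, 16.0, 32.0])
    n_replicates: int = Field(3, ge=2)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    nm_types: list[str] = Field(default_factory=lambda: ["TiO2"])
    doses: list[float] = Field(default_factory=lambda: list(DOSE_GRID))
    timepoints_h: list[float] = Field(default_factory=lambda: [72.0])
    n_events: int = Field(5000, ge=100)
    n_replicates: int = Field(3, ge=1)
    synergy_coeff: float = Field(0.0, ge=0)
    distance_scaling: str = "unit"
    seed: int = 0
    outdir: str = "runs/out"
    gating: GatingConfig = Field(default_factory=GatingConfig)
    counting: CountingConfig = Field(default_factory=CountingConfig)
    growth: GrowthConfig = Field(default_factory=GrowthConfig)
    pcr: PcrConfig = Field(default_factory=PcrConfig)

    def model_post_init(self, __context) -> None:
        bad = [n for n in self.nm_types if n not in {m.value for m in NMType} - {"none"}]
        if bad:
            raise ValueError(f"unknown nm_types: {bad}")
        if any(d < 0 for d in self.doses):
            raise ValueError(f"doses must be >= 0, got {sorted(self.doses)}")
        if 0.0 not in self.doses:
            raise ValueError("dose grid must include the 0 control")


@dataclass
class RunReport:
    """Paths and summaries of a completed run, with a provenance hash."""

    outdir: Path
    outputs: dict[str, str]
    heatmap: pd.DataFrame | None
    summary: dict
    provenance_hash: str

    def to_json(self) -> dict:
        return {
            "outputs": self.outputs,
            "heatmap": None if self.heatmap is None else self.heatmap.to_dict(),
            "summary": self.summary,
            "provenance_hash": self.provenance_hash,
        }


def validate_config(raw: str | dict | Path) -> RunConfig:
    """Parse and validate a YAML/JSON config, enumerating every violation."""
    if isinstance(raw, Path) or (isinstance(raw, str) and "\n" not in raw
                                 and raw.endswith((".yaml", ".yml", ".json"))):
        raw = Path(raw).read_text()
    data = yaml.safe_load(raw) if isinstance(raw, str) else raw
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        msgs = [
            f"{'.'.join(str(p) for p in e['loc']) or '<root>'}: {e['msg']}"
            for e in err.errors()
        ]
        raise ValueError("invalid config:\n  " + "\n  ".join(msgs)) from err


# ---------------------------------------------------------------- stages

def _stable_hash(label: str) -> int:
    """Process-independent 31-bit hash of a condition label (for sub-seeds)."""
    return zlib.crc32(label.encode()) & 0x7FFFFFFF


def _conditions(cfg: RunConfig):
    for nm in cfg.nm_types:
        nm_t = NMType(nm)
        for t_h in cfg.timepoints_h:
            for irr in (False, True):
                for d in cfg.doses:
                    yield SampleCondition(
                        nm_type=nm_t if d > 0 else NMType.NONE,
                        dose_surface=d if d > 0 else 0.0,
                        irradiated=irr, timepoint_h=t_h,
                    ), nm_t


def _event_path(outdir: Path, nm: NMType, cond: SampleCondition, rep: int) -> Path:
    return outdir / "events" / f"{nm.value}_{cond.label}_rep{rep}.csv"


def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[str]:
    paths = []
    (outdir / "events").mkdir(parents=True, exist_ok=True)
    for cond, nm in _conditions(cfg):
        gp = default_generative_params(nm, cond.timepoint_h, cfg.synergy_coeff)
        for rep in range(cfg.n_replicates):
            sub = np.random.SeedSequence(
                [cfg.seed, _stable_hash(cond.label), rep]
            ).generate_state(1)[0] & 0x7FFFFFFF
            table = simulate_events(cond, gp, cfg.n_events, int(sub))
            p = _event_path(outdir, nm, cond, rep)
            table.to_csv(p)
            paths.append(str(p))
    return paths


def _load_events(cfg: RunConfig, outdir: Path, nm: NMType, cond: SampleCondition,
                 rep: int) -> EventTable:
    return EventTable.from_csv(_event_path(outdir, nm, cond, rep))


def _stage_gate(cfg: RunConfig, outdir: Path) -> str:
    rows = []
    for nm in cfg.nm_types:
        nm_t = NMType(nm)
        for t_h in cfg.timepoints_h:
            for irr in (False, True):
                ctrl_cond = SampleCondition(irradiated=irr, timepoint_h=t_h)
                ctrl = _load_events(cfg, outdir, nm_t, ctrl_cond, 0)
                target = (cfg.gating.low_fraction_ir if irr
                          else cfg.gating.low_fraction_ni)
                thr = compute_ssc_threshold(ctrl, target)
                for d in cfg.doses:
                    cond = SampleCondition(
                        nm_type=nm_t if d > 0 else NMType.NONE,
                        dose_surface=d if d > 0 else 0.0,
                        irradiated=irr, timepoint_h=t_h,
                    )
                    for rep in range(cfg.n_replicates):
                        sample = _load_events(cfg, outdir, nm_t, cond, rep)
                        g = apply_ssc_gate(sample, thr)
                        rows.append({
                            "nm_type": nm, "dose_surface": d, "irradiated": irr,
                            "timepoint_h": t_h, "replicate": rep,
                            "ssc_threshold": g.threshold,
                            "frac_low": g.frac_low, "frac_high": g.frac_high,
                        })
    path = outdir / "gating.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return str(path)


def _stage_death(cfg: RunConfig, outdir: Path) -> str:
    rows = []
    for nm in cfg.nm_types:
        nm_t = NMType(nm)
        for t_h in cfg.timepoints_h:
            # pool all samples of the timepoint so both live and dead
            # populations are represented for the valley rule
            pooled = []
            for irr in (False, True):
                for d in cfg.doses:
                    cond = SampleCondition(
                        nm_type=nm_t if d > 0 else NMType.NONE,
                        dose_surface=d if d > 0 else 0.0,
                        irradiated=irr, timepoint_h=t_h,
                    )
                    pooled.append(_load_events(cfg, outdir, nm_t, cond, 0).data)
            pool = EventTable("pooled", pd.concat(pooled, ignore_index=True))
            thr = derive_fluor_thresholds(pool)
            for irr in (False, True):
                for d in cfg.doses:
                    cond = SampleCondition(
                        nm_type=nm_t if d > 0 else NMType.NONE,
                        dose_surface=d if d > 0 else 0.0,
                        irradiated=irr, timepoint_h=t_h,
                    )
                    for rep in range(cfg.n_replicates):
                        sample = _load_events(cfg, outdir, nm_t, cond, rep)
                        f = classify_death(sample, thr.dioc, thr.pi)
                        rows.append({
                            "nm_type": nm, "dose_surface": d, "irradiated": irr,
                            "timepoint_h": t_h, "replicate": rep,
                            "live": f.live, "apoptotic": f.apoptotic,
                            "dead": f.dead, "mortality": f.mortality,
                            "dioc_threshold": thr.dioc, "pi_threshold": thr.pi,
                        })
    path = outdir / "death.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return str(path)


def _death_table(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "death.csv")


def _stage_fit(cfg: RunConfig, outdir: Path) -> str:
    death = _death_table(outdir)
    fits = []
    for (nm, t_h, irr), grp in death.groupby(["nm_type", "timepoint_h", "irradiated"]):
        data = DoseResponseData(grp["dose_surface"].to_numpy(),
                                grp["mortality"].to_numpy())
        fit = fit_ll4(data, seed=cfg.seed)
        fits.append({
            "nm_type": nm, "timepoint_h": t_h, "irradiated": bool(irr),
            "lower": fit.params.lower, "upper": fit.params.upper,
            "ed50": fit.params.ed50, "shape": fit.params.shape,
            "sse": fit.sse, "converged": fit.converged,
            "degenerate": fit.degenerate,
        })
    path = outdir / "fits.json"
    path.write_text(json.dumps(fits, indent=2))
    return str(path)


def _stage_synergy(cfg: RunConfig, outdir: Path) -> tuple[str, str]:
    death = _death_table(outdir)
    results = {}
    records = []
    for (nm, t_h), grp in death.groupby(["nm_type", "timepoint_h"]):
        ni = grp[~grp["irradiated"]]
        ir = grp[grp["irradiated"]]
        ni_data = DoseResponseData(ni["dose_surface"].to_numpy(),
                                   ni["mortality"].to_numpy())
        ir_data = DoseResponseData(ir["dose_surface"].to_numpy(),
                                   ir["mortality"].to_numpy())
        p_ni_ctrl = float(ni.loc[ni["dose_surface"] == 0, "mortality"].mean())
        p_ir_ctrl = float(ir.loc[ir["dose_surface"] == 0, "mortality"].mean())
        res = synergy_call(ir_data, ni_data, (p_ni_ctrl, p_ir_ctrl),
                           scaling=cfg.distance_scaling, fit_seed=cfg.seed)
        results[(str(nm), float(t_h))] = res
        records.append({
            "nm_type": nm, "timepoint_h": t_h, "q_ir": res.q_ir,
            "distance": res.distance, "sign": res.sign,
            "signed_score": res.signed_score,
            "per_dose_delta": res.per_dose_delta,
            "simulated_fit": vars(res.simulated_fit.params),
            "observed_fit": vars(res.observed_fit.params),
        })
    jpath = outdir / "synergy.json"
    jpath.write_text(json.dumps(records, indent=2, default=str))
    hm = synergy_heatmap(results)
    hpath = outdir / "synergy_heatmap.csv"
    hm.to_csv(hpath)
    return str(jpath), str(hpath)


def _stage_growth(cfg: RunConfig, outdir: Path) -> str:
    gdir = outdir / "growth_images"
    gdir.mkdir(parents=True, exist_ok=True)
    shape = (cfg.growth.image_size, cfg.growth.image_size)
    series = {}
    for nm in cfg.nm_types:
        nm_t = NMType(nm)
        for irr in (False, True):
            for d in cfg.doses:
                cond = SampleCondition(
                    nm_type=nm_t if d > 0 else NMType.NONE,
                    dose_surface=d if d > 0 else 0.0, irradiated=irr,
                )
                gp = default_generative_params(nm_t, 72.0, cfg.synergy_coeff)
                by_day = {}
                for day in cfg.growth.days:
                    imgs = simulate_growth_images(
                        cond, day, gp, n_fields=cfg.growth.n_fields,
                        seed=cfg.seed, shape=shape,
                    )
                    for i, im in enumerate(imgs):
                        tifffile.imwrite(
                            gdir / f"{nm}_{cond.label}_d{day}_f{i}.tif", im.pixels
                        )
                    by_day[day] = imgs
                series[f"{nm}_{cond.label}"] = build_growth_series(
                    by_day, smooth_sigma=cfg.counting.smooth_sigma,
                    min_area=cfg.counting.min_area,
                    threshold_rule=cfg.counting.threshold_rule,
                )
    table = growth_table(series)
    path = outdir / "growth.csv"
    table.to_csv(path, index=False)

    # growth inhibition of every treated condition vs its arm's control
    rows = []
    last_day = max(cfg.growth.days)
    for key, s in series.items():
        nm = key.split("_")[0]
        irr = "_IR" in key or "IR4Gy" in key
        ctrl_key = next(
            k for k in series
            if k.startswith(nm + "_none_d0")
            and (("IR4Gy" in k) == irr)
        )
        if key == ctrl_key:
            continue
        rows.append({
            "condition": key,
            "inhibition": growth_inhibition(s, series[ctrl_key], last_day),
            "day": last_day,
        })
    pd.DataFrame(rows).to_csv(outdir / "growth_inhibition.csv", index=False)
    return str(path)


def _stage_pcr(cfg: RunConfig, outdir: Path) -> tuple[str, str]:
    frames = []
    for nm in cfg.nm_types:
        nm_t = NMType(nm)
        for t_h in cfg.timepoints_h:
            gp = default_generative_params(nm_t, t_h, cfg.synergy_coeff)
            for irr in (False, True):
                for d in cfg.pcr.doses:
                    cond = SampleCondition(
                        nm_type=nm_t if d > 0 else NMType.NONE,
                        dose_surface=d if d > 0 else 0.0,
                        irradiated=irr, timepoint_h=t_h,
                    )
                    sub = np.random.SeedSequence(
                        [cfg.seed, 7, _stable_hash(cond.label)]
                    ).generate_state(1)[0] & 0x7FFFFFFF
                    df = simulate_pcr(cond, gp, seed=int(sub),
                                      n_replicates=cfg.pcr.n_replicates)
                    df.insert(1, "nm_label", nm)
                    frames.append(df)
    ct = pd.concat(frames, ignore_index=True)
    ct_path = outdir / "pcr_ct.csv"
    ct.to_csv(ct_path, index=False)
    fc = fold_changes(ct.drop(columns=["nm_type"]).rename(columns={"nm_label": "nm_type"}),
                      reference_gene="GAPDH")
    fc_path = outdir / "pcr_foldchange.csv"
    fc.to_csv(fc_path, index=False)
    return str(ct_path), str(fc_path)


def _stage_report(cfg: RunConfig, outdir: Path, outputs: dict[str, str],
                  log: list[dict]) -> RunReport:
    death = _death_table(outdir)
    comparisons = comparison_suite(death)
    cpath = outdir / "comparisons.csv"
    comparisons.to_csv(cpath, index=False)
    outputs["comparisons"] = str(cpath)

    heatmap = None
    if (outdir / "synergy_heatmap.csv").exists():
        heatmap = pd.read_csv(outdir / "synergy_heatmap.csv", index_col=0)

    hasher = hashlib.sha256()
    hasher.update(json.dumps(cfg.model_dump(), sort_keys=True).encode())
    for key in sorted(outputs):
        p = Path(outputs[key])
        if p.exists() and p.is_file():
            hasher.update(p.read_bytes())
    provenance = hasher.hexdigest()

    summary = {
        "n_conditions": int(
            death[["nm_type", "dose_surface", "irradiated", "timepoint_h"]]
            .drop_duplicates().shape[0]
        ),
        "n_significant_ir_vs_ni": int(
            comparisons.query("family == 'ir_vs_ni'")["significant"].sum()
        ),
        "mean_mortality": float(death["mortality"].mean()),
    }
    report = RunReport(outdir=outdir, outputs=outputs, heatmap=heatmap,
                       summary=summary, provenance_hash=provenance)
    (outdir / "report.json").write_text(json.dumps(report.to_json(), indent=2))
    return report


def run_pipeline(cfg: RunConfig, stage: str | None = None) -> RunReport | dict:
    """Run the whole pipeline (or one named stage) under ``cfg``.

    Returns the `RunReport` for a full run; for a single stage, a dict of
    that stage's output paths.  Deterministic given the config (including
    its seed): two identical runs yield identical provenance hashes.
    """
    if stage is not None and stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    log: list[dict] = []

    def run_stage(name, fn):
        t0 = time.monotonic()
        try:
            result = fn()
        except Exception as err:
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        log.append({
            "stage": name, "seed": cfg.seed,
            "duration_s": round(time.monotonic() - t0, 3),
            "params": cfg.model_dump(mode="json"),
        })
        return result

    todo = STAGES if stage is None else (stage,)
    for name in todo:
        if name == "simulate":
            run_stage(name, lambda: _stage_simulate(cfg, outdir))
            outputs["events"] = str(outdir / "events")
        elif name == "gate":
            outputs["gating"] = run_stage(name, lambda: _stage_gate(cfg, outdir))
        elif name == "death":
            outputs["death"] = run_stage(name, lambda: _stage_death(cfg, outdir))
        elif name == "fit":
            outputs["fits"] = run_stage(name, lambda: _stage_fit(cfg, outdir))
        elif name == "synergy":
            jpath, hpath = run_stage(name, lambda: _stage_synergy(cfg, outdir))
            outputs["synergy"] = jpath
            outputs["heatmap"] = hpath
        elif name == "growth":
            outputs["growth"] = run_stage(name, lambda: _stage_growth(cfg, outdir))
        elif name == "pcr":
            ct_path, fc_path = run_stage(name, lambda: _stage_pcr(cfg, outdir))
            outputs["pcr_ct"] = ct_path
            outputs["pcr_foldchange"] = fc_path
        elif name == "report":
            report = run_stage(name, lambda: _stage_report(cfg, outdir, outputs, log))
            (outdir / "log.jsonl").write_text(
                "\n".join(json.dumps(rec) for rec in log) + "\n"
            )
            return report
    return outputs
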