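"""End-to-end orchestration: simulate → track → probability map → VTA →
metrics → statistics, with a manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures, io_core, metrics as metrics_mod, outcomes_stats, probmap as probmap_mod
from .io_core import write_manifest, write_streamlines, write_volume
from .phantom import Phantom, PhantomConfig, generate_cohort
from .stimfield import ConductivityModel, compute_vta, merge_vtas
from .tracking import TrackingParams, merge_tracts, track_soz_to_thalamus

log = logging.getLogger("thalnet")

__all__ = ["RunConfig", "run_patient", "run_all", "reproduce_cohort_tables"]


@dataclasses.dataclass
class RunConfig:
    """Everything a full run needs; serializes losslessly to YAML."""

    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    tracking: TrackingParams = dataclasses.field(default_factory=TrackingParams)
    conductivity: ConductivityModel = dataclasses.field(default_factory=ConductivityModel)
    probmap_mass: float = 0.95
    seed: int = 0
    run_dir: str = "thalnet_run"
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(dataclasses.asdict(self))))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        from .phantom import BundleSpec, OutcomeModel, SOZSpec

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            for key in set(ph) - {f.name for f in dataclasses.fields(PhantomConfig)}:
                raise ValueError(f"unknown phantom config key: {key}")
            if "sozs" in ph:
                ph["sozs"] = [SOZSpec(**_tupled(s, "center_mm")) for s in ph["sozs"]]
            if "bundles" in ph:
                ph["bundles"] = [BundleSpec(**_tupled(b, "via_mm")) for b in ph["bundles"]]
            if "outcome" in ph:
                ph["outcome"] = OutcomeModel(**ph["outcome"])
            if "shape" in ph:
                ph["shape"] = tuple(ph["shape"])
            kwargs["phantom"] = PhantomConfig(**ph)
        if "tracking" in raw:
            kwargs["tracking"] = TrackingParams(**raw["tracking"])
        if "conductivity" in raw:
            kwargs["conductivity"] = ConductivityModel(**raw["conductivity"])
        for key in ("probmap_mass", "seed", "run_dir", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_as_plain(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _tupled(d: dict, key: str) -> dict:
    d = dict(d)
    if key in d and d[key] is not None:
        d[key] = tuple(d[key])
    return d


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_patient(
    phantom: Phantom,
    tracking: TrackingParams,
    conductivity: ConductivityModel,
    probmap_mass: float = 0.95,
    patient_seed: int = 0,
) -> dict:
    """Track every SOZ, merge, build the thresholded map and the VTA, and
    measure the two engagement metrics for one patient."""
    tracts = []
    for i, (name, seed_mask) in enumerate(sorted(phantom.soz_masks.items())):
        params = dataclasses.replace(tracking, seed=patient_seed * 1000 + i)
        t = track_soz_to_thalamus(
            phantom.field, seed_mask, phantom.thalamus, phantom.brainstem, params, soz_id=name
        )
        tracts.append(t)
    merged = merge_tracts(tracts)
    if merged.n_retained == 0:
        raise RuntimeError("no streamlines reached the thalamus")
    grid = phantom.labels
    raw = probmap_mod.tract_to_probability_map(merged, grid)
    thresholded = probmap_mod.threshold_map(raw, probmap_mass)
    vtas = [
        compute_vta(e, s, phantom.labels, conductivity, grid)
        for e, s in zip(phantom.electrodes, phantom.settings)
    ]
    vta = merge_vtas(vtas)
    act = metrics_mod.proportion_activated(merged, vta)
    peak = metrics_mod.peak_probability_in_vta(thresholded, vta)
    return {
        "tracts": tracts,
        "merged": merged,
        "probmap_raw": raw,
        "probmap": thresholded,
        "vta": vta,
        "activation": act,
        "peak": peak,
    }


def run_all(config: RunConfig) -> Path:
    """Full phantom-cohort run; writes per-patient artifacts, cohort.csv,
    stats.json, and a checksummed manifest into the run directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log.info("run config: %s", _as_plain(dataclasses.asdict(config)))
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")

    phantoms, cohort, truth = generate_cohort(config.phantom, config.conductivity)
    rows = []
    artifacts = {"config": "config.yaml"}
    for i, ph in enumerate(phantoms):
        pid = cohort.loc[i, "patient_id"]
        res = run_patient(
            ph, config.tracking, config.conductivity, config.probmap_mass, patient_seed=config.seed * 100 + i
        )
        pdir = run_dir / pid
        pdir.mkdir(exist_ok=True)
        write_volume(pdir / "labels.nii.gz", ph.labels)
        write_volume(pdir / "vta.nii.gz", res["vta"].mask)
        write_volume(pdir / "probmap.nii.gz", res["probmap"].volume)
        write_streamlines(pdir / "merged.tck", res["merged"])
        for name in ("labels", "vta", "probmap"):
            artifacts[f"{pid}/{name}"] = f"{pid}/{name}.nii.gz"
        artifacts[f"{pid}/merged"] = f"{pid}/merged.tck"
        rows.append(
            {
                "patient_id": pid,
                "n_total": res["activation"].n_total,
                "n_activated": res["activation"].n_activated,
                "proportion": res["activation"].proportion,
                "percent": res["activation"].percent_rounded,
                "peak_probability": res["peak"].peak,
                "true_proportion": cohort.loc[i, "true_proportion"],
                "pre_per_month": cohort.loc[i, "pre_per_month"],
                "post_per_month": cohort.loc[i, "post_per_month"],
                "reduction_percent": cohort.loc[i, "reduction_percent"],
            }
        )
        log.info("patient %s: proportion %.3f peak %.3f", pid, res["activation"].proportion, res["peak"].peak)

    table = pd.DataFrame(rows)
    table.to_csv(run_dir / "cohort.csv", index=False)
    artifacts["cohort"] = "cohort.csv"
    truth_json = {
        "true_proportion": [float(x) for x in truth.true_proportion],
        "expected_reduction": [float(x) for x in truth.expected_reduction],
    }
    (run_dir / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))
    artifacts["ground_truth"] = "ground_truth.json"

    stats = outcomes_stats.analyze_cohort(table)
    (run_dir / "stats.json").write_text(json.dumps(stats.to_dict(), indent=2))
    artifacts["stats"] = "stats.json"
    write_manifest(run_dir, artifacts, seed=config.seed, config_hash=config.config_hash())
    return run_dir


def reproduce_cohort_tables() -> dict:
    """Recompute the derivable columns of the packaged cohort tables and
    report pass/fail per check: the rounded activated-percent column, the
    responder counts, and the Spearman correlation between activation ratio
    and printed seizure reduction."""
    t1 = fixtures.load_table1()
    t2 = fixtures.load_table2()
    report: dict = {}

    recomputed = [
        metrics_mod.round_half_away(100 * a / n)
        for a, n in zip(t2["n_streamlines_activated"], t2["n_streamlines_total"])
    ]
    matches = [int(r) == int(p) for r, p in zip(recomputed, t2["percent_activated"])]
    report["percent_column"] = {
        "n_match": sum(matches),
        "n_rows": len(matches),
        "pass": all(matches),
    }

    cats = [
        outcomes_stats.classify_response(
            outcomes_stats.seizure_reduction(pre, post)
        )
        for pre, post in zip(t2["preop_per_month"], t2["postop_per_month"])
    ]
    counts = {c: cats.count(c) for c in ("responder", "partial", "nonresponder")}
    report["response_counts"] = {
        **counts,
        "pass": counts == {"responder": 7, "partial": 2, "nonresponder": 3},
    }

    ratio = t2["n_streamlines_activated"] / t2["n_streamlines_total"]
    rho, p = outcomes_stats.spearman(ratio, t2["reduction_percent"], method="t")
    report["spearman"] = {"rho": rho, "p": p, "rho_2dp": round(rho, 2), "pass": round(rho, 2) == 0.78}

    mean_age = float(np.mean(t1["age_years"]))
    report["mean_age"] = {"value": mean_age, "rounded": round(mean_age), "pass": round(mean_age) == 26}
    report["pass"] = all(v["pass"] for v in report.values() if isinstance(v, dict))
    return report
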