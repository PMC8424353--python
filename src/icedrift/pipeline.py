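"""Orchestration: the full monitoring workflow from one configuration.

``run_all`` chains load (or synthesize) -> spatio-temporal grouping and
min-size filter -> diversity and differentiation tables -> trend model
selection and the sign test -> bottleneck tests -> forward simulations,
writing every artifact as delimited text plus a manifest of seeds and
settings.  All randomness derives from one master seed through named
seed-sequence substreams, so a rerun with the same configuration is
reproducible."""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bottleneck, divstats, forwardsim, genio, synthdata, trendmodels

logger = logging.getLogger(__name__)

#: response -> (source table, model family)
RESPONSES = {
    "AR": ("diversity", "linear"),
    "HE": ("diversity", "beta"),
    "HO": ("diversity", "beta"),
    "rw": ("diversity", "linear"),
    "Gpp": ("pairwise", "beta"),
}

DEFAULT_CONFIG = {
    "input": {"synth": {}},
    "periods": None,  # genio.DEFAULT_PERIODS
    "min_group_size": 10,
    "rarefaction_g": None,  # auto: smallest per-locus gene-copy count
    "responses": ["AR", "HE", "rw", "Gpp"],
    "trend_formulas": list(trendmodels.FORMULAS),
    "bottleneck": {"model": "tpm", "reps": 2000, "per": "area"},
    "scenarios": [],
    "scenario_reps": 5,
    "scenario_horizon": 100,
    "seed": 0,
}


def _substream(master: int, name: str) -> np.random.Generator:
    h = zlib.crc32(name.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(master), h]))


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user}
    for key in ("input", "bottleneck"):
        if key in user and isinstance(user[key], dict):
            cfg[key] = {**DEFAULT_CONFIG[key], **user[key]} if key == "bottleneck" else user[key]
    return cfg


def _load_dataset(cfg: dict) -> genio.GenotypeDataset:
    inp = cfg["input"]
    if "synth" in inp:
        spec = synthdata.SynthSpec(**inp["synth"])
        rng = _substream(cfg["seed"], "synth")
        ds, truth = synthdata.generate_structured_series(spec, rng)
        ds.provenance += f" seed={cfg['seed']}"
        return ds
    fmt = inp.get("format", "genepop")
    if fmt == "genepop":
        return genio.read_genepop(inp["path"], repeat_units=inp.get("repeat_units", 2))
    if fmt == "structure":
        return genio.read_structure_two_row(
            inp["path"],
            repeat_units=inp.get("repeat_units", 2),
            has_year=inp.get("has_year", True),
        )
    raise ValueError(f"unknown input format {fmt!r}")


def period_index(gt: genio.GroupTable) -> dict[str, int]:
    return {label: i + 1 for i, (label, _, _) in enumerate(gt.period_bins)}


def trend_table_from_diversity(div: pd.DataFrame, gt: genio.GroupTable, response: str) -> pd.DataFrame:
    pidx = period_index(gt)
    return pd.DataFrame(
        {
            "area": div["area"],
            "time": div["period"].map(pidx),
            "response": div[response],
        }
    )


def trend_table_from_pairwise(pw: pd.DataFrame, gt: genio.GroupTable) -> pd.DataFrame:
    """Within-period area-pair G''_ST as a trend table ('area' = pair label)."""
    pidx = period_index(gt)
    sub = pw[pw["period_1"] == pw["period_2"]].copy()
    sub["pair"] = sub["area_1"] + "-" + sub["area_2"]
    return pd.DataFrame(
        {
            "area": sub["pair"],
            "period": sub["period_1"],
            "time": sub["period_1"].map(pidx),
            "response": sub["Gpp"],
        }
    )


def run_all(cfg: dict, outdir) -> dict:
    """Execute the whole workflow; returns the report dict (also written
    to ``outdir``).  Any stage failure aborts with the stage name; tables
    already produced remain on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg["seed"]}
    stage = "load"
    try:
        ds = _load_dataset(cfg)
        report["n_individuals"] = ds.n_individuals
        report["n_loci"] = ds.n_loci

        stage = "group"
        gt = genio.assign_periods(ds, cfg["periods"])
        gt = genio.filter_min_group_size(gt, cfg["min_group_size"])
        if not gt.groups:
            raise RuntimeError(
                f"no group of size >= {cfg['min_group_size']} remains after filtering"
            )
        gt.sizes().to_csv(outdir / "groups.tsv", sep="\t", index=False)
        report["n_groups"] = len(gt.groups)

        stage = "stats"
        div = divstats.diversity_table(ds, gt.groups, cfg["rarefaction_g"])
        div.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        per_period_groups = {}
        for label, _, _ in gt.period_bins:
            sub = [(a, p, m) for a, p, m in gt.groups if p == label]
            if len(sub) >= 2:
                per_period_groups[label] = sub
        pw = pd.concat(
            [divstats.pairwise_table(ds, sub) for sub in per_period_groups.values()],
            ignore_index=True,
        )
        pw.to_csv(outdir / "pairwise.tsv", sep="\t", index=False)

        stage = "trends"
        trend_report = {}
        for response in cfg["responses"]:
            source, family = RESPONSES[response]
            td = (
                trend_table_from_diversity(div, gt, response)
                if source == "diversity"
                else trend_table_from_pairwise(pw, gt)
            )
            table, fits = trendmodels.model_selection(
                td, family=family, formulas=tuple(cfg["trend_formulas"])
            )
            table.to_csv(outdir / f"model_selection_{response}.tsv", sep="\t", index=False)
            time_fit = next((f for f in fits if f.formula == "time"), None)
            if time_fit is not None:
                lo, hi = time_fit.slope_ci()
                trend_report[response] = {
                    "slope": time_fit.slope,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "best_model": table["model"].iloc[0],
                }
        report["trends"] = trend_report

        stage = "sign_test"
        pw_td = trend_table_from_pairwise(pw, gt)
        changes = trendmodels.consecutive_changes(
            pw_td, "response", period_col="period", by=["area"],
            period_order=gt.period_labels,
        )
        k, n, p = trendmodels.sign_test_differentiation(changes)
        report["sign_test"] = {"increases": k, "steps": n, "p": p}

        stage = "bottleneck"
        bn = cfg["bottleneck"]
        model = bottleneck.MutationModel(kind=bn.get("model", "tpm"))
        if bn.get("per", "area") == "area":
            labels = sorted({a for a, _, _ in gt.groups})
            group_counts = {
                a: divstats.allele_counts(
                    ds, [m for ar, _, mm in gt.groups if ar == a for m in mm]
                )
                for a in labels
            }
        else:
            group_counts = {
                f"{a}_{p}": divstats.allele_counts(ds, m) for a, p, m in gt.groups
            }
        bn_table = bottleneck.bottleneck_table(
            group_counts,
            repeat_units=[loc.repeat_unit for loc in ds.loci],
            model=model,
            reps=bn.get("reps", 2000),
            rng=_substream(cfg["seed"], "bottleneck"),
            locus_names=ds.locus_names,
        )
        bn_table.to_csv(outdir / "bottleneck.tsv", sep="\t", index=False)
        report["bottleneck"] = bn_table.to_dict(orient="records")

        stage = "simulate"
        sim_report = {}
        for sid in cfg["scenarios"]:
            spec = forwardsim.build_scenario(
                sid,
                horizon=cfg["scenario_horizon"],
                **({"init_dataset": ds} if sid == 6 else {}),
            )
            traj = forwardsim.run_scenario(
                spec,
                reps=cfg["scenario_reps"],
                seed=np.random.SeedSequence([cfg["seed"], 1000 + sid]),
                record_every=max(1, cfg["scenario_horizon"] // 20),
            )
            traj.stats.to_csv(outdir / f"trajectory_s{sid}.tsv", sep="\t", index=False)
            final = traj.stats[traj.stats["gen"] == traj.stats["gen"].max()]
            sim_report[str(sid)] = {
                "final_HE": float(final["HE"].mean()),
                "final_GST": float(final["GST"].mean()),
            }
        if sim_report:
            report["scenarios"] = sim_report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items() if k != "input" or "path" in str(v)},
        "seed": cfg["seed"],
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_jsonable(manifest), fh)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
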