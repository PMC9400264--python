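"""End-to-end pipeline orchestration from one YAML config.

Stages run in dependency order (simulate -> filter -> diversity ->
kinship -> sweep -> sex/STR -> load); each stage writes its outputs
before the next starts, and a RunReport (JSON) records per-stage record
counts, the thresholds actually used and the global seed, so a rerun with
the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinship, mutload, popdiv, sexstr, simdata, sweep, vario

log = logging.getLogger("garrupop")

KNOWN_KEYS = {
    "seed",
    "outdir",
    "log_level",
    "simdata",
    "inputs",
    "filter",
    "popdiv",
    "kinship",
    "sweep",
    "sexstr",
    "mutload",
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "simdata" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs either a 'simdata' block or an 'inputs' block")
    if "outdir" not in cfg:
        raise ConfigError("config needs 'outdir'")


def _sim_config(cfg: dict) -> simdata.SimConfig:
    blk = dict(cfg.get("simdata") or {})
    groups = [simdata.GroupSpec(**g) for g in blk.pop("groups", [])] or None
    sweeps = [simdata.SweepSpec(**s) for s in blk.pop("sweep_regions", [])]
    rel = [simdata.RelatedPair(**r) for r in blk.pop("related_pairs", [])]
    roh = [simdata.ROHBlock(**r) for r in blk.pop("roh_blocks", [])]
    kwargs = dict(blk)
    if groups is not None:
        kwargs["groups"] = groups
    kwargs["sweep_regions"] = sweeps
    kwargs["related_pairs"] = rel
    kwargs["roh_blocks"] = roh
    kwargs.setdefault("seed", cfg.get("seed", 0))
    return simdata.SimConfig(**kwargs)


def run_pipeline(cfg: dict) -> dict:
    """Execute all applicable stages; returns (and writes) the run report."""
    validate_config(cfg)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg.get("log_level", "INFO")).upper(), logging.INFO))
    report: dict = {"seed": cfg.get("seed", 0), "stages": {}}

    # -- stage: inputs ------------------------------------------------------
    if "simdata" in cfg:
        sc = _sim_config(cfg)
        gm, samples, truth = simdata.simulate_cohort(sc)
        depth = simdata.simulate_depth_profiles(sc, samples)
        strs = simdata.simulate_str_table(sc, truth)
        effects = simdata.simulate_effect_labels(sc, gm)
        simdata.write_tables(out / "inputs", gm, samples, truth, depth, strs, effects)
        report["stages"]["simulate"] = {"n_sites": gm.n_sites, "n_samples": gm.n_samples}
    else:
        ins = cfg["inputs"]
        gm = vario.read_vcf(ins["vcf"])
        samples = pd.read_csv(ins["samples"], sep="\t")
        depth = pd.read_csv(ins["depth"], sep="\t") if "depth" in ins else None
        strs = pd.read_csv(ins["strs"], sep="\t") if "strs" in ins else None
        effects = pd.read_csv(ins["effects"], sep="\t") if "effects" in ins else None
        report["stages"]["load"] = {"n_sites": gm.n_sites, "n_samples": gm.n_samples}

    groups = {g: samples.loc[samples["group"] == g, "sample"].tolist() for g in samples["group"].unique()}
    sexes = dict(zip(samples["sample"], samples["sex"])) if "sex" in samples else {}

    # -- stage: hard filter -------------------------------------------------
    fcfg = cfg.get("filter", {})
    gm_f, n_removed = vario.hard_filter_variants(gm, fcfg.get("thresholds"))
    report["stages"]["filter"] = {"n_in": gm.n_sites, "n_removed": n_removed, "n_out": gm_f.n_sites}

    # -- stage: diversity ---------------------------------------------------
    pcfg = cfg.get("popdiv", {})
    wsize = int(pcfg.get("window_size", 40_000))
    windows = vario.make_windows(
        {s: l for s, l in gm_f.scaffold_lengths.items() if (gm_f.sites["scaffold"] == s).any()},
        wsize,
    )
    focal = pcfg.get("group") or next(iter(groups))
    pi = popdiv.pi_windows(gm_f, windows, samples=groups[focal])
    pi.to_csv(out / "pi_windows.tsv", sep="\t", index=False)
    td = popdiv.tajima_d_windows(gm_f, windows, samples=groups[focal])
    td.to_csv(out / "tajima_windows.tsv", sep="\t", index=False)
    report["stages"]["popdiv"] = {"n_windows": len(windows), "group": focal}

    # -- stage: kinship -----------------------------------------------------
    kcfg = cfg.get("kinship", {})
    kin_group = kcfg.get("group", focal)
    pairs = kinship.pairwise_kinship(gm_f, groups[kin_group])
    pairs.to_csv(out / "kinship_pairs.tsv", sep="\t", index=False)
    quality = dict(zip(samples["sample"], samples.get("quality", pd.Series(dtype=float)).fillna(0.0)))
    if depth is not None and not quality:
        quality = depth.groupby("sample")["mean_depth"].mean().to_dict()
    kept = kinship.prune_related(pairs, quality, kcfg.get("pi_hat_threshold", 0.2))
    (out / "kept_samples.txt").write_text("\n".join(sorted(kept)) + "\n")
    report["stages"]["kinship"] = {"n_pairs": len(pairs), "n_kept": len(kept)}
    if len(groups[kin_group]) >= 3:
        dm, ids = kinship.ibs_distance_matrix(gm_f, groups[kin_group])
        (out / "nj_tree.nwk").write_text(kinship.nj_tree(dm, ids) + "\n")

    # -- stage: sweep scan --------------------------------------------------
    scfg = cfg.get("sweep", {})
    pop_a = groups.get(scfg.get("pop_a", focal), groups[focal])
    others = [g for g in groups if groups[g] is not pop_a]
    pop_b = groups.get(scfg.get("pop_b")) or [s for g in others for s in groups[g]]
    if pop_b:
        hp = sweep.hp_windows(gm_f, windows, pop=pop_a)
        hp["zhp"] = sweep.zhp_standardize(hp["hp"].to_numpy())
        fst = sweep.wc_fst_windows(gm_f, pop_a, pop_b, windows)
        scan, thresholds = sweep.dual_threshold_overlap(fst, hp[["scaffold", "start", "end", "zhp"]].assign(zhp=hp["zhp"]), scfg.get("quantile", 0.01))
        scan.to_csv(out / "sweep_scan.tsv", sep="\t", index=False)
        report["stages"]["sweep"] = {
            "n_overlap": int(scan["is_overlap"].sum()),
            **thresholds,
        }

    # -- stage: sex / STR ---------------------------------------------------
    if depth is not None and sexes:
        norm = sexstr.normalize_depth(depth, sexes)
        classes = sexstr.classify_scaffolds(norm, sexes, scaffold_lengths=gm.scaffold_lengths or None)
        classes.to_csv(out / "scaffold_classes.tsv", sep="\t", index=False)
        w_scafs = classes.loc[classes["cls"] == "W", "scaffold"].tolist()
        if w_scafs:
            sexcalls = sexstr.call_sample_sex(norm, w_scafs)
            sexcalls.to_csv(out / "sex_calls.tsv", sep="\t", index=False)
        report["stages"]["sexstr"] = {"n_w": len(w_scafs)}
        if strs is not None:
            kin_panel = sexstr.filter_kinship_strs(strs)
            kin_panel.to_csv(out / "kinship_strs.tsv", sep="\t", index=False)
            sex_panel = sexstr.select_sex_strs(strs, w_scafs, sexes)
            sex_panel.to_csv(out / "sex_strs.tsv", sep="\t", index=False)
            report["stages"]["sexstr"].update(
                {"n_kinship_strs": len(kin_panel), "n_sex_strs": len(sex_panel)}
            )

    # -- stage: deleterious load --------------------------------------------
    if effects is not None and len(groups) >= 2:
        profiles = mutload.load_profiles(gm_f, effects)
        profiles.to_csv(out / "load_profiles.tsv", sep="\t", index=False)
        gnames = list(groups)
        sel = lambda g, z: profiles[
            profiles["sample"].isin(groups[g])
            & (profiles["zygosity"] == z)
            & (profiles["cls"] == "strong")
        ]["proportion"]
        try:
            stat, p = mutload.compare_groups(sel(gnames[0], "homozygous"), sel(gnames[1], "homozygous"))
            report["stages"]["mutload"] = {"hom_strong_stat": stat, "hom_strong_p": p}
        except ValueError as exc:
            report["stages"]["mutload"] = {"skipped": str(exc)}

    # provenance covers the scientific inputs/parameters, not output paths
    prov = {k: v for k, v in cfg.items() if k not in ("outdir", "log_level")}
    report["provenance_sha256"] = hashlib.sha256(
        json.dumps(prov, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
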