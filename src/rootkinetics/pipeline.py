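"""Batch orchestration: simulate → static-profile → kinematics → ploidy → compare.

A run is configured by a flat mapping with one section per stage (only the
sections present are executed) plus a single integer seed.  Everything a
run produces goes into one output directory, together with
``manifest.json`` — the config echo, seed, package/library versions,
interpretation flags and collected per-root failures — from which the run
can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, InsufficientDataError, SegmentationError
from .growthzone import GrowthZoneSpec
from .io import (
    read_cellfile_csv,
    read_particles_csv,
    read_ploidy_csv,
    write_cellfile_csv,
    write_particles_csv,
    write_ploidy_csv,
    write_proportions_csv,
    write_truth_json,
)
from .kinematics import analyze_cohort, strain_rate_profile, estimate_velocity_profile, interpolate_cell_lengths
from .ploidy import classify_ploidy, compare_ploidy, estimate_anchor, ploidy_proportions
from .static_profile import segment_profile, summarize_seedling
from .stats import anova_tukey, welch_t
from .synthetic import simulate_cohort, simulate_ploidy

log = logging.getLogger("rootkinetics")

__all__ = ["validate_config", "run_pipeline"]

_SPEC_KEYS = {
    "meristem_length",
    "initial_cell_length",
    "meristem_strain_rate",
    "elongation_zone_length",
    "elongation_strain_integral",
    "bump_shape",
    "domain_extent",
}

#: Allowed keys per config section (None = validated separately).
_SCHEMA: dict[str, set[str] | None] = {
    "simulate": {
        "cohorts",
        "roots",
        "particles_per_root",
        "dt",
        "position_noise_sd",
        "length_cv",
        "ploidy",
    },
    "static_profile": {"tol", "median_filter", "qc_offset"},
    "kinematics": {
        "bandwidth",
        "grid_step",
        "min_points",
        "plateau_frac",
        "include_candidate",
        "write_profiles",
    },
    "ploidy": {"anchor", "min_intensity", "max_intensity", "bh"},
    "compare": {"metrics", "test"},
}

_SIM_PLOIDY_KEYS = {"proportions", "samples_per_genotype", "n_nuclei", "anchor", "cv"}


def validate_config(config: Mapping[str, Any]) -> None:
    """Reject unknown sections or keys, naming the offender."""
    for section, content in config.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(content, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        allowed = _SCHEMA[section]
        for key in content:
            if key not in allowed:
                raise ConfigError(f"unknown key {key!r} in section {section!r}")
    sim = config.get("simulate", {})
    for name, cohort in sim.get("cohorts", {}).items():
        if not isinstance(cohort, Mapping):
            raise ConfigError(f"cohort {name!r} must be a mapping")
        for key in cohort:
            if key != "spec":
                raise ConfigError(f"unknown key {key!r} in cohort {name!r}")
        for key in cohort.get("spec", {}):
            if key not in _SPEC_KEYS:
                raise ConfigError(f"unknown spec key {key!r} in cohort {name!r}")
    for key in sim.get("ploidy", {}):
        if key not in _SIM_PLOIDY_KEYS:
            raise ConfigError(f"unknown key {key!r} in simulate.ploidy")


def _stage_simulate(cfg: Mapping, seed: int, out: Path) -> None:
    cohorts = cfg.get("cohorts")
    if not cohorts:
        raise ConfigError("simulate stage requires a 'cohorts' mapping")
    ss_root, ss_ploidy = np.random.SeedSequence(seed).spawn(2)
    all_obs, all_profiles, root_rows = [], [], []
    for (name, cohort), ss in zip(sorted(cohorts.items()), ss_root.spawn(len(cohorts))):
        spec = GrowthZoneSpec(**cohort["spec"])
        sims = simulate_cohort(
            spec,
            n_roots=int(cfg.get("roots", 10)),
            particles_per_root=int(cfg.get("particles_per_root", 40)),
            dt=float(cfg.get("dt", 1.0)),
            position_noise_sd=float(cfg.get("position_noise_sd", 5.0)),
            length_cv=float(cfg.get("length_cv", 0.05)),
            seed=ss,
            root_prefix=f"{name}-",
        )
        for obs, prof in sims:
            all_obs.append(obs)
            all_profiles.append(prof)
            root_rows.append({"root_id": prof.root_id, "genotype": name})
        write_truth_json(out / f"truth_{name}.json", spec)
        log.info("simulate: cohort %s, %d roots", name, len(sims))
    write_particles_csv(out / "particles.csv", all_obs)
    write_cellfile_csv(out / "cellfile.csv", all_profiles)
    pd.DataFrame(root_rows).to_csv(out / "roots.csv", index=False)

    pcfg = cfg.get("ploidy")
    if pcfg:
        samples = []
        n_per = int(pcfg.get("samples_per_genotype", 6))
        genotypes = sorted(pcfg["proportions"].items())
        seeds = ss_ploidy.spawn(len(genotypes) * n_per)
        i = 0
        for gname, props in genotypes:
            for j in range(n_per):
                samples.append(
                    simulate_ploidy(
                        {k: float(v) for k, v in props.items()},
                        n=int(pcfg.get("n_nuclei", 10_000)),
                        anchor=float(pcfg.get("anchor", 100.0)),
                        cv=float(pcfg.get("cv", 0.05)),
                        rng=np.random.default_rng(seeds[i]),
                        sample_id=f"{gname}-s{j + 1}",
                        genotype=gname,
                    )
                )
                i += 1
        write_ploidy_csv(out / "ploidy.csv", samples)
        log.info("simulate: %d ploidy samples", len(samples))


def _stage_static(cfg: Mapping, out: Path, failures: dict) -> None:
    profiles = read_cellfile_csv(out / "cellfile.csv")
    by_root: dict[str, dict] = {}
    for prof in profiles:
        qc = cfg.get("qc_offset")
        if qc is not None:
            prof.qc_offset = float(qc)
        try:
            summary = segment_profile(
                prof,
                tol=float(cfg.get("tol", 0.05)),
                median_filter=bool(cfg.get("median_filter", False)),
            )
        except (SegmentationError, InsufficientDataError) as exc:
            failures[f"static:{prof.root_id}/{prof.file_side}"] = str(exc)
            summary = None
        by_root.setdefault(prof.root_id, {})[prof.file_side] = summary
    rows = []
    for rid, sides in sorted(by_root.items()):
        files = [s for s in sides.values() if s is not None]
        if not files:
            continue
        seedling = summarize_seedling(
            files[0], files[1] if len(files) > 1 else None
        )
        rows.append(
            {
                "root_id": rid,
                "meristem_cells": seedling.meristem_cell_count,
                "meristem_length_um": seedling.meristem_length,
                "elongation_onset_index": seedling.elongation_onset_index,
                "maturation_onset_index": seedling.maturation_onset_index,
                "mature_cell_length_um": seedling.mature_cell_length,
                "n_files_used": seedling.n_files_used,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "root_id",
            "meristem_cells",
            "meristem_length_um",
            "elongation_onset_index",
            "maturation_onset_index",
            "mature_cell_length_um",
            "n_files_used",
        ],
    ).to_csv(out / "static_summary.csv", index=False, float_format="%.6f")
    log.info("static-profile: %d seedlings summarized", len(rows))


def _stage_kinematics(cfg: Mapping, out: Path, failures: dict) -> None:
    observations = read_particles_csv(out / "particles.csv")
    profiles = {p.root_id: p for p in read_cellfile_csv(out / "cellfile.csv")}
    pairs = []
    for obs in observations:
        rid = str(obs.records["root_id"].iloc[0])
        if rid not in profiles:
            failures[f"kinematics:{rid}"] = "no paired cell file"
            continue
        pairs.append((obs, profiles[rid]))
    kwargs = dict(
        bandwidth=float(cfg.get("bandwidth", 50.0)),
        grid_step=float(cfg.get("grid_step", 1.0)),
        min_points=cfg.get("min_points", 16),
        plateau_frac=float(cfg.get("plateau_frac", 0.95)),
        include_candidate=bool(cfg.get("include_candidate", False)),
    )
    if kwargs["min_points"] is not None:
        kwargs["min_points"] = int(kwargs["min_points"])
    table, root_failures = analyze_cohort(pairs, **kwargs)
    for rid, msg in root_failures.items():
        failures[f"kinematics:{rid}"] = msg
    table.to_csv(out / "kinematics_summary.csv", index=False, float_format="%.6f")
    log.info(
        "kinematics: %d roots analyzed, %d failed", len(table), len(root_failures)
    )
    if cfg.get("write_profiles", True):
        frames = []
        for obs, prof in pairs:
            rid = prof.root_id
            try:
                vp = estimate_velocity_profile(
                    obs,
                    bandwidth=kwargs["bandwidth"],
                    grid_step=kwargs["grid_step"],
                    min_points=kwargs["min_points"],
                )
            except Exception:
                continue
            lg = interpolate_cell_lengths(vp.grid, prof)
            with np.errstate(invalid="ignore", divide="ignore"):
                flux = np.where(lg > 0, vp.v / lg, np.nan)
            frames.append(
                pd.DataFrame(
                    {
                        "root_id": rid,
                        "x_um": vp.grid,
                        "v_um_per_h": vp.v,
                        "flux_per_h": flux,
                        "regr_per_h": strain_rate_profile(vp),
                    }
                )
            )
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / "regr_profile.csv", index=False, float_format="%.6f"
            )


def _stage_ploidy(cfg: Mapping, out: Path, failures: dict) -> None:
    samples = read_ploidy_csv(out / "ploidy.csv")
    lo, hi = cfg.get("min_intensity"), cfg.get("max_intensity")
    results = []
    for s in samples:
        intens = s.intensities
        if lo is not None:
            intens = intens[intens >= float(lo)]
        if hi is not None:
            intens = intens[intens <= float(hi)]
        anchor = cfg.get("anchor")
        anchor = float(anchor) if anchor is not None else estimate_anchor(intens)
        classes = classify_ploidy(intens, anchor)
        results.append(
            ploidy_proportions(
                classes, sample_id=s.sample_id, genotype=s.genotype, anchor_used=anchor
            )
        )
    write_proportions_csv(out / "ploidy_proportions.csv", results)
    by_geno: dict[str, list] = {}
    for r in results:
        by_geno.setdefault(r.genotype, []).append(r)
    genotypes = sorted(by_geno)
    if len(genotypes) == 2 and all(len(by_geno[g]) >= 2 for g in genotypes):
        table = compare_ploidy(
            by_geno[genotypes[0]],
            by_geno[genotypes[1]],
            bh=bool(cfg.get("bh", False)),
            label_a=genotypes[0],
            label_b=genotypes[1],
        )
        table.to_csv(out / "ploidy_tests.csv", index=False, float_format="%.6g")
    log.info("ploidy: %d samples, %d genotypes", len(results), len(genotypes))


def _stage_compare(cfg: Mapping, out: Path) -> None:
    summary = pd.read_csv(out / "kinematics_summary.csv")
    roots = pd.read_csv(out / "roots.csv")
    merged = summary.merge(roots, on="root_id", how="left")
    metrics = cfg.get(
        "metrics", ["P_cells_per_h", "mature_len_um", "Tc_h", "V_um_per_h"]
    )
    test = cfg.get("test", "welch_t")
    genotypes = sorted(merged["genotype"].dropna().unique())
    rows = []
    for metric in metrics:
        groups = {
            g: merged.loc[merged["genotype"] == g, metric].to_numpy(float)
            for g in genotypes
        }
        if test == "welch_t" and len(genotypes) == 2:
            cmp_res = welch_t(
                groups[genotypes[0]], groups[genotypes[1]],
                metric=metric, labels=(genotypes[0], genotypes[1]),
            )
        elif test == "anova_tukey" or len(genotypes) > 2:
            cmp_res = anova_tukey(groups, metric=metric)
        else:
            raise ConfigError(f"unknown test {test!r} or wrong group count")
        row = {
            "metric": metric,
            "test": cmp_res.test,
            "statistic": cmp_res.statistic,
            "p": cmp_res.p_value,
        }
        for g in genotypes:
            row[f"mean_{g}"] = cmp_res.mean[g]
            row[f"n_{g}"] = cmp_res.n[g]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "comparisons.csv", index=False, float_format="%.6g")
    log.info("compare: %d metrics, %d genotypes", len(metrics), len(genotypes))


def run_pipeline(config: Mapping[str, Any], seed: int, out_dir) -> dict:
    """Execute the configured stages; return the run manifest.

    Per-root segmentation or estimation failures are collected in the
    manifest, not raised; malformed configuration or missing inputs raise
    immediately.
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failures: dict[str, str] = {}
    stage_order = ["simulate", "static_profile", "kinematics", "ploidy", "compare"]
    for stage in stage_order:
        if stage not in config:
            continue
        cfg = config[stage]
        log.info("stage %s: start", stage)
        if stage == "simulate":
            _stage_simulate(cfg, seed, out)
        elif stage == "static_profile":
            _stage_static(cfg, out, failures)
        elif stage == "kinematics":
            _stage_kinematics(cfg, out, failures)
        elif stage == "ploidy":
            if (out / "ploidy.csv").exists():
                _stage_ploidy(cfg, out, failures)
            else:
                log.info("ploidy: no ploidy.csv, stage skipped")
        elif stage == "compare":
            _stage_compare(cfg, out)
    import scipy

    manifest = {
        "config": _jsonable(config),
        "seed": int(seed),
        "versions": {
            "rootkinetics": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "interpretation": {
            "plateau_rule": "first point >= frac * mean of strictly distal points",
            "candidate_in_remaining_mean": bool(
                config.get("kinematics", {}).get("include_candidate", False)
            ),
            "t_test_variant": "welch_unequal_variance",
            "tc_formula": "ln(2) * N / P (exponential doubling)",
        },
        "failures": failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
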