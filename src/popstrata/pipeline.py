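"""Config-driven orchestration of the full analysis into reproducible run directories.

A run config (YAML or dict) names a synthetic scenario (or input files), stage
toggles and every numeric default as an explicit key; unknown keys are
rejected and every stochastic stage must carry a seed. Stages execute in
dependency order (simulate/load -> QC -> frequencies -> f-statistics screen ->
dating -> IBD statistics -> differential screen -> ROH -> PCA -> supervised
ancestry), each writing one TSV into the run directory tagged with the config
hash; identical configs produce byte-identical outputs. When the input is
synthetic, a truth-vs-estimate report is added.

Exit codes used by the CLI: 0 ok, 2 config error, 3 data error, 4 numeric
failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    ancestry_structure,
    differential_screen,
    fstats,
    ibd_sharing,
    io_qc,
    synthetic_data,
    wld_dating,
)

log = logging.getLogger("popstrata")

_TOP_KEYS = {"scenario", "input", "stages", "qc", "fstats", "dating", "ibd", "screen", "ancestry"}
_STAGE_KEYS = {"qc", "fstats", "dating", "ibd", "screen", "roh", "pca", "ancestry"}
_QC_KEYS = {
    "min_snp_callrate",
    "max_ind_missing",
    "relatedness_threshold",
    "remove_ambiguous",
    "ld_prune",
    "r2_max",
    "window_snps",
    "step_snps",
}
_FSTATS_KEYS = {"n_blocks", "z_threshold", "groups"}
_DATING_KEYS = {"bin_width_cM", "d_min_cM", "d_max_cM", "generation_time", "targets"}
_IBD_KEYS = {"stitch_max_gap_cM", "min_cM"}
_SCREEN_KEYS = {"groups", "comparisons", "lower_pct", "upper_pct", "length_class"}
_ANCESTRY_KEYS = {"k_pca", "components", "n_sim_per_component", "seed", "tol", "max_iter"}


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(source) -> dict:
    """Load and validate a run config from a YAML path or a dict."""
    if isinstance(source, (str, Path)):
        cfg = yaml.safe_load(Path(source).read_text())
    else:
        cfg = dict(source)
    _check_keys(cfg, _TOP_KEYS, "config")
    if "scenario" not in cfg and "input" not in cfg:
        raise ConfigError("config needs a 'scenario' or 'input' section")
    if "scenario" in cfg and "seed" not in cfg["scenario"]:
        raise ConfigError("scenario section must set an explicit seed")
    for name, keys in [
        ("stages", _STAGE_KEYS),
        ("qc", _QC_KEYS),
        ("fstats", _FSTATS_KEYS),
        ("dating", _DATING_KEYS),
        ("ibd", _IBD_KEYS),
        ("screen", _SCREEN_KEYS),
        ("ancestry", _ANCESTRY_KEYS),
    ]:
        if name in cfg:
            _check_keys(cfg[name] or {}, keys, name)
    anc = cfg.get("ancestry", {})
    if cfg.get("stages", {}).get("ancestry", False) and "seed" not in anc:
        raise ConfigError("ancestry stage must set an explicit seed")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {chash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    log.info("wrote %s (%d rows)", path, len(df))


def run_pipeline(config, out_dir) -> Path:
    """Execute the configured stages; returns the run directory."""
    cfg = load_config(config)
    chash = config_hash(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg, sort_keys=True, indent=1))
    stages = {k: True for k in _STAGE_KEYS} | dict(cfg.get("stages", {}))

    scenario = None
    if "scenario" in cfg:
        scenario = synthetic_data.generate_scenario(cfg["scenario"])
        gm = scenario.genotypes
        segments = scenario.segments
        scenario.truth.save(out / "scenario")
    else:
        inp = cfg["input"]
        gm = io_qc.load_dataset(inp["prefix"], inp.get("format", "eigenstrat"))
        segments = (
            ibd_sharing.read_segments(inp["segments"]) if "segments" in inp else None
        )

    qc_cfg = dict(cfg.get("qc", {}))
    if stages.get("qc", True):
        log.info("QC: %d samples x %d variants in", gm.n_samples, gm.n_variants)
        if qc_cfg.get("remove_ambiguous", True):
            gm = io_qc.remove_ambiguous_sites(gm)
        gm = io_qc.apply_qc_filters(
            gm,
            float(qc_cfg.get("min_snp_callrate", 0.90)),
            float(qc_cfg.get("max_ind_missing", 0.01)),
        )
        if qc_cfg.get("ld_prune", False):
            gm = io_qc.ld_prune(
                gm,
                float(qc_cfg.get("r2_max", 0.1)),
                int(qc_cfg.get("window_snps", 50)),
                int(qc_cfg.get("step_snps", 10)),
            )
        log.info("QC: %d samples x %d variants out", gm.n_samples, gm.n_variants)
        io_qc.save_dataset(gm, out / "qc_data", "eigenstrat")

    freqs = fstats.population_freqs(gm)
    n_blocks = int(cfg.get("fstats", {}).get("n_blocks", min(fstats.DEFAULT_N_BLOCKS, gm.n_variants)))
    blocks = fstats.make_blocks(gm.variants, min(n_blocks, gm.n_variants))

    screen_table = None
    if stages.get("fstats", True):
        groups = cfg.get("fstats", {}).get("groups") or list(freqs.populations)
        screen_table = fstats.screen_trios(
            freqs, groups, blocks, float(cfg.get("fstats", {}).get("z_threshold", -2.0))
        )
        _write(screen_table, out / "f3_screen.tsv", chash)

    if stages.get("dating", True):
        dcfg = dict(cfg.get("dating", {}))
        targets = dcfg.get("targets", [])
        rows = []
        for t in targets:
            target, r1, r2 = t["target"], t["ref1"], t["ref2"]
            sub = gm.take_samples(
                np.flatnonzero(gm.samples["population"].to_numpy() == target)
            )
            curve = wld_dating.weighted_ld_curve(
                sub,
                freqs.freq[freqs.index_of(r1)],
                freqs.freq[freqs.index_of(r2)],
                float(dcfg.get("bin_width_cM", 0.1)),
                float(dcfg.get("d_min_cM", 0.5)),
                float(dcfg.get("d_max_cM", 30.0)),
            )
            date = wld_dating.fit_decay(curve)
            row = {
                "target": target,
                "ref1": r1,
                "ref2": r2,
                "G": date.G_hat,
                "se_G": date.se_G,
                "converged": date.converged,
            }
            if date.converged:
                date = wld_dating.to_years(
                    date, float(dcfg.get("generation_time", wld_dating.GENERATION_TIME_YEARS))
                )
                row |= {
                    "years": date.date_years,
                    "se_years": date.se_years,
                    "beyond_threshold": date.beyond_threshold,
                }
            rows.append(row)
        if rows:
            _write(pd.DataFrame(rows), out / "admixture_dates.tsv", chash)

    sharing = None
    if stages.get("ibd", True) and segments is not None:
        icfg = dict(cfg.get("ibd", {}))
        processed = ibd_sharing.filter_min_length(
            ibd_sharing.stitch_segments(segments, float(icfg.get("stitch_max_gap_cM", 0.5))),
            float(icfg.get("min_cM", 1.0)),
        )
        sample_pops = dict(zip(gm.samples["id"], gm.samples["population"]))
        # Segments may reference QC-dropped samples; keep labeled ones only.
        keep = processed.segments["sample_1"].isin(sample_pops) & processed.segments[
            "sample_2"
        ].isin(sample_pops)
        processed = ibd_sharing.IBDSegmentSet(processed.segments[keep], processed.provenance)
        sharing = ibd_sharing.sharing_matrix(processed, sample_pops)
        _write(sharing.to_frame(), out / "ibd_sharing.tsv", chash)
        summary = ibd_sharing.within_population_summary(processed, gm)
        _write(summary, out / "within_population.tsv", chash)

    if stages.get("screen", True) and sharing is not None and "screen" in cfg:
        scfg = dict(cfg["screen"])
        reports = differential_screen.run_screen(
            sharing,
            scfg["groups"],
            scfg["comparisons"],
            scfg.get("length_class", ibd_sharing.TOTAL_CLASS),
            float(scfg.get("lower_pct", 0.10)),
            float(scfg.get("upper_pct", 0.90)),
        )
        _write(differential_screen.screen_to_frame(reports), out / "difference_screen.tsv", chash)

    if stages.get("roh", True):
        runs = ibd_sharing.roh_to_frame(ibd_sharing.roh_detect(gm))
        _write(runs, out / "roh.tsv", chash)

    if stages.get("pca", True):
        k = int(cfg.get("ancestry", {}).get("k_pca", min(5, gm.n_samples - 1)))
        model = ancestry_structure.fit_pca(gm, k)
        _write(model.scores, out / "pca_scores.tsv", chash)

    if stages.get("ancestry", False):
        acfg = dict(cfg.get("ancestry", {}))
        comp_refs = acfg["components"]
        F = ancestry_structure.estimate_component_freqs(gm, comp_refs)
        qmat = ancestry_structure.supervised_q(
            gm, F, float(acfg.get("tol", 1e-6)), int(acfg.get("max_iter", 2000))
        )
        qdf = qmat.to_frame()
        qdf.insert(1, "population", gm.samples["population"].to_numpy())
        _write(qdf, out / "ancestry_q.tsv", chash)
        if scenario is not None:
            truth_q = scenario.truth.true_q.set_index("individual")
            comps = [c for c in qmat.components if c in truth_q.columns]
            est = qdf.set_index("individual")[comps]
            common = est.index.intersection(truth_q.index)
            err = (est.loc[common, comps] - truth_q.loc[common, comps]).abs().mean(axis=1)
            report = pd.DataFrame(
                {
                    "individual": common,
                    "population": truth_q.loc[common, "population"],
                    "mean_abs_error": err.to_numpy(),
                }
            )
            _write(report, out / "truth_vs_estimate.tsv", chash)
    return out
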