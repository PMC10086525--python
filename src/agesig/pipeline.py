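"""End-to-end orchestration: simulate -> associate -> MAG -> GSEA -> enrich ->
PVCA -> regulatory -> composition, from a single YAML-able config.

Every stage writes TSV outputs into the run directory and registers them in a
JSON manifest with SHA-256 hashes, the stage parameters and the seed, so a
re-run with the same config is hash-reproducible. A stage failure is recorded
as FAILED in the manifest (partial outputs retained) and aborts the run with
the failing stage named.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from agesig import composition as comp_mod
from agesig import conservation, diffassoc, pvca, regulatory, simdata
from agesig import io_formats, settests
from agesig.errors import AgesigError

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate", "diffassoc", "mag", "gsea", "enrich",
    "pvca", "regulatory", "composition",
]

DEPENDENCIES = {
    "simulate": [],
    "diffassoc": ["simulate"],
    "mag": ["diffassoc"],
    "gsea": ["mag"],
    "enrich": ["diffassoc"],
    "pvca": ["diffassoc"],
    "regulatory": ["simulate"],
    "composition": ["simulate"],
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"n_genes": 2000, "replicates_per_age": 4, "chrom_length": 2_000_000,
                 "n_peaks": 400, "footprints_per_group": 1500},
    "stages": {name: True for name in STAGE_ORDER},
    "thresholds": {
        "fdr_max": 0.05,
        "min_abs_log2fc": 1.0,
        "min_log2cpm": 1.0,
        "min_samples": 2,
        "purity_min": 0.9,
        "peak_min_support": 2,
        "promoter_window": 2000,
        "locus_window": 100_000,
        "profile_flank": 100,
    },
    "gsea": {"n_perm": 10_000, "weight_exponent": 1.0, "gene_set": "conserved"},
    "pvca": {"var_threshold": 0.6, "min_pcs": 3,
             "factors": ["strain", "tissue", "age_months", "sex"]},
    "inputs": {},  # counts/samples/gene-set paths when simulate is off
}


def merge_config(user: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label, float_format="%.10g")


class PipelineRun:
    """Holds in-memory stage products and the manifest during one run."""

    def __init__(self, config: dict, outdir: Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"seed": config["seed"], "stages": {}}
        self.data: dict = {}

    def record(self, stage: str, params: dict, outputs: list[Path], status: str = "COMPLETE"):
        self.manifest["stages"][stage] = {
            "status": status,
            "params": params,
            "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        }

    def write_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return path


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(run: PipelineRun) -> list[Path]:
    cfg = run.config
    sim_cfg = simdata.SimConfig(seed=cfg["seed"], **cfg.get("simulate", {}))
    if cfg.get("inputs", {}).get("counts"):
        counts, samples = io_formats.read_counts(
            cfg["inputs"]["counts"], cfg["inputs"]["samples"]
        )
        truth = None
    else:
        counts, samples, truth = simdata.generate_study(sim_cfg)
    run.data["sim_cfg"] = sim_cfg
    run.data["counts"], run.data["samples"], run.data["truth"] = counts, samples, truth
    out_counts = run.outdir / "counts.tsv"
    out_samples = run.outdir / "samples.tsv"
    io_formats.write_counts(counts, samples, out_counts, out_samples)
    outputs = [out_counts, out_samples]
    if truth is not None and truth.effects is not None:
        out_truth = run.outdir / "truth_effects.tsv"
        _write_tsv(truth.effects, out_truth, index=True, index_label="gene")
        outputs.append(out_truth)
    return outputs


def _stage_diffassoc(run: PipelineRun) -> list[Path]:
    thr = run.config["thresholds"]
    results = diffassoc.fit_all_strata(
        run.data["counts"], run.data["samples"],
        min_log2cpm=thr["min_log2cpm"], min_samples=thr["min_samples"],
    )
    called = {
        label: diffassoc.call_differential(
            df, fdr_max=thr["fdr_max"], min_abs_log2fc=thr["min_abs_log2fc"]
        )
        for label, df in results.items()
    }
    run.data["assoc"] = called
    outputs = []
    for label, df in called.items():
        path = run.outdir / f"assoc_{label.replace(':', '_')}.tsv"
        _write_tsv(df[["feature", "beta", "log2fc_span", "se", "p", "fdr",
                       "mean_log2cpm", "called", "direction"]], path)
        logger.info("stratum %s: %d features tested, %d called", label, len(df),
                    int(df["called"].sum()))
        outputs.append(path)
    return outputs


def _stage_mag(run: PipelineRun) -> list[Path]:
    sim_cfg = run.data["sim_cfg"]
    ranks = {label: conservation.rank_stratum(df) for label, df in run.data["assoc"].items()}
    mag = conservation.mag_scores(ranks, list(sim_cfg.strains), list(sim_cfg.tissues))
    run.data["mag"] = mag
    path = run.outdir / "mag.tsv"
    _write_tsv(mag, path, index=True, index_label="gene")
    return [path]


def _stage_gsea(run: PipelineRun) -> list[Path]:
    gcfg = run.config["gsea"]
    truth = run.data.get("truth")
    set_name = gcfg["gene_set"]
    if run.config.get("inputs", {}).get("gene_sets"):
        sets = io_formats.read_gmt(run.config["inputs"]["gene_sets"])
        gene_set = sets[set_name]
    elif truth is not None and set_name in truth.planted_sets:
        gene_set = truth.planted_sets[set_name]
    else:
        raise AgesigError(f"no gene set named {set_name!r} available")
    result = conservation.preranked_gsea(
        run.data["mag"]["mag_total"], gene_set, set_name=set_name,
        weight_exponent=gcfg["weight_exponent"], n_perm=gcfg["n_perm"],
        seed=run.config["seed"],
    )
    run.data["gsea"] = result
    summary = pd.DataFrame([{
        "set_name": result.set_name, "es": result.es, "nes": result.nes,
        "p": result.p, "n_perm": result.n_perm,
        "leading_edge": ",".join(result.leading_edge),
    }])
    out_sum = run.outdir / "gsea.tsv"
    out_trace = run.outdir / "gsea_running.tsv"
    _write_tsv(summary, out_sum)
    _write_tsv(result.running, out_trace)
    return [out_sum, out_trace]


def _stage_enrich(run: PipelineRun) -> list[Path]:
    truth = run.data.get("truth")
    collection = dict(truth.planted_sets) if truth is not None else {}
    if run.config.get("inputs", {}).get("gene_sets"):
        collection = io_formats.read_gmt(run.config["inputs"]["gene_sets"])
    outputs = []
    for label, df in run.data["assoc"].items():
        universe = set(df["feature"])
        query = set(df.loc[df["called"], "feature"])
        if not query or not collection:
            logger.info("stratum %s: no differential genes or no modules; enrichment skipped",
                        label)
            continue
        table = settests.hypergeom_enrich(query, collection, universe)
        path = run.outdir / f"enrich_{label.replace(':', '_')}.tsv"
        _write_tsv(table, path)
        outputs.append(path)
    return outputs


def _stage_pvca(run: PipelineRun) -> list[Path]:
    pcfg = run.config["pvca"]
    counts, samples = run.data["counts"], run.data["samples"]
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    log_cpm = np.log2(counts.to_numpy(dtype=float) / lib * 1e6 + 0.5)
    features = pd.DataFrame(log_cpm, index=counts.index, columns=counts.columns)
    factors = samples[[c for c in pcfg["factors"] if c in samples.columns]].astype(str)
    result = pvca.pvca_decompose(
        features, factors, var_threshold=pcfg["var_threshold"], min_pcs=pcfg["min_pcs"]
    )
    run.data["pvca"] = result
    path = run.outdir / "pvca.tsv"
    _write_tsv(result.to_frame(), path)
    report = run.outdir / "pvca_pcs.tsv"
    _write_tsv(result.per_pc, report, index=True, index_label="pc")
    return [path, report]


def _stage_regulatory(run: PipelineRun) -> list[Path]:
    thr = run.config["thresholds"]
    sim_cfg = run.data["sim_cfg"]
    per_sample_peaks, footprints, cut_signal, reg_truth = simdata.generate_regulatory(sim_cfg)
    run.data["reg_truth"] = reg_truth
    consensus = regulatory.build_consensus_peaks(
        per_sample_peaks, min_support=thr["peak_min_support"]
    )
    fp = regulatory.footprint_filter(footprints, min_purity=thr["purity_min"])
    proportions = regulatory.footprint_proportions(fp)

    # assign consensus peaks their underlying region status by position
    region_status = _region_status_by_position(per_sample_peaks, consensus)
    opening = consensus[region_status == "opening"]
    closing = consensus[region_status == "closing"]
    stable = consensus[region_status == "stable"]

    ages = sorted(sim_cfg.ages_months)
    enrich_by_stratum = {}
    for strain, tissue in sim_cfg.strata:
        old_fp = fp[(fp["strain"] == strain) & (fp["tissue"] == tissue)
                    & (fp["age_months"] == ages[-1])]
        if len(old_fp) == 0:
            continue
        enrich_by_stratum[f"{strain}:{tissue}"] = regulatory.footprint_peak_enrichment(
            old_fp, opening, closing, stable
        )
    support = regulatory.pan_stratum_support(enrich_by_stratum)
    enriched_sets = {
        label: set(df.loc[(df["direction"] == "opening") & df["enriched"], "tf"])
        for label, df in enrich_by_stratum.items()
    }
    upset, shared_all = regulatory.shared_tf_sets(enriched_sets) if enriched_sets else (
        pd.DataFrame(columns=["combination", "n_strata", "count"]), 0)
    logger.info("opening-peak enriched TFs shared by all strata: %d", shared_all)

    profiles = []
    for (strain, tissue, age), signal in cut_signal.items():
        grp = fp[(fp["strain"] == strain) & (fp["tissue"] == tissue)
                 & (fp["age_months"] == age)]
        centers = ((grp["start"] + grp["end"]) // 2).to_numpy()
        if len(centers) == 0:
            continue
        profile, n_used, _ = regulatory.aggregate_cut_profile(
            signal, centers, flank=thr["profile_flank"]
        )
        flank = thr["profile_flank"]
        profiles.append(pd.DataFrame({
            "offset": np.arange(-flank, flank + 1),
            "group": f"{strain}:{tissue}:{age:g}m",
            "mean_normalized_cuts": profile,
        }))
    profile_df = pd.concat(profiles, ignore_index=True) if profiles else pd.DataFrame(
        columns=["offset", "group", "mean_normalized_cuts"])

    outputs = []
    for name, df in [
        ("consensus_peaks.tsv", consensus),
        ("footprint_proportions.tsv", proportions),
        ("footprint_enrichment.tsv", pd.concat(
            [df.assign(stratum=label) for label, df in enrich_by_stratum.items()],
            ignore_index=True) if enrich_by_stratum else pd.DataFrame()),
        ("tf_pan_stratum.tsv", support),
        ("tf_upset.tsv", upset),
        ("cut_profiles.tsv", profile_df),
    ]:
        path = run.outdir / name
        _write_tsv(df, path)
        outputs.append(path)
    return outputs


def _region_status_by_position(per_sample_peaks, consensus) -> np.ndarray:
    """Label each consensus peak opening/closing/stable via the generator's
    region names (carried in the per-sample peak names)."""
    stacked = pd.concat(per_sample_peaks.values(), ignore_index=True)
    status = np.full(len(consensus), "stable", dtype=object)
    if "name" not in stacked.columns or len(consensus) == 0:
        return status
    stacked = stacked.sort_values("start")
    starts = stacked["start"].to_numpy()
    names = stacked["name"].to_numpy(dtype=object)
    for i, row in enumerate(consensus.itertuples(index=False)):
        j = np.searchsorted(starts, row.start, side="left")
        if j < len(names):
            name = str(names[j])
            for label in ("opening", "closing"):
                if name.endswith(label):
                    status[i] = label
    return status


def _stage_composition(run: PipelineRun) -> list[Path]:
    sim_cfg = run.data["sim_cfg"]
    table, truth = simdata.generate_composition(sim_cfg)
    trends = comp_mod.fit_composition_trends(table)
    run.data["composition"] = trends
    run.data["composition_truth"] = truth
    out_table = run.outdir / "composition.tsv"
    out_trends = run.outdir / "composition_trends.tsv"
    _write_tsv(table, out_table)
    _write_tsv(trends, out_trends)
    return [out_table, out_trends]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "diffassoc": _stage_diffassoc,
    "mag": _stage_mag,
    "gsea": _stage_gsea,
    "enrich": _stage_enrich,
    "pvca": _stage_pvca,
    "regulatory": _stage_regulatory,
    "composition": _stage_composition,
}


def resolve_stages(requested: dict[str, bool]) -> list[str]:
    """Enabled stages plus their transitive dependencies, in run order."""
    enabled = {s for s in STAGE_ORDER if requested.get(s, True)}
    changed = True
    while changed:
        changed = False
        for s in list(enabled):
            for dep in DEPENDENCIES[s]:
                if dep not in enabled:
                    enabled.add(dep)
                    changed = True
    return [s for s in STAGE_ORDER if s in enabled]


def run_pipeline(config: dict | None = None, outdir="agesig_run") -> PipelineRun:
    """Run all enabled stages; returns the :class:`PipelineRun` with products.

    The manifest (JSON) lists per-stage status, parameters and output hashes;
    a failing stage is marked FAILED, the manifest is still written, and the
    error is re-raised naming the stage.
    """
    cfg = merge_config(config)
    run = PipelineRun(cfg, Path(outdir))
    stages = resolve_stages(cfg["stages"])
    for stage in stages:
        params = {k: v for k, v in cfg.items() if k in (stage, "thresholds", "seed")}
        try:
            outputs = _STAGE_FUNCS[stage](run)
        except Exception as exc:
            run.record(stage, params, [], status="FAILED")
            run.write_manifest()
            raise AgesigError(f"stage {stage!r} failed: {exc}") from exc
        run.record(stage, params, outputs)
    run.write_manifest()
    return run
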