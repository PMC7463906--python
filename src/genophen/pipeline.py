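"""End-to-end orchestration of the two published analyses.

``run_resting`` reproduces the resting-state predictability analysis:
per-locus genetic distance matrices, the ITS_LSU neighbor-joining tree
with bootstrap, FTIR and LC-MS clustering of the control samples, and
the whole-profile marker-vs-phenotype correlation ranking.

``run_stress`` reproduces the stress-predictivity analysis: mortality
table, per-marker PSW trajectories across ethanol doses with trend
classes, and the region-wise maximum-correlation table for control vs
pooled stressed spectra.

Inputs come either from a :class:`~genophen.synthdata.ScenarioConfig`
(simulated on the fly) or from a directory of files previously written
by ``simulate``. Every random stage derives its seed from the run seed,
so a rerun with the same configuration is identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlate, ftir, metabolome, seqdist, synthdata
from .distmat import DistanceMatrix
from .ftir import SpectrumSet
from .metabolome import FeatureTable

__all__ = ["RunConfig", "RestingReport", "StressReport", "simulate", "run_resting", "run_stress", "run_all"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Inputs, thresholds and model choices for one pipeline run.

    Exactly one of ``scenario`` (simulate inputs) or ``input_dir`` (a
    directory produced by :func:`simulate`) must be set.
    """

    scenario: synthdata.ScenarioConfig | None = None
    input_dir: str | Path | None = None
    out_dir: str | Path | None = None
    correlation_threshold: float = 0.75
    vip_threshold: float = 1.0
    snr_threshold: float = 4000.0
    trend_split: float = 5.0
    iqr_drop_fraction: float = 0.1
    model: str = "K80"
    deletion: str = "complete"
    bootstrap_reps: int = 1000
    #: windows concatenated for the whole-profile FTIR distance
    #: (fatty-acid plus amide/mixed block)
    profile_regions: tuple[str, ...] = ("W1", "W2", "W3")
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.input_dir is None):
            raise ValueError("set exactly one of scenario or input_dir")
        for name in ("correlation_threshold", "vip_threshold", "snr_threshold", "trend_split"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class RestingReport:
    distances: dict[str, DistanceMatrix] = field(repr=False)
    tree_newick: str
    correlations: pd.DataFrame = field(repr=False)
    ftir_dendrogram: metabolome.Dendrogram = field(repr=False)
    lcms_dendrogram: metabolome.Dendrogram = field(repr=False)
    selected_metabolites: tuple[str, ...] = ()


@dataclass(frozen=True)
class StressReport:
    mortality: pd.DataFrame = field(repr=False)
    psw_trends: tuple[correlate.PSWTrend, ...]
    scan_table: pd.DataFrame = field(repr=False)
    region_table: pd.DataFrame = field(repr=False)


# ---------------------------------------------------------------------------
# input handling
# ---------------------------------------------------------------------------


def simulate(scenario: synthdata.ScenarioConfig, out_dir) -> Path:
    """Write all synthetic inputs for a scenario; returns the directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    synthdata.write_scenario_outputs(scenario, out_dir)
    return out_dir


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        sc = config.scenario
        alignments = synthdata.simulate_alignments(sc)
        sset = synthdata.simulate_spectra(sc, alignments)
        table = synthdata.simulate_feature_table(sc, alignments=alignments)
        viability = synthdata.simulate_viability(sc)
        return alignments, sset, table, viability
    d = Path(config.input_dir)
    alignments = {}
    for p in sorted((d / "loci").glob("*.fasta")):
        alignments[p.stem] = seqdist.read_alignment_fasta(p)
    if not alignments:
        raise ValueError(f"no loci FASTA files under {d / 'loci'}")
    sset = ftir.read_spectra_csv(d / "spectra.csv")
    table = metabolome.read_feature_csv(d / "features.csv")
    viability = pd.read_csv(d / "viability.csv")
    return alignments, sset, table, viability


def _marker_distances(alignments, model, deletion) -> dict[str, DistanceMatrix]:
    """Per-locus distances plus the ITS_LSU concatenation when available."""
    out = {
        name: seqdist.evolutionary_distance(aln, model, deletion)
        for name, aln in sorted(alignments.items())
    }
    if "ITS" in alignments and "LSU" in alignments and "ITS_LSU" not in out:
        concat = seqdist.concatenate(
            [alignments["ITS"], alignments["LSU"]], name="ITS_LSU"
        )
        out["ITS_LSU"] = seqdist.evolutionary_distance(concat, model, deletion)
    return out


def _subset_table(table: FeatureTable, mask: np.ndarray) -> FeatureTable:
    return FeatureTable(
        table.data.loc[mask], table.meta.loc[mask].reset_index(drop=True), table.state
    )


def _processed_features(table: FeatureTable, drop_fraction: float) -> FeatureTable:
    return metabolome.pareto_scale(
        metabolome.median_normalize(metabolome.iqr_filter(table, drop_fraction))
    )


def _strain_means(table: FeatureTable) -> pd.DataFrame:
    df = table.data.copy()
    df["strain"] = table.meta["strain"].to_numpy()
    return df.groupby("strain", sort=True).mean()


def _lcms_log_profiles(table: FeatureTable, drop_fraction: float) -> pd.DataFrame:
    """Strain-mean log2 profiles for whole-profile distances.

    IQR filter, median normalization, log2 and per-sample centering
    (the log-space analogue of vector normalization, removing loading
    offsets); Pareto scaling is reserved for VIP/HCA, where the
    variable-wise reweighting is wanted.
    """
    norm = metabolome.median_normalize(metabolome.iqr_filter(table, drop_fraction))
    logdata = np.log2(norm.data)
    logdata = logdata.sub(logdata.mean(axis=1), axis=0)
    logdata["strain"] = norm.meta["strain"].to_numpy()
    return logdata.groupby("strain", sort=True).mean()


# ---------------------------------------------------------------------------
# resting-state analysis
# ---------------------------------------------------------------------------


def run_resting(config: RunConfig) -> RestingReport:
    """Resting-condition predictability analysis (control samples only)."""
    t0 = time.time()
    alignments, sset, table, _ = _load_inputs(config)
    distances = _marker_distances(alignments, config.model, config.deletion)
    control = float(np.min(sset.meta["condition"]))

    # ITS_LSU NJ tree with bootstrap
    if "ITS" in alignments and "LSU" in alignments:
        concat = seqdist.concatenate([alignments["ITS"], alignments["LSU"]], name="ITS_LSU")
        tree = seqdist.bootstrap_support(
            concat, config.model, config.deletion, config.bootstrap_reps, config.seed
        )
        tree_newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    else:
        tree_newick = ""

    # FTIR side: preprocess, keep control condition, average replicates
    proc = ftir.preprocess(sset)
    ctrl_mask = (proc.meta["condition"] == control).to_numpy()
    ctrl = proc.subset(ctrl_mask)
    avg = ftir.average_replicates(ctrl, by=["strain"])
    strains = sorted(avg.meta["strain"])
    region_blocks = ftir.concat_regions(
        avg, getattr(config.scenario, "region_map", ftir.DEFAULT_REGIONS)
        if config.scenario is not None
        else ftir.DEFAULT_REGIONS,
        config.profile_regions,
    )
    ftir_profiles = pd.DataFrame(region_blocks, index=list(avg.meta["strain"])).loc[strains]
    ftir_D = correlate.profile_distance(ftir_profiles)
    ftir_dend = metabolome.hca(ftir_profiles, distance="euclidean")

    # LC-MS side: whole-profile distances on strain-mean log2 profiles,
    # Pareto-scaled chain for VIP selection
    lc_mask = (table.meta["condition"] == control).to_numpy()
    lc_sub = _subset_table(table, lc_mask)
    lc_profiles = _lcms_log_profiles(lc_sub, config.iqr_drop_fraction).loc[strains]
    lcms_D = correlate.profile_distance(lc_profiles)
    lcms_dend = metabolome.hca(lc_profiles, distance="spearman")
    lc_proc = _processed_features(lc_sub, config.iqr_drop_fraction)

    # VIP selection on the processed control table
    vip = metabolome.plsda_vip(lc_proc)
    selected = tuple(metabolome.select_discriminant(vip, config.vip_threshold))

    rows = []
    for marker, D in distances.items():
        for target, pheno_D in (("FTIR", ftir_D), ("LC-MS", lcms_D)):
            perm = correlate.matrix_correlation(D, pheno_D, "permutation", seed=config.seed)
            para = correlate.matrix_correlation(D, pheno_D, "parametric_t")
            rows.append(
                {
                    "marker": marker,
                    "target": target,
                    "r": perm.r,
                    "p_permutation": perm.p_value,
                    "p_parametric": para.p_value,
                    "significant": perm.r > config.correlation_threshold,
                }
            )
    correlations = pd.DataFrame(rows).sort_values(
        ["target", "r"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)

    report = RestingReport(
        distances, tree_newick, correlations, ftir_dend, lcms_dend, selected
    )
    if config.out_dir is not None:
        _write_resting(config, report, time.time() - t0)
    return report


def _echo_config(config: RunConfig, out: Path) -> None:
    cfg = dataclasses.asdict(config)
    for key in ("input_dir", "out_dir"):
        if cfg[key] is not None:
            cfg[key] = str(cfg[key])
    if config.scenario is not None:
        cfg["scenario"]["region_map"] = {
            k: list(v) for k, v in config.scenario.region_map.items()
        }
    with open(out / "run_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=list)


def _write_resting(config: RunConfig, report: RestingReport, wall: float) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_config(config, out)
    (out / "distances").mkdir(exist_ok=True)
    for marker, D in report.distances.items():
        D.write_csv(out / "distances" / f"{marker}.csv")
    if report.tree_newick:
        (out / "its_lsu_nj.nwk").write_text(report.tree_newick + "\n")
    report.correlations.to_csv(out / "marker_correlations.csv", index=False)
    (out / "ftir_hca.nwk").write_text(
        metabolome.dendrogram_to_newick(report.ftir_dendrogram) + "\n"
    )
    (out / "lcms_hca.nwk").write_text(
        metabolome.dendrogram_to_newick(report.lcms_dendrogram) + "\n"
    )
    (out / "selected_metabolites.txt").write_text(
        "\n".join(report.selected_metabolites) + "\n"
    )
    ranked = report.correlations[report.correlations["target"] == "LC-MS"]
    top = ranked.iloc[0] if len(ranked) else None
    summary = [
        "resting-state analysis",
        f"markers: {len(report.distances)}",
        f"discriminant metabolites (VIP > {config.vip_threshold}): {len(report.selected_metabolites)}",
    ]
    if top is not None:
        summary.append(f"best LC-MS marker: {top['marker']} (r={top['r']:.3f})")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    _write_log(out, "resting", config.seed, wall, {"n_markers": len(report.distances)})


# ---------------------------------------------------------------------------
# stress analysis
# ---------------------------------------------------------------------------


def run_stress(config: RunConfig) -> StressReport:
    """Short-term ethanol-stress predictivity analysis."""
    t0 = time.time()
    alignments, sset, _, viability = _load_inputs(config)
    conditions = sorted(set(sset.meta["condition"]))
    if len(conditions) < 3:
        raise ValueError("stress analysis needs >= 3 conditions")
    distances = _marker_distances(alignments, config.model, config.deletion)
    mort = metabolome.mortality_table(viability)

    proc = ftir.preprocess(sset)
    trends = []
    scan_rows = []
    for marker, D in distances.items():
        scans = correlate.scan_spectra_by_condition(D, proc, marker, p_values=False)
        trend = correlate.psw_trend(
            marker, scans, config.correlation_threshold, config.trend_split
        )
        trends.append(trend)
        for cond, scan in scans.items():
            for w, r in zip(scan.descriptors, scan.r):
                scan_rows.append(
                    {"marker": marker, "condition": cond, "descriptor": w, "r": r}
                )
    scan_table = pd.DataFrame(scan_rows)

    region_map = (
        config.scenario.region_map if config.scenario is not None else ftir.DEFAULT_REGIONS
    )
    region_table = correlate.region_max_correlation(
        distances,
        proc,
        region_map,
        control_condition=conditions[0],
        threshold=config.correlation_threshold,
    )
    report = StressReport(mort, tuple(trends), scan_table, region_table)
    if config.out_dir is not None:
        _write_stress(config, report, time.time() - t0)
    return report


def _write_stress(config: RunConfig, report: StressReport, wall: float) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_config(config, out)
    report.mortality.to_csv(out / "mortality.csv", index=False)
    report.scan_table.to_csv(out / "descriptor_scan.csv", index=False)
    report.region_table.to_csv(out / "region_max_correlation.csv", index=False)
    rows = []
    for t in report.psw_trends:
        for cond, val in zip(t.conditions, t.psw_percent):
            rows.append(
                {
                    "marker": t.marker,
                    "condition": cond,
                    "psw_percent": val,
                    "trend_class": t.trend_class,
                }
            )
    pd.DataFrame(rows).to_csv(out / "psw_trends.csv", index=False)
    lines = ["stress analysis", f"markers: {len(report.psw_trends)}"]
    for t in report.psw_trends:
        vals = ", ".join(f"{v:.2f}" for v in t.psw_percent)
        lines.append(f"{t.marker}: PSW [{vals}] -> {t.trend_class}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    _write_log(
        out,
        "stress",
        config.seed,
        wall,
        {
            "n_markers": len(report.psw_trends),
            "scan_rows": int(len(report.scan_table)),
            "correlation_threshold": config.correlation_threshold,
            "trend_split": config.trend_split,
        },
    )


def _write_log(out: Path, stage: str, seed: int, wall: float, extra: dict) -> None:
    entry = {"stage": stage, "seed": seed, "wall_seconds": round(wall, 3), **extra}
    with open(out / "run_log.json", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def run_all(config: RunConfig) -> tuple[RestingReport, StressReport]:
    """simulate (when a scenario is given) + resting + stress."""
    if config.scenario is not None and config.out_dir is not None:
        simulate(config.scenario, Path(config.out_dir) / "inputs")
    resting = run_resting(
        replace(config, out_dir=None if config.out_dir is None else Path(config.out_dir) / "resting")
    )
    stress = run_stress(
        replace(config, out_dir=None if config.out_dir is None else Path(config.out_dir) / "stress")
    )
    return resting, stress
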