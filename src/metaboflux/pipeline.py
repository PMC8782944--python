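"""End-to-end orchestration: simulate -> (optional NMR round trip) ->
stats -> co-regulation network -> FBA, with per-stage derived seeds, a
structured log and a hash manifest for reproducibility checks."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import coreg, nmr, stats, synthetic
from .config import RunConfig
from .flux import (
    analyze_flux_distributions,
    load_network,
    reduced_cardiomyocyte_network,
    solve_cohort,
    subsystem_enrichment,
)
from .table import ConcentrationTable, read_table

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Fixed derivation of per-stage seeds from the single global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns (and writes) a manifest mapping every output file to its
    content hash; a failed stage is recorded and earlier outputs are kept.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    table: ConcentrationTable | None = None
    significant: dict[str, list[str]] = {}

    def record(stage: str, outputs: list[Path], status: str = "ok",
               error: str | None = None) -> None:
        entry: dict = {"status": status,
                       "outputs": {str(p): _sha256(p) for p in outputs}}
        if error:
            entry["error"] = error
        manifest["stages"][stage] = entry

    def wants(stage: str) -> bool:
        return stage in config.stages

    try:
        if wants("simulate"):
            design = config.resolved_design()
            design.seed = stage_seed(config.seed, "simulate")
            table = synthetic.generate_concentration_table(design)
            path = out_dir / "concentrations.csv"
            table.write_csv(path)
            record("simulate", [path])
        elif config.table:
            table = read_table(config.table)
    except Exception as exc:  # noqa: BLE001 - manifest must record failures
        logger.exception("simulate stage failed")
        record("simulate", [], status="failed", error=str(exc))
        _write_manifest(manifest, out_dir)
        return manifest

    if wants("nmr") and table is not None:
        try:
            outputs = _nmr_stage(table, config, out_dir)
            record("nmr", outputs)
        except Exception as exc:  # noqa: BLE001
            logger.exception("nmr stage failed")
            record("nmr", [], status="failed", error=str(exc))

    augmented = table
    if wants("stats") and table is not None:
        try:
            augmented = stats.derived_indices(table)
            outputs = []
            for tissue in sorted(set(augmented.data["tissue"])):
                results = stats.compare_all(augmented, tissue, alpha=config.alpha)
                path = out_dir / f"stats_{tissue}.csv"
                results.to_csv(path, index=False)
                outputs.append(path)
                significant[tissue] = list(
                    results.loc[results["significant"], "metabolite"]
                )
            record("stats", outputs)
        except Exception as exc:  # noqa: BLE001
            logger.exception("stats stage failed")
            record("stats", [], status="failed", error=str(exc))

    if wants("network") and table is not None:
        try:
            outputs = []
            for tissue, mets in significant.items():
                mets = [m for m in mets if "/" not in m]  # ratio indices stay out
                if len(mets) < 2:
                    logger.info("network: %s has < 2 significant metabolites", tissue)
                    continue
                graph = coreg.build_network(
                    augmented, mets, threshold=config.threshold, tissue=tissue
                )
                gpath = out_dir / f"network_{tissue}.graphml"
                coreg.export_network(graph, gpath)
                epath = out_dir / f"edges_{tissue}.csv"
                coreg.edge_list(graph).to_csv(epath, index=False)
                outputs += [gpath, epath]
            record("network", outputs)
        except Exception as exc:  # noqa: BLE001
            logger.exception("network stage failed")
            record("network", [], status="failed", error=str(exc))

    if wants("fba") and table is not None:
        try:
            outputs = _fba_stage(table, config, out_dir)
            record("fba", outputs)
        except Exception as exc:  # noqa: BLE001
            logger.exception("fba stage failed")
            record("fba", [], status="failed", error=str(exc))

    _write_manifest(manifest, out_dir)
    return manifest


def _nmr_stage(table: ConcentrationTable, config: RunConfig,
               out_dir: Path) -> list[Path]:
    """Simulate one FID per sample from the library-covered metabolites and
    quantify it back — a per-sample processing round trip."""
    library = synthetic.DEFAULT_PEAK_LIBRARY
    regions = (nmr.read_regions(config.regions) if config.regions
               else synthetic.regions_for_library(library))
    covered = [e.metabolite for e in library if e.metabolite != nmr.TSP]
    tsp_amount = 0.3  # µmol, matching the table's µmol/g scale
    rows = []
    for _, row in table.data.iterrows():
        conc = {m: float(row[m]) for m in covered if m in table.data.columns}
        conc[nmr.TSP] = tsp_amount / row["wet_weight_g"]
        fid = synthetic.generate_fid(
            conc, library=library, noise_sd=0.0,
            seed=stage_seed(config.seed, f"nmr:{row['sample_id']}"),
        )
        result = nmr.process_fid(
            fid, regions, tsp_nmol=tsp_amount, wet_weight_g=row["wet_weight_g"],
            lb_hz=config.lb_hz, sample_id=str(row["sample_id"]),
        )
        rows.append({"sample_id": result.sample_id, "tissue": row["tissue"],
                     "group": row["group"], "wet_weight_g": row["wet_weight_g"],
                     **result.concentrations})
    path = out_dir / "nmr_quantified.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


def _fba_stage(table: ConcentrationTable, config: RunConfig,
               out_dir: Path) -> list[Path]:
    network = (load_network(config.fba.network) if config.fba.network
               else reduced_cardiomyocyte_network())
    distributions = solve_cohort(
        network, table, tissue=config.fba.tissue,
        reference_group=config.fba.reference_group, v_max=config.fba.v_max,
    )
    sub = table.subset(config.fba.tissue)
    groups = dict(zip(sub.data["sample_id"], sub.data["group"]))
    analysis = analyze_flux_distributions(distributions, groups, network=network)

    flux_rows = [
        {"sample_id": d.sample_id, "reaction_id": rid, "flux": flux}
        for d in distributions for rid, flux in d.fluxes.items()
    ]
    outputs = []
    fpath = out_dir / "fluxes.csv"
    pd.DataFrame(flux_rows).to_csv(fpath, index=False)
    outputs.append(fpath)
    spath = out_dir / "pca_scores.csv"
    analysis.scores.to_csv(spath, index_label="sample_id")
    outputs.append(spath)
    cpath = out_dir / "clusters.csv"
    analysis.cluster_labels.rename("cluster").to_csv(cpath, index_label="sample_id")
    outputs.append(cpath)

    loadings = analysis.loadings.loc["PC1"].abs()
    selected = set(loadings[loadings >= loadings.quantile(0.75)].index)
    epath = out_dir / "enrichment.csv"
    subsystem_enrichment(selected, network).to_csv(epath, index=False)
    outputs.append(epath)

    readouts = pd.DataFrame({
        "ros_flux": analysis.ros_flux,
        "lactate_efflux": analysis.lactate_efflux,
    })
    rpath = out_dir / "readouts.csv"
    readouts.to_csv(rpath, index_label="sample_id")
    outputs.append(rpath)
    return outputs


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
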