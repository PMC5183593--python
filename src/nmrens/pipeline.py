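"""Config-driven orchestration of the full analysis sequence.

A single :class:`AnalysisConfig` (usually loaded from YAML) names the input
structures and tables, the residue selections (rigid core, N-terminal span,
loop anchor residues) and the analysis parameters, and
:func:`run_pipeline` executes the stages in order, writing one JSON report
plus per-stage TSV tables into the output directory.  Stages are isolated:
a failing stage is logged and the remaining independent stages still run;
the report records per-stage status.

The default selections ship with the NGF residue definitions (core
15–22, 51–58, 78–89, 100–111; N-terminal donor span 2–10; loop II anchor
residue 46; loop V anchor residue 95) so that an accession-based run needs
only file paths.
"""

from __future__ import annotations

import json
import logging
import sys
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .clustering import daura_cluster, representative
from .csp_epitope import TitrationSeries, titration_report
from .geometry import ca_distance, cross_rmsd, ensemble_rmsd, rmsf
from .helicity import HelixCriteria, helical_fraction, nterm_hbond_report
from .io_formats import (
    Selection,
    read_multimodel_pdb,
    read_peak_table,
    read_relaxation_table,
)
from .relaxation import estimate_tau_c, flexibility_flags

logger = logging.getLogger("nmrens.pipeline")

REPORT_SCHEMA_VERSION = 1

NGF_CORE_RANGES = ((15, 22), (51, 58), (78, 89), (100, 111))


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs; paths resolve relative to the config file."""

    ensemble_path: str = ""
    reference_structures: dict[str, str] = field(default_factory=dict)
    relaxation_table: Optional[str] = None
    peak_tables: list[str] = field(default_factory=list)  # reference first
    titration_equivalents: list[float] = field(default_factory=list)
    output_dir: str = "results/pipeline"
    core_ranges: tuple = NGF_CORE_RANGES
    nterm_span: tuple[int, int] = (2, 10)
    helix_span: tuple[int, int] = (6, 10)
    loop_anchors: tuple[int, ...] = (46, 95)
    cluster_cutoff: float = 1.5  # Å (= 0.15 nm)
    field_mhz: float = 600.0
    csp_alpha: float = 0.14
    contact_cutoff: float = 8.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        base = path.parent

        def resolve(p):
            return str((base / p).resolve()) if p and not Path(p).is_absolute() else p

        cfg.ensemble_path = resolve(cfg.ensemble_path)
        cfg.reference_structures = {
            k: resolve(v) for k, v in cfg.reference_structures.items()
        }
        cfg.relaxation_table = resolve(cfg.relaxation_table)
        cfg.peak_tables = [resolve(p) for p in cfg.peak_tables]
        cfg.core_ranges = tuple(tuple(r) for r in cfg.core_ranges)
        cfg.nterm_span = tuple(cfg.nterm_span)
        cfg.helix_span = tuple(cfg.helix_span)
        return cfg


def _stage(report: dict, name: str, fn) -> None:
    try:
        report["stages"][name] = {"status": "ok", "result": fn()}
        logger.info("stage %s: ok", name)
    except Exception as exc:  # noqa: BLE001 — stage isolation is the contract
        logger.error("stage %s failed: %s", name, exc)
        report["stages"][name] = {
            "status": "error",
            "error": f"{type(exc).__name__}: {exc}",
            "traceback": traceback.format_exc(),
        }


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every configured stage; return (and write) the report dict.

    The report's ``any_failures`` flag is what the CLI exit code reflects.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "nmrens_version": __version__,
        "seed": config.seed,
        "parameters": {
            "core_ranges": [list(r) for r in config.core_ranges],
            "nterm_span": list(config.nterm_span),
            "helix_span": list(config.helix_span),
            "loop_anchors": list(config.loop_anchors),
            "cluster_cutoff_A": config.cluster_cutoff,
            "field_mhz": config.field_mhz,
            "csp_alpha": config.csp_alpha,
            "contact_cutoff_A": config.contact_cutoff,
        },
        "stages": {},
    }

    ensemble = None
    if config.ensemble_path:
        try:
            ensemble = read_multimodel_pdb(config.ensemble_path)
            report["stages"]["read_ensemble"] = {
                "status": "ok",
                "result": {"n_models": len(ensemble),
                           "n_topology_atoms": len(ensemble.topology_key)},
            }
        except Exception as exc:  # noqa: BLE001
            report["stages"]["read_ensemble"] = {
                "status": "error", "error": str(exc)}

    if ensemble is not None:
        chains = ensemble.models[0].chains

        def stage_ensemble_rmsd():
            res = ensemble_rmsd(ensemble, Selection.backbone())
            rows = ["model\trmsd_A"] + [
                f"{i + 1}\t{v:.4f}" for i, v in enumerate(res.per_model)
            ]
            (out / "ensemble_rmsd.tsv").write_text("\n".join(rows) + "\n")
            return {"mean_A": res.mean, "sd_A": res.sd,
                    "reference_model": res.reference_index + 1}

        _stage(report, "ensemble_rmsd", stage_ensemble_rmsd)

        if config.reference_structures:
            def stage_core_rmsd():
                sel = Selection.backbone(residue_ranges=config.core_ranges)
                vals = {}
                for label, path in config.reference_structures.items():
                    ref = read_multimodel_pdb(path).models[0]
                    r, cmap = cross_rmsd(ensemble.models[0], ref, sel)
                    vals[label] = {"rmsd_A": r, "chain_map": cmap}
                return vals

            _stage(report, "core_rmsd_vs_references", stage_core_rmsd)
        else:
            report["stages"]["core_rmsd_vs_references"] = {
                "status": "skipped", "reason": "no reference structures"}

        def stage_rmsf():
            prof = rmsf(ensemble)
            rows = ["chain\tres_seq\trmsf_A"] + [
                f"{c}\t{r}\t{v:.4f}" for (c, r), v in sorted(prof.values.items())
            ]
            (out / "rmsf.tsv").write_text("\n".join(rows) + "\n")
            loop_res = set(config.loop_anchors)
            return {"n_residues": len(prof.values),
                    "max_rmsf_A": max(prof.values.values()),
                    "anchor_rmsf_A": {
                        str(r): prof.values.get((chains[0], r))
                        for r in loop_res}}

        _stage(report, "rmsf", stage_rmsf)

        def stage_nterm():
            df, summary = nterm_hbond_report(ensemble, chains[0], config.nterm_span)
            df.to_csv(out / "nterm_hbonds.tsv", sep="\t", index=False)
            prof = helical_fraction(ensemble, chains[0], config.helix_span,
                                    HelixCriteria())
            prof.to_frame().to_csv(out / "helicity_labels.tsv", sep="\t",
                                   index=False)
            return {
                "bundle_min_A": summary["min"],
                "bundle_max_A": summary["max"],
                "segment_fraction": prof.segment_fraction,
                "fraction_helical": {
                    str(r): v for r, v in prof.fraction_helical.items()},
            }

        _stage(report, "nterm_helicity", stage_nterm)

        def stage_distances():
            vals = {}
            for anchor in config.loop_anchors:
                if len(chains) >= 2:
                    d = ca_distance(ensemble.models[0], chains[0], anchor,
                                    chains[1], anchor)
                    vals[f"ca_{anchor}_{anchor}"] = d
            if not vals:
                raise ValueError("need two chains for inter-protomer distances")
            return {"interprotomer_A": vals}

        _stage(report, "interprotomer_distances", stage_distances)

        def stage_cluster():
            res = daura_cluster(ensemble, Selection.backbone(),
                                config.cluster_cutoff)
            rows = ["cluster\tcenter_model\tsize\tmembers"]
            for i, (c, members) in enumerate(res.clusters, 1):
                rows.append(f"{i}\t{c + 1}\t{len(members)}\t"
                            + ",".join(str(m + 1) for m in sorted(members)))
            (out / "clusters.tsv").write_text("\n".join(rows) + "\n")
            return {"n_clusters": len(res.clusters),
                    "sizes": res.sizes,
                    "representative_model": representative(res) + 1}

        _stage(report, "clustering", stage_cluster)

    if config.relaxation_table:
        def stage_relax():
            records = read_relaxation_table(config.relaxation_table)
            flex = flexibility_flags(records, threshold="mean")
            tau = estimate_tau_c(records, config.field_mhz,
                                 noe_threshold=flex.threshold)
            rows = ["res_seq\ttau_c_ns\tused"] + [
                f"{r}\t{v:.3f}\t{int(r in tau.residues_used)}"
                for r, v in sorted(tau.per_residue_ns.items())
            ]
            (out / "tau_c.tsv").write_text("\n".join(rows) + "\n")
            return {"tau_c_ns": tau.tau_c_ns,
                    "n_residues_used": len(tau.residues_used),
                    "hetnoe_threshold": flex.threshold,
                    "n_flexible": len(flex.flexible)}

        _stage(report, "relaxation", stage_relax)
    else:
        report["stages"]["relaxation"] = {"status": "skipped",
                                          "reason": "no relaxation table"}

    if len(config.peak_tables) >= 2:
        def stage_titration():
            lists = [read_peak_table(p) for p in config.peak_tables]
            eqs = config.titration_equivalents or list(range(len(lists)))
            series = TitrationSeries(equivalents=[float(e) for e in eqs],
                                     peak_lists=lists)
            structure = ensemble.models[0] if ensemble is not None else None
            rep = titration_report(series, structure, alpha=config.csp_alpha,
                                   contact_cutoff=config.contact_cutoff)
            rep.per_point[-1].to_csv(out / "csp_final.tsv", sep="\t",
                                     index=False)
            result = {"class_members": rep.class_members}
            if rep.epitope is not None:
                result["epitope_patches"] = [
                    sorted(f"{c}{r}" for c, r in p["residues"])
                    for p in rep.epitope.patches
                ]
                sel_lines = [
                    "select patch%d, resi %s" % (
                        i + 1, "+".join(sorted({str(r) for _, r in p["residues"]})))
                    for i, p in enumerate(rep.epitope.patches)
                ]
                (out / "epitope_selection.pml").write_text(
                    "\n".join(sel_lines) + "\n")
            return result

        _stage(report, "titration_epitope", stage_titration)
    else:
        report["stages"]["titration_epitope"] = {"status": "skipped",
                                                 "reason": "no peak tables"}

    report["any_failures"] = any(
        s.get("status") == "error" for s in report["stages"].values()
    )
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    logger.removeHandler(fh)
    fh.close()
    return report
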