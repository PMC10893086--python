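"""End-to-end orchestration: simulate/load -> hygiene -> normalise ->
test -> integrate -> ordinate -> network, as one reproducible run.

A run is driven by a TOML config with three sections:

* ``[run]`` — out_dir, seed, alpha, n_permutations, per-layer test
  choices;
* ``[simulate]`` — any :class:`~chemomix.synthetic.SyntheticConfig`
  field (generates the inputs); or
* ``[inputs]`` — paths to real CSV tables (matrices, metadata,
  internal-standard areas, blank tables, known-artefact list).

Every intermediate table, test result, ordination, graph export, a
summary CSV and a manifest (config + versions + seeds) are written into
the run directory.  All randomness flows from the single ``run.seed``,
so identical config + seed reproduces identical outputs.

Only analytes detected in at least one sample of *each* treatment group
are univariate-tested; structurally absent (unique-to-treatment)
volatiles are reported through the presence/absence partition instead
of a rank test on all-zero groups.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as cio
from .datamodel import AnalyteTable, ValidationError
from .integrate import integrate_layers
from .multivariate import (
    PCAResult,
    PermanovaResult,
    euclidean_distance,
    hierarchical_cluster,
    pca,
    permanova,
)
from .network import (
    CorrelationNetwork,
    NetworkClusters,
    export_graph,
    significance_gated_network,
    write_clusters,
    write_edges,
)
from .normalize import (
    cnp_ratio,
    log_transform,
    mean_centre,
    normalise_elementome,
    normalise_metabolome,
)
from .synthetic import (
    RecoveryReport,
    SyntheticConfig,
    SyntheticStudy,
    generate_study,
    truth_recovery_report,
)
from .univariate import TestResult, run_univariate, significant_ids
from .volatiles import class_summary, partition_by_treatment, preprocess_volatiles

_RUN_KEYS = {
    "out_dir", "seed", "alpha", "n_permutations",
    "element_test", "metabolite_test", "volatile_test", "integrated_test",
    "network_k", "blank_presence_fraction", "min_present", "blank_mode",
}
_SIMULATE_KEYS = set(SyntheticConfig.__dataclass_fields__)
_INPUT_KEYS = {
    "elements", "metabolites", "volatiles", "blanks", "meta", "volatile_meta",
    "blank_meta", "metabolite_is", "volatile_is", "blank_is", "contaminants",
}

_DEFAULT_TESTS = {
    "element": "welch",
    "metabolite": "wilcoxon",
    "volatile": "wilcoxon",
    "integrated": "wilcoxon",
}


@dataclass
class PipelineResult:
    run_dir: Path
    tables: dict[str, AnalyteTable]
    results: dict[str, list[TestResult]]
    partition: dict[str, set[str]]
    pca_per_layer: dict[str, PCAResult]
    pca_integrated: PCAResult
    permanova: PermanovaResult
    network: CorrelationNetwork
    clusters: NetworkClusters
    stoichiometry: pd.DataFrame | None
    recovery: RecoveryReport | None
    summary: pd.DataFrame
    study: SyntheticStudy | None = None


def _validate_config(config: dict[str, Any]) -> None:
    allowed = {"run": _RUN_KEYS, "simulate": _SIMULATE_KEYS, "inputs": _INPUT_KEYS}
    for section, body in config.items():
        if section not in allowed:
            raise ValidationError(f"unknown config section {section!r}")
        if not isinstance(body, dict):
            raise ValidationError(f"config section {section!r} must be a table")
        for key in body:
            if key not in allowed[section]:
                raise ValidationError(
                    f"unknown config key {section}.{key}"
                )
    if "run" not in config or "seed" not in config["run"]:
        raise ValidationError("config requires run.seed (explicit seeding)")
    if ("simulate" in config) == ("inputs" in config):
        raise ValidationError("config needs exactly one of [simulate] or [inputs]")


def load_config(path: str | Path) -> dict[str, Any]:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _testable_ids(table: AnalyteTable) -> list[str]:
    """Analytes detected at least once in each treatment group."""
    heat = table.detected[table.treatment_columns("heat")].any(axis=1)
    control = table.detected[table.treatment_columns("control")].any(axis=1)
    return list(table.abundance.index[heat & control])


def run_pipeline(
    config: dict[str, Any] | str | Path, out_dir: str | Path | None = None
) -> PipelineResult:
    """Run the full workflow; returns in-memory results and the run dir."""
    if not isinstance(config, dict):
        config = load_config(config)
    _validate_config(config)
    run_cfg = config["run"]
    seed = int(run_cfg["seed"])
    alpha = float(run_cfg.get("alpha", 0.05))
    n_perm = int(run_cfg.get("n_permutations", 9999))
    k_core = int(run_cfg.get("network_k", 3))
    tests = {
        layer: run_cfg.get(f"{layer}_test", _DEFAULT_TESTS[layer])
        for layer in _DEFAULT_TESTS
    }

    run_dir = Path(out_dir or run_cfg.get("out_dir", "chemomix_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, **info: Any) -> None:
        log_lines.append(json.dumps({"stage": stage, **info}, default=str))

    # ---- inputs -----------------------------------------------------------
    study: SyntheticStudy | None = None
    if "simulate" in config:
        sim = dict(config["simulate"])
        sim.setdefault("seed", seed)
        study = generate_study(SyntheticConfig(**sim))
        elements, metabolites = study.elements, study.metabolites
        volatiles, blanks = study.volatiles, study.blanks
        met_is, voc_is, blank_is = (
            study.metabolite_is, study.volatile_is, study.blank_is,
        )
        exclusion = study.known_artefacts
        raw = run_dir / "raw"
        raw.mkdir(exist_ok=True)
        cio.write_analyte_table(elements, raw / "elements.csv", raw / "meta.csv")
        cio.write_analyte_table(metabolites, raw / "metabolites.csv")
        cio.write_analyte_table(volatiles, raw / "volatiles.csv",
                                raw / "volatile_meta.csv")
        cio.write_analyte_table(blanks, raw / "blanks.csv", raw / "blank_meta.csv")
        met_is.to_csv(raw / "metabolite_is.csv")
        voc_is.to_csv(raw / "volatile_is.csv")
        blank_is.to_csv(raw / "blank_is.csv")
        (raw / "truth.json").write_text(
            json.dumps(
                {
                    "differential": study.truth.differential,
                    "cluster_membership": study.truth.cluster_membership,
                    "contaminant_ids": sorted(study.truth.contaminant_ids),
                    "unique_to_heat_ids": sorted(study.truth.unique_to_heat_ids),
                    "unique_to_control_ids": sorted(
                        study.truth.unique_to_control_ids
                    ),
                },
                indent=2,
            )
        )
        log("simulate", n_samples=len(study.samples),
            n_analytes=[elements.n_analytes, metabolites.n_analytes,
                        volatiles.n_analytes])
    else:
        paths = config["inputs"]
        for req in ("elements", "metabolites", "volatiles", "blanks", "meta"):
            if req not in paths:
                raise ValidationError(f"inputs.{req} is required")
            if not Path(paths[req]).exists():
                raise ValidationError(f"input file missing: {paths[req]}")
        meta = cio.read_sample_meta(paths["meta"])
        elements = cio.read_analyte_table(paths["elements"], "element", meta)
        metabolites = cio.read_analyte_table(paths["metabolites"], "metabolite", meta)
        voc_meta = (
            cio.read_sample_meta(paths["volatile_meta"])
            if "volatile_meta" in paths
            else meta
        )
        volatiles = cio.read_analyte_table(paths["volatiles"], "volatile", voc_meta)
        blank_meta = (
            cio.read_sample_meta(paths["blank_meta"])
            if "blank_meta" in paths
            else meta
        )
        blanks = cio.read_analyte_table(paths["blanks"], "volatile", blank_meta)
        met_is = cio.read_series(paths["metabolite_is"])
        voc_is = cio.read_series(paths["volatile_is"])
        blank_is = (
            cio.read_series(paths["blank_is"]) if "blank_is" in paths else None
        )
        exclusion = (
            [
                line.strip()
                for line in Path(paths["contaminants"]).read_text().splitlines()
                if line.strip()
            ]
            if "contaminants" in paths
            else []
        )
        log("load", files=list(paths.values()))

    # ---- volatile hygiene -------------------------------------------------
    vol_clean = preprocess_volatiles(
        volatiles,
        blanks,
        voc_is,
        blank_is_areas=blank_is,
        exclusion_list=exclusion,
        presence_fraction=float(run_cfg.get("blank_presence_fraction", 0.5)),
        min_present=int(run_cfg.get("min_present", 4)),
        blank_mode=run_cfg.get("blank_mode", "subtract"),
    )
    partition = partition_by_treatment(vol_clean)
    classes = class_summary(vol_clean, partition)
    log("volatile_hygiene", n_in=volatiles.n_analytes, n_out=vol_clean.n_analytes,
        unique_to_heat=len(partition["unique_to_heat"]),
        unique_to_control=len(partition["unique_to_control"]),
        shared=len(partition["shared"]))

    # ---- per-layer normalisation ------------------------------------------
    el_norm = normalise_elementome(elements)
    met_norm = normalise_metabolome(metabolites, met_is)
    tables = {
        "element": el_norm,
        "metabolite": met_norm,
        "volatile": vol_clean,
    }

    # ---- C:N:P stoichiometry ----------------------------------------------
    stoich = None
    if {"C", "N", "P"} <= set(el_norm.analyte_ids):
        rows = []
        for treatment in ("control", "heat"):
            cols = el_norm.treatment_columns(treatment)
            means = el_norm.abundance.loc[["C", "N", "P"], cols].mean(axis=1)
            ratio = cnp_ratio(means["C"], means["N"], means["P"])
            rows.append(
                {"treatment": treatment, "c": ratio.c, "n": ratio.n, "p": ratio.p}
            )
        stoich = pd.DataFrame(rows)
        stoich.to_csv(run_dir / "stoichiometry.csv", index=False)

    # ---- per-layer univariate tests ---------------------------------------
    results: dict[str, list[TestResult]] = {}
    for layer, table in tables.items():
        testable = _testable_ids(table)
        res = run_univariate(table.subset_analytes(testable), test=tests[layer],
                             alpha=alpha)
        results[layer] = res
        cio.write_results(res, run_dir / f"results_{layer}.csv")
        log("univariate", layer=layer, tested=len(res),
            significant=len(significant_ids(res)))

    # ---- integration -------------------------------------------------------
    combined = integrate_layers([el_norm, met_norm, vol_clean])
    cio.write_analyte_table(combined, run_dir / "combined.csv",
                            run_dir / "combined_meta.csv")
    logt = mean_centre(log_transform(combined))

    # ---- ordination --------------------------------------------------------
    pca_per_layer: dict[str, PCAResult] = {}
    for layer, table in tables.items():
        lt = mean_centre(log_transform(table))
        pca_per_layer[layer] = pca(lt.abundance.T, center=False)
        cio.write_pca(pca_per_layer[layer], run_dir, prefix=f"pca_{layer}")
    pca_int = pca(logt.abundance.T, center=False)
    cio.write_pca(pca_int, run_dir, prefix="pca_integrated")

    D = euclidean_distance(logt.abundance.T)
    labels = [s.treatment for s in logt.samples]
    perm = permanova(D, labels, n_perm=n_perm, seed=seed)
    (run_dir / "permanova.json").write_text(
        json.dumps(
            {
                "pseudo_F": perm.pseudo_F,
                "p": perm.p,
                "n_permutations": perm.n_permutations,
                "seed": perm.seed,
            },
            indent=2,
        )
    )
    log("permanova", pseudo_F=perm.pseudo_F, p=perm.p)

    # ---- integrated univariate + heatmap ordering -------------------------
    testable = _testable_ids(combined)
    res_int = run_univariate(combined.subset_analytes(testable),
                             test=tests["integrated"], alpha=alpha)
    results["integrated"] = res_int
    cio.write_results(res_int, run_dir / "results_integrated.csv")
    sig = significant_ids(res_int)
    log("univariate", layer="integrated", tested=len(res_int), significant=len(sig))

    if len(sig) >= 2:
        from .normalize import autoscale

        heat_table = autoscale(logt.subset_analytes(sig))
        order = hierarchical_cluster(heat_table.abundance.T, axis="samples").order
        pd.Series(order, name="sample_id").to_csv(
            run_dir / "heatmap_sample_order.csv", index=False
        )

    # ---- correlation network ----------------------------------------------
    network, clusters, rho, p_holm = significance_gated_network(
        logt, sig, alpha=alpha, k=k_core
    )
    write_edges(network, run_dir / "edges.csv")
    write_clusters(clusters, run_dir / "clusters.csv")
    export_graph(network, clusters, "GraphML", run_dir / "network.graphml")
    export_graph(network, clusters, "SIF", run_dir / "network.sif")
    log("network", nodes=len(network.nodes), edges=len(network.edges),
        positive=network.n_positive, negative=network.n_negative,
        components=[len(c) for c in clusters.components],
        core=len(clusters.core_nodes))

    # ---- recovery ----------------------------------------------------------
    recovery = None
    if study is not None:
        recovery = truth_recovery_report(study.truth, res_int, clusters)
        (run_dir / "recovery.json").write_text(
            json.dumps(
                {
                    "sensitivity": recovery.sensitivity,
                    "false_discovery_proportion":
                        recovery.false_discovery_proportion,
                    "ari": recovery.ari,
                    "n_called": recovery.n_called,
                    "n_true": recovery.n_true,
                },
                indent=2,
            )
        )
        log("recovery", sensitivity=recovery.sensitivity,
            fdp=recovery.false_discovery_proportion, ari=recovery.ari)

    # ---- outputs: partition, classes, summary, manifest --------------------
    pd.DataFrame(
        [
            {"set": name, "n": len(ids), "analytes": ";".join(sorted(ids))}
            for name, ids in partition.items()
        ]
    ).to_csv(run_dir / "volatile_partition.csv", index=False)
    classes.to_csv(run_dir / "volatile_classes.csv", index_label="class")

    summary = _build_summary(results, partition, pca_per_layer, pca_int, perm,
                             clusters)
    summary.to_csv(run_dir / "summary.csv", index=False)

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "chemomix": _version(),
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(p.name for p in run_dir.glob("*") if p.is_file()),
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (run_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        run_dir=run_dir,
        tables=tables,
        results=results,
        partition=partition,
        pca_per_layer=pca_per_layer,
        pca_integrated=pca_int,
        permanova=perm,
        network=network,
        clusters=clusters,
        stoichiometry=stoich,
        recovery=recovery,
        summary=summary,
        study=study,
    )


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("chemomix")
    except PackageNotFoundError:
        return "unknown"


def _build_summary(results, partition, pca_per_layer, pca_int, perm, clusters):
    rows = []
    for layer, res in results.items():
        sig = [r for r in res if r.significant]
        rows.append({"metric": f"significant_{layer}", "value": len(sig)})
        rows.append(
            {
                "metric": f"significant_{layer}_higher_in_heat",
                "value": sum(1 for r in sig if r.direction == "higher_in_heat"),
            }
        )
        rows.append(
            {
                "metric": f"significant_{layer}_lower_in_heat",
                "value": sum(1 for r in sig if r.direction == "lower_in_heat"),
            }
        )
    for name, ids in partition.items():
        rows.append({"metric": f"volatile_{name}", "value": len(ids)})
    for layer, p in pca_per_layer.items():
        rows.append(
            {"metric": f"pca_{layer}_pc1_pct",
             "value": float(p.explained_variance_pct[0])}
        )
    rows.append(
        {"metric": "pca_integrated_pc1_pct",
         "value": float(pca_int.explained_variance_pct[0])}
    )
    rows.append({"metric": "permanova_pseudo_F", "value": perm.pseudo_F})
    rows.append({"metric": "permanova_p", "value": perm.p})
    for idx, comp in enumerate(clusters.components):
        rows.append({"metric": f"network_component_{idx}_size", "value": len(comp)})
    rows.append({"metric": "network_core_size", "value": len(clusters.core_nodes)})
    return pd.DataFrame(rows, columns=["metric", "value"])


def summarise_run(run_dir: str | Path) -> pd.DataFrame:
    """Rebuild the run summary from the files of a completed run."""
    run_dir = Path(run_dir)
    required = ["summary.csv", "results_integrated.csv", "permanova.json"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise ValidationError(f"incomplete run, missing: {missing}")
    summary = pd.read_csv(run_dir / "summary.csv")
    # consistency: counts must equal the underlying result files
    for layer in ("element", "metabolite", "volatile", "integrated"):
        path = run_dir / f"results_{layer}.csv"
        if path.exists():
            df = pd.read_csv(path)
            n_sig = int(df["significant"].sum()) if len(df) else 0
            row = summary.loc[summary["metric"] == f"significant_{layer}", "value"]
            if len(row) and int(row.iloc[0]) != n_sig:
                raise ValidationError(
                    f"summary inconsistent with results_{layer}.csv"
                )
    return summary
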