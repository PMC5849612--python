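"""End-to-end orchestration: geometry → trait table → volancy → flight mode.

`run_analysis` drives the statistical chain on in-memory objects and is
what the command-line interface, the tests and downstream scripts call;
`run_pipeline` wraps it with file IO, logging and a serialised run report
so a whole study is reproducible from one config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import comparative_inference as ci
from .phylo_model import Chronogram, prune_to, read_tree

logger = logging.getLogger("wingbeam")

__all__ = ["RunConfig", "run_analysis", "run_pipeline"]

#: Species-average relative cortical thickness separating volant from
#: non-volant archosaurs.
VOLANCY_CA_TA_REFERENCE = 0.60


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs, serialised verbatim into the report."""

    traits_csv: str | None = None
    tree_newick: str | None = None
    out_dir: str = "wingbeam_out"
    schemes: tuple[str, ...] = ("viscor", "close")
    log_jm: bool = True
    standardise: bool = False
    n_pca_components: int = 3  # pPC scores handed to PAM
    n_sims: int = 10_000  # BM simulations per ANCOVA
    seed: int = 0
    volancy_threshold: float = VOLANCY_CA_TA_REFERENCE
    run_ancova: bool = True


def _volancy_stage(
    table: ci.TraitTable, tree: Chronogram, config: RunConfig
) -> dict[str, Any]:
    df = table.aligned_to(tree)
    X = ci.analysis_matrix(df, log_jm=config.log_jm, standardise=config.standardise)
    pca = ci.phyl_pca(X, tree, mode="cor")
    k = min(config.n_pca_components, pca.scores.shape[1])
    pam = ci.pam_cluster(pca.scores.iloc[:, :k], k=2)
    km = ci.kmeans_cluster(X, k=2, seed=config.seed)
    volant = df["volant"].astype(bool)
    pam_rate, pam_miss, pam_map = ci.volancy_success(pam.assignments, volant)
    km_rate, km_miss, km_map = ci.volancy_success(km.assignments, volant)
    pam_volant = pam.assignments.map(pam_map)
    km_volant = km.assignments.map(km_map)
    identical = bool((pam_volant == km_volant).all())

    avg_ca_ta = df[["ca_ta_h", "ca_ta_u"]].mean(axis=1)
    thr = config.volancy_threshold
    threshold_ok = (avg_ca_ta < thr) == volant
    return {
        "pca": pca,
        "pam": pam,
        "kmeans": km,
        "pam_success_pct": pam_rate,
        "pam_misclassified": pam_miss,
        "kmeans_success_pct": km_rate,
        "kmeans_misclassified": km_miss,
        "partitions_identical": identical,
        "ca_ta_threshold": thr,
        "ca_ta_threshold_agreement_pct": 100.0 * float(threshold_ok.mean()),
    }


def _flight_mode_stage(
    table: ci.TraitTable, tree: Chronogram, config: RunConfig
) -> dict[str, Any]:
    df = table.aligned_to(tree)
    X = ci.analysis_matrix(df, log_jm=config.log_jm, standardise=config.standardise)
    screen = ci.screen_phylogenetic_signal(X, tree)
    out: dict[str, Any] = {"signal_screen": screen}
    mystery = table.mystery
    X_mystery = (
        ci.analysis_matrix(mystery, log_jm=config.log_jm, standardise=False)
        if len(mystery)
        else None
    )
    for scheme in config.schemes:
        groups = df[f"scheme_{scheme}"]
        lda = ci.lda_fit(X, groups)
        entry: dict[str, Any] = {"lda": lda}
        if X_mystery is not None:
            entry["mystery"] = ci.lda_classify(lda, X_mystery)
        entry["manova"] = ci.manova(X, groups)
        out[scheme] = entry
    return out


def _ancova_stage(
    table: ci.TraitTable, tree: Chronogram, config: RunConfig, scheme: str = "close"
) -> dict[str, Any]:
    df = table.aligned_to(tree)
    # an F test for the group effect needs within-group df: locomotor modes
    # represented by a single taxon cannot contribute and are set aside
    counts = df[f"scheme_{scheme}"].value_counts()
    keep = df[f"scheme_{scheme}"].isin(counts.index[counts >= 2])
    if not keep.all():
        dropped = sorted(df.index[~keep])
        logger.info("ancova: dropping singleton-group taxa %s", dropped)
        tree = prune_to(tree, list(df.index[keep]))
        df = df.loc[tree.tip_labels]
    group = df[f"scheme_{scheme}"].to_numpy()
    mass = np.log10(df["mass_g"].to_numpy())
    out = {}
    rng = np.random.default_rng(config.seed)
    for i, param in enumerate(ci.PARAMETER_COLUMNS):
        y = df[param].to_numpy(dtype=float)
        if param.startswith("jm"):
            y = np.log10(y) if config.log_jm else y
        out[param] = ci.phylo_ancova(
            y, group, mass, tree,
            n_sims=config.n_sims,
            seed=int(rng.integers(2**31)),
        )
    return out


def run_analysis(
    table: ci.TraitTable, tree: Chronogram, config: RunConfig | None = None
) -> dict[str, Any]:
    """Run the statistical chain on in-memory inputs; returns a result dict."""
    config = config or RunConfig()
    results: dict[str, Any] = {"config": config}
    t0 = time.perf_counter()
    logger.info("volancy stage: pPCA + PAM + k-means on %d taxa", len(table.training))
    results["volancy"] = _volancy_stage(table, tree, config)
    logger.info("flight-mode stage: lambda screen + LDA + MANOVA")
    results["flight_mode"] = _flight_mode_stage(table, tree, config)
    if config.run_ancova and config.n_sims >= 100:
        logger.info("phylogenetic ANCOVA: %d BM sims per parameter", config.n_sims)
        results["ancova"] = _ancova_stage(table, tree, config)
    results["elapsed_s"] = time.perf_counter() - t0
    return results


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: _jsonable(v)
            for k, v in dataclasses.asdict(obj).items()
            if not isinstance(v, np.ndarray)
        }
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """File-level pipeline: read inputs, run all stages, write outputs.

    Writes per-stage CSV tables, a JSON run report (config, seeds, success
    rates, λ̂, p-values) and a log under ``config.out_dir``; any stage error
    aborts with a stage-tagged message, retaining partial outputs.
    """
    if config.traits_csv is None or config.tree_newick is None:
        raise ValueError("config error: traits_csv and tree_newick are required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        df = pd.read_csv(config.traits_csv, index_col=0)
        table = ci.TraitTable(df)
        tree = read_tree(config.tree_newick)
        results = run_analysis(table, tree, config)

        vol = results["volancy"]
        vol["pca"].scores.to_csv(out / "ppca_scores.csv")
        vol["pca"].loadings.to_csv(out / "ppca_loadings.csv")
        pd.DataFrame(
            {
                "pam_cluster": vol["pam"].assignments,
                "kmeans_cluster": vol["kmeans"].assignments,
            }
        ).to_csv(out / "volancy_clusters.csv")
        for scheme in config.schemes:
            entry = results["flight_mode"][scheme]
            entry["lda"].training_scores.to_csv(out / f"lda_scores_{scheme}.csv")
            entry["lda"].confusion.to_csv(out / f"lda_confusion_{scheme}.csv")
            if "mystery" in entry:
                entry["mystery"].to_csv(out / f"mystery_classification_{scheme}.csv")
            entry["manova"].pairwise.to_csv(
                out / f"manova_pairwise_{scheme}.csv", index=False
            )

        report = {
            "config": _jsonable(config),
            "volancy": {
                "pam_success_pct": vol["pam_success_pct"],
                "pam_misclassified": vol["pam_misclassified"],
                "kmeans_success_pct": vol["kmeans_success_pct"],
                "partitions_identical": vol["partitions_identical"],
                "ca_ta_threshold_agreement_pct": vol["ca_ta_threshold_agreement_pct"],
            },
            "signal_screen": {
                "recommendation": results["flight_mode"]["signal_screen"].recommendation,
                "lambda_hat": {
                    k: f.lam
                    for k, f in results["flight_mode"]["signal_screen"].lambda_fits.items()
                },
                "p_values": results["flight_mode"]["signal_screen"].p_values,
            },
            "lda": {
                scheme: {
                    "percent_correct": results["flight_mode"][scheme]["lda"].percent_correct,
                    "mystery": _jsonable(
                        results["flight_mode"][scheme]["mystery"]["assigned"]
                    )
                    if "mystery" in results["flight_mode"][scheme]
                    else None,
                }
                for scheme in config.schemes
            },
            "manova": {
                scheme: {
                    "wilks_lambda": results["flight_mode"][scheme]["manova"].wilks_lambda,
                    "p_value": results["flight_mode"][scheme]["manova"].p_value,
                }
                for scheme in config.schemes
            },
            "elapsed_s": results["elapsed_s"],
        }
        if "ancova" in results:
            report["ancova"] = {
                param: {"F": r.f_observed, "p": r.p_value, "n_sims": r.n_sims}
                for param, r in results["ancova"].items()
            }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        results["report"] = report
        return results
    except Exception as exc:  # stage-tagged abort, partial outputs retained
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
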