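"""End-to-end orchestration: preprocess -> SR + Elastic Net -> consensus ->
annotation -> molecular network, with a key=value run log for reproducibility.

The consensus report mirrors the field's usual presentation: one row per
molecular feature appearing in either estimator's top-K, sorted by
selectivity ratio descending, with the Elastic Net rank (``r (of N)``),
library annotation and the feature's plain Pearson correlation with
viability alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import mgf
from .annotation import CompoundLibrary, annotate, read_library
from .elasticnet import ENRankResult, EnsembleConfig, en_analysis
from .network import (
    NetworkParams,
    build_network,
    export_graphml,
    map_bioactivity,
    merge_identical,
)
from .preprocess import (
    DEFAULT_ADDUCT_RULES,
    BioactivityVector,
    FeatureMatrix,
    deconvolute,
    log_transform,
    pearson_feature_viability,
    read_feature_table,
    read_viability_table,
)
from .selectivity import SRResult, sr_analysis

__all__ = ["RunConfig", "ConsensusTable", "consensus", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run.

    Matrices may be given as in-memory objects or as file paths (one per
    ion mode); a missing mode is skipped with a log note, not an error.
    """

    matrices: dict[str, FeatureMatrix | str] = field(default_factory=dict)
    viability: BioactivityVector | str | None = None
    spectra: list | str | None = None       # MsmsSpectrum list or MGF path
    library: CompoundLibrary | str | None = None
    out_dir: str | Path = "phytoactive_run"
    seed: int = 0
    top_k: int = 50
    n_components: int | str = "auto"
    deconvolute: bool = True
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    network_params: NetworkParams = field(default_factory=NetworkParams)
    annotation_ppm: float = 10.0


@dataclass
class ConsensusTable:
    frame: pd.DataFrame
    overlap_count: int  # features in both estimators' top-K lists


def consensus(
    sr_results: dict[str, SRResult],
    en_results: dict[str, ENRankResult],
    annotations: dict[str, str],
    correlations: dict[str, float],
    top_k: int = 50,
) -> ConsensusTable:
    """Union of per-mode top-K feature sets from both estimators, SR-sorted."""
    sr_frames = {m: r.to_frame() for m, r in sr_results.items()}
    en_frames = {m: r.to_frame() for m, r in en_results.items()}
    sr_top: set[tuple[str, str]] = set()
    en_top: set[tuple[str, str]] = set()
    for mode, df in sr_frames.items():
        sr_top |= {(mode, f) for f in df.head(top_k)["feature_id"]}
    for mode, df in en_frames.items():
        sel = df[df["rank"].notna()].head(top_k)
        en_top |= {(mode, f) for f in sel["feature_id"]}
    keys = sr_top | en_top

    rows = []
    for mode, fid in keys:
        sr_df = sr_frames[mode]
        row = sr_df[sr_df["feature_id"] == fid].iloc[0]
        en = en_results[mode]
        rows.append(
            {
                "feature_id": fid,
                "ion_mode": mode,
                "sr": float(row["sr"]),
                "sr_rank": int(row["rank"]),
                "en_rank": en.rank_label(fid),
                "en_n_selected": en.n_selected,
                "annotation": annotations.get(fid, "N/A"),
                "pearson_r_vs_viability": correlations.get(fid, np.nan),
            }
        )
    frame = (
        pd.DataFrame(
            rows,
            columns=[
                "feature_id", "ion_mode", "sr", "sr_rank", "en_rank",
                "en_n_selected", "annotation", "pearson_r_vs_viability",
            ],
        )
        .sort_values(["sr", "feature_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    overlap = len(sr_top & en_top)
    return ConsensusTable(frame=frame, overlap_count=overlap)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write reports under ``config.out_dir``.

    Outputs: ``sr_report.csv``, ``en_report.csv``, ``consensus.csv``,
    ``network.graphml`` (when spectra are given) and ``run.log``.
    Deterministic given the seed: reruns produce byte-identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed={config.seed}", f"top_k={config.top_k}"]

    if config.viability is None:
        raise ValueError("stage=input: viability data are required")
    viability = (
        read_viability_table(config.viability)
        if isinstance(config.viability, str)
        else config.viability
    )

    matrices: dict[str, FeatureMatrix] = {}
    for mode in ("POS", "NEG"):
        src = config.matrices.get(mode)
        if src is None:
            log_lines.append(f"mode_{mode}=skipped (no matrix provided)")
            continue
        matrices[mode] = read_feature_table(src, mode) if isinstance(src, str) else src
    if not matrices:
        raise ValueError("stage=input: no feature matrix provided for any ion mode")

    sr_results: dict[str, SRResult] = {}
    en_results: dict[str, ENRankResult] = {}
    annotations: dict[str, str] = {}
    correlations: dict[str, float] = {}
    library = (
        read_library(config.library)
        if isinstance(config.library, str)
        else config.library
    )

    deconvoluted: dict[str, FeatureMatrix] = {}
    for mode, matrix in sorted(matrices.items()):
        try:
            log_lines.append(f"n_features_raw_{mode}={matrix.n_features}")
            if config.deconvolute:
                matrix, report = deconvolute(matrix, DEFAULT_ADDUCT_RULES)
                log_lines.append(f"n_merge_groups_{mode}={len(report)}")
            deconvoluted[mode] = matrix
            log_lines.append(f"n_features_{mode}={matrix.n_features}")
            logged = log_transform(matrix)
            sr_results[mode] = sr_analysis(
                logged, viability, n_components=config.n_components
            )
            en_cfg = replace(config.ensemble, seed=config.ensemble.seed + config.seed)
            en_results[mode] = en_analysis(logged, viability, en_cfg)
            log_lines.append(f"en_n_selected_{mode}={en_results[mode].n_selected}")
        except Exception as exc:  # annotate failures with the stage
            raise RuntimeError(f"stage=estimators mode={mode}: {exc}") from exc

    # per-feature annotation + correlation for every candidate in either top-K
    cand: set[tuple[str, str]] = set()
    for mode, res in sr_results.items():
        cand |= {(mode, f) for f in res.to_frame().head(config.top_k)["feature_id"]}
    for mode, res in en_results.items():
        df = res.to_frame()
        cand |= {
            (mode, f)
            for f in df[df["rank"].notna()].head(config.top_k)["feature_id"]
        }
    for mode, fid in sorted(cand):
        if library is not None:
            recs = annotate(fid, mode, library, ppm=config.annotation_ppm)
            if recs:
                annotations[fid] = recs[0].compound_name
        try:
            correlations[fid] = pearson_feature_viability(
                deconvoluted[mode], viability, fid
            )
        except ValueError:
            correlations[fid] = np.nan

    table = consensus(
        sr_results, en_results, annotations, correlations, top_k=config.top_k
    )
    log_lines.append(f"consensus_overlap={table.overlap_count}")

    for mode, res in sr_results.items():
        res.to_frame().to_csv(out / f"sr_report_{mode}.csv", index=False)
    for mode, res in en_results.items():
        res.to_frame().to_csv(out / f"en_report_{mode}.csv", index=False)
    table.frame.to_csv(out / "consensus.csv", index=False)

    if config.spectra is not None:
        spectra = (
            mgf.read_mgf(config.spectra)
            if isinstance(config.spectra, str)
            else config.spectra
        )
        try:
            merged = merge_identical(spectra, params=config.network_params)
            net = build_network(merged, config.network_params)
            ref_mode = "NEG" if "NEG" in deconvoluted else "POS"
            net = map_bioactivity(net, deconvoluted[ref_mode], viability)
            export_graphml(net, out / "network.graphml")
            log_lines.append(f"network_nodes={net.n_nodes}")
            log_lines.append(f"network_edges={net.n_edges}")
            log_lines.append(f"network_clusters={len(net.clusters)}")
        except Exception as exc:
            raise RuntimeError(f"stage=networking: {exc}") from exc

    for mode in sr_results:
        log_lines.append(f"sr_n_components_auto_{mode}={config.n_components}")
    log_lines.append(f"ensemble_n_models={config.ensemble.n_models}")
    log_lines.append(f"ensemble_alpha={config.ensemble.alpha}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
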