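"""End-to-end orchestration: load/generate -> preprocess -> rank -> factorize
-> threshold -> score, plus the benchmark grid runner.

Everything here is a thin composition of the library modules; the CLI and
the example scripts call these functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import BiclusterSet, DataMatrix, read_matrix, write_matrix
from .evaluate import overall_match_score
from .factorize import FactorizationResult, nmf_fit, pca_fit
from .preprocess import (
    median_fold_change_log,
    median_fold_change_normalize,
    shift_to_nonnegative,
    total_intensity_normalize,
)
from .rank_select import BCVResult, select_rank
from .simulate import (
    SimulatedDataset,
    generate_block_example,
    generate_gene_expression_style,
    generate_benchmark_dataset1,
)
from .threshold import ThresholdSpec, extract_biclusters

logger = logging.getLogger("mfbiclust")

__all__ = ["RunConfig", "RunResult", "run_biclustering", "run_benchmark", "summarize_benchmark"]

DESIGNS = ("dataset1", "gene_expr", "blocks")


@dataclass
class RunConfig:
    """Configuration of one biclustering run.

    Exactly one of ``input_path`` (a labeled CSV/TSV matrix) or ``design``
    (a named synthetic design: ``dataset1``, ``gene_expr`` or ``blocks``) must
    be given.  ``k`` is an integer rank or ``"auto"`` to delegate to BCV.
    """

    input_path: str | Path | None = None
    design: str | None = None
    noise_sd: float = 0.25
    design_k: int = 3
    normalize: str = "none"  # none | total | mfc
    log_transform: bool = False
    shift: bool = True
    method: str = "nmf"  # nmf | pca
    k: int | str = "auto"
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    seed: int = 0
    restarts: int = 10
    tol: float = 1e-6
    max_iter: int = 500
    bcv_grid: tuple[int, int] = (2, 2)
    bcv_kmax: int = 8
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.design is None):
            raise ValueError("give exactly one of input_path or design")
        if self.design is not None and self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if self.method not in ("nmf", "pca"):
            raise ValueError("method must be 'nmf' or 'pca'")
        if self.normalize not in ("none", "total", "mfc"):
            raise ValueError("normalize must be none|total|mfc")

    def to_dict(self) -> dict[str, Any]:
        d = {
            "input_path": str(self.input_path) if self.input_path else None,
            "design": self.design,
            "noise_sd": self.noise_sd,
            "design_k": self.design_k,
            "normalize": self.normalize,
            "log_transform": self.log_transform,
            "shift": self.shift,
            "method": self.method,
            "k": self.k,
            "threshold": {
                "method": self.threshold.method,
                "n_bins": self.threshold.n_bins,
                "fcm_fuzzifier": self.threshold.fcm_fuzzifier,
            },
            "seed": self.seed,
            "restarts": self.restarts,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "bcv_grid": list(self.bcv_grid),
            "bcv_kmax": self.bcv_kmax,
        }
        return d


@dataclass
class RunResult:
    biclusters: BiclusterSet
    factorization: FactorizationResult
    bcv: BCVResult | None
    matrix: DataMatrix
    truth: BiclusterSet | None
    shift: float
    report: dict | None = None


def _blocks_dataset(seed: int, noise_sd: float) -> SimulatedDataset:
    # the small 8x8 illustration: three constant-value blocks, beta={1,2,3}
    return generate_block_example(
        betas=(1.0, 2.0, 3.0), m=8, n=8, noise_sd=noise_sd, seed=seed
    )


def _load_or_generate(config: RunConfig) -> tuple[DataMatrix, BiclusterSet | None]:
    if config.input_path is not None:
        return read_matrix(config.input_path), None
    if config.design == "dataset1":
        ds = generate_benchmark_dataset1(config.seed, noise_sd=config.noise_sd)
    elif config.design == "gene_expr":
        ds = generate_gene_expression_style(
            config.design_k, config.seed, noise_sd=config.noise_sd
        )
    else:
        ds = _blocks_dataset(config.seed, config.noise_sd)
    return ds.matrix, ds.truth


def _preprocess(matrix: DataMatrix, config: RunConfig) -> tuple[DataMatrix, float]:
    if config.normalize == "total":
        matrix = total_intensity_normalize(matrix)
    elif config.normalize == "mfc":
        matrix = median_fold_change_normalize(matrix)
    if config.log_transform:
        matrix = median_fold_change_log(matrix)
    shift = 0.0
    if config.shift:
        matrix, shift = shift_to_nonnegative(matrix)
    return matrix, shift


def run_biclustering(config: RunConfig) -> RunResult:
    """Run the full pipeline described by ``config``.

    Returns the bicluster set, the factorization, the BCV table (when
    ``k='auto'``) and, for synthetic designs, the match report against the
    planted truth.  When ``config.outdir`` is set, writes biclusters JSON,
    factor matrices TSV, the rank table and a run log.
    """
    t0 = time.perf_counter()
    matrix, truth = _load_or_generate(config)
    matrix, shift = _preprocess(matrix, config)
    timings = {"load_preprocess": time.perf_counter() - t0}

    bcv = None
    k = config.k
    if k == "auto":
        t1 = time.perf_counter()
        m, n = matrix.shape
        kmax = min(config.bcv_kmax, min(m, n) - 1)
        bcv = select_rank(
            matrix,
            candidate_ranks=list(range(1, kmax + 1)),
            seed=config.seed,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        k = bcv.selected_k
        timings["rank_select"] = time.perf_counter() - t1
        logger.info("BCV selected k=%d", k)
    k = int(k)

    t2 = time.perf_counter()
    if config.method == "nmf":
        fit = nmf_fit(
            matrix,
            k,
            seed=config.seed,
            tol=config.tol,
            max_iter=config.max_iter,
            restarts=config.restarts,
        )
    else:
        fit = pca_fit(matrix, k)
    timings["factorize"] = time.perf_counter() - t2

    biclusters = extract_biclusters(fit, config.threshold)
    report = None
    if truth is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = overall_match_score(biclusters, truth).to_dict()

    result = RunResult(
        biclusters=biclusters,
        factorization=fit,
        bcv=bcv,
        matrix=matrix,
        truth=truth,
        shift=shift,
        report=report,
    )
    if config.outdir is not None:
        _write_outputs(config, result, timings)
    return result


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_outputs(config: RunConfig, result: RunResult, timings: dict) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.biclusters.save(outdir / "biclusters.json")
    fit = result.factorization
    pd.DataFrame(
        fit.W, index=fit.row_labels, columns=[f"factor{a + 1}" for a in range(fit.k)]
    ).to_csv(outdir / "W.tsv", sep="\t")
    pd.DataFrame(
        fit.H, index=[f"factor{a + 1}" for a in range(fit.k)], columns=fit.col_labels
    ).to_csv(outdir / "H.tsv", sep="\t")
    write_matrix(result.matrix, outdir / "matrix.tsv")
    if result.bcv is not None:
        result.bcv.table().to_csv(outdir / "bcv.tsv", sep="\t", index=False)
    if result.truth is not None:
        result.truth.save(outdir / "truth.json")
    log = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "k_used": fit.k,
        "factors_retained": result.biclusters.k,
        "shift_applied": result.shift,
        "final_objective": fit.objective,
        "converged": fit.converged,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "report": result.report,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, sort_keys=True, indent=1) + "\n")


def run_benchmark(
    designs: Sequence[str] = ("dataset1",),
    methods: Sequence[str] = ("nmf", "pca"),
    thresholds: Sequence[str] = ("otsu", "fcm", "iter", "maxen"),
    noise_grid: Sequence[float] = (0.25,),
    k_grid: Sequence[int | str] = ("auto",),
    replicates: int = 20,
    seed: int = 0,
    design_k: int = 3,
    restarts: int = 10,
    bcv_kmax: int = 8,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Sweep designs x noise x k x replicates, scoring every method/threshold.

    Each replicate generates one dataset and runs rank selection once (per
    ``k`` policy), then reuses the NMF and PCA fits across the four
    thresholding methods, so the grid stays cheap.  Failures are recorded
    per cell (score columns NaN, ``error`` filled) and the sweep continues.
    Returns a long-format table; also written as TSV when ``out`` is given.
    """
    rows: list[dict] = []
    rng = np.random.default_rng(seed)
    for design in designs:
        for noise in noise_grid:
            for rep in range(replicates):
                rep_seed = int(rng.integers(2**31))
                try:
                    if design == "dataset1":
                        ds = generate_benchmark_dataset1(rep_seed, noise_sd=noise)
                    elif design == "gene_expr":
                        ds = generate_gene_expression_style(
                            design_k, rep_seed, noise_sd=noise
                        )
                    elif design == "blocks":
                        ds = _blocks_dataset(rep_seed, noise)
                    else:
                        raise ValueError(f"unknown design {design!r}")
                except Exception as exc:  # pragma: no cover - defensive
                    rows.append(
                        {
                            "design": design,
                            "noise_sd": noise,
                            "replicate": rep,
                            "error": f"generate: {exc}",
                        }
                    )
                    continue
                matrix, truth = ds.matrix, ds.truth
                for k_policy in k_grid:
                    if k_policy == "auto":
                        m, n = matrix.shape
                        kmax = min(bcv_kmax, min(m, n) - 1)
                        bcv = select_rank(
                            matrix,
                            candidate_ranks=list(range(1, kmax + 1)),
                            seed=rep_seed,
                        )
                        k_used = bcv.selected_k
                    else:
                        k_used = int(k_policy)
                    fits = {}
                    for method in methods:
                        try:
                            if method == "nmf":
                                fits[method] = nmf_fit(
                                    matrix, k_used, seed=rep_seed, restarts=restarts
                                )
                            else:
                                fits[method] = pca_fit(matrix, k_used)
                        except Exception as exc:
                            rows.append(
                                {
                                    "design": design,
                                    "method": method,
                                    "noise_sd": noise,
                                    "k_policy": str(k_policy),
                                    "k_used": k_used,
                                    "replicate": rep,
                                    "error": f"fit: {exc}",
                                }
                            )
                    for method, fit in fits.items():
                        for thr in thresholds:
                            row = {
                                "design": design,
                                "method": method,
                                "threshold": thr,
                                "noise_sd": noise,
                                "k_policy": str(k_policy),
                                "k_used": k_used,
                                "replicate": rep,
                                "seed": rep_seed,
                                "error": "",
                            }
                            try:
                                found = extract_biclusters(
                                    fit, ThresholdSpec(method=thr)
                                )
                                with warnings.catch_warnings():
                                    warnings.simplefilter("ignore")
                                    rpt = overall_match_score(found, truth)
                                row.update(
                                    overall=rpt.overall,
                                    recovery=rpt.recovery,
                                    relevance=rpt.relevance,
                                    n_found=found.k,
                                )
                            except Exception as exc:
                                row["error"] = f"threshold: {exc}"
                            rows.append(row)
    df = pd.DataFrame(rows)
    if out is not None:
        df.to_csv(out, sep="\t", index=False)
    return df


def summarize_benchmark(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of the scores per (design, method, threshold, noise)."""
    ok = df[df.get("error", "").fillna("") == ""]
    grouped = ok.groupby(["design", "method", "threshold", "noise_sd"], sort=True)
    summary = grouped.agg(
        overall_mean=("overall", "mean"),
        overall_sd=("overall", "std"),
        recovery_mean=("recovery", "mean"),
        relevance_mean=("relevance", "mean"),
        n=("overall", "size"),
    ).reset_index()
    return summary
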