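"""Full-experiment orchestration: data -> SNV -> models -> reports.

For each requested (component, method) cell the pipeline

1. aligns spectra with that component's reference values,
2. holds out one outer cross-validation fold as the prediction set and
   uses the remaining folds as the calibration set,
3. for plain ``pls``/``svr``: fits on the calibration set,
4. for ``bpso_pls``/``bpso_svr``: partitions the wavenumber axis into
   segments, runs repeated seeded BPSO with cross-validated RMSE on the
   calibration set as fitness, applies the frequency-consensus rule, and
   refits on the consensus variables,
5. emits a six-metric report row plus, for BPSO methods, per-run
   convergence curves, the per-segment count table and the selected
   wavenumber ranges.

Everything is seeded; a rerun with the same config reproduces every
number exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bpso import BPSOConfig
from .metrics import EvaluationReport, evaluate
from .models import (
    FoldAssignment,
    PLSParams,
    SVRParams,
    cv_rmse,
    fit_model,
    pls_cv_rmse_path_gram,
    tenfold_split,
)
from .preprocess import average_replicates, snv
from .segmentation import (
    make_segments,
    mask_to_variables,
    segments_to_wavenumber_ranges,
)
from .selection import ConsensusResult, consensus_refit, run_consensus
from .spectra_io import (
    ReferenceTable,
    SpectraSet,
    align,
    read_reference_csv,
    read_spectra_csv,
)
from .synthetic import SimulationConfig, default_tea_config, simulate

__all__ = ["RunConfig", "ExperimentResult", "run_experiment", "PROFILES"]

log = logging.getLogger("nircal")

METHODS = ("pls", "svr", "bpso_pls", "bpso_svr")

#: named optimizer scales: "ci" is the desk-scale default, "full" the
#: 100-runs-of-100-generations consensus setting.
PROFILES = {
    "ci": {"n_runs": 20, "max_generations": 30},
    "full": {"n_runs": 100, "max_generations": 100},
}


@dataclass
class RunConfig:
    """Everything one experiment needs, serializable to/from YAML."""

    simulation: SimulationConfig | None = None
    spectra_path: str | None = None
    reference_path: str | None = None
    components: tuple[str, ...] = ()
    models: tuple[str, ...] = ("pls", "bpso_pls")
    bpso: BPSOConfig = field(default_factory=BPSOConfig)
    n_runs: int = 100
    threshold: int | None = None
    n_segments: int = 21
    n_folds: int = 10
    cv_seed: int = 7
    inner_cv_seed: int = 11
    prediction_fold: int = 0
    snv_ddof: int = 1
    average_replicates: bool = False
    max_latent: int = 15
    svr_C: float = 1.0
    svr_epsilon: float = 0.1
    outdir: str | None = None
    profile: str | None = None

    def __post_init__(self):
        if self.simulation is None and self.spectra_path is None:
            raise ValueError("config needs either a simulation or input paths")
        unknown = set(self.models) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}; choose from {METHODS}")
        if not self.models:
            raise ValueError("at least one model is required")
        if self.profile is not None:
            scale = PROFILES[self.profile]
            self.n_runs = scale["n_runs"]
            self.bpso = replace(self.bpso, max_generations=scale["max_generations"])


@dataclass
class ExperimentResult:
    reports: list[EvaluationReport]
    consensus: dict[tuple[str, str], ConsensusResult]
    selected_ranges: dict[tuple[str, str], list[tuple[float, float]]]
    segment_counts: dict[tuple[str, str], np.ndarray]
    predictions: dict[tuple[str, str], pd.DataFrame]
    manifest: dict
    failures: dict[tuple[str, str], str] = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.reports])


def _model_spec(cfg: RunConfig, method: str):
    if method.endswith("pls"):
        return PLSParams(n_latent=None, max_latent=cfg.max_latent)
    return SVRParams(C=cfg.svr_C, epsilon=cfg.svr_epsilon)


def _load_data(cfg: RunConfig):
    if cfg.simulation is not None:
        spectra, tables, truth = simulate(cfg.simulation)
        refs = {t.component: t for t in tables}
        components = cfg.components or tuple(refs)
        return spectra, refs, components, truth
    spectra = read_spectra_csv(cfg.spectra_path)
    if not cfg.components:
        raise ValueError("components must be listed when loading from files")
    refs = {
        c: read_reference_csv(cfg.reference_path, c) for c in cfg.components
    }
    return spectra, refs, cfg.components, None


def make_cv_fitness(model_spec, X, y, folds: FoldAssignment, scheme, cache=None):
    """Segment-mask fitness: cross-validated RMSE of the model restricted to
    the mask's variables; empty masks score +inf so selection is never empty.

    For the PLS spec with automatic latent-count selection the fitness is
    evaluated through the Gram-matrix CV path: per-segment Gram matrices
    are precomputed once, a mask's Gram is their sum, and the whole
    latent-count path costs O(n^2) per fold instead of O(n * n_vars).
    """
    if cache is None:
        cache = {}
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    use_gram = isinstance(model_spec, PLSParams) and model_spec.n_latent is None
    if use_gram:
        seg_grams = np.stack(
            [X[:, s:e] @ X[:, s:e].T for s, e in scheme.boundaries]
        )

    def fitness(mask) -> float:
        mask = np.asarray(mask, dtype=np.uint8)
        key = mask.tobytes()
        if key not in cache:
            if mask.sum() == 0:
                cache[key] = float("inf")
            elif use_gram:
                K = seg_grams[mask.astype(bool)].sum(axis=0)
                cap = min(
                    model_spec.max_latent,
                    int(mask_to_variables(mask, scheme).size),
                )
                cache[key] = float(
                    pls_cv_rmse_path_gram(K, y, folds, cap).min()
                )
            else:
                cols = mask_to_variables(mask, scheme)
                cache[key] = cv_rmse(model_spec, X[:, cols], y, folds)
        return cache[key]

    return fitness


def run_experiment(cfg: RunConfig) -> ExperimentResult:
    """Run every (component, method) cell and collect/write all reports."""
    spectra, refs, components, truth = _load_data(cfg)
    if cfg.average_replicates:
        spectra = average_replicates(spectra)
    spectra = snv(spectra, ddof=cfg.snv_ddof)

    reports: list[EvaluationReport] = []
    consensus: dict[tuple[str, str], ConsensusResult] = {}
    ranges: dict[tuple[str, str], list[tuple[float, float]]] = {}
    counts: dict[tuple[str, str], np.ndarray] = {}
    predictions: dict[tuple[str, str], pd.DataFrame] = {}
    failures: dict[tuple[str, str], str] = {}

    for comp in components:
        try:
            s, r = align(spectra, refs[comp])
            X = s.absorbance
            y = r.array(s.row_ids)
            n = X.shape[0]
            outer = tenfold_split(n, cfg.n_folds, cfg.cv_seed)
            cal_idx = outer.train_indices(cfg.prediction_fold)
            pred_idx = outer.test_indices(cfg.prediction_fold)
            inner = tenfold_split(
                cal_idx.size, min(cfg.n_folds, cal_idx.size), cfg.inner_cv_seed
            )
            scheme = make_segments(X.shape[1], cfg.n_segments)
        except Exception as exc:
            for method in cfg.models:
                failures[(comp, method)] = str(exc)
            log.error("component=%s stage=data failed reason=%s", comp, exc)
            continue

        for method in cfg.models:
            key = (comp, method)
            log.info("component=%s method=%s stage=start cv_seed=%d bpso_seed=%d",
                     comp, method, cfg.cv_seed, cfg.bpso.seed)
            try:
                spec = _model_spec(cfg, method)
                if method in ("pls", "svr"):
                    model = fit_model(spec, X[cal_idx], y[cal_idx], folds=inner)
                    report = evaluate(
                        model, X[cal_idx], y[cal_idx], X[pred_idx], y[pred_idx],
                        component=comp, method=method,
                    )
                else:
                    cache: dict = {}
                    fitness_factory = lambda i: make_cv_fitness(  # noqa: E731
                        spec, X[cal_idx], y[cal_idx], inner, scheme, cache
                    )
                    cons = run_consensus(
                        fitness_factory, scheme.n_segments, cfg.bpso,
                        n_runs=cfg.n_runs, threshold=cfg.threshold,
                    )
                    consensus[key] = cons
                    counts[key] = cons.counts
                    ranges[key] = segments_to_wavenumber_ranges(
                        cons.selected, scheme, s.wavenumbers
                    )
                    model, report = consensus_refit(
                        cons.selected, X, y, scheme, spec, outer,
                        prediction_fold=cfg.prediction_fold, inner_folds=inner,
                        component=comp, method=method,
                    )
                reports.append(report)
                from .models import predict as _predict

                cols = (
                    mask_to_variables(consensus[key].selected, scheme)
                    if key in consensus
                    else np.arange(X.shape[1])
                )
                predictions[key] = pd.DataFrame(
                    {
                        "sample_id": [s.row_ids[i] for i in pred_idx],
                        "actual": y[pred_idx],
                        "predicted": _predict(model, X[np.ix_(pred_idx, cols)]),
                    }
                )
                log.info("component=%s method=%s stage=done Rp=%.4f RMSEP=%.4f",
                         comp, method, report.Rp, report.RMSEP)
            except Exception as exc:  # one failing cell must not sink the rest
                failures[key] = str(exc)
                log.error("component=%s method=%s stage=failed reason=%s",
                          comp, method, exc)

    cfg_record = _jsonable(cfg)
    cfg_record.pop("outdir", None)  # environment detail, not experiment identity
    manifest = {
        "nircal_version": __version__,
        "config": cfg_record,
        "components": list(components),
        "seeds": {
            "cv": cfg.cv_seed,
            "inner_cv": cfg.inner_cv_seed,
            "bpso_base": cfg.bpso.seed,
            "simulation": cfg.simulation.seed if cfg.simulation else None,
        },
        "planted_segments": truth.informative_segments if truth else None,
    }
    result = ExperimentResult(
        reports, consensus, ranges, counts, predictions, manifest, failures
    )
    if cfg.outdir:
        _write_outputs(result, cfg)
    return result


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_outputs(result: ExperimentResult, cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.metrics_frame().to_csv(out / "metrics.csv", index=False, float_format="%.10g")
    for (comp, method), cons in result.consensus.items():
        tag = f"{comp}_{method}"
        pd.DataFrame(
            {"segment": np.arange(cons.counts.size), "count": cons.counts,
             "selected": cons.selected.astype(int)}
        ).to_csv(out / f"segment_counts_{tag}.csv", index=False)
        pd.DataFrame(
            result.selected_ranges[(comp, method)], columns=["low_cm1", "high_cm1"]
        ).to_csv(out / f"selected_ranges_{tag}.csv", index=False, float_format="%.10g")
        curves = pd.DataFrame(
            {f"run{i}": run.convergence for i, run in enumerate(cons.runs)}
        )
        curves.insert(0, "generation", np.arange(1, curves.shape[0] + 1))
        curves.to_csv(out / f"convergence_{tag}.csv", index=False, float_format="%.10g")
    for (comp, method), df in result.predictions.items():
        df.to_csv(out / f"predictions_{comp}_{method}.csv", index=False,
                  float_format="%.10g")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
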