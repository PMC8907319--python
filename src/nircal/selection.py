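"""Consensus wavelength selection from repeated BPSO runs.

A single BPSO run is stochastic; the field's remedy is to repeat the
optimization many times with independent seeds and keep the segments
that the per-run best masks agree on. A segment enters the final
selection when its count across runs strictly exceeds the threshold
(e.g. more than 50 of 100 runs).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bpso import BPSOConfig, BPSORun, run_bpso
from .metrics import EvaluationReport, evaluate
from .models import FittedModel, FoldAssignment, PLSParams, fit_model
from .segmentation import SegmentScheme, mask_to_variables

__all__ = ["ConsensusResult", "run_consensus", "consensus_refit", "derive_run_seed"]


@dataclass
class ConsensusResult:
    """Per-segment selection counts over n_runs best masks, and the verdict."""

    n_runs: int
    threshold: int
    counts: np.ndarray
    selected: np.ndarray  # uint8, counts > threshold
    runs: list[BPSORun]


def derive_run_seed(base_seed: int, run_index: int) -> int:
    """Independent, reproducible per-run seed below 2^31."""
    ss = np.random.SeedSequence((int(base_seed), int(run_index)))
    return int(ss.generate_state(1)[0] % (2**31))


def run_consensus(
    fitness_factory,
    n_bits: int,
    cfg: BPSOConfig,
    n_runs: int = 100,
    threshold: int | None = None,
) -> ConsensusResult:
    """Repeat BPSO ``n_runs`` times and apply the frequency-consensus rule.

    Parameters
    ----------
    fitness_factory : callable
        ``fitness_factory(run_index) -> fitness callable``. A factory (not
        a bare function) so each run may carry its own cache or state.
    threshold : int, optional
        Strict count threshold; default ``n_runs // 2`` (i.e. "selected in
        more than half the runs").
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if threshold is None:
        threshold = n_runs // 2
    if not 0 <= threshold <= n_runs:
        raise ValueError("threshold must be in [0, n_runs]")
    counts = np.zeros(n_bits, dtype=int)
    runs: list[BPSORun] = []
    for i in range(n_runs):
        run_cfg = replace(cfg, seed=derive_run_seed(cfg.seed, i))
        try:
            run = run_bpso(fitness_factory(i), n_bits, run_cfg)
        except Exception as exc:
            raise RuntimeError(f"BPSO run {i} failed: {exc}") from exc
        counts += run.best_position.astype(int)
        runs.append(run)
    selected = (counts > threshold).astype(np.uint8)
    return ConsensusResult(n_runs, threshold, counts, selected, runs)


def consensus_refit(
    selected,
    X,
    y,
    scheme: SegmentScheme,
    model_spec,
    folds: FoldAssignment,
    prediction_fold: int = 0,
    inner_folds: FoldAssignment | None = None,
    component: str = "",
    method: str = "",
) -> tuple[FittedModel, EvaluationReport]:
    """Refit on the consensus variables and report calibration/prediction metrics.

    ``folds`` is the outer split: ``prediction_fold`` is held out as the
    prediction set, the remaining folds form the calibration set. For a
    PLS spec with ``n_latent=None`` the latent count is chosen on the
    calibration set using ``inner_folds`` (built there if not given).
    """
    selected = np.asarray(selected)
    if selected.sum() == 0:
        raise ValueError("empty segment selection; cannot refit")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cols = mask_to_variables(selected, scheme)
    cal = folds.train_indices(prediction_fold)
    pred = folds.test_indices(prediction_fold)
    X_cal, y_cal = X[np.ix_(cal, cols)], y[cal]
    X_pred, y_pred = X[np.ix_(pred, cols)], y[pred]
    if (
        isinstance(model_spec, PLSParams)
        and model_spec.n_latent is None
        and inner_folds is None
    ):
        inner_folds = FoldAssignment(
            cal.size,
            min(folds.n_folds, cal.size),
            np.arange(cal.size) % min(folds.n_folds, cal.size),
            folds.seed,
        )
    model = fit_model(model_spec, X_cal, y_cal, folds=inner_folds)
    report = evaluate(
        model, X_cal, y_cal, X_pred, y_pred, component=component, method=method
    )
    return model, report
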