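"""Wavelength-segment selection by consensus over repeated BPSO runs.

Builds a desk-scale synthetic tea dataset (654 variables, 21 segments),
uses tenfold cross-validated PLS RMSE as the fitness of a segment
bitmask, repeats a 30-generation binary PSO 20 times and keeps the
segments selected in more than half of the runs — then compares the
result against the generator's planted ground truth.
"""

import numpy as np

from nircal import (
    BPSOConfig,
    PLSParams,
    align,
    default_tea_config,
    make_segments,
    run_consensus,
    simulate,
    snv,
    tenfold_split,
)
from nircal.pipeline import make_cv_fitness

component = "moisture"

cfg = default_tea_config(seed=1, n_vars=654)
spectra, tables, truth = simulate(cfg)
spectra = snv(spectra)
ref = next(t for t in tables if t.component == component)
s, r = align(spectra, ref)
X, y = s.absorbance, r.array(s.row_ids)

outer = tenfold_split(len(y), 10, seed=7)          # fold 0 held out for prediction
cal = outer.train_indices(0)
inner = tenfold_split(cal.size, 10, seed=11)       # fitness folds, calibration only
scheme = make_segments(X.shape[1], 21)

cache: dict = {}
factory = lambda i: make_cv_fitness(  # noqa: E731
    PLSParams(), X[cal], y[cal], inner, scheme, cache
)
result = run_consensus(factory, scheme.n_segments,
                       BPSOConfig(seed=42, max_generations=30), n_runs=20)

print(f"component: {component}")
print(f"per-segment counts over {result.n_runs} runs (threshold > {result.threshold}):")
print("  " + " ".join(f"{c:2d}" for c in result.counts))
selected = sorted(np.where(result.selected)[0].tolist())
print(f"selected segments: {selected}")
print(f"planted segments:  {truth.informative_segments[component]}")
print()
print("Segments holding the two water bands are selected in (almost) every")
print("run; segments with no moisture information stay far below threshold.")
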