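"""Spectral pretreatment: replicate averaging and the standard normal variate.

SNV transforms each spectrum x to (x - mean(x)) / sd(x), removing the
per-spectrum multiplicative gain and additive offset that particle-size
and path-length variation impose on diffuse-reflectance measurements.
Averaging of replicate scans, when replicate grouping is present, happens
before any pretreatment so the averaged spectrum is the analytical unit.
"""

from __future__ import annotations

import numpy as np

from .spectra_io import SpectraSet

__all__ = ["average_replicates", "snv"]


def average_replicates(s: SpectraSet) -> SpectraSet:
    """Collapse replicate scans to one arithmetic-mean spectrum per sample.

    Groups come from ``s.replicate_of`` (row_id -> sample_id); output rows
    follow the first-appearance order of groups. Raises ``ValueError`` if no
    replicate map is present — in that case skip averaging.
    """
    if s.replicate_of is None:
        raise ValueError(
            "SpectraSet has no replicate_of map; skip replicate averaging"
        )
    groups: dict[str, list[int]] = {}
    for i, rid in enumerate(s.row_ids):
        sid = s.replicate_of.get(rid, rid)
        groups.setdefault(sid, []).append(i)
    out = np.vstack([s.absorbance[idx].mean(axis=0) for idx in groups.values()])
    return SpectraSet(s.wavenumbers.copy(), out, list(groups.keys()))


def snv(s: SpectraSet, ddof: int = 1) -> SpectraSet:
    """Standard normal variate: center and scale each spectrum row-wise.

    Parameters
    ----------
    s : SpectraSet
        Input spectra; every row needs at least 2 variables and nonzero
        spread.
    ddof : {0, 1}
        Delta degrees of freedom for the row standard deviation; the
        default 1 (sample sd) is the dominant SNV convention.

    Returns
    -------
    SpectraSet
        Rows with mean 0 and sd (at the chosen ddof) 1.
    """
    if s.n_wavenumbers < 2:
        raise ValueError("SNV needs at least 2 variables per spectrum")
    mean = s.absorbance.mean(axis=1, keepdims=True)
    sd = s.absorbance.std(axis=1, ddof=ddof, keepdims=True)
    zero = np.where(sd[:, 0] == 0)[0]
    if zero.size:
        raise ValueError(
            f"constant spectrum (zero variance) in rows: "
            f"{[s.row_ids[i] for i in zero]}"
        )
    return SpectraSet(
        s.wavenumbers.copy(),
        (s.absorbance - mean) / sd,
        list(s.row_ids),
        dict(s.replicate_of) if s.replicate_of is not None else None,
    )
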