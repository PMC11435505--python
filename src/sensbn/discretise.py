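"""Supervised discretisation by class-attribute interdependence maximisation.

Continuous assay and physico-chemical inputs enter the Bayesian network as
discrete nodes.  Cut points are chosen on training data only, by greedily
maximising the CAIM criterion

    caim(B) = (1 / n_intervals) * sum_r  max_c n_rc ** 2 / n_r

where ``n_rc`` counts training compounds of potency class ``c`` falling in
interval ``r`` and ``n_r`` is the interval total.  Candidate boundaries are
midpoints between consecutive distinct sorted values, added one at a time;
ties in the criterion are broken by the smallest boundary so a fit is fully
deterministic.  By default a variable is forced into four bins when enough
distinct values exist (the network treats every discretised input as a
4-level node); ``force_max_bins=False`` instead stops as soon as adding a
boundary no longer increases the criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class DiscretisationScheme:
    """Ordered cut points mapping a continuous variable to bins.

    ``n_bins == len(cut_points) + 1``; intervals are left-closed/right-open,
    with values below the first cut in bin 0 and values at/above the last cut
    in the last bin.
    """

    variable: str
    cut_points: tuple[float, ...]
    n_bins: int

    def __post_init__(self):
        cuts = tuple(float(c) for c in self.cut_points)
        if any(not np.isfinite(c) for c in cuts):
            raise ValueError(f"{self.variable}: cut points must be finite")
        if list(cuts) != sorted(set(cuts)):
            raise ValueError(f"{self.variable}: cut points must strictly increase")
        if self.n_bins != len(cuts) + 1:
            raise ValueError(f"{self.variable}: n_bins must equal len(cut_points)+1")
        object.__setattr__(self, "cut_points", cuts)

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "DiscretisationScheme":
        return cls(d["variable"], tuple(d["cut_points"]), int(d["n_bins"]))


def caim_score(boundaries: Sequence[float], values: np.ndarray,
               labels: np.ndarray) -> float:
    """CAIM criterion for a boundary set on (value, label) pairs."""
    edges = np.asarray(sorted(boundaries), dtype=float)
    bins = np.searchsorted(edges, values, side="right")
    n_intervals = len(edges) + 1
    total = 0.0
    for r in range(n_intervals):
        in_r = labels[bins == r]
        if in_r.size == 0:
            continue
        _, counts = np.unique(in_r, return_counts=True)
        total += counts.max() ** 2 / in_r.size
    return total / n_intervals


def caim_fit(values, labels, max_bins: int = 4, variable: str = "",
             force_max_bins: bool = True) -> DiscretisationScheme:
    """Fit a CAIM scheme on training values and their potency labels.

    Missing values (NaN/None) are dropped together with their labels before
    fitting.  Requires at least two distinct observed values.
    """
    values = np.asarray(
        [np.nan if v is None else v for v in np.asarray(values, dtype=object)],
        dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    keep = np.isfinite(values) & np.array([l is not None and l == l for l in labels])
    values, labels = values[keep], labels[keep]
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError(
            f"{variable or 'variable'}: need >= 2 distinct observed values, "
            f"got {distinct.size}")

    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    boundaries: list[float] = []
    current = -np.inf
    while len(boundaries) + 1 < max_bins and len(boundaries) < candidates.size:
        best_c, best_s = None, -np.inf
        for c in candidates:
            if c in boundaries:
                continue
            s = caim_score(boundaries + [c], values, labels)
            if s > best_s + 1e-12:  # strict improvement; first (smallest) c wins ties
                best_c, best_s = c, s
        if best_c is None:
            break
        if not force_max_bins and best_s <= current:
            break  # improvement-based stop: criterion no longer increases
        boundaries.append(float(best_c))
        current = best_s
    boundaries.sort()
    return DiscretisationScheme(variable, tuple(boundaries), len(boundaries) + 1)


def apply_scheme(scheme: DiscretisationScheme, value) -> Optional[int]:
    """Bin index of ``value`` under ``scheme``; missing propagates as None."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{scheme.variable}: non-finite value {value!r}")
    return int(np.searchsorted(np.asarray(scheme.cut_points), value, side="right"))


def apply_scheme_array(scheme: DiscretisationScheme, values) -> np.ndarray:
    """Vectorised :func:`apply_scheme`; missing entries become -1."""
    values = np.asarray(values, dtype=float)
    if np.isinf(values).any():
        raise ValueError(f"{scheme.variable}: non-finite values present")
    out = np.searchsorted(np.asarray(scheme.cut_points), values, side="right")
    out = out.astype(np.int64)
    out[~np.isfinite(values)] = -1
    return out


def schemes_to_json(schemes: dict[str, DiscretisationScheme]) -> list[dict]:
    return [schemes[k].to_json() for k in schemes]


def schemes_from_json(items: list[dict]) -> dict[str, DiscretisationScheme]:
    out = {}
    for d in items:
        s = DiscretisationScheme.from_json(d)
        out[s.variable] = s
    return out
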