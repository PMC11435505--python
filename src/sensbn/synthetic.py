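"""Seeded generator of synthetic compound datasets.

The generator emulates the *statistical* structure the defined approach
assumes — not the chemistry of any real compound set: a 4-class potency
mixture; a true pEC3 drawn uniformly within the class interval; continuous
assay readouts that are monotone functions of pEC3 (depletions and rate
constants increase with potency, effective concentrations decrease) with
seeded noise and a shared within-group latent factor so the latent-class
stage has genuine structure to find; a kDPRA GHS call thresholded from the
generated Kmax; categorical in silico calls drawn from per-class confusion
rows; per-column missingness; and a molecular weight drawn log-uniformly in
[100, 500] g/mol with the LLNA EC3% back-derived from pEC3 so every
data-model formula round-trips exactly.

``noiseless=True`` switches off assay noise, missingness and in silico
confusion (calls become the deterministic class mapping), producing a
class-separable dataset on which the full pipeline must score near-perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .data_model import (CLASSES4, COLUMNS, DEREK_LEVELS, SKIN_DOCTOR_LEVELS,
                         TIMES_LEVELS, Dataset, dataset_from_frame,
                         map4_to_human3)

#: pEC3 interval bounds for the open outer classes.
PEC3_LO, PEC3_HI = -3.5, 1.0
_CLASS_EDGES = (PEC3_LO, -1.9, -1.1, -0.35, PEC3_HI)

#: GHS 1A call when log10 Kmax >= this (OECD 442C convention, generator only).
LOG_KMAX_1A = -2.0

_DEFAULT_MISSING = {
    "dpra_cys": 0.05, "dpra_lys": 0.05,
    "kdpra_kmax": 0.30, "kdpra_class": 0.30,
    "ks_ec15": 0.10, "ks_ec3": 0.15, "ks_ic50": 0.15,
    "hclat_ec150": 0.10, "hclat_ec200": 0.12, "hclat_cv75": 0.12,
    "log_kow": 0.02, "log_d_ph7": 0.02, "ws_ph7": 0.05,
    "protein_binding": 0.05,
    "skin_doctor_class": 0.05, "derek_class": 0.05, "times_class": 0.05,
}

# confusion rows: true 4-class -> call distribution
_SD_CONFUSION = np.array([  # -> non / weak-to-moderate / strong-to-extreme
    [0.80, 0.15, 0.05],
    [0.30, 0.55, 0.15],
    [0.15, 0.60, 0.25],
    [0.05, 0.25, 0.70],
])
_SD_EXACT = np.array([[1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1]], dtype=float)

_DEREK_CONFUSION = np.array([
    [0.70, 0.20, 0.07, 0.03],
    [0.20, 0.55, 0.18, 0.07],
    [0.07, 0.20, 0.55, 0.18],
    [0.03, 0.07, 0.25, 0.65],
])
_DEREK_EXACT = np.eye(4)

_TIMES_CONFUSION = np.array([  # -> non/weak/moderate/strong/extreme
    [0.70, 0.18, 0.08, 0.03, 0.01],
    [0.18, 0.52, 0.20, 0.08, 0.02],
    [0.07, 0.18, 0.50, 0.20, 0.05],
    [0.02, 0.06, 0.17, 0.50, 0.25],
])
_TIMES_EXACT = np.array([[1, 0, 0, 0, 0], [0, 1, 0, 0, 0],
                         [0, 0, 1, 0, 0], [0, 0, 0, 1, 0]], dtype=float)


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the package's standard
    realistic conditions and should not be tuned per-experiment."""

    n: int = 200
    seed: int = 0
    class_mixture: tuple[float, ...] = (0.25, 0.30, 0.25, 0.20)
    noise: float = 0.40          # sd of assay noise on the log/logit scale
    group_sd: float = 0.30       # sd of the shared within-group latent factor
    missing_rates: dict = field(default_factory=lambda: dict(_DEFAULT_MISSING))
    sd_confusion: Optional[np.ndarray] = None
    derek_confusion: Optional[np.ndarray] = None
    times_confusion: Optional[np.ndarray] = None
    noiseless: bool = False
    n_structureless: int = 0     # rows emitted without SMILES / Mw

    def __post_init__(self):
        mix = np.asarray(self.class_mixture, dtype=float)
        if mix.shape != (4,) or not np.isclose(mix.sum(), 1.0):
            raise ValueError("class_mixture must be a probability 4-vector")
        if any(not (0 <= r < 1) for r in self.missing_rates.values()):
            raise ValueError("missing rates must lie in [0, 1)")
        if self.n < 0:
            raise ValueError("n must be non-negative")

    def to_yaml(self) -> str:
        d = asdict(self)
        for k in ("sd_confusion", "derek_confusion", "times_confusion"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        d["class_mixture"] = list(d["class_mixture"])
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text)
        d["class_mixture"] = tuple(d["class_mixture"])
        for k in ("sd_confusion", "derek_confusion", "times_confusion"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_dataset(cfg: SimConfig, role: str = "train") -> Dataset:
    """Draw a synthetic compound dataset under ``cfg`` (bit-reproducible)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    noise = 0.0 if cfg.noiseless else cfg.noise
    gsd = 0.0 if cfg.noiseless else cfg.group_sd

    cls = rng.choice(4, size=n, p=np.asarray(cfg.class_mixture, dtype=float))
    lo = np.asarray(_CLASS_EDGES[:-1])[cls]
    hi = np.asarray(_CLASS_EDGES[1:])[cls]
    pec3 = rng.uniform(lo, hi)
    mw = np.exp(rng.uniform(np.log(100.0), np.log(500.0), size=n))
    ec3 = mw / 250.0 / 10.0 ** pec3

    eps = lambda: rng.normal(0.0, 1.0, size=n) * noise
    g_cys = rng.normal(0.0, 1.0, size=n) * gsd
    g_cyt = rng.normal(0.0, 1.0, size=n) * gsd
    g_hcl = rng.normal(0.0, 1.0, size=n) * gsd

    dpra_cys = 100.0 * _sigmoid(1.8 * (pec3 + 1.1) + g_cys + eps())
    dpra_lys = 100.0 * _sigmoid(1.2 * (pec3 + 1.3) + g_cys + eps())
    log_kmax = 1.5 * pec3 - 0.5 + 0.5 * g_cys + eps()
    kdpra_kmax = 10.0 ** np.clip(log_kmax, -6.0, 3.0)
    kdpra_class = np.where(log_kmax >= LOG_KMAX_1A, "1A", "1B/NC")

    ks_ec15 = 10.0 ** np.clip(1.2 - 1.1 * pec3 + g_cyt + eps(), -3.0, 4.0)
    ks_ec3 = 10.0 ** np.clip(1.5 - 1.1 * pec3 + g_cyt + eps(), -3.0, 4.0)
    ks_ic50 = 10.0 ** np.clip(2.0 - 0.9 * pec3 + g_cyt + eps(), -3.0, 4.0)

    hclat_ec150 = 10.0 ** np.clip(1.3 - 1.0 * pec3 + g_hcl + eps(), -3.0, 4.0)
    hclat_ec200 = 10.0 ** np.clip(1.5 - 1.0 * pec3 + g_hcl + eps(), -3.0, 4.0)
    hclat_cv75 = 10.0 ** np.clip(1.8 - 0.8 * pec3 + g_hcl + eps(), -3.0, 4.0)

    # physico-chemical block: driven by a lipophilicity latent, potency-free
    lipo = rng.normal(2.5, 1.2, size=n)
    log_kow = lipo + eps() * 0.3
    delta = np.abs(rng.normal(0.4, 0.3, size=n))  # ionisation drop, logD<=logKow
    log_d = log_kow - delta
    ws = 10.0 ** np.clip(3.0 - 0.9 * lipo + eps(), -4.0, 6.0)
    protein_binding = 100.0 * _sigmoid(0.8 * (lipo - 1.5) + eps())

    def draw_calls(levels, confusion, exact):
        P = np.asarray(exact if cfg.noiseless else confusion, dtype=float)
        idx = np.array([rng.choice(P.shape[1], p=P[c] / P[c].sum())
                        for c in cls]) if n else np.array([], dtype=int)
        return np.asarray(levels, dtype=object)[idx] if n else np.array([], dtype=object)

    skin_doctor = draw_calls(SKIN_DOCTOR_LEVELS,
                             cfg.sd_confusion if cfg.sd_confusion is not None
                             else _SD_CONFUSION, _SD_EXACT)
    derek = draw_calls(DEREK_LEVELS,
                       cfg.derek_confusion if cfg.derek_confusion is not None
                       else _DEREK_CONFUSION, _DEREK_EXACT)
    times = draw_calls(TIMES_LEVELS,
                       cfg.times_confusion if cfg.times_confusion is not None
                       else _TIMES_CONFUSION, _TIMES_EXACT)

    class4 = np.asarray(CLASSES4, dtype=object)[cls]
    df = pd.DataFrame({
        "compound_id": [f"synth-{cfg.seed}-{i:04d}" for i in range(n)],
        "smiles": [f"C(synthetic-{i})" for i in range(n)],
        "mw": mw,
        "dpra_cys": dpra_cys, "dpra_lys": dpra_lys,
        "kdpra_kmax": kdpra_kmax, "kdpra_class": kdpra_class,
        "ks_ec15": ks_ec15, "ks_ec3": ks_ec3, "ks_ic50": ks_ic50,
        "hclat_ec150": hclat_ec150, "hclat_ec200": hclat_ec200,
        "hclat_cv75": hclat_cv75,
        "log_kow": log_kow, "log_d_ph7": log_d, "ws_ph7": ws,
        "protein_binding": protein_binding,
        "f_ion": np.abs(1.0 - 10.0 ** (log_d - log_kow)),
        "skin_doctor_class": skin_doctor, "derek_class": derek,
        "times_class": times,
        "llna_ec3": ec3, "pec3": pec3,
        "potency_class4": class4,
        "human_class3": [map4_to_human3(c) for c in class4],
    }, columns=list(COLUMNS))

    if not cfg.noiseless:
        for col in sorted(cfg.missing_rates):
            rate = cfg.missing_rates[col]
            if rate <= 0 or col not in df.columns:
                continue
            mask = rng.random(n) < rate
            df.loc[mask, col] = np.nan

    if cfg.n_structureless > 0 and n > 0:
        drop = rng.choice(n, size=min(cfg.n_structureless, n), replace=False)
        df.loc[drop, ["smiles", "mw", "llna_ec3"]] = np.nan

    return dataset_from_frame(df, role=role)
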