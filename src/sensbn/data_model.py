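"""Domain types, unit conversions, class mappings and CSV I/O.

The potency endpoint is the murine LLNA EC3 value: the % concentration of a
compound that triggers a 3-fold lymphocyte proliferation.  For modelling it is
put on a molar log scale,

    pEC3 = log10(Mw / 250 / EC3%),

so that *larger* pEC3 means *more potent* (a lower effective concentration).
Four potency classes are derived from pEC3 with thresholds -1.9 / -1.1 / -0.35:
non < weak < moderate < strong.  For comparison against human potency gradings
the four classes collapse to three (moderate and weak merge).

Records carry three groups of inputs:

* in chemico / in vitro panel: DPRA cysteine & lysine % depletion, kDPRA rate
  constant Kmax (1/sM) and its GHS 1A vs 1B/NC call, KeratinoSens EC1.5 / EC3 /
  IC50 (uM), h-CLAT EC150 / EC200 / CV75 (uM);
* in silico panel: logKow, logD@pH7, water solubility@pH7, plasma-protein
  binding, fraction ionised, and categorical potency calls from Skin Doctor CP,
  Derek Nexus and (baseline model only) TIMES-SS;
* the LLNA outcome (EC3 / pEC3 / 4-class label) for training and evaluation,
  plus an optional 3-class human label for external evaluation.

Every assay field is independently optional: the Bayesian network marginalises
over whatever is missing.  Missing values are empty CSV cells externally and
NaN / None internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Class labels and thresholds
# ---------------------------------------------------------------------------

#: 4-class LLNA potency labels in increasing potency order.
CLASSES4: tuple[str, ...] = ("non", "weak", "moderate", "strong")

#: 3-class human potency labels in increasing potency order.
CLASSES3: tuple[str, ...] = ("non", "weak", "strong")

#: pEC3 thresholds separating the four potency classes.
PEC3_THRESHOLDS: tuple[float, float, float] = (-1.9, -1.1, -0.35)

#: Categorical level orders (index = network state).
KDPRA_LEVELS: tuple[str, ...] = ("1B/NC", "1A")
SKIN_DOCTOR_LEVELS: tuple[str, ...] = ("non", "weak-to-moderate", "strong-to-extreme")
DEREK_LEVELS: tuple[str, ...] = ("non", "weak", "moderate", "strong+extreme")
TIMES_LEVELS: tuple[str, ...] = ("non", "weak", "moderate", "strong", "extreme")

#: Fixed CSV schema, one row per compound.
COLUMNS: tuple[str, ...] = (
    "compound_id", "smiles", "mw",
    "dpra_cys", "dpra_lys", "kdpra_kmax", "kdpra_class",
    "ks_ec15", "ks_ec3", "ks_ic50",
    "hclat_ec150", "hclat_ec200", "hclat_cv75",
    "log_kow", "log_d_ph7", "ws_ph7", "protein_binding", "f_ion",
    "skin_doctor_class", "derek_class", "times_class",
    "llna_ec3", "pec3", "potency_class4", "human_class3",
)

_NUMERIC_COLUMNS = (
    "mw", "dpra_cys", "dpra_lys", "kdpra_kmax",
    "ks_ec15", "ks_ec3", "ks_ic50",
    "hclat_ec150", "hclat_ec200", "hclat_cv75",
    "log_kow", "log_d_ph7", "ws_ph7", "protein_binding", "f_ion",
    "llna_ec3", "pec3",
)

_POSITIVE_COLUMNS = (
    "mw", "kdpra_kmax", "ks_ec15", "ks_ec3", "ks_ic50",
    "hclat_ec150", "hclat_ec200", "hclat_cv75", "llna_ec3",
)

_PERCENT_COLUMNS = ("dpra_cys", "dpra_lys")

_CATEGORICAL_LEVELS = {
    "kdpra_class": set(KDPRA_LEVELS),
    # binary Skin Doctor CP calls are accepted on read; the shipped networks
    # use the ternary potency levels
    "skin_doctor_class": set(SKIN_DOCTOR_LEVELS) | {"sensitiser"},
    "derek_class": set(DEREK_LEVELS),
    "times_class": set(TIMES_LEVELS),
    "potency_class4": set(CLASSES4),
    "human_class3": set(CLASSES3),
}

#: Sentinel Skin Doctor CP output when the conformal predictor abstains.
NO_PREDICTION = "no prediction"


class DataError(ValueError):
    """Raised on schema violations, out-of-range values or inconsistent rows."""


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------

def pec3_from_ec3(mw: float, ec3_percent: float) -> float:
    """Molar-adjusted log potency from an LLNA EC3 in % w/w.

    pEC3 = log10(mw / 250 / ec3_percent); higher values are more potent.
    """
    if not (mw > 0) or not (ec3_percent > 0):
        raise DataError(
            f"pec3_from_ec3 requires mw > 0 and ec3_percent > 0, "
            f"got mw={mw!r}, ec3_percent={ec3_percent!r}"
        )
    return math.log10(mw / 250.0 / ec3_percent)


def potency_class_from_pec3(pec3: float) -> str:
    """4-class potency label from pEC3.

    Intervals are left-closed / right-open; pEC3 >= -0.35 is "strong".
    """
    if pec3 is None or not math.isfinite(pec3):
        raise DataError(f"pec3 must be finite, got {pec3!r}")
    t_non, t_weak, t_mod = PEC3_THRESHOLDS
    if pec3 < t_non:
        return "non"
    if pec3 < t_weak:
        return "weak"
    if pec3 < t_mod:
        return "moderate"
    return "strong"


def depletion_from_remaining(remaining: float) -> float:
    """DPRA % depletion from % peptide remaining (their complement)."""
    if not (0.0 <= remaining <= 100.0):
        raise DataError(f"remaining must lie in [0, 100], got {remaining!r}")
    return 100.0 - remaining


def fraction_ionised(log_d: float, log_kow: float) -> float:
    """Fraction of compound ionised at pH 7: |1 - 10^logD / 10^logKow|.

    The value is not clamped to [0, 1]; logD > logKow yields values above 1
    which downstream discretisation absorbs.
    """
    if not (math.isfinite(log_d) and math.isfinite(log_kow)):
        raise DataError(
            f"log_d and log_kow must be finite, got {log_d!r}, {log_kow!r}"
        )
    return abs(1.0 - 10.0 ** (log_d - log_kow))


def map4_to_human3(class4: str) -> str:
    """Collapse 4 LLNA classes to 3 human classes (moderate merges into weak)."""
    mapping = {"non": "non", "weak": "weak", "moderate": "weak", "strong": "strong"}
    try:
        return mapping[class4]
    except KeyError:
        raise DataError(f"unknown 4-class label {class4!r}") from None


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass
class AssayPanel:
    dpra_cys: Optional[float] = None
    dpra_lys: Optional[float] = None
    kdpra_kmax: Optional[float] = None
    kdpra_class: Optional[str] = None
    ks_ec15: Optional[float] = None
    ks_ec3: Optional[float] = None
    ks_ic50: Optional[float] = None
    hclat_ec150: Optional[float] = None
    hclat_ec200: Optional[float] = None
    hclat_cv75: Optional[float] = None


@dataclass
class InSilicoPanel:
    log_kow: Optional[float] = None
    log_d_ph7: Optional[float] = None
    ws_ph7: Optional[float] = None
    protein_binding: Optional[float] = None
    f_ion: Optional[float] = None
    skin_doctor_class: Optional[str] = None
    derek_class: Optional[str] = None
    times_class: Optional[str] = None


@dataclass
class LLNAOutcome:
    ec3_percent: Optional[float] = None
    pec3: Optional[float] = None
    potency_class4: Optional[str] = None


@dataclass
class CompoundRecord:
    compound_id: str
    smiles: Optional[str] = None
    mw: Optional[float] = None
    assay: AssayPanel = field(default_factory=AssayPanel)
    insilico: InSilicoPanel = field(default_factory=InSilicoPanel)
    llna: Optional[LLNAOutcome] = None
    human_class3: Optional[str] = None


@dataclass
class Dataset:
    """An ordered compound table plus its role (train / test / external).

    The canonical in-memory form is a pandas DataFrame with the fixed column
    schema; ``records`` materialises typed :class:`CompoundRecord` views.
    """

    frame: pd.DataFrame
    role: str = "train"

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[CompoundRecord]:
        out = []
        for _, row in self.frame.iterrows():
            g = lambda c: None if pd.isna(row[c]) else row[c]
            llna = None
            if any(g(c) is not None for c in ("llna_ec3", "pec3", "potency_class4")):
                llna = LLNAOutcome(g("llna_ec3"), g("pec3"), g("potency_class4"))
            out.append(CompoundRecord(
                compound_id=row["compound_id"],
                smiles=g("smiles"),
                mw=g("mw"),
                assay=AssayPanel(*(g(c) for c in (
                    "dpra_cys", "dpra_lys", "kdpra_kmax", "kdpra_class",
                    "ks_ec15", "ks_ec3", "ks_ic50",
                    "hclat_ec150", "hclat_ec200", "hclat_cv75"))),
                insilico=InSilicoPanel(*(g(c) for c in (
                    "log_kow", "log_d_ph7", "ws_ph7", "protein_binding", "f_ion",
                    "skin_doctor_class", "derek_class", "times_class"))),
                llna=llna,
                human_class3=g("human_class3"),
            ))
        return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _validate_frame(df: pd.DataFrame, allow_duplicates: bool) -> None:
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"missing required columns: {missing_cols}")
    ids = df["compound_id"]
    if ids.isna().any():
        raise DataError("compound_id must be present on every row")
    if not allow_duplicates and ids.duplicated().any():
        dup = sorted(ids[ids.duplicated()].unique())
        raise DataError(
            f"duplicate compound_id(s) {dup}; pass allow_duplicates=True to "
            f"keep a published split that intentionally repeats compounds"
        )
    for col in _PERCENT_COLUMNS:
        bad = df.index[(df[col] < 0) | (df[col] > 100)]
        if len(bad):
            raise DataError(
                f"column {col!r} out of [0, 100] on row(s) {list(bad)} "
                f"(compound {df.loc[bad[0], 'compound_id']!r})"
            )
    for col in _POSITIVE_COLUMNS:
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise DataError(
                f"column {col!r} must be > 0 on row(s) {list(bad)} "
                f"(compound {df.loc[bad[0], 'compound_id']!r})"
            )
    for col, levels in _CATEGORICAL_LEVELS.items():
        vals = df[col].dropna()
        bad = sorted(set(vals) - levels)
        if bad:
            raise DataError(f"column {col!r} has unknown level(s) {bad}")


def _backfill(df: pd.DataFrame) -> pd.DataFrame:
    """Derive pec3, f_ion and potency_class4 where the formulas apply.

    f_ion is always recomputed when both logD and logKow are present so the
    stored value can never drift from its defining formula.
    """
    df = df.copy()
    for col in _CATEGORICAL_LEVELS:
        df[col] = df[col].astype(object)
    df["potency_class4"] = df["potency_class4"].astype(object)
    for i in df.index:
        mw, ec3, pec3 = df.at[i, "mw"], df.at[i, "llna_ec3"], df.at[i, "pec3"]
        if pd.isna(pec3) and not pd.isna(mw) and not pd.isna(ec3):
            pec3 = pec3_from_ec3(mw, ec3)
            df.at[i, "pec3"] = pec3
        elif not pd.isna(pec3) and not pd.isna(mw) and not pd.isna(ec3):
            if abs(pec3 - pec3_from_ec3(mw, ec3)) > 1e-6:
                raise DataError(
                    f"row {i} (compound {df.at[i, 'compound_id']!r}): supplied "
                    f"pec3={pec3} inconsistent with log10(mw/250/ec3)"
                )
        ld, lk = df.at[i, "log_d_ph7"], df.at[i, "log_kow"]
        if not pd.isna(ld) and not pd.isna(lk):
            df.at[i, "f_ion"] = fraction_ionised(ld, lk)
        if pd.isna(df.at[i, "potency_class4"]) and not pd.isna(df.at[i, "pec3"]):
            df.at[i, "potency_class4"] = potency_class_from_pec3(df.at[i, "pec3"])
    return df


def dataset_from_frame(df: pd.DataFrame, role: str = "train",
                       allow_duplicates: bool = False) -> Dataset:
    """Validate and back-fill an in-memory frame into a :class:`Dataset`."""
    df = df.reindex(columns=list(COLUMNS))
    for col in _NUMERIC_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise DataError(f"column {col!r} is not numeric: {exc}") from None
    _validate_frame(df, allow_duplicates)
    return Dataset(_backfill(df).reset_index(drop=True), role=role)


def read_dataset(path: str | Path, role: str = "train",
                 allow_duplicates: bool = False) -> Dataset:
    """Read a compound CSV (fixed schema, empty cells = missing)."""
    df = pd.read_csv(path, dtype={"compound_id": str, "smiles": str},
                     keep_default_na=True)
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise DataError(f"unexpected column(s) {extra} in {path}")
    return dataset_from_frame(df, role=role, allow_duplicates=allow_duplicates)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a Dataset back to the fixed CSV schema (UTF-8, '.' decimals)."""
    ds.frame.reindex(columns=list(COLUMNS)).to_csv(path, index=False)
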