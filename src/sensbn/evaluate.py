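"""Model training pipeline, metrics, cross-validation and grid search.

``train_full`` runs the complete two-stage training procedure on a labelled
dataset: CAIM discretisation of the continuous inputs (fitted on the training
rows only), latent class analysis per latent node over its discretised
indicator group, writing the modal latent assignments into the training table
as observed values, Dirichlet-smoothed CPT learning, and recording the
(+1-smoothed) training class distribution as the Bayes-factor prior.  The
result is a self-contained :class:`~sensbn.predict.ModelBundle`.

Headline metric everywhere is balanced accuracy — the mean per-class recall
over the four potency classes — reported in percent.  Confidence-stratified
tables use plain accuracy within each Bayes-factor confidence band.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, confusion_matrix

from . import bayesnet, discretise, latent_lca
from .bayesnet import (CATEGORICAL_NODE_COLUMNS, CONTINUOUS_NODE_COLUMNS,
                       NetworkSpec, build_structure, latent_member_map,
                       learn_parameters)
from .data_model import CLASSES3, CLASSES4, Dataset, map4_to_human3
from .predict import (CONFIDENCE_LABELS, NODE_LEVELS, ModelBundle, Prediction,
                      predict_dataset)

logger = logging.getLogger("sensbn")

#: Fallback pEC3 interval bounds when the training labels give no range.
DEFAULT_PEC3_BOUNDS = (-3.5, 1.0)

#: Published optimal hyperparameters per model (latent class counts, NREP).
TABLE1_HYPERPARAMS: dict[str, dict] = {
    "baseline": {"n_classes": {"CYTOX": 3, "CYSTEINE": 4, "HCLAT": 4,
                               "BIOAV": 3}, "n_rep": 20, "pseudo_count": 1},
    "A": {"n_classes": {"CYTOX": 3, "CYSTEINE": 3, "HCLAT": 4, "BIOAV": 3},
          "n_rep": 20, "pseudo_count": 1},
    "B": {"n_classes": {"CYTOX": 3, "CYSTEINE": 3, "HCLAT": 3, "BIOAV": 3,
                        "INSILICO": 4}, "n_rep": 20, "pseudo_count": 1},
}


@dataclass
class HyperParams:
    """Latent-node class counts, LCA restart count, CPT pseudo-count."""

    n_classes: dict[str, int]
    n_rep: int = 20
    pseudo_count: float = 1.0

    @classmethod
    def table1(cls, model_id: str) -> "HyperParams":
        return cls(**{k: (dict(v) if isinstance(v, dict) else v)
                      for k, v in TABLE1_HYPERPARAMS[model_id].items()})

    def to_json(self) -> dict:
        return {"n_classes": dict(self.n_classes), "n_rep": int(self.n_rep),
                "pseudo_count": float(self.pseudo_count)}


@dataclass
class EvalReport:
    balanced_accuracy: float
    overall_accuracy: float
    by_confidence: dict[str, dict]        # label -> {accuracy, n}
    confusion: pd.DataFrame
    n: int
    fold_results: Optional[list[dict]] = None
    n_excluded: int = 0

    def to_json(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "by_confidence": self.by_confidence,
            "confusion": self.confusion.values.tolist(),
            "classes": list(self.confusion.columns),
            "n": self.n,
            "n_excluded": self.n_excluded,
            "fold_results": self.fold_results,
        }


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def balanced_accuracy(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    """Mean per-class recall over the classes present in the truth, in %."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    return 100.0 * float(balanced_accuracy_score(y_true, y_pred))


def accuracy_by_confidence(predictions: Sequence[Prediction],
                           y_true: Sequence[str]) -> dict[str, dict]:
    """Plain accuracy and N within each confidence stratum plus overall."""
    y_true = list(y_true)
    if len(predictions) != len(y_true):
        raise ValueError("predictions and truth must align")
    table: dict[str, dict] = {}
    correct_all = 0
    for label in CONFIDENCE_LABELS:
        idx = [i for i, p in enumerate(predictions) if p.confidence == label]
        n = len(idx)
        correct = sum(predictions[i].predicted_class == y_true[i] for i in idx)
        correct_all += correct
        table[label] = {"accuracy": (100.0 * correct / n) if n else float("nan"),
                        "n": n}
    table["all"] = {"accuracy": 100.0 * correct_all / len(y_true) if y_true
                    else float("nan"), "n": len(y_true)}
    return table


def _report(y_true: Sequence[str], preds: Sequence[Prediction],
            classes: Sequence[str] = CLASSES4, y_pred=None,
            n_excluded: int = 0) -> EvalReport:
    y_pred = [p.predicted_class for p in preds] if y_pred is None else list(y_pred)
    y_true = list(y_true)
    cm = confusion_matrix(y_true, y_pred, labels=list(classes))
    return EvalReport(
        balanced_accuracy=balanced_accuracy(y_true, y_pred),
        overall_accuracy=100.0 * float(np.mean(np.array(y_true) == np.array(y_pred))),
        by_confidence=accuracy_by_confidence(preds, y_true),
        confusion=pd.DataFrame(cm, index=list(classes), columns=list(classes)),
        n=len(y_true),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _discretised_table(ds: Dataset, spec: NetworkSpec,
                       schemes: Mapping[str, discretise.DiscretisationScheme]
                       ) -> pd.DataFrame:
    """Node-state table (int, -1 = missing) for every observable node."""
    df = ds.frame
    out = {}
    for node, col in CONTINUOUS_NODE_COLUMNS.items():
        if node in spec.nodes and node in schemes:
            out[node] = discretise.apply_scheme_array(schemes[node], df[col])
    for node, col in CATEGORICAL_NODE_COLUMNS.items():
        if node in spec.nodes:
            levels = NODE_LEVELS[node]
            out[node] = np.array(
                [levels.index(v) if isinstance(v, str) and v in levels else -1
                 for v in df[col]], dtype=np.int64)
    return pd.DataFrame(out, index=df.index)


def train_full(train: Dataset, model_id: str, hp: HyperParams, seed: int,
               include_kdpra: bool = True) -> ModelBundle:
    """Full training pipeline; deterministic for fixed inputs and seed."""
    df = train.frame
    labels = df["potency_class4"]
    if labels.isna().any():
        raise ValueError("every training row needs a potency_class4 label")

    spec = build_structure(model_id, include_kdpra=include_kdpra)

    # 1. CAIM schemes on the training rows only
    schemes: dict[str, discretise.DiscretisationScheme] = {}
    node_cards: dict[str, int] = {}
    for node, col in CONTINUOUS_NODE_COLUMNS.items():
        if node not in spec.nodes:
            continue
        values = df[col].to_numpy(dtype=float)
        if np.isfinite(values).sum() < 2 or len(np.unique(
                values[np.isfinite(values)])) < 2:
            logger.warning("column %s has < 2 distinct observed values; "
                           "dropping node %s from the network", col, node)
            continue
        scheme = discretise.caim_fit(values, labels.to_numpy(), max_bins=4,
                                     variable=node)
        schemes[node] = scheme
        node_cards[node] = scheme.n_bins
    dropped = [n for n in CONTINUOUS_NODE_COLUMNS
               if n in spec.nodes and n not in schemes]
    if dropped:
        spec = NetworkSpec(
            nodes={k: v for k, v in spec.nodes.items() if k not in dropped},
            edges=[e for e in spec.edges
                   if e[0] not in dropped and e[1] not in dropped],
            target=spec.target, latent=set(spec.latent))

    # 2. latent class analysis per latent node, then 3. write assignments
    for ln in spec.latent:
        node_cards[ln] = hp.n_classes[ln]
    spec = spec.with_cardinalities(node_cards)
    table = _discretised_table(train, spec, schemes)

    lca_models: dict[str, latent_lca.LCAModel] = {}
    members = latent_member_map(spec)
    for i, ln in enumerate(sorted(spec.latent)):
        group = members[ln]
        lspec = latent_lca.LatentSpec(ln, group, hp.n_classes[ln], hp.n_rep)
        rows = table[group].to_numpy()
        model = latent_lca.lca_fit(rows, lspec, seed=seed + 1000 * (i + 1),
                                   n_levels=[spec.nodes[g] for g in group])
        lca_models[ln] = model
        table[ln] = latent_lca.lca_assign_matrix(model, rows)

    # 4. target column and CPT learning
    table[spec.target] = np.array([CLASSES4.index(l) for l in labels],
                                  dtype=np.int64)
    cpts = learn_parameters(spec, table, pseudo_count=hp.pseudo_count)

    # 5. smoothed training prior and pEC3 interval bounds
    counts = np.array([np.sum(labels == c) for c in CLASSES4], dtype=float) + 1.0
    prior4 = counts / counts.sum()
    pec3 = df["pec3"].to_numpy(dtype=float)
    pec3 = pec3[np.isfinite(pec3)]
    lo = min(float(pec3.min()), DEFAULT_PEC3_BOUNDS[0]) if pec3.size else DEFAULT_PEC3_BOUNDS[0]
    hi = max(float(pec3.max()), DEFAULT_PEC3_BOUNDS[1]) if pec3.size else DEFAULT_PEC3_BOUNDS[1]

    return ModelBundle(model_id=model_id, spec=spec, cpts=cpts,
                       schemes=schemes, lca_models=lca_models, prior4=prior4,
                       pec3_bounds=(lo, hi), hyperparams=hp.to_json(),
                       seed=seed)


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------

def evaluate_test(bundle: ModelBundle, test: Dataset) -> EvalReport:
    """Predict a labelled set and score 4-class balanced accuracy."""
    preds = predict_dataset(bundle, test)
    return _report(list(test.frame["potency_class4"]), preds)


def cross_validate(full: Dataset, model_id: str, hp: HyperParams,
                   k: int = 10, seed: int = 0,
                   include_kdpra: bool = True) -> EvalReport:
    """k-fold CV with per-fold refitting of schemes, LCA and CPTs.

    Folds are a seeded uniform random permutation chunked into k near-equal
    parts (unstratified).  The pooled predictions give the cross-validated
    balanced accuracy; per-fold accuracies are reported alongside.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(full)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    y_true_all: list[str] = []
    preds_all: list[Prediction] = []
    fold_results = []
    for f, hold in enumerate(folds):
        hold = np.sort(hold)
        train_idx = np.setdiff1d(perm, hold)
        train_ds = Dataset(full.frame.iloc[train_idx].reset_index(drop=True),
                           role="train")
        test_ds = Dataset(full.frame.iloc[hold].reset_index(drop=True),
                          role="test")
        if train_ds.frame["potency_class4"].nunique() < len(CLASSES4):
            logger.warning("fold %d training data misses a potency class; "
                           "prior smoothing covers it", f)
        bundle = train_full(train_ds, model_id, hp, seed=seed + f,
                            include_kdpra=include_kdpra)
        preds = predict_dataset(bundle, test_ds)
        truth = list(test_ds.frame["potency_class4"])
        fold_results.append({
            "fold": f, "n": len(truth),
            "balanced_accuracy": balanced_accuracy(
                truth, [p.predicted_class for p in preds]),
        })
        y_true_all.extend(truth)
        preds_all.extend(preds)

    report = _report(y_true_all, preds_all)
    report.fold_results = fold_results
    return report


def grid_search(train: Dataset, test: Dataset, model_id: str,
                grids: Optional[Mapping[str, Sequence]] = None,
                seed: int = 0) -> tuple[HyperParams, pd.DataFrame]:
    """Exhaustive hyperparameter search maximising test balanced accuracy.

    Default grids: 3-5 classes per latent node, NREP in {10, 20, 50},
    pseudo-count in {1, 5}.  Ties break toward the smaller total parameter
    count, then lexicographically.
    """
    spec = build_structure(model_id)
    latent_nodes = sorted(spec.latent)
    grids = dict(grids or {})
    node_grids = {ln: list(grids.get(ln, (3, 4, 5))) for ln in latent_nodes}
    rep_grid = list(grids.get("n_rep", (10, 20, 50)))
    pc_grid = list(grids.get("pseudo_count", (1, 5)))
    if not all([*node_grids.values(), rep_grid, pc_grid]):
        raise ValueError("grids must be non-empty")

    rows = []
    best = None  # (-ba, total_params, lexicographic key, hp)
    for combo in itertools.product(*(node_grids[ln] for ln in latent_nodes),
                                   rep_grid, pc_grid):
        *cards, n_rep, pc = combo
        hp = HyperParams(n_classes=dict(zip(latent_nodes, cards)),
                         n_rep=int(n_rep), pseudo_count=float(pc))
        bundle = train_full(train, model_id, hp, seed=seed)
        ba = evaluate_test(bundle, test).balanced_accuracy
        rows.append({**{f"N_{ln}": c for ln, c in zip(latent_nodes, cards)},
                     "n_rep": n_rep, "pseudo_count": pc,
                     "balanced_accuracy": ba})
        key = (-ba, sum(cards), tuple(cards) + (n_rep, pc))
        if best is None or key < best[0]:
            best = (key, hp)
    return best[1], pd.DataFrame(rows)


def evaluate_external(external: Dataset, bundle: ModelBundle,
                      endpoint: str = "llna4") -> EvalReport:
    """Score an external dataset on the LLNA 4-class or human 3-class endpoint.

    Rows without a molecular weight or a defined structure (no SMILES) cannot
    be converted to molar units; they are excluded up-front and counted in
    ``n_excluded``.  For ``human3`` the predicted 4-class labels are collapsed
    (moderate+weak -> weak) before scoring.
    """
    if endpoint not in ("llna4", "human3"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    col = "potency_class4" if endpoint == "llna4" else "human_class3"
    df = external.frame
    if df[col].isna().all():
        raise ValueError(f"external dataset carries no {col!r} labels")
    smiles = df["smiles"]
    has_structure = (~smiles.isna()) & (smiles.astype(str).str.len() > 0)
    usable = has_structure & (~df["mw"].isna()) & (~df[col].isna())
    n_excluded = int((~usable).sum())
    sub = Dataset(df[usable].reset_index(drop=True), role="external")

    preds = predict_dataset(bundle, sub)
    truth = list(sub.frame[col])
    if endpoint == "human3":
        y_pred = [map4_to_human3(p.predicted_class) for p in preds]
        # strata accuracies must compare mapped labels too
        mapped = [Prediction(p.compound_id, p.posterior4, p.prior4,
                             p.bayes_factors4, map4_to_human3(p.predicted_class),
                             p.confidence, p.pec3_at) for p in preds]
        rep = _report(truth, mapped, classes=CLASSES3, y_pred=y_pred,
                      n_excluded=n_excluded)
    else:
        rep = _report(truth, preds, n_excluded=n_excluded)
    return rep
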