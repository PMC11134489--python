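"""Site- and molecule-level evaluation metrics and dataset splits.

Reactive and unreactive sites are heavily imbalanced (a typical
substrate has one reactive position out of several candidates), so the
headline site metric is Matthews' correlation coefficient; plain
accuracy is reported but is inflated by the easy negatives. The
molecule-level criterion is strict: a substrate counts as correct only
when *every* one of its sites is classified correctly, since a single
wrong site changes the predicted regiochemical outcome.

All metric formulas are evaluated directly from the confusion counts or
residuals; degenerate denominators follow the 0-by-convention rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_core import ReactionRecord, count_aromatic_rings, ring_is_heterocyclic
from .site_enum import SiteInstance

DEFAULT_SUCCESS_THRESHOLD = 5.0


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    @classmethod
    def from_labels(cls, labels, predictions) -> "ConfusionCounts":
        if len(labels) != len(predictions):
            raise ValueError(
                f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions"
            )
        c = cls()
        for y, p in zip(labels, predictions):
            if y not in (0, 1) or p not in (0, 1):
                raise ValueError("labels and predictions must be 0/1")
            if y == 1 and p == 1:
                c.TP += 1
            elif y == 0 and p == 1:
                c.FP += 1
            elif y == 0 and p == 0:
                c.TN += 1
            else:
                c.FN += 1
        return c

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    site_accuracy: float = math.nan
    ppv: float = math.nan
    recall: float = math.nan
    f1: float = math.nan
    mcc: float = math.nan
    counts: ConfusionCounts | None = None
    molecule_accuracy_allsites: float | None = None
    molecule_accuracy_major: float | None = None
    regression: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "site_accuracy": self.site_accuracy,
            "ppv": self.ppv,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
        }
        if self.counts is not None:
            out["confusion"] = {
                "TP": self.counts.TP,
                "FP": self.counts.FP,
                "TN": self.counts.TN,
                "FN": self.counts.FN,
            }
        if self.molecule_accuracy_allsites is not None:
            out["molecule_accuracy_allsites"] = self.molecule_accuracy_allsites
        if self.molecule_accuracy_major is not None:
            out["molecule_accuracy_major"] = self.molecule_accuracy_major
        if self.regression:
            out["regression"] = dict(self.regression)
        return out


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)


def site_metrics(labels, predictions) -> MetricsReport:
    """Accuracy, PPV (precision), recall, F1 and MCC over aligned 0/1 lists."""
    c = ConfusionCounts.from_labels(labels, predictions)
    n = c.total
    accuracy = (c.TP + c.TN) / n if n else math.nan
    ppv = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    f1 = (2 * ppv * recall / (ppv + recall)) if (ppv + recall) else 0.0
    return MetricsReport(
        site_accuracy=accuracy, ppv=ppv, recall=recall, f1=f1, mcc=mcc(c), counts=c
    )


def molecule_accuracy(grouped: dict[str, list[tuple[int, int]]]) -> float:
    """Fraction of substrates whose every (label, prediction) pair agrees."""
    if not grouped:
        raise ValueError("no substrate groups to evaluate")
    correct = sum(
        1 for pairs in grouped.values() if all(y == p for y, p in pairs)
    )
    return correct / len(grouped)


def major_product_accuracy(
    grouped_predictions: dict[str, list[tuple[int, float, float | None]]],
) -> tuple[float, int]:
    """Accuracy of the predicted major site against the experimental one.

    ``grouped_predictions`` maps substrate -> list of
    (site_atom, predicted_yield, experimental_yield_or_None). The
    experimental major site is the highest experimental yield; ties mean
    any tying site counts as correct. Substrates with no labeled site
    are excluded; the count of exclusions is returned alongside.
    """
    correct = 0
    evaluated = 0
    excluded = 0
    for sites in grouped_predictions.values():
        labeled = [(a, e) for a, _, e in sites if e is not None]
        if not labeled:
            excluded += 1
            continue
        best_exp = max(e for _, e in labeled)
        exp_major = {a for a, e in labeled if e == best_exp}
        pred_major = max(sites, key=lambda t: (t[1], -t[0]))[0]
        evaluated += 1
        if pred_major in exp_major:
            correct += 1
    if evaluated == 0:
        raise ValueError("no substrate with a labeled major site")
    return correct / evaluated, excluded


def regression_metrics(
    y, yhat, success_threshold: float = DEFAULT_SUCCESS_THRESHOLD
) -> dict[str, float]:
    """R2, MAE, RMSE and the thresholded reaction-outcome MCC.

    The outcome MCC binarizes true and predicted yields at the success
    threshold (default 5 percent: below it the reaction is called
    failed) and scores the agreement of the two binary outcomes.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    residual = y - yhat
    mae = float(np.abs(residual).mean())
    rmse = float(math.sqrt((residual**2).mean()))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("constant true yields: R2 undefined", stacklevel=2)
        r2 = math.nan
    else:
        r2 = 1.0 - float((residual**2).sum()) / ss_tot
    outcome = mcc(
        ConfusionCounts.from_labels(
            [int(v >= success_threshold) for v in y],
            [int(v >= success_threshold) for v in yhat],
        )
    )
    return {"r2": r2, "mae": mae, "rmse": rmse, "outcome_mcc": outcome}


@dataclass
class SplitSpec:
    """Named train/test membership over substrate canonical SMILES."""

    name: str
    train: set[str]
    test: set[str]
    seed: int | None = None


def _substrate_ids(records: list[ReactionRecord]) -> list[str]:
    seen: list[str] = []
    for r in records:
        smi = r.substrate.smiles
        if smi not in seen:
            seen.append(smi)
    return seen


def split_random(
    records: list[ReactionRecord], seed: int, held_out_fraction: float = 0.1
) -> SplitSpec:
    """Substrate-level random split; a substrate is never in both halves."""
    substrates = _substrate_ids(records)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(substrates))
    n_test = max(1, int(round(held_out_fraction * len(substrates))))
    test = {substrates[i] for i in order[:n_test]}
    train = {s for s in substrates if s not in test}
    return SplitSpec(name="random", train=train, test=test, seed=seed)


def split_ring_type(
    records: list[ReactionRecord],
) -> tuple[SplitSpec, SplitSpec, list[str]]:
    """HET / CARB partition by the ring kind at the experimental site.

    A substrate goes to HET if any of its reactions borylates a
    heterocyclic ring position. Substrates reacting at both ring kinds
    (mixtures) go to HET and are returned in the ambiguity log. The two
    memberships partition the substrate set exactly.
    """
    het: set[str] = set()
    carb: set[str] = set()
    ambiguous: list[str] = []
    by_substrate: dict[str, list[ReactionRecord]] = {}
    for r in records:
        if r.site_atom is None:
            raise ValueError(
                f"record {r.source_id or r.to_reaction_smiles()} lacks a site label"
            )
        by_substrate.setdefault(r.substrate.smiles, []).append(r)
    for smi, recs in by_substrate.items():
        kinds = {ring_is_heterocyclic(r.substrate, r.site_atom) for r in recs}
        if kinds == {True, False}:
            ambiguous.append(smi)
        if True in kinds:
            het.add(smi)
        else:
            carb.add(smi)
    return (
        SplitSpec(name="HET", train=carb, test=het),
        SplitSpec(name="CARB", train=het, test=carb),
        ambiguous,
    )


def split_ring_count(records: list[ReactionRecord]) -> tuple[SplitSpec, SplitSpec]:
    """ONE / MULT partition by the substrate's aromatic ring count."""
    one: set[str] = set()
    mult: set[str] = set()
    for r in records:
        smi = r.substrate.smiles
        if count_aromatic_rings(r.substrate) == 1:
            one.add(smi)
        else:
            mult.add(smi)
    return (
        SplitSpec(name="ONE", train=mult, test=one),
        SplitSpec(name="MULT", train=one, test=mult),
    )


def make_splits(
    records: list[ReactionRecord],
    kind: str,
    seed: int = 0,
    held_out_fraction: float = 0.1,
):
    """Dispatch to the named split family: random, ring_type, ring_count."""
    if kind == "random":
        return split_random(records, seed, held_out_fraction)
    if kind == "ring_type":
        return split_ring_type(records)
    if kind == "ring_count":
        return split_ring_count(records)
    raise ValueError(f"unknown split kind {kind!r}")


def filter_instances(
    instances: list[SiteInstance], members: set[str]
) -> list[SiteInstance]:
    """Site instances whose substrate belongs to a split membership."""
    return [i for i in instances if i.substrate.smiles in members]
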