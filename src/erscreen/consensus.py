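"""Tier-1 consensus prediction and the screen report.

Two Decision Forest models — one per training set — each output a binder
probability for every screened compound.  The consensus probability is
their unweighted mean, the call is binder when it exceeds 0.5, and the
prediction confidence rescales the distance from the decision boundary to
[0, 1]:

    confidence = |p - 0.5| / 0.5

so 1 means a maximally confident call and 0 a coin flip.  For compounds
called binders the tier-2 logRBA estimate is attached when a binding free
energy is available; a binder whose docking failed is reported with
status ``failed``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from erscreen.affinity import ConversionModel, free_energy_to_logrba
from erscreen.dataset_io import LabeledDataset
from erscreen.decision_forest import DecisionForest, predict_proba

__all__ = [
    "PredictionRecord",
    "ScreenReport",
    "consensus_probability",
    "confidence",
    "screen",
    "write_report",
    "read_report",
]


def _check_prob(p: float, what: str = "probability") -> float:
    p = float(p)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{what} outside [0, 1]: {p!r}")
    return p


def consensus_probability(*probs: float) -> float:
    """Unweighted mean of k >= 2 model probabilities.

    The screen uses exactly two models; the mean generalises to more
    without changing the two-model behaviour.
    """
    if len(probs) < 2:
        raise ValueError("consensus requires at least two model probabilities")
    vals = [_check_prob(p) for p in probs]
    return float(sum(vals) / len(vals))


def confidence(p: float) -> float:
    """Prediction confidence |p - 0.5| / 0.5, symmetric about the boundary."""
    p = _check_prob(p, "consensus probability")
    return abs(p - 0.5) / 0.5


@dataclass
class PredictionRecord:
    """One screened compound: model probabilities, call, confidence, logRBA."""

    compound_id: str
    name: str | None
    p_model1: float
    p_model2: float
    p_consensus: float
    call: str  # "binder" | "non-binder"
    confidence: float
    logrba: float | None = None
    logrba_status: str = "not_applicable"  # ok | not_applicable | failed

    @property
    def is_binder(self) -> bool:
        return self.call == "binder"


@dataclass
class ScreenReport:
    records: list[PredictionRecord]
    provenance: dict = field(default_factory=dict)

    @property
    def n_binders(self) -> int:
        return sum(r.is_binder for r in self.records)

    @property
    def n_nonbinders(self) -> int:
        return len(self.records) - self.n_binders


def _config_hash(doc: dict) -> str:
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def screen(
    ds: LabeledDataset | None = None,
    model1: DecisionForest | None = None,
    model2: DecisionForest | None = None,
    energies: dict[str, float] | None = None,
    conv: ConversionModel = ConversionModel(),
    probabilities: pd.DataFrame | None = None,
    names: dict[str, str] | None = None,
) -> ScreenReport:
    """Run the two-tier screen over a compound set.

    Probabilities come either from live models (*ds* plus *model1* and
    *model2*) or from a precomputed table *probabilities* with columns
    ``p_model1``/``p_model2`` indexed by compound id — the injection seam
    that lets published probability pairs be fed through the consensus
    arithmetic without the original training data.

    Tier 2 runs only for compounds called binders: with an energy entry
    the logRBA is attached (status ``ok``); without one the status is
    ``failed``.  Energies for unknown compounds raise a warning and are
    ignored.
    """
    if probabilities is not None:
        ids = [str(i) for i in probabilities.index]
        p1 = probabilities["p_model1"].to_numpy(dtype=float)
        p2 = probabilities["p_model2"].to_numpy(dtype=float)
    else:
        if ds is None or model1 is None or model2 is None:
            raise ValueError(
                "screen needs either a probabilities table or a dataset plus two models"
            )
        ids = ds.compound_ids
        p1 = np.asarray(predict_proba(model1, ds))
        p2 = np.asarray(predict_proba(model2, ds))

    energies = dict(energies or {})
    unknown = set(energies) - set(ids)
    if unknown:
        warnings.warn(
            f"free energies for unknown compound(s) ignored: {sorted(unknown)}",
            stacklevel=2,
        )

    names = names or {}
    records = []
    for cid, a, b in zip(ids, p1, p2):
        p = consensus_probability(float(a), float(b))
        call = "binder" if p > 0.5 else "non-binder"
        logrba = None
        status = "not_applicable"
        if call == "binder":
            if cid in energies:
                logrba = free_energy_to_logrba(float(energies[cid]), conv)
                status = "ok"
            else:
                status = "failed"
        records.append(
            PredictionRecord(
                compound_id=cid,
                name=names.get(cid),
                p_model1=float(a),
                p_model2=float(b),
                p_consensus=p,
                call=call,
                confidence=confidence(p),
                logrba=logrba,
                logrba_status=status,
            )
        )

    prov = {
        "n_compounds": len(records),
        "probability_source": "injected" if probabilities is not None else "models",
        "conversion": {"intercept": conv.intercept, "slope": conv.slope},
    }
    prov["config_hash"] = _config_hash(prov)
    return ScreenReport(records=records, provenance=prov)


_REPORT_COLUMNS = [
    "compound_id",
    "name",
    "p_model1",
    "p_model2",
    "call",
    "confidence",
    "logrba",
]


def _fmt3(x: float | None) -> str:
    return "" if x is None else f"{x:.3f}"


def write_report(report: ScreenReport, path) -> None:
    """Write the screen report as CSV plus a JSON provenance sidecar.

    Probabilities and confidence are rendered to 3 decimals (round half to
    even); calls are printed as ``+``/``-``.  Full-precision values are
    preserved in the ``<path>.json`` sidecar.
    """
    rows = []
    for r in report.records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "name": r.name or "",
                "p_model1": _fmt3(r.p_model1),
                "p_model2": _fmt3(r.p_model2),
                "call": "+" if r.is_binder else "-",
                "confidence": _fmt3(r.confidence),
                "logrba": _fmt3(r.logrba),
            }
        )
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, index=False)

    sidecar = {
        "provenance": report.provenance,
        "n_binders": report.n_binders,
        "n_nonbinders": report.n_nonbinders,
        "records": [
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "p_model1": r.p_model1,
                "p_model2": r.p_model2,
                "p_consensus": r.p_consensus,
                "call": r.call,
                "confidence": r.confidence,
                "logrba": r.logrba,
                "logrba_status": r.logrba_status,
            }
            for r in report.records
        ],
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
        fh.write("\n")


def read_report(path) -> pd.DataFrame:
    """Read back a written report CSV (rendered string values preserved)."""
    return pd.read_csv(path, dtype=str, keep_default_na=False)
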