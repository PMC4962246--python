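"""Synthetic labeled descriptor datasets and the published-consensus fixture.

The real training sets behind the screen (232 and 1086 compounds with
rat-ER binding calls, each described by 777 Mold2 descriptors) live in
curated databases and are not redistributable.  This module generates
datasets with the same statistical skeleton so every pipeline stage is
testable offline: a controllable number of class-informative Gaussian
descriptors with a controllable standardized mean shift between binders
and non-binders, class-independent noise descriptors, and planted
duplicate/constant columns to exercise preprocessing.  Tree splits only
depend on value order within a column, so Gaussian marginals exercise the
classifier as well as any monotone transform of them would; an optional
flag adds integer count-like columns to mimic mixed descriptor types.

It also packages the 29 published consensus probability pairs for the
candidate bisphenol-A replacement compounds, transcribed verbatim, for
exact arithmetic checks of the consensus tier.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from erscreen.dataset_io import LabeledDataset

__all__ = [
    "SynthSpec",
    "Table1Entry",
    "Table1Fixture",
    "generate",
    "generate_external",
    "strong_preset",
    "null_preset",
    "table1_fixture",
]

_FIXTURE_NAME = "table1_consensus.csv"
_FIXTURE_SHA256 = "0d12c8091481d1f9256b504bda3aae85d0499248734fb87a988f88ff42d0083e"


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic labeled descriptor dataset.

    ``effect_size`` is the standardized mean shift (in units of
    ``noise_sd``) of each informative descriptor between binders and
    non-binders.  Duplicate columns are exact copies of earlier columns
    and constant columns hold a single value, so they are precisely what
    descriptor preprocessing must remove.
    """

    n_compounds: int
    n_binders: int
    n_descriptors: int = 777
    n_informative: int = 10
    effect_size: float = 1.0
    n_duplicate_cols: int = 0
    n_constant_cols: int = 0
    noise_sd: float = 1.0
    integer_like: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if not (0 <= self.n_binders <= self.n_compounds):
            raise ValueError("n_binders must lie in [0, n_compounds]")
        if self.n_informative + self.n_duplicate_cols + self.n_constant_cols > self.n_descriptors:
            raise ValueError(
                "n_informative + n_duplicate_cols + n_constant_cols exceeds n_descriptors"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def strong_preset(seed: int = 0) -> SynthSpec:
    """Separable preset sized like the smaller training set (232, 131 binders)."""
    return SynthSpec(
        n_compounds=232,
        n_binders=131,
        n_descriptors=777,
        n_informative=10,
        effect_size=2.0,
        seed=seed,
    )


def null_preset(seed: int = 0) -> SynthSpec:
    """Balanced no-signal preset for chance-level calibration checks."""
    return SynthSpec(
        n_compounds=100,
        n_binders=50,
        n_descriptors=777,
        n_informative=0,
        effect_size=0.0,
        seed=seed,
    )


def _make(spec: SynthSpec, id_prefix: str, seed: int) -> LabeledDataset:
    rng = np.random.default_rng(seed)
    n, d = spec.n_compounds, spec.n_descriptors
    n_extra = spec.n_duplicate_cols + spec.n_constant_cols
    n_base = d - n_extra  # informative + noise columns, drawn fresh

    labels = np.zeros(n, dtype=np.int64)
    labels[: spec.n_binders] = 1

    X = rng.normal(0.0, spec.noise_sd, size=(n, n_base))
    shift = spec.effect_size * spec.noise_sd
    X[labels == 1, : spec.n_informative] += shift
    if spec.integer_like:
        # second half of the noise block becomes count-like
        start = spec.n_informative + (n_base - spec.n_informative) // 2
        X[:, start:n_base] = rng.poisson(5.0, size=(n, n_base - start))

    blocks = [X]
    if spec.n_duplicate_cols:
        src = rng.integers(0, n_base, size=spec.n_duplicate_cols)
        blocks.append(X[:, src])
    if spec.n_constant_cols:
        const_vals = rng.normal(0.0, 1.0, size=spec.n_constant_cols)
        blocks.append(np.tile(const_vals, (n, 1)))
    full = np.concatenate(blocks, axis=1)

    width = max(4, len(str(d)))
    cols = [f"D{j + 1:0{width}d}" for j in range(d)]
    ids = [f"{id_prefix}{i + 1:04d}" for i in range(n)]
    matrix = pd.DataFrame(full, index=pd.Index(ids, name="compound_id"), columns=cols)
    return LabeledDataset(matrix, pd.Series(labels, index=matrix.index))


def generate(spec: SynthSpec) -> LabeledDataset:
    """Draw one labeled dataset; fully determined by ``spec`` (incl. seed).

    Column layout, in order: ``n_informative`` informative columns, then
    fresh noise columns, then ``n_duplicate_cols`` copies of earlier
    columns, then ``n_constant_cols`` constant columns.  The first
    ``n_binders`` rows are the binders (fold assignment is randomised
    downstream, so row order carries no information).
    """
    return _make(spec, "cpd", spec.seed)


def generate_external(spec: SynthSpec, seed2: int) -> LabeledDataset:
    """Independent draw from the same distribution with disjoint compound ids."""
    return _make(replace(spec, seed=seed2), "ext", seed2)


# ---------------------------------------------------------------------------
# published consensus fixture


@dataclass(frozen=True)
class Table1Entry:
    """One candidate compound's published consensus row, transcribed verbatim."""

    compound_index: int
    name: str | None
    p_model1: float
    p_model2: float
    printed_call: str  # "+" binder / "-" non-binder
    printed_confidence: float
    printed_logrba: float | None  # None: not printed (non-binder) or "NA"
    logrba_is_na: bool  # docking failed for this binder


@dataclass(frozen=True)
class Table1Fixture:
    entries: tuple[Table1Entry, ...]

    def probability_frame(self) -> pd.DataFrame:
        """p_model1/p_model2 indexed by compound index, for the screen seam."""
        return pd.DataFrame(
            {
                "p_model1": [e.p_model1 for e in self.entries],
                "p_model2": [e.p_model2 for e in self.entries],
            },
            index=pd.Index([str(e.compound_index) for e in self.entries]),
        )

    @property
    def n_printed_binders(self) -> int:
        return sum(e.printed_call == "+" for e in self.entries)


def table1_fixture() -> Table1Fixture:
    """Load the packaged 29-compound consensus fixture, checksum-verified."""
    path = resources.files("erscreen").joinpath("data", _FIXTURE_NAME)
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"fixture {_FIXTURE_NAME} corrupted: sha256 {digest} != {_FIXTURE_SHA256}"
        )
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    entries = []
    for _, row in df.iterrows():
        lr = row["printed_logrba"]
        entries.append(
            Table1Entry(
                compound_index=int(row["compound_index"]),
                name=row["name"] or None,
                p_model1=float(row["p_model1"]),
                p_model2=float(row["p_model2"]),
                printed_call=row["printed_call"],
                printed_confidence=float(row["printed_confidence"]),
                printed_logrba=float(lr) if lr not in ("", "NA") else None,
                logrba_is_na=lr == "NA",
            )
        )
    return Table1Fixture(entries=tuple(entries))
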