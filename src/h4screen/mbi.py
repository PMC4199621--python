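"""Molecular Bioactivity Index (MBI) scoring and enrichment evaluation.

The MBI combines an ensemble of n efficient range filters into one
per-molecule score. Each filter i contributes through its per-class pass
percentages (PA_i, PNA_i, NA_i, NNA_i): a molecule that passes filter i
earns the filter's pass-side efficiency factor PA_i/PNA_i (how much more
often actives pass than non-actives), while a molecule that fails it is
penalised by NNA_i/NA_i (how much more often non-actives fail than
actives). With δ_Ai the pass indicator and δ_NAi = 1 − δ_Ai:

    MBI = (1/n) · Σ_i [ δ_Ai · PA_i/max(PNA_i, ε) − δ_NAi · NNA_i/max(NA_i, ε) ]

ε (0.5 percentage points) caps the ratios when a filter has no false
positives or no false negatives on its training set. A molecule passing
many discriminative filters accumulates a large positive MBI; one failing
them goes negative.

Ranking a screening library by descending MBI yields the enrichment curve
(fraction of actives recovered vs fraction of the library screened) and
enrichment factors (ratio of active to reference pass rates).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .ise import RangeFilter
from .molkit import LabelledMolecule

__all__ = [
    "EnrichmentResult",
    "FilterEnsemble",
    "MBIScore",
    "RATIO_EPS",
    "enrichment_curve",
    "enrichment_factor",
    "mbi_score",
    "rank_library",
]

#: Floor (percentage points) for the denominators of the efficiency ratios.
RATIO_EPS = 0.5


@dataclass
class FilterEnsemble:
    """The n efficient filters feeding the MBI; every filter carries stats."""

    filters: Sequence[RangeFilter]

    def __post_init__(self) -> None:
        if not self.filters:
            raise ValueError("empty ensemble")
        for f in self.filters:
            if f.stats is None or f.mcc is None:
                raise ValueError("every ensemble filter needs stats and mcc")

    @property
    def n(self) -> int:
        return len(self.filters)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([f.to_dict() for f in self.filters], indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterEnsemble":
        data = json.loads(Path(path).read_text())
        return cls(filters=[RangeFilter.from_dict(d) for d in data])


@dataclass(frozen=True)
class MBIScore:
    id: str
    mbi: float
    n_passed: int


def mbi_score(
    mol: LabelledMolecule | Mapping[str, float],
    ens: FilterEnsemble,
    eps: float = RATIO_EPS,
) -> MBIScore:
    """Score one molecule against the ensemble (see module docstring)."""
    desc = mol.descriptors if isinstance(mol, LabelledMolecule) else mol
    mol_id = mol.id if isinstance(mol, LabelledMolecule) else ""
    total = 0.0
    n_passed = 0
    for f in ens.filters:
        s = f.stats
        assert s is not None
        if f.passes(desc):
            n_passed += 1
            total += s.PA / max(s.PNA, eps)
        else:
            total -= s.NNA / max(s.NA, eps)
    return MBIScore(id=mol_id, mbi=total / ens.n, n_passed=n_passed)


def rank_library(
    mols: Sequence[LabelledMolecule], ens: FilterEnsemble
) -> list[MBIScore]:
    """Rank a library by descending MBI; ties by n_passed then id."""
    if not mols:
        raise ValueError("empty library")
    scores = [mbi_score(m, ens) for m in mols]
    return sorted(scores, key=lambda s: (-s.mbi, -s.n_passed, s.id))


@dataclass
class EnrichmentResult:
    """Pass fractions (percent), their ratio, and optionally the curve.

    ``enrichment_factor`` is infinite (flagged) when the reference pass
    fraction is zero. ``curve`` is (fraction screened, fraction of
    actives recovered) pairs, non-decreasing and ending at (1, 1).
    """

    frac_active_pass: float
    frac_reference_pass: float
    enrichment_factor: float
    curve: list[tuple[float, float]] = field(default_factory=list)
    fold_pass_mean: float | None = None
    fold_pass_std: float | None = None
    n_folds: int | None = None


def enrichment_factor(active_pass: float, reference_pass: float) -> float:
    """Ratio of active to reference pass percentages; inf when reference is 0."""
    for v in (active_pass, reference_pass):
        if not 0 <= v <= 100:
            raise ValueError("pass percentages must be in [0, 100]")
    if reference_pass == 0:
        return math.inf
    return active_pass / reference_pass


def enrichment_curve(
    ranked: Sequence[MBIScore], labels: Mapping[str, str]
) -> EnrichmentResult:
    """Cumulative actives-recovered curve over a ranked library.

    Evaluated at every rank; the i-th point is (i/n, actives in top i /
    total actives). Requires every ranked id to be labelled and at least
    one active.
    """
    if not ranked:
        raise ValueError("empty ranking")
    is_active = np.array([labels[s.id] == "active" for s in ranked], dtype=float)
    n_act = is_active.sum()
    if n_act == 0:
        raise ValueError("no actives in the ranked library")
    n = len(ranked)
    recovered = np.cumsum(is_active) / n_act
    fractions = np.arange(1, n + 1) / n
    curve = list(zip(fractions.tolist(), recovered.tolist()))
    pct_act = 100.0
    return EnrichmentResult(
        frac_active_pass=pct_act,
        frac_reference_pass=100.0,
        enrichment_factor=1.0,
        curve=curve,
    )


def top_fraction_ids(ranked: Sequence[MBIScore], fraction: float) -> list[str]:
    """Ids of the highest-indexed *fraction* of the ranking (at least one)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = max(1, int(math.floor(fraction * len(ranked))))
    return [s.id for s in ranked[:k]]
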