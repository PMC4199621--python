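"""Descriptor-range filter learning by Iterative Stochastic Elimination (ISE).

A *filter* is a conjunction of closed numeric intervals over a subset of
the descriptor panel: a molecule "passes" iff every constrained
descriptor lies inside its interval. Filter quality is the Matthews
correlation coefficient (MCC) of the pass/fail decision against the
active/inactive labels, computed on class-normalised counts (per-class
percentages, equal class weight) so that class imbalance in the training
library does not dominate the objective.

ISE treats the interval bounds as a combinatorial optimisation problem:
descriptor values are discretised at pooled empirical quantiles, candidate
filters are sampled at random, and cut-point values that are
over-represented among the worst-scoring samples (relative to the best)
are eliminated from the search space. When the surviving space is small
enough it is enumerated exhaustively. The output is the best filter found
plus the ensemble of "efficient filters" — every distinct evaluated filter
whose MCC clears a floor — which downstream feeds the Molecular
Bioactivity Index.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .molkit import LabelledMolecule

__all__ = [
    "BinaryEncoding",
    "DiscretizedSpace",
    "FilterStats",
    "ISEConfig",
    "RangeFilter",
    "compute_mcc",
    "discretize",
    "encode_binary",
    "evaluate_filter",
    "ise_optimize",
]


class FilterStats(NamedTuple):
    """Per-class pass/fail percentages of a filter.

    PA: % of actives passing (true-positive rate ×100)
    PNA: % of non-actives passing (false-positive rate ×100)
    NA: % of actives failing; NNA: % of non-actives failing.
    PA + NA = 100 and PNA + NNA = 100.
    """

    PA: float
    PNA: float
    NA: float
    NNA: float


@dataclass(frozen=True)
class RangeFilter:
    """Conjunction of closed per-descriptor intervals with its performance.

    ``constraints`` maps descriptor name -> (low, high), low ≤ high,
    either bound possibly infinite. ``stats`` and ``mcc`` are attached by
    :func:`evaluate_filter`.
    """

    constraints: Mapping[str, tuple[float, float]]
    stats: FilterStats | None = None
    mcc: float | None = None

    def __post_init__(self) -> None:
        for name, (low, high) in self.constraints.items():
            if low > high:
                raise ValueError(f"{name}: low {low} > high {high}")

    def passes(self, descriptors: Mapping[str, float]) -> bool:
        return all(
            low <= descriptors[name] <= high
            for name, (low, high) in self.constraints.items()
        )

    def key(self) -> tuple:
        """Hashable identity of the constraint set (for deduplication)."""
        return tuple(sorted((n, lo, hi) for n, (lo, hi) in self.constraints.items()))

    def to_dict(self) -> dict:
        d: dict = {"constraints": {n: list(c) for n, c in sorted(self.constraints.items())}}
        if self.stats is not None:
            d["stats"] = {"PA": self.stats.PA, "PNA": self.stats.PNA,
                          "NA": self.stats.NA, "NNA": self.stats.NNA}
        if self.mcc is not None:
            d["mcc"] = self.mcc
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RangeFilter":
        stats = None
        if "stats" in d:
            s = d["stats"]
            stats = FilterStats(s["PA"], s["PNA"], s["NA"], s["NNA"])
        constraints = {n: (float(c[0]), float(c[1])) for n, c in d["constraints"].items()}
        return cls(constraints=constraints, stats=stats, mcc=d.get("mcc"))


def compute_mcc(tp: float, fn: float, fp: float, tn: float) -> float:
    """Matthews correlation coefficient from a 2×2 confusion table.

    (tp·tn − fp·fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); by convention 0
    when any denominator factor is zero. Counts may be fractional (e.g.
    class-normalised percentages).
    """
    if min(tp, fn, fp, tn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn + fp + tn == 0:
        raise ValueError("all counts are zero")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


# ---------------------------------------------------------------------------
# Discretisation and binary encoding


@dataclass
class DiscretizedSpace:
    """Quantile discretisation of the descriptor panel.

    ``cuts[name]`` holds strictly increasing interior cut-points; k cuts
    define k+1 bins, bin b covering (cut[b-1], cut[b]] (closed on the
    right, so a value exactly on a cut-point falls in the lower bin).
    ``integer[name]`` records whether the descriptor is integer-valued
    (its cut-points are integers). Descriptors that were constant in the
    training data are listed in ``degenerate`` and carry no cut-points.
    """

    cuts: dict[str, np.ndarray]
    integer: dict[str, bool]
    degenerate: set[str] = field(default_factory=set)

    @property
    def names(self) -> list[str]:
        return [n for n in self.cuts if n not in self.degenerate]

    def n_bins(self, name: str) -> int:
        return len(self.cuts[name]) + 1

    def bin_of(self, name: str, value: float) -> int:
        return int(np.searchsorted(self.cuts[name], value, side="left"))

    def interval_of(self, name: str, lo_bin: int, hi_bin: int) -> tuple[float, float]:
        """Closed numeric interval equivalent to bins [lo_bin, hi_bin]."""
        cuts = self.cuts[name]
        low = -math.inf if lo_bin == 0 else float(cuts[lo_bin - 1])
        if lo_bin > 0 and self.integer[name]:
            low = low + 1  # (c, d] over integers is [c+1, d]
        high = math.inf if hi_bin == len(cuts) else float(cuts[hi_bin])
        return low, high


def discretize(
    training: Sequence[LabelledMolecule],
    panel: Iterable[str],
    bins: int = 10,
) -> DiscretizedSpace:
    """Cut-points at pooled empirical quantiles of the training data.

    ``bins`` quantile bins per descriptor (deciles by default);
    integer-valued descriptors get integer cut-points; duplicate
    quantiles collapse. A descriptor constant in the pooled sample is
    flagged degenerate (single interval, never constrained).
    """
    if bins < 2:
        raise ValueError("bins must be ≥ 2")
    if not training:
        raise ValueError("empty training set")
    cuts: dict[str, np.ndarray] = {}
    integer: dict[str, bool] = {}
    degenerate: set[str] = set()
    for name in panel:
        values = np.array([m.descriptors[name] for m in training], dtype=float)
        is_int = bool(np.all(values == np.round(values)))
        integer[name] = is_int
        qs = np.quantile(values, np.arange(1, bins) / bins)
        if is_int:
            qs = np.floor(qs)
        qs = np.unique(qs)
        qs = qs[(qs >= values.min()) & (qs < values.max())]
        if qs.size == 0:
            degenerate.add(name)
        cuts[name] = qs.astype(float)
    return DiscretizedSpace(cuts=cuts, integer=integer, degenerate=degenerate)


@dataclass(frozen=True)
class BinaryEncoding:
    """One-hot interval membership: one bit per (descriptor, bin) pair."""

    bits: np.ndarray  # uint8 vector
    layout: tuple[tuple[str, int], ...]  # (descriptor, n_bins) in order

    def __len__(self) -> int:
        return int(self.bits.size)


def encode_binary(
    mol: LabelledMolecule, space: DiscretizedSpace
) -> BinaryEncoding:
    """Encode a molecule as the concatenated one-hot bin memberships.

    Exactly one bit is set per descriptor; a value on a cut-point sets the
    lower interval's bit; values outside the training range clamp to the
    outermost interval.
    """
    segments: list[np.ndarray] = []
    layout: list[tuple[str, int]] = []
    for name in space.cuts:
        nb = space.n_bins(name)
        one_hot = np.zeros(nb, dtype=np.uint8)
        one_hot[space.bin_of(name, mol.descriptors[name])] = 1
        segments.append(one_hot)
        layout.append((name, nb))
    return BinaryEncoding(bits=np.concatenate(segments), layout=tuple(layout))


# ---------------------------------------------------------------------------
# Filter evaluation


def _class_matrices(
    mols: Sequence[LabelledMolecule], names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    act = [m for m in mols if m.label == "active"]
    ina = [m for m in mols if m.label == "inactive"]
    if not act or not ina:
        raise ValueError("need at least one active and one inactive molecule")
    A = np.array([[m.descriptors[n] for n in names] for m in act], dtype=float)
    I = np.array([[m.descriptors[n] for n in names] for m in ina], dtype=float)
    return A, I


def _stats_from_rates(pa: float, pna: float) -> tuple[FilterStats, float]:
    stats = FilterStats(PA=pa, PNA=pna, NA=100.0 - pa, NNA=100.0 - pna)
    mcc = compute_mcc(tp=stats.PA, fn=stats.NA, fp=stats.PNA, tn=stats.NNA)
    return stats, mcc


def evaluate_filter(
    f: RangeFilter, mols: Sequence[LabelledMolecule]
) -> RangeFilter:
    """Attach per-class pass percentages and class-normalised MCC to a filter.

    A molecule passes iff every constrained descriptor lies in its closed
    interval. The MCC is computed on the per-class percentages (equal
    class weight): tp=PA, fn=NA, fp=PNA, tn=NNA.
    """
    names = list(f.constraints)
    A, I = _class_matrices(mols, names)
    lows = np.array([f.constraints[n][0] for n in names])
    highs = np.array([f.constraints[n][1] for n in names])
    pa = 100.0 * np.all((A >= lows) & (A <= highs), axis=1).mean() if names else 100.0
    pna = 100.0 * np.all((I >= lows) & (I <= highs), axis=1).mean() if names else 100.0
    stats, mcc = _stats_from_rates(float(pa), float(pna))
    return RangeFilter(constraints=dict(f.constraints), stats=stats, mcc=mcc)


def evaluate_counts(
    f: RangeFilter, mols: Sequence[LabelledMolecule]
) -> tuple[int, int, int, int]:
    """Raw (tp, fn, fp, tn) counts of a filter — the unnormalised option."""
    names = list(f.constraints)
    A, I = _class_matrices(mols, names)
    lows = np.array([f.constraints[n][0] for n in names])
    highs = np.array([f.constraints[n][1] for n in names])
    tp = int(np.all((A >= lows) & (A <= highs), axis=1).sum())
    fp = int(np.all((I >= lows) & (I <= highs), axis=1).sum())
    return tp, len(A) - tp, fp, len(I) - fp


# ---------------------------------------------------------------------------
# ISE optimisation


@dataclass
class ISEConfig:
    """Tunable ISE parameters.

    sample_size: candidate filters drawn per iteration.
    worst_fraction / best_fraction: tail fractions of the ranked sample
        used for the elimination statistic.
    elimination_margin: a cut-point value is dropped when its frequency
        among the worst exceeds its frequency among the best by more than
        this margin.
    exhaustive_limit: once the surviving space holds at most this many
        filters it is enumerated exhaustively.
    mcc_floor: minimum MCC for membership in the efficient-filter ensemble.
    subset_min / subset_max: descriptors constrained per filter.
    max_iterations: hard stop for the elimination loop.
    """

    sample_size: int = 1000
    worst_fraction: float = 0.1
    best_fraction: float = 0.1
    elimination_margin: float = 0.1
    exhaustive_limit: int = 100_000
    mcc_floor: float = 0.6
    subset_min: int = 3
    subset_max: int = 6
    max_iterations: int = 50
    max_ensemble: int = 1000


class _BinData:
    """Pre-binned descriptor matrices for fast vectorised filter scoring."""

    def __init__(self, mols: Sequence[LabelledMolecule], space: DiscretizedSpace):
        self.names = space.names
        act = [m for m in mols if m.label == "active"]
        ina = [m for m in mols if m.label == "inactive"]
        if not act or not ina:
            raise ValueError("need both classes in the training set")
        def binmat(group: list[LabelledMolecule]) -> np.ndarray:
            cols = [
                np.searchsorted(space.cuts[n], [m.descriptors[n] for m in group], side="left")
                for n in self.names
            ]
            return np.stack(cols, axis=1)
        self.A = binmat(act)
        self.I = binmat(ina)

    def rates(self, cols: Sequence[int], lo: np.ndarray, hi: np.ndarray) -> tuple[float, float]:
        a = self.A[:, cols]
        i = self.I[:, cols]
        pa = 100.0 * np.all((a >= lo) & (a <= hi), axis=1).mean()
        pna = 100.0 * np.all((i >= lo) & (i <= hi), axis=1).mean()
        return float(pa), float(pna)


def _space_size(pair_counts: list[int], smin: int, smax: int) -> int:
    """Number of filters: sum over descriptor subsets of admissible-pair products.

    Computed via the elementary-symmetric-polynomial recurrence, so no
    enumeration is needed for the count itself.
    """
    D = len(pair_counts)
    e = [0] * (D + 1)
    e[0] = 1
    for c in pair_counts:
        for s in range(D, 0, -1):
            e[s] += e[s - 1] * c
    return sum(e[s] for s in range(smin, min(smax, D) + 1))


def ise_optimize(
    training: Sequence[LabelledMolecule],
    space: DiscretizedSpace,
    config: ISEConfig | None = None,
    seed: int = 0,
) -> tuple[RangeFilter, list[RangeFilter]]:
    """Learn the best range filter and the efficient-filter ensemble.

    Iteratively samples random filters (random descriptor subset, random
    admissible cut-point pair per descriptor), ranks them by
    class-normalised MCC, and eliminates cut-point values over-represented
    in the worst tail relative to the best tail. When the surviving
    combinatorial space is at most ``exhaustive_limit`` filters it is
    enumerated exhaustively. Returns the highest-MCC filter seen and all
    distinct evaluated filters with MCC ≥ ``mcc_floor`` (deduplicated by
    constraint set), both reproducible for a fixed seed.
    """
    cfg = config or ISEConfig()
    rng = np.random.default_rng(seed)
    data = _BinData(training, space)
    names = data.names
    if not names:
        raise ValueError("discretized space is fully degenerate")
    smin = max(1, min(cfg.subset_min, len(names)))
    smax = min(cfg.subset_max, len(names))

    # admissible bin-edge values per variable; variables are (descriptor, side)
    adm_lo: dict[str, set[int]] = {n: set(range(space.n_bins(n))) for n in names}
    adm_hi: dict[str, set[int]] = {n: set(range(space.n_bins(n))) for n in names}

    best: tuple[float, tuple] | None = None  # (mcc, key) for ordering
    best_filter: RangeFilter | None = None
    ensemble: dict[tuple, RangeFilter] = {}
    trace: list[dict] = []

    def to_range_filter(cols: Sequence[int], lo: np.ndarray, hi: np.ndarray,
                        pa: float, pna: float) -> RangeFilter:
        constraints = {
            names[c]: space.interval_of(names[c], int(l), int(h))
            for c, l, h in zip(cols, lo, hi)
        }
        stats, mcc = _stats_from_rates(pa, pna)
        return RangeFilter(constraints=constraints, stats=stats, mcc=mcc)

    def consider(f: RangeFilter) -> None:
        nonlocal best, best_filter
        key = f.key()
        rank = (f.mcc, key)
        if best is None or rank > best:
            best, best_filter = rank, f
        if f.mcc >= cfg.mcc_floor and key not in ensemble:
            if len(ensemble) < cfg.max_ensemble:
                ensemble[key] = f

    def admissible_pairs(n: str) -> int:
        los = sorted(adm_lo[n])
        his = np.array(sorted(adm_hi[n]))
        return int(sum(len(his) - np.searchsorted(his, l, side="left") for l in los))

    def exhaustive() -> None:
        for s in range(smin, smax + 1):
            for subset in itertools.combinations(range(len(names)), s):
                per_desc = []
                for c in subset:
                    n = names[c]
                    pairs = [
                        (l, h)
                        for l in sorted(adm_lo[n])
                        for h in sorted(adm_hi[n])
                        if l <= h
                    ]
                    per_desc.append(pairs)
                if any(not p for p in per_desc):
                    continue
                for combo in itertools.product(*per_desc):
                    lo = np.array([c[0] for c in combo])
                    hi = np.array([c[1] for c in combo])
                    pa, pna = data.rates(list(subset), lo, hi)
                    consider(to_range_filter(list(subset), lo, hi, pa, pna))

    for iteration in range(cfg.max_iterations):
        pair_counts = [admissible_pairs(n) for n in names]
        live = [c for c in pair_counts if c > 0]
        if len(live) < smin:
            raise RuntimeError(
                f"search space eliminated to empty at iteration {iteration}; trace: {trace}"
            )
        total = _space_size(pair_counts, smin, smax)
        if total <= cfg.exhaustive_limit:
            exhaustive()
            break

        # --- sample candidate filters
        sampled: list[tuple[float, list[int], np.ndarray, np.ndarray, float, float]] = []
        usable = [i for i, c in enumerate(pair_counts) if c > 0]
        for _ in range(cfg.sample_size):
            s = int(rng.integers(smin, min(smax, len(usable)) + 1))
            cols = sorted(rng.choice(usable, size=s, replace=False).tolist())
            lo = np.empty(s, dtype=int)
            hi = np.empty(s, dtype=int)
            ok = True
            for j, c in enumerate(cols):
                n = names[c]
                los = sorted(adm_lo[n])
                l = int(los[rng.integers(len(los))])
                his = [h for h in sorted(adm_hi[n]) if h >= l]
                if not his:
                    ok = False
                    break
                lo[j] = l
                hi[j] = int(his[rng.integers(len(his))])
            if not ok:
                continue
            pa, pna = data.rates(cols, lo, hi)
            _, mcc = _stats_from_rates(pa, pna)
            sampled.append((mcc, cols, lo, hi, pa, pna))
            consider(to_range_filter(cols, lo, hi, pa, pna))

        if not sampled:
            raise RuntimeError(f"no sampleable filters at iteration {iteration}")

        # --- rank and compute elimination margins per (variable, value)
        sampled.sort(key=lambda t: t[0])
        n_tail = max(1, int(round(cfg.worst_fraction * len(sampled))))
        n_head = max(1, int(round(cfg.best_fraction * len(sampled))))
        worst = sampled[:n_tail]
        top = sampled[-n_head:]

        def value_freqs(group) -> tuple[dict, dict]:
            flo: dict[tuple[str, int], float] = {}
            fhi: dict[tuple[str, int], float] = {}
            for _, cols, lo, hi, _, _ in group:
                for c, l, h in zip(cols, lo, hi):
                    n = names[c]
                    flo[(n, int(l))] = flo.get((n, int(l)), 0) + 1
                    fhi[(n, int(h))] = fhi.get((n, int(h)), 0) + 1
            return (
                {k: v / len(group) for k, v in flo.items()},
                {k: v / len(group) for k, v in fhi.items()},
            )

        wlo, whi = value_freqs(worst)
        blo, bhi = value_freqs(top)
        eliminated = 0
        for (adm, wfreq, bfreq) in ((adm_lo, wlo, blo), (adm_hi, whi, bhi)):
            for n in names:
                removable = [
                    v
                    for v in sorted(adm[n])
                    if wfreq.get((n, v), 0.0) - bfreq.get((n, v), 0.0)
                    > cfg.elimination_margin
                ]
                for v in removable:
                    if len(adm[n]) > 1:
                        adm[n].discard(v)
                        eliminated += 1
        trace.append({"iteration": iteration, "space": total, "eliminated": eliminated})
        if eliminated == 0 and iteration > 0:
            # stalled: no value distinguishes worst from best any more
            if total <= cfg.exhaustive_limit:
                exhaustive()
            break

    assert best_filter is not None
    ens = sorted(ensemble.values(), key=lambda f: (-(f.mcc or 0.0), f.key()))
    return best_filter, ens
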