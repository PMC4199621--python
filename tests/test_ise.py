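"""Range-filter learning: MCC, discretisation, encoding, ISE optimisation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from h4screen import (
    DiscretizedSpace,
    ISEConfig,
    LabelledMolecule,
    RangeFilter,
    compute_mcc,
    discretize,
    encode_binary,
    evaluate_filter,
    ise_optimize,
)


def records(values_by_class: dict[str, np.ndarray], names: list[str]):
    """Build labelled descriptor-vector records from per-class matrices."""
    out = []
    for label, matrix in values_by_class.items():
        for i, row in enumerate(np.atleast_2d(matrix)):
            out.append(
                LabelledMolecule(
                    id=f"{label[:3]}{i}", smiles="", label=label,
                    descriptors=dict(zip(names, map(float, np.atleast_1d(row)))),
                )
            )
    return out


# ---------------------------------------------------------------------------
# MCC


def test_mcc_three_rules_rates_give_published_value():
    # class-normalised counts from 87% actives / 5% non-actives passing
    assert round(compute_mcc(87, 13, 5, 95), 2) == 0.82


def test_mcc_edge_cases():
    assert compute_mcc(50, 0, 0, 50) == 1.0
    assert compute_mcc(50, 0, 50, 0) == 0.0  # zero-denominator convention
    with pytest.raises(ValueError):
        compute_mcc(0, 0, 0, 0)
    with pytest.raises(ValueError):
        compute_mcc(-1, 1, 1, 1)


@settings(deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 200)] * 4))
def test_mcc_antisymmetric_under_class_swap(counts):
    tp, fn, fp, tn = counts
    if sum(counts) == 0:
        return
    assert compute_mcc(tp, fn, fp, tn) == pytest.approx(
        -compute_mcc(fp, tn, tp, fn)
    )
    assert -1 <= compute_mcc(tp, fn, fp, tn) <= 1


# ---------------------------------------------------------------------------
# discretisation / encoding


def test_discretize_uniform_grid_gives_deciles():
    mols = records({"active": np.arange(1, 51)[:, None],
                    "inactive": np.arange(51, 101)[:, None]}, ["x"])
    space = discretize(mols, ["x"], bins=10)
    assert space.integer["x"]
    np.testing.assert_array_equal(space.cuts["x"], np.arange(10, 100, 10))


def test_discretize_constant_descriptor_flagged():
    mols = records({"active": np.full((5, 1), 2.0),
                    "inactive": np.full((5, 1), 2.0)}, ["x"])
    space = discretize(mols, ["x"], bins=4)
    assert "x" in space.degenerate
    with pytest.raises(ValueError):
        discretize(mols, ["x"], bins=1)


def test_discretize_matches_sorted_quantile_oracle():
    rng = np.random.default_rng(3)
    values = np.concatenate([rng.normal(0, 1, 40), rng.normal(4, 2, 60)])
    mols = records({"active": values[:40, None],
                    "inactive": values[40:, None]}, ["x"])
    space = discretize(mols, ["x"], bins=5)

    # oracle: sort-based linear-interpolation quantiles, written out longhand
    xs = np.sort(values)
    expected = []
    for q in (0.2, 0.4, 0.6, 0.8):
        pos = q * (len(xs) - 1)
        lo = int(math.floor(pos))
        frac = pos - lo
        expected.append(xs[lo] * (1 - frac) + xs[min(lo + 1, len(xs) - 1)] * frac)
    np.testing.assert_allclose(space.cuts["x"], expected, rtol=1e-12)


def test_encode_binary_one_hot_and_boundaries():
    space = DiscretizedSpace(
        cuts={"a": np.array([1.0, 2.0, 3.0]), "b": np.array([10.0])},
        integer={"a": False, "b": False},
    )
    enc = encode_binary(
        LabelledMolecule("m", "", descriptors={"a": 2.0, "b": -5.0}), space
    )
    assert len(enc) == 4 + 2
    # value exactly on a cut-point falls in the lower interval
    np.testing.assert_array_equal(enc.bits[:4], [0, 1, 0, 0])
    # below all cut-points -> first interval
    np.testing.assert_array_equal(enc.bits[4:], [1, 0])
    # above all cut-points clamps to the outermost interval
    enc_hi = encode_binary(
        LabelledMolecule("m", "", descriptors={"a": 99.0, "b": 99.0}), space
    )
    assert enc_hi.bits[3] == 1 and enc_hi.bits[5] == 1
    assert enc.bits.sum() == 2  # exactly one bit per descriptor


# ---------------------------------------------------------------------------
# filter evaluation


def _regime_set(pa=0.87, pna=0.05, n=100):
    """Planted set where exactly round(pa*n) actives / round(pna*n) decoys pass x∈[0,1]."""
    n_pass_a, n_pass_i = round(pa * n), round(pna * n)
    act = np.concatenate([np.linspace(0.1, 0.9, n_pass_a), np.full(n - n_pass_a, 5.0)])
    ina = np.concatenate([np.linspace(0.1, 0.9, n_pass_i), np.full(n - n_pass_i, 5.0)])
    return records({"active": act[:, None], "inactive": ina[:, None]}, ["x"])


def test_evaluate_filter_published_regime_mcc():
    f = evaluate_filter(RangeFilter({"x": (0.0, 1.0)}), _regime_set())
    assert f.stats.PA == 87.0 and f.stats.PNA == 5.0
    assert round(f.mcc, 2) == 0.82


def test_evaluate_filter_degenerate_filters():
    mols = _regime_set()
    allpass = evaluate_filter(RangeFilter({}), mols)
    assert allpass.stats.PA == 100 and allpass.stats.PNA == 100
    assert allpass.mcc == 0.0
    none = evaluate_filter(RangeFilter({"x": (100.0, 200.0)}), mols)
    assert none.stats.NA == 100 and none.stats.NNA == 100
    assert none.mcc == 0.0
    with pytest.raises(ValueError):
        evaluate_filter(RangeFilter({}), [m for m in mols if m.label == "active"])


def test_evaluate_filter_monotone_under_widening():
    rng = np.random.default_rng(11)
    mols = records(
        {"active": rng.normal(0, 1, (80, 2)), "inactive": rng.normal(1, 1, (80, 2))},
        ["x", "y"],
    )
    f = RangeFilter({"x": (-0.5, 0.5), "y": (-0.5, 0.5)})
    base = evaluate_filter(f, mols)
    for name in ("x", "y"):
        for widened in (
            {**f.constraints, name: (-1.5, 0.5)},
            {**f.constraints, name: (-0.5, 1.5)},
        ):
            w = evaluate_filter(RangeFilter(widened), mols)
            assert w.stats.PA >= base.stats.PA
            assert w.stats.PNA >= base.stats.PNA


def test_range_filter_validation_and_json_roundtrip():
    with pytest.raises(ValueError):
        RangeFilter({"x": (2.0, 1.0)})
    f = evaluate_filter(RangeFilter({"x": (0.0, 1.0)}), _regime_set())
    g = RangeFilter.from_dict(f.to_dict())
    assert g.constraints == dict(f.constraints)
    assert g.mcc == f.mcc and g.stats == f.stats


# ---------------------------------------------------------------------------
# ISE optimisation


def _separable_set():
    """Actives in [2,4], decoys outside; cut-points 0..6."""
    act = np.array([2.5, 3.0, 3.5, 2.7, 3.3] * 10)
    ina = np.array([0.5, 1.5, 4.5, 5.5, 0.8] * 10)
    mols = records({"active": act[:, None], "inactive": ina[:, None]}, ["x"])
    space = DiscretizedSpace(cuts={"x": np.arange(0.0, 7.0)}, integer={"x": False})
    return mols, space


def test_ise_recovers_planted_separable_interval():
    mols, space = _separable_set()
    cfg = ISEConfig(sample_size=50, subset_min=1, subset_max=1,
                    exhaustive_limit=10_000, mcc_floor=0.6)
    best, ensemble = ise_optimize(mols, space, cfg, seed=0)
    assert best.mcc == 1.0
    assert best.constraints == {"x": (2.0, 4.0)}
    assert all(f.mcc >= 0.6 for f in ensemble)
    assert best.mcc >= max(f.mcc for f in ensemble)


def test_ise_deterministic_for_fixed_seed():
    rng = np.random.default_rng(5)
    mols = records(
        {"active": rng.normal(0, 1, (60, 3)), "inactive": rng.normal(1.5, 1, (60, 3))},
        ["x", "y", "z"],
    )
    space = discretize(mols, ["x", "y", "z"], bins=5)
    cfg = ISEConfig(sample_size=100, subset_min=1, subset_max=2,
                    exhaustive_limit=10, max_iterations=4, mcc_floor=0.3)
    r1 = ise_optimize(mols, space, cfg, seed=123)
    r2 = ise_optimize(mols, space, cfg, seed=123)
    assert r1[0].constraints == r2[0].constraints
    assert [f.key() for f in r1[1]] == [f.key() for f in r2[1]]


def _brute_force_best_mcc(mols, space, smin, smax):
    """Independent oracle: enumerate every bin-range filter, direct arithmetic."""
    names = space.names
    act = np.array([[m.descriptors[n] for n in names] for m in mols
                    if m.label == "active"])
    ina = np.array([[m.descriptors[n] for n in names] for m in mols
                    if m.label == "inactive"])
    binned = {}
    for j, n in enumerate(names):
        binned[n] = (
            np.searchsorted(space.cuts[n], act[:, j], side="left"),
            np.searchsorted(space.cuts[n], ina[:, j], side="left"),
        )
    best = -2.0
    for s in range(smin, smax + 1):
        for subset in itertools.combinations(names, s):
            ranges = [
                [(lo, hi) for lo in range(space.n_bins(n))
                 for hi in range(lo, space.n_bins(n))]
                for n in subset
            ]
            for combo in itertools.product(*ranges):
                pa_mask = np.ones(len(act), dtype=bool)
                pna_mask = np.ones(len(ina), dtype=bool)
                for n, (lo, hi) in zip(subset, combo):
                    ba, bi = binned[n]
                    pa_mask &= (ba >= lo) & (ba <= hi)
                    pna_mask &= (bi >= lo) & (bi <= hi)
                tp = 100.0 * pa_mask.mean()
                fp = 100.0 * pna_mask.mean()
                fn, tn = 100.0 - tp, 100.0 - fp
                den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
                mcc = 0.0 if den == 0 else (tp * tn - fp * fn) / math.sqrt(den)
                best = max(best, mcc)
    return best


def test_ise_exhaustive_equals_brute_force_optimum():
    rng = np.random.default_rng(21)
    mols = records(
        {"active": rng.normal(0, 1, (100, 2)), "inactive": rng.normal(1.2, 1.3, (100, 2))},
        ["x", "y"],
    )
    space = discretize(mols, ["x", "y"], bins=6)
    cfg = ISEConfig(sample_size=50, subset_min=1, subset_max=2,
                    exhaustive_limit=10**6, mcc_floor=0.9)
    best, _ = ise_optimize(mols, space, cfg, seed=1)
    oracle = _brute_force_best_mcc(mols, space, 1, 2)
    assert best.mcc == pytest.approx(oracle, abs=1e-9)


def test_ise_null_labels_give_near_zero_mcc():
    rng = np.random.default_rng(17)
    # labels carry no signal: both classes drawn from the same distribution
    mols = records(
        {"active": rng.normal(0, 1, (500, 2)), "inactive": rng.normal(0, 1, (500, 2))},
        ["x", "y"],
    )
    space = discretize(mols, ["x", "y"], bins=6)
    cfg = ISEConfig(sample_size=100, subset_min=1, subset_max=2,
                    exhaustive_limit=10**6, mcc_floor=0.99)
    best, _ = ise_optimize(mols, space, cfg, seed=2)
    assert abs(best.mcc) <= 0.1


def test_ise_planted_and_rule_with_noise_matches_exhaustive():
    rng = np.random.default_rng(31)
    n = 500
    act = np.column_stack([rng.uniform(2, 4, n), rng.uniform(10, 20, n)])
    ina = np.column_stack([rng.uniform(0, 6, n), rng.uniform(0, 30, n)])
    # 5% label noise: swap tails
    act[: n // 20] = rng.uniform(0, 6, (n // 20, 2)) * [1, 5]
    mols = records({"active": act, "inactive": ina}, ["x", "y"])
    space = discretize(mols, ["x", "y"], bins=6)
    cfg = ISEConfig(sample_size=200, subset_min=2, subset_max=2,
                    exhaustive_limit=10**6, mcc_floor=0.6)
    best, _ = ise_optimize(mols, space, cfg, seed=3)
    oracle = _brute_force_best_mcc(mols, space, 2, 2)
    assert best.mcc == pytest.approx(oracle, abs=1e-9)
    # recovered bounds within one discretisation bin of the planted rule
    lo, hi = best.constraints["x"]
    cuts = space.cuts["x"]
    bin_w = np.diff(cuts).max()
    assert lo == -math.inf or abs(lo - 2.0) <= 1.5 * bin_w
    assert hi == math.inf or abs(hi - 4.0) <= 1.5 * bin_w


def test_ise_empty_space_is_fatal():
    mols, _ = _separable_set()
    space = DiscretizedSpace(cuts={"x": np.array([])}, integer={"x": False},
                             degenerate={"x"})
    with pytest.raises(ValueError):
        ise_optimize(mols, space, ISEConfig(), seed=0)
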