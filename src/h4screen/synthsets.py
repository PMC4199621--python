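"""Synthetic screening inputs with planted ground truth.

Real inputs to this pipeline are curated antagonist/decoy libraries and
docking runs; neither is redistributable nor cheap to produce, so this
module generates stand-ins with the statistical structure the analysis
assumes, plus a few hard-coded structure fixtures.

Two generators:

* :func:`gen_descriptor_set` — labelled descriptor vectors (no chemical
  structures: the range-filter learner and the bioactivity index never
  consult the structure, and structure-free records keep ground truth
  exact). Actives satisfy a planted descriptor-interval rule with
  probability 1 − label_noise; decoys satisfy it at a configured
  background rate. The default active population mirrors the published
  H4-antagonist property profile: formal charge +1, 3–7 nitrogens,
  molecular weight centred near 280 Da, moderate logP, fractional
  negative VdW surface area around 0.30.

* :func:`gen_pose_set` — docking-pose populations around a synthetic
  two-carboxylate reference site: planted binders place a polar nitrogen
  within hydrogen-bonding distance of each anchor residue and draw
  electrostatic energies from a low-energy component; non-binders sit
  beyond the contact threshold with near-zero energies. Distance supports
  are disjoint by construction, so the planted truth is recoverable
  exactly by the geometric filter.

All generators are pure functions of (spec, seed): repeat calls are
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .molkit import LabelledMolecule
from .pose import DockedPose, ReferenceSite

__all__ = [
    "DescriptorSetSpec",
    "Distribution",
    "PoseSetSpec",
    "SyntheticRecord",
    "default_site",
    "fixtures",
    "gen_descriptor_set",
    "gen_pose_set",
]


@dataclass(frozen=True)
class Distribution:
    """One per-class descriptor distribution.

    family: "normal" (mean, sd, optional truncation), "uniform" (low,
    high) or "categorical" (values with probabilities). Truncation is by
    rejection, preserving the shape inside the window.
    """

    family: str
    params: Mapping[str, object]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "normal":
            lo = float(p.get("low", -math.inf))
            hi = float(p.get("high", math.inf))
            out = np.empty(0)
            while out.size < n:
                draw = rng.normal(p["mean"], p["sd"], size=2 * n + 16)
                out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
            return out[:n]
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size=n)
        if self.family == "categorical":
            values = np.asarray(p["values"], dtype=float)
            probs = p.get("probs")
            return rng.choice(values, size=n, p=probs)
        raise ValueError(f"unknown family {self.family!r}")

    def support(self) -> tuple[float, float]:
        p = self.params
        if self.family == "normal":
            return float(p.get("low", -math.inf)), float(p.get("high", math.inf))
        if self.family == "uniform":
            return float(p["low"]), float(p["high"])
        values = np.asarray(p["values"], dtype=float)
        return float(values.min()), float(values.max())

    def conditioned(self, low: float, high: float, inside: bool) -> "Distribution":
        """Restrict (inside=True) or exclude (inside=False) an interval."""
        p = dict(self.params)
        if inside:
            if self.family == "normal":
                p["low"] = max(float(p.get("low", -math.inf)), low)
                p["high"] = min(float(p.get("high", math.inf)), high)
                return Distribution("normal", p)
            if self.family == "uniform":
                return Distribution(
                    "uniform",
                    {"low": max(p["low"], low), "high": min(p["high"], high)},
                )
            values = [v for v in p["values"] if low <= v <= high]
            if not values:
                raise ValueError("planted interval has empty support")
            return Distribution("categorical", {"values": values})
        # outside: categorical drops the window; continuous families use
        # rejection at sampling time via _sample_outside
        return Distribution(
            "_outside", {"base": Distribution(self.family, self.params),
                         "low": low, "high": high},
        )


def _sample_outside(dist: Distribution, n: int, rng: np.random.Generator) -> np.ndarray:
    base: Distribution = dist.params["base"]  # type: ignore[assignment]
    low, high = float(dist.params["low"]), float(dist.params["high"])
    out = np.empty(0)
    tries = 0
    while out.size < n:
        draw = base.sample(2 * n + 16, rng)
        out = np.concatenate([out, draw[(draw < low) | (draw > high)]])
        tries += 1
        if tries > 200:
            raise ValueError("cannot sample outside the planted interval")
    return out[:n]


def _default_active_dists() -> dict[str, Distribution]:
    return {
        "molecular_weight": Distribution("normal", {"mean": 280, "sd": 60, "low": 100}),
        "total_charge": Distribution("categorical", {"values": [0, 1, 2], "probs": [0.08, 0.80, 0.12]}),
        "n_nitrogen": Distribution("categorical", {"values": [3, 4, 5, 6, 7]}),
        "logp": Distribution("normal", {"mean": 2.2, "sd": 1.0}),
        "fasa_neg": Distribution("normal", {"mean": 0.30, "sd": 0.06, "low": 0.0, "high": 1.0}),
    }


def _default_decoy_dists() -> dict[str, Distribution]:
    return {
        "molecular_weight": Distribution("normal", {"mean": 350, "sd": 110, "low": 80}),
        "total_charge": Distribution("categorical", {"values": [-1, 0, 1, 2], "probs": [0.15, 0.60, 0.20, 0.05]}),
        "n_nitrogen": Distribution("categorical", {"values": [0, 1, 2, 3, 4, 5, 6, 7, 8], "probs": [0.18, 0.22, 0.20, 0.12, 0.10, 0.08, 0.05, 0.03, 0.02]}),
        "logp": Distribution("normal", {"mean": 2.8, "sd": 1.6}),
        "fasa_neg": Distribution("normal", {"mean": 0.40, "sd": 0.12, "low": 0.0, "high": 1.0}),
    }


@dataclass
class DescriptorSetSpec:
    """Specification of a planted-rule labelled descriptor population.

    ``planted_rule`` maps descriptor -> closed interval; actives satisfy
    every interval with probability 1 − label_noise, decoys with
    probability ``decoy_background``. Rule intervals must intersect the
    distribution supports.
    """

    n_active: int = 500
    n_decoy: int = 5000
    active_dists: dict[str, Distribution] = field(default_factory=_default_active_dists)
    decoy_dists: dict[str, Distribution] = field(default_factory=_default_decoy_dists)
    planted_rule: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "total_charge": (1, 1),
            "n_nitrogen": (3, 7),
            "fasa_neg": (0.0, 0.42),
        }
    )
    label_noise: float = 0.0
    decoy_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise <= 1 or not 0 <= self.decoy_background <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        for name, (low, high) in self.planted_rule.items():
            for dists in (self.active_dists, self.decoy_dists):
                lo_s, hi_s = dists[name].support()
                if high < lo_s or low > hi_s:
                    raise ValueError(f"planted rule on {name} outside support")


@dataclass
class SyntheticRecord(LabelledMolecule):
    """Descriptor vector with label and ground-truth rule membership."""

    in_rule: bool = False


def gen_descriptor_set(spec: DescriptorSetSpec) -> list[SyntheticRecord]:
    """Generate the labelled descriptor population of *spec* (seeded)."""
    rng = np.random.default_rng(spec.seed)
    records: list[SyntheticRecord] = []

    def build(n: int, dists: Mapping[str, Distribution], p_in: float,
              label: str, prefix: str) -> None:
        in_rule = rng.random(n) < p_in
        columns: dict[str, np.ndarray] = {}
        for name, dist in dists.items():
            values = np.empty(n)
            if name in spec.planted_rule:
                low, high = spec.planted_rule[name]
                n_in = int(in_rule.sum())
                if n_in:
                    values[in_rule] = dist.conditioned(low, high, True).sample(n_in, rng)
                if n - n_in:
                    # records violating the rule get unconditioned draws per
                    # descriptor, then one descriptor is forced outside below
                    values[~in_rule] = dist.sample(n - n_in, rng)
            else:
                values[:] = dist.sample(n, rng)
            columns[name] = values
        # force every out-of-rule record outside at least one interval,
        # choosing only descriptors whose distribution extends past it
        rule_names = list(spec.planted_rule)
        forceable = []
        for n_ in rule_names:
            lo_s, hi_s = dists[n_].support()
            low, high = spec.planted_rule[n_]
            if lo_s < low or hi_s > high:
                forceable.append(n_)
        out_rows = np.flatnonzero(~in_rule)
        if out_rows.size and not forceable:
            raise ValueError(
                "planted rule covers the full support of every constrained "
                "descriptor; out-of-rule records are infeasible"
            )
        for i in out_rows:
            inside = all(
                spec.planted_rule[n_][0] <= columns[n_][i] <= spec.planted_rule[n_][1]
                for n_ in rule_names
            )
            if inside:
                name = forceable[int(rng.integers(len(forceable)))]
                low, high = spec.planted_rule[name]
                out_dist = dists[name].conditioned(low, high, False)
                columns[name][i] = _sample_outside(out_dist, 1, rng)[0]
        for i in range(n):
            records.append(
                SyntheticRecord(
                    id=f"{prefix}{i+1:05d}",
                    smiles="",
                    label=label,
                    descriptors={k: float(v[i]) for k, v in columns.items()},
                    in_rule=bool(in_rule[i]),
                )
            )

    build(spec.n_active, spec.active_dists, 1.0 - spec.label_noise, "active", "act")
    build(spec.n_decoy, spec.decoy_dists, spec.decoy_background, "inactive", "dec")
    return records


# ---------------------------------------------------------------------------
# Pose populations


def default_site() -> ReferenceSite:
    """Synthetic two-residue reference site (fixed coordinates).

    Stand-in for the receptor's D3.32/E5.46 carboxylates: two pairs of
    oxygens ~8 Å apart, the spacing of the two anchor residues across the
    orthosteric pocket.
    """
    return ReferenceSite(
        oxygens={
            "D3.32": np.array([[0.0, 0.0, 0.0], [1.2, 0.8, 0.0]]),
            "E5.46": np.array([[8.0, 1.0, 1.5], [8.9, 0.2, 2.1]]),
        }
    )


@dataclass
class PoseSetSpec:
    """Planted docking-pose population.

    Binders appear among actives with probability ``p_binder_active`` and
    among the reference set with ``p_binder_reference``; their contact
    distances and electrostatic energies come from the binder
    distributions, everything else from the non-binder ones. The binder
    distance support must end below where the non-binder support begins
    so the geometric truth is exact.
    """

    n_active_compounds: int = 100
    n_reference_compounds: int = 500
    p_binder_active: float = 0.2
    p_binder_reference: float = 0.01
    binder_distance: tuple[float, float] = (2.5, 3.8)
    nonbinder_distance: tuple[float, float] = (5.0, 12.0)
    binder_ee: tuple[float, float] = (-4.5, 0.5)  # mean, sd (kcal/mol)
    nonbinder_ee: tuple[float, float] = (-0.5, 0.7)
    poses_per_compound: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.binder_distance[1] >= self.nonbinder_distance[0]:
            raise ValueError("binder/non-binder distance supports must be disjoint")
        if self.poses_per_compound < 1:
            raise ValueError("poses_per_compound must be ≥ 1")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def gen_pose_set(
    spec: PoseSetSpec, site: ReferenceSite
) -> tuple[list[DockedPose], dict[str, bool]]:
    """Generate poses for actives and reference compounds with planted truth.

    Compound ids are ``act*``/``ref*``; the returned mapping flags the
    planted binders. Each compound's rank-1 pose is the informative one
    (strictly lowest docked energy); higher ranks are displaced decoys
    with non-binder geometry and energies, so best-pose selection
    recovers the planted pose.
    """
    rng = np.random.default_rng(spec.seed)
    all_ox = np.vstack(list(site.oxygens.values()))
    poses: list[DockedPose] = []
    truth: dict[str, bool] = {}

    def place_binder() -> list[tuple[str, float, float, float, bool]]:
        atoms = []
        for label, ox in site.oxygens.items():
            o = ox[rng.integers(len(ox))]
            for _ in range(500):
                d = rng.uniform(*spec.binder_distance)
                pos = o + d * _random_unit(rng)
                if np.linalg.norm(pos - all_ox, axis=1).min() >= spec.binder_distance[0] - 1.0:
                    break
            else:
                raise RuntimeError("binder placement failed")
            atoms.append(("N", float(pos[0]), float(pos[1]), float(pos[2]), True))
        return atoms

    def place_nonbinder() -> list[tuple[str, float, float, float, bool]]:
        lo, hi = spec.nonbinder_distance
        centre = all_ox.mean(axis=0)
        for _ in range(1000):
            d = rng.uniform(lo, hi)
            pos = centre + (d + 4.0) * _random_unit(rng)
            dmin = np.linalg.norm(pos - all_ox, axis=1).min()
            if lo <= dmin:
                return [("N", float(pos[0]), float(pos[1]), float(pos[2]), True)]
        raise RuntimeError("non-binder placement failed")

    def carbons(anchor: np.ndarray) -> list[tuple[str, float, float, float, bool]]:
        out = []
        for _ in range(3):
            pos = anchor + 1.5 * _random_unit(rng)
            out.append(("C", float(pos[0]), float(pos[1]), float(pos[2]), False))
        return out

    def build(prefix: str, n: int, p_binder: float) -> None:
        flags = rng.random(n) < p_binder
        for i in range(n):
            cid = f"{prefix}{i+1:05d}"
            is_binder = bool(flags[i])
            truth[cid] = is_binder
            if is_binder:
                key_atoms = place_binder()
                ee = float(rng.normal(*spec.binder_ee))
            else:
                key_atoms = place_nonbinder()
                ee = float(rng.normal(*spec.nonbinder_ee))
            anchor = np.array(key_atoms[0][1:4])
            base_energy = float(rng.normal(-7.0, 0.8))
            poses.append(
                DockedPose(
                    compound_id=cid, pose_rank=1,
                    atoms=key_atoms + carbons(anchor),
                    ee=ee, docked_energy=base_energy,
                )
            )
            for rank in range(2, spec.poses_per_compound + 1):
                decoy_atoms = place_nonbinder()
                poses.append(
                    DockedPose(
                        compound_id=cid, pose_rank=rank,
                        atoms=decoy_atoms + carbons(np.array(decoy_atoms[0][1:4])),
                        ee=float(rng.normal(*spec.nonbinder_ee)),
                        docked_energy=base_energy + 0.5 + 0.3 * rank + float(rng.uniform(0, 0.2)),
                    )
                )

    build("act", spec.n_active_compounds, spec.p_binder_active)
    build("ref", spec.n_reference_compounds, spec.p_binder_reference)
    return poses, truth


# ---------------------------------------------------------------------------
# Hard-coded structure fixtures


def fixtures() -> dict[str, LabelledMolecule]:
    """Named structure fixtures with known rule-filter outcomes.

    Includes the selective H4 antagonist JNJ-7777120, protonated
    histamine, and small hand-built exemplars chosen to pass or fail
    specific rule filters (extreme molecular weight, logP, charge or
    nitrogen count).
    """
    smiles = {
        # selective hH4R antagonist; MW 277.75 (C14H16ClN3O), 3 N, 1 O, 3 rings
        "jnj7777120": "CN1CCN(CC1)C(=O)c1cc2cc(Cl)ccc2[nH]1",
        # endogenous agonist, side-chain ammonium: charge +1, 3 N
        "histamine_cation": "[NH3+]CCc1c[nH]cn1",
        "methane": "C",
        # charge +1, 4 N, small: passes the charge/nitrogen rules
        "triamine_cation": "NCCN(CCN)CC[NH3+]",
        # neutral diamine: fails three_rules on charge and N count
        "ethylenediamine": "NCCN",
        # 8 nitrogens, +1: fails the 3≤N≤7 bound from above
        "octaazacation": "NCCN(CCN)N(CCN)CCN(CCN)CC[NH3+]",
        # C30 alkane: logP far above 5 → fails Lipinski/Oprea logP
        "triacontane": "C" * 30,
        # MW ≈ 703, fails Lipinski MW ≤ 500 and Oprea MW ≤ 450
        "pentacontane": "C" * 50,
        # glycerol: tiny, neutral, passes Lipinski and Oprea
        "glycerol": "OCC(O)CO",
        # citrate trianion: negative charge, fails three_rules
        "citrate": "OC(CC([O-])=O)(CC([O-])=O)C([O-])=O",
        # caffeine: neutral, 4 N → fails three_rules on charge only
        "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
        # serotonin cation: +1, 2 N → fails the N count from below
        "serotonin_cation": "c1cc2c(cc1O)c(c[nH]2)CC[NH3+]",
    }
    return {
        name: LabelledMolecule(id=name, smiles=smi, label="unknown")
        for name, smi in smiles.items()
    }
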