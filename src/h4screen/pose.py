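"""Docking-pose triage: energy clustering, distance scoring, consensus.

Post-processes rigid-receptor docking output for a GPCR whose orthosteric
site carries two negatively charged residues (Asp at Ballesteros–Weinstein
position 3.32 and Glu at 5.46). Poses are triaged by two nearly orthogonal
filters applied conjunctively:

1. an electrostatic-energy (EE) filter — 1-D k-means clustering of the
   per-pose Coulombic energies separates the population into energy
   groups; a pose passes if it falls in the lowest cluster (or the two
   lowest, the permissive mode), decided by comparison against the
   midpoint boundaries between adjacent cluster centroids;
2. a geometric filter — a distance score counting how many of the two
   reference carboxylates have at least one oxygen within a 4 Å (strict)
   threshold of any polar heavy ligand atom (N or O).

Only the best pose per compound (minimal total docked energy) is triaged.
Enrichment of actives over a random reference set is estimated with
sub-sampling of the reference population, and the consensus library is
the intersection of the ligand-based (MBI) top ranks with the pose-filter
pass set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mbi import EnrichmentResult, MBIScore, enrichment_factor

__all__ = [
    "DockedPose",
    "EnergyClustering",
    "PoseVerdict",
    "ReferenceSite",
    "TriageConfig",
    "best_pose_per_compound",
    "combined_filter",
    "consensus_select",
    "distance_score",
    "ee_filter",
    "kmeans_1d",
    "read_pose_bundle",
    "read_reference_site",
    "subsampled_enrichment",
    "triage_poses",
    "write_pose_bundle",
]

POLAR_ELEMENTS = frozenset({"N", "O"})


@dataclass
class DockedPose:
    """One docked ligand geometry with its energy terms.

    ``atoms``: (element, x, y, z, is_polar_heavy) records, coordinates in
    Å. ``ee`` is the electrostatic (Coulombic) component and
    ``docked_energy`` the total docked energy, both kcal/mol.
    """

    compound_id: str
    pose_rank: int
    atoms: list[tuple[str, float, float, float, bool]]
    ee: float
    docked_energy: float

    def __post_init__(self) -> None:
        if self.pose_rank < 1:
            raise ValueError("pose_rank must be ≥ 1")
        if not self.atoms:
            raise ValueError(f"{self.compound_id}: pose has no atoms")
        for el, x, y, z, polar in self.atoms:
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ValueError(f"{self.compound_id}: non-finite coordinates")
            if polar != (el in POLAR_ELEMENTS):
                raise ValueError(f"{self.compound_id}: polar flag inconsistent for {el}")

    def polar_coords(self) -> np.ndarray:
        return np.array(
            [(x, y, z) for el, x, y, z, p in self.atoms if p], dtype=float
        ).reshape(-1, 3)


@dataclass
class ReferenceSite:
    """Carboxylate oxygen coordinates of the two anchor residues.

    Keys are the Ballesteros–Weinstein labels ("D3.32", "E5.46"); each
    residue contributes the side-chain oxygens (OD1/OD2 for Asp,
    OE1/OE2 for Glu).
    """

    oxygens: dict[str, np.ndarray]  # label -> (n, 3) array

    def __post_init__(self) -> None:
        if len(self.oxygens) != 2:
            raise ValueError("a reference site names exactly two residues")
        for label, arr in self.oxygens.items():
            arr = np.asarray(arr, dtype=float).reshape(-1, 3)
            if arr.shape[0] < 1:
                raise ValueError(f"{label}: no oxygens")
            self.oxygens[label] = arr


def read_reference_site(
    receptor_pdb: str | Path, residues: Mapping[str, Mapping]
) -> ReferenceSite:
    """Extract carboxylate oxygens from a receptor PDB.

    ``residues`` maps a label to {"chain": ..., "resid": ...}, e.g.
    {"D3.32": {"chain": "A", "resid": 94}, "E5.46": {"chain": "A",
    "resid": 182}}. Side-chain oxygen atom names OD1/OD2/OE1/OE2 are
    collected; carboxylate carbons are excluded.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("receptor", str(receptor_pdb))
    model = next(structure.get_models())
    oxygens: dict[str, np.ndarray] = {}
    for label, spec in residues.items():
        chain = model[spec["chain"]]
        residue = chain[(" ", int(spec["resid"]), " ")]
        coords = [
            atom.get_coord()
            for atom in residue
            if atom.get_name() in ("OD1", "OD2", "OE1", "OE2")
        ]
        if not coords:
            raise ValueError(f"{label}: no carboxylate oxygens on {spec}")
        oxygens[label] = np.array(coords, dtype=float)
    return ReferenceSite(oxygens=oxygens)


# ---------------------------------------------------------------------------
# Pose bundle I/O (multi-model PDB + energy CSV)


def write_pose_bundle(
    poses: Sequence[DockedPose], pdb_path: str | Path, csv_path: str | Path
) -> None:
    """Write poses as a multi-model PDB plus an energy CSV (1:1 by order)."""
    import pandas as pd

    lines: list[str] = []
    for i, pose in enumerate(poses, start=1):
        lines.append(f"MODEL {i:8d}")
        for serial, (el, x, y, z, _) in enumerate(pose.atoms, start=1):
            name = f"{el}{serial}"[:4]
            lines.append(
                f"HETATM{serial:5d} {name:<4s}LIG A{1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(pdb_path).write_text("\n".join(lines) + "\n")
    pd.DataFrame(
        {
            "compound_id": [p.compound_id for p in poses],
            "pose_rank": [p.pose_rank for p in poses],
            "ee": [p.ee for p in poses],
            "docked_energy": [p.docked_energy for p in poses],
        }
    ).to_csv(csv_path, index=False)


def read_pose_bundle(
    pdb_path: str | Path, energy_csv: str | Path
) -> list[DockedPose]:
    """Join a multi-model pose PDB with its per-pose energy table.

    Models (MODEL/ENDMDL blocks of HETATM records) pair 1:1, in order,
    with CSV rows carrying compound_id, pose_rank, ee and docked_energy.
    A count mismatch or an empty model is fatal; a row with non-numeric
    energies drops that pose with a warning.
    """
    import pandas as pd

    models: list[list[tuple[str, float, float, float, bool]]] = []
    current: list[tuple[str, float, float, float, bool]] | None = None
    for line in Path(pdb_path).read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            current = []
        elif rec == "ENDMDL":
            if current is not None and not current:
                raise ValueError(f"{pdb_path}: empty MODEL block")
            if current is not None:
                models.append(current)
            current = None
        elif rec in ("HETATM", "ATOM") and current is not None:
            el = line[76:78].strip() or line[12:16].strip()[0]
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            current.append((el, x, y, z, el in POLAR_ELEMENTS))
    table = pd.read_csv(energy_csv)
    required = {"compound_id", "pose_rank", "ee", "docked_energy"}
    if not required <= set(table.columns):
        raise ValueError(f"{energy_csv}: missing columns {required - set(table.columns)}")
    if len(models) != len(table):
        raise ValueError(
            f"model/CSV count mismatch: {len(models)} models vs {len(table)} rows"
        )
    poses: list[DockedPose] = []
    for atoms, (_, row) in zip(models, table.iterrows()):
        try:
            ee = float(row["ee"])
            de = float(row["docked_energy"])
            if not (math.isfinite(ee) and math.isfinite(de)):
                raise ValueError
        except (TypeError, ValueError):
            warnings.warn(
                f"{energy_csv}: non-numeric energy for "
                f"{row['compound_id']}/{row['pose_rank']}, pose skipped",
                stacklevel=2,
            )
            continue
        poses.append(
            DockedPose(
                compound_id=str(row["compound_id"]),
                pose_rank=int(row["pose_rank"]),
                atoms=atoms,
                ee=ee,
                docked_energy=de,
            )
        )
    return poses


def best_pose_per_compound(poses: Sequence[DockedPose]) -> list[DockedPose]:
    """Keep one pose per compound: minimal docked energy, ties by pose rank.

    Output follows first-appearance order of compounds.
    """
    best: dict[str, DockedPose] = {}
    for pose in poses:
        cur = best.get(pose.compound_id)
        if cur is None or (pose.docked_energy, pose.pose_rank) < (
            cur.docked_energy,
            cur.pose_rank,
        ):
            best[pose.compound_id] = pose
    return list(best.values())


# ---------------------------------------------------------------------------
# Electrostatic-energy clustering


@dataclass
class EnergyClustering:
    """1-D k-means result: increasing centroids, midpoint boundaries."""

    k: int
    centroids: np.ndarray  # strictly increasing, kcal/mol
    boundaries: np.ndarray  # k-1 midpoints between adjacent centroids
    assignment: np.ndarray  # cluster index per input value (0 = lowest energy)
    sse: float

    def cluster_of(self, value: float) -> int:
        """Cluster index by boundary comparison (ties go to the lower cluster)."""
        return int(np.searchsorted(self.boundaries, value, side="left"))


def kmeans_1d(values: Sequence[float], k: int, seed: int = 0) -> EnergyClustering:
    """Exact 1-D k-means by dynamic programming over contiguous partitions.

    In one dimension the SSE-optimal clusters are contiguous in value
    order, so the global optimum is found exactly by dynamic programming
    on the sorted values with prefix sums — deterministic, with no
    dependence on initialisation (the seed is accepted for interface
    stability only). Centroids are the cluster means in increasing
    order; boundaries are midpoints between adjacent centroids.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    distinct = np.unique(x)
    if k < 1 or k > distinct.size:
        raise ValueError(f"k={k} but only {distinct.size} distinct values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def seg_cost(a: np.ndarray, b: int) -> np.ndarray:
        """SSE of sorted segments [a, b) for a vector of starts a."""
        cnt = b - a
        s = s1[b] - s1[a]
        return (s2[b] - s2[a]) - s**2 / cnt

    # dp[m, i]: optimal SSE of the first i points in m clusters
    dp = np.full((k + 1, n + 1), np.inf)
    dp[0, 0] = 0.0
    back = np.zeros((k + 1, n + 1), dtype=int)
    for m in range(1, k + 1):
        for i in range(m, n - (k - m) + 1):
            starts = np.arange(m - 1, i)
            costs = dp[m - 1, starts] + seg_cost(starts, i)
            j = int(np.argmin(costs))
            dp[m, i] = costs[j]
            back[m, i] = starts[j]
    # recover cluster edges
    edges = [n]
    i = n
    for m in range(k, 0, -1):
        i = int(back[m, i])
        edges.append(i)
    edges = edges[::-1]
    centroids = np.array(
        [xs[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    )
    assignment_sorted = np.empty(n, dtype=int)
    for j, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        assignment_sorted[a:b] = j
    assignment = np.empty(n, dtype=int)
    assignment[order] = assignment_sorted
    boundaries = (centroids[:-1] + centroids[1:]) / 2.0
    return EnergyClustering(
        k=k, centroids=centroids, boundaries=boundaries,
        assignment=assignment, sse=float(dp[k, n]),
    )


def ee_filter(
    pose: DockedPose, clustering: EnergyClustering, mode: str = "two_lowest_clusters"
) -> bool:
    """Pass iff the pose's EE falls in the lowest (or two lowest) clusters."""
    if mode not in ("lowest_cluster", "two_lowest_clusters"):
        raise ValueError(f"unknown ee mode {mode!r}")
    cluster = clustering.cluster_of(pose.ee)
    allowed = 1 if mode == "lowest_cluster" else 2
    return cluster < allowed


# ---------------------------------------------------------------------------
# Distance scoring and combined verdicts


def distance_score(
    pose: DockedPose, site: ReferenceSite, threshold: float = 4.0
) -> int:
    """Count reference residues with a polar contact below the threshold.

    A residue interacts when the minimum Euclidean distance between any
    polar heavy ligand atom (N/O) and any of its carboxylate oxygens is
    strictly below *threshold* Å. Score ∈ {0, 1, 2}; a pose with no polar
    heavy atoms scores 0.
    """
    polar = pose.polar_coords()
    if polar.shape[0] == 0:
        return 0
    score = 0
    for arr in site.oxygens.values():
        d = np.linalg.norm(polar[:, None, :] - arr[None, :, :], axis=2)
        if d.min() < threshold:
            score += 1
    return score


@dataclass(frozen=True)
class PoseVerdict:
    compound_id: str
    ee: float
    ee_cluster: int
    distance_score: int
    passed: bool


@dataclass
class TriageConfig:
    k: int = 3
    threshold: float = 4.0
    ee_mode: str = "two_lowest_clusters"
    min_distance_score: int = 2


def combined_filter(
    verdicts: Sequence[PoseVerdict],
    ee_mode: str = "two_lowest_clusters",
    min_distance_score: int = 2,
) -> set[str]:
    """Conjunction of the two triage filters → set of passing compound ids.

    The two criteria (EE cluster membership and geometric closeness) are
    applied together; a compound passes iff its EE cluster is within the
    allowed set AND its distance score reaches the minimum.
    """
    allowed = 1 if ee_mode == "lowest_cluster" else 2
    return {
        v.compound_id
        for v in verdicts
        if v.ee_cluster < allowed and v.distance_score >= min_distance_score
    }


def triage_poses(
    poses: Sequence[DockedPose],
    site: ReferenceSite,
    config: TriageConfig | None = None,
    clustering: EnergyClustering | None = None,
) -> tuple[list[PoseVerdict], EnergyClustering]:
    """Best pose per compound → EE clustering → per-compound verdicts.

    If *clustering* is given (e.g. thresholds derived on a different pose
    population) it is reused; otherwise k-means runs on this population's
    best-pose EE values.
    """
    cfg = config or TriageConfig()
    best = best_pose_per_compound(poses)
    if clustering is None:
        clustering = kmeans_1d([p.ee for p in best], k=cfg.k)
    allowed = 1 if cfg.ee_mode == "lowest_cluster" else 2
    verdicts = []
    for pose in best:
        cluster = clustering.cluster_of(pose.ee)
        ds = distance_score(pose, site, cfg.threshold)
        verdicts.append(
            PoseVerdict(
                compound_id=pose.compound_id,
                ee=pose.ee,
                ee_cluster=cluster,
                distance_score=ds,
                passed=cluster < allowed and ds >= cfg.min_distance_score,
            )
        )
    return verdicts, clustering


# ---------------------------------------------------------------------------
# Sub-sampled enrichment and consensus selection


def subsampled_enrichment(
    actives: Sequence[PoseVerdict],
    reference: Sequence[PoseVerdict],
    folds: int = 20,
    subsample_size: int | None = None,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment factor with sub-sampling of the reference population.

    Per fold, ``subsample_size`` reference compounds are drawn without
    replacement and their pass count recorded; the enrichment factor is
    the active pass percentage (full active set) divided by the mean
    reference pass percentage over folds. Reports mean and standard
    deviation of the fold pass counts; an all-failing reference flags the
    factor as infinite.
    """
    if folds < 1:
        raise ValueError("folds must be ≥ 1")
    if subsample_size is None:
        subsample_size = len(reference)
    if subsample_size > len(reference):
        raise ValueError("subsample_size exceeds the reference population")
    rng = np.random.default_rng(seed)
    ref_pass = np.array([v.passed for v in reference], dtype=float)
    fold_counts = np.empty(folds)
    for i in range(folds):
        idx = rng.choice(len(reference), size=subsample_size, replace=False)
        fold_counts[i] = ref_pass[idx].sum()
    active_pct = 100.0 * sum(v.passed for v in actives) / len(actives)
    ref_pct = 100.0 * fold_counts.mean() / subsample_size
    return EnrichmentResult(
        frac_active_pass=active_pct,
        frac_reference_pass=ref_pct,
        enrichment_factor=enrichment_factor(active_pct, ref_pct),
        fold_pass_mean=float(fold_counts.mean()),
        fold_pass_std=float(fold_counts.std(ddof=1)) if folds > 1 else 0.0,
        n_folds=folds,
    )


def consensus_select(
    ranked_mbi: Sequence[MBIScore],
    pose_pass: Iterable[str],
    size: int = 11,
) -> list[str]:
    """Consensus library: pose-filter passers ordered by MBI rank, top *size*.

    Warns and returns everything available when fewer compounds pass than
    requested.
    """
    passers = set(pose_pass)
    chosen = [s.id for s in ranked_mbi if s.id in passers][:size]
    if len(chosen) < size:
        warnings.warn(
            f"only {len(chosen)} compounds pass both stages (requested {size})",
            stacklevel=2,
        )
    return chosen


def verdict_table(verdicts: Sequence[PoseVerdict]):
    """Verdicts as a DataFrame: compound_id, ee, ee_cluster, distance_score, passed."""
    import pandas as pd

    return pd.DataFrame(
        {
            "compound_id": [v.compound_id for v in verdicts],
            "ee": [v.ee for v in verdicts],
            "ee_cluster": [v.ee_cluster for v in verdicts],
            "distance_score": [v.distance_score for v in verdicts],
            "passed": [v.passed for v in verdicts],
        }
    )
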