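"""End-to-end orchestration: learn → score → triage → consensus.

Runs the sequential ligand-based / structure-based screen from a single
JSON config with explicit per-stage seeds, writing every intermediate
artefact plus a machine-readable run manifest (inputs, seeds, versions,
output checksums). Stages:

1. simulate (or load) the labelled training descriptor set;
2. learn the range-filter ensemble by ISE;
3. generate and MBI-rank the screening library, keeping the top fraction
   as the focused set;
4. generate docking poses for the focused compounds and a reference set,
   then triage them (EE clustering + distance score);
5. sub-sampled enrichment of focused actives over the reference set;
6. consensus library: pose-filter passers in MBI order.

Logging goes to standard error; all randomness flows from the configured
seeds, never from wall-clock time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .ise import ISEConfig, discretize, ise_optimize
from .mbi import FilterEnsemble, rank_library, top_fraction_ids
from .pose import (
    TriageConfig,
    combined_filter,
    consensus_select,
    subsampled_enrichment,
    triage_poses,
    verdict_table,
)
from .synthsets import (
    DescriptorSetSpec,
    PoseSetSpec,
    default_site,
    gen_descriptor_set,
    gen_pose_set,
)

__all__ = ["RunConfig", "default_config", "run_pipeline", "validate_config"]

logger = logging.getLogger("h4screen")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """Validated pipeline configuration (see :func:`validate_config`)."""

    workdir: str = "h4screen_run"
    seeds: dict[str, int] = field(
        default_factory=lambda: {"training": 11, "ise": 17, "library": 23,
                                 "poses": 29, "subsample": 31}
    )
    training: dict[str, Any] = field(default_factory=dict)
    library: dict[str, Any] = field(default_factory=dict)
    ise: dict[str, Any] = field(default_factory=dict)
    bins: int = 10
    top_fraction: float = 0.01
    poses: dict[str, Any] = field(default_factory=dict)
    triage: dict[str, Any] = field(default_factory=dict)
    folds: int = 20
    subsample_size: int | None = None
    consensus_size: int = 11


_SCHEMA: dict[str, Any] = {
    "workdir": str,
    "seeds": dict,
    "training": dict,
    "library": dict,
    "ise": dict,
    "bins": int,
    "top_fraction": float,
    "poses": dict,
    "triage": dict,
    "folds": int,
    "subsample_size": (int, type(None)),
    "consensus_size": int,
}

_BOUNDS = {
    "bins": lambda v: v >= 2 or "bins must be ≥ 2",
    "top_fraction": lambda v: 0 < v <= 1 or "top_fraction must be in (0, 1]",
    "folds": lambda v: v >= 1 or "folds must be ≥ 1",
    "consensus_size": lambda v: v >= 1 or "consensus_size must be ≥ 1",
}

_TRIAGE_BOUNDS = {
    "k": lambda v: v >= 1 or "k must be ≥ 1",
    "threshold": lambda v: v > 0 or "threshold must be > 0 Å",
    "ee_mode": lambda v: v in ("lowest_cluster", "two_lowest_clusters")
    or "ee_mode must be lowest_cluster or two_lowest_clusters",
    "min_distance_score": lambda v: v in (0, 1, 2)
    or "min_distance_score must be 0, 1 or 2",
}


def validate_config(source: str | Path | Mapping) -> tuple[RunConfig | None, list[str]]:
    """Type- and bound-check a config; unknown keys are rejected.

    Returns (config, []) on success or (None, errors) with every problem
    reported at once.
    """
    if isinstance(source, (str, Path)):
        try:
            raw = json.loads(Path(source).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            return None, [f"cannot read config: {exc}"]
    else:
        raw = dict(source)
    errors: list[str] = []
    for key in raw:
        if key not in _SCHEMA:
            errors.append(f"unknown key {key!r}")
    for key, expected in _SCHEMA.items():
        if key not in raw:
            continue
        v = raw[key]
        if expected is float and isinstance(v, int):
            v = raw[key] = float(v)
        if not isinstance(v, expected) or isinstance(v, bool):
            errors.append(f"{key}: expected {expected}, got {type(v).__name__}")
            continue
        check = _BOUNDS.get(key)
        if check is not None:
            res = check(v)
            if res is not True:
                errors.append(str(res))
    for key, check in _TRIAGE_BOUNDS.items():
        if key in raw.get("triage", {}):
            res = check(raw["triage"][key])
            if res is not True:
                errors.append(f"triage.{key}: {res}")
    if "seeds" in raw:
        for name, s in raw["seeds"].items():
            if not isinstance(s, int) or isinstance(s, bool):
                errors.append(f"seeds.{name}: expected integer")
    if errors:
        return None, errors
    return RunConfig(**raw), []


def default_config(workdir: str = "h4screen_run", seed: int = 7) -> RunConfig:
    """A complete synthetic-run config derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("training", "ise", "library", "poses", "subsample"), ss.spawn(5)
        )
    }
    return RunConfig(
        workdir=workdir,
        seeds=seeds,
        training={"n_active": 300, "n_decoy": 3000, "label_noise": 0.13,
                  "decoy_background": 0.05},
        library={"n_active": 500, "n_decoy": 5000, "label_noise": 0.13,
                 "decoy_background": 0.05},
        ise={"sample_size": 300, "exhaustive_limit": 20_000, "max_iterations": 20,
             "subset_min": 2, "subset_max": 3, "mcc_floor": 0.6},
        bins=8,
        top_fraction=0.1,
        poses={"p_binder_active": 0.2, "p_binder_reference": 0.01,
               "n_reference_compounds": 500, "poses_per_compound": 4},
        triage={},
        folds=100,
        subsample_size=137,
        consensus_size=11,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": asdict(config),
        "stages": [],
    }

    def record(name: str, outputs: dict[str, Path], **info: Any) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "outputs": {k: str(p) for k, p in outputs.items()},
                "checksums": {k: _sha256(p) for k, p in outputs.items()},
                **info,
            }
        )
        logger.info("stage %s done (%s)", name, ", ".join(outputs))

    # 1 — training set
    train_spec = DescriptorSetSpec(**config.training, seed=config.seeds["training"])
    training = gen_descriptor_set(train_spec)
    from .molkit import descriptor_table

    train_csv = workdir / "training.csv"
    descriptor_table(training).to_csv(train_csv, index=False)
    record("training_set", {"table": train_csv},
           n_active=train_spec.n_active, n_decoy=train_spec.n_decoy)

    # 2 — learn filters
    panel = list(training[0].descriptors)
    space = discretize(training, panel, bins=config.bins)
    best, ensemble_filters = ise_optimize(
        training, space, ISEConfig(**config.ise), seed=config.seeds["ise"]
    )
    if not ensemble_filters:
        ensemble_filters = [best]
    ensemble = FilterEnsemble(filters=ensemble_filters)
    ens_json = workdir / "ensemble.json"
    ensemble.to_json(ens_json)
    record("learn", {"ensemble": ens_json},
           n_filters=ensemble.n, best_mcc=best.mcc)

    # 3 — rank screening library, keep the focused set
    lib_spec = DescriptorSetSpec(**config.library, seed=config.seeds["library"])
    library = gen_descriptor_set(lib_spec)
    ranked = rank_library(library, ensemble)
    ranked_csv = workdir / "ranked.csv"
    import pandas as pd

    pd.DataFrame(
        {
            "id": [s.id for s in ranked],
            "mbi": [s.mbi for s in ranked],
            "n_passed": [s.n_passed for s in ranked],
            "rank": range(1, len(ranked) + 1),
        }
    ).to_csv(ranked_csv, index=False)
    focused = top_fraction_ids(ranked, config.top_fraction)
    focused_path = workdir / "focused.txt"
    focused_path.write_text("\n".join(focused) + "\n")
    labels = {m.id: m.label for m in library}
    n_focused_active = sum(labels[i] == "active" for i in focused)
    record("score", {"ranked": ranked_csv, "focused": focused_path},
           n_library=len(library), n_focused=len(focused),
           n_focused_active=n_focused_active)

    # 4 — poses for the focused actives + reference set, then triage
    site = default_site()
    pose_spec = PoseSetSpec(
        **{**config.poses, "n_active_compounds": n_focused_active},
        seed=config.seeds["poses"],
    )
    poses, truth = gen_pose_set(pose_spec, site)
    verdicts, clustering = triage_poses(poses, site, TriageConfig(**config.triage))
    verdict_csv = workdir / "verdicts.csv"
    verdict_table(verdicts).to_csv(verdict_csv, index=False)
    record("triage", {"verdicts": verdict_csv},
           n_poses=len(poses),
           centroids=clustering.centroids.tolist(),
           boundaries=clustering.boundaries.tolist())

    # 5 — sub-sampled enrichment of actives over the reference set
    act_v = [v for v in verdicts if v.compound_id.startswith("act")]
    ref_v = [v for v in verdicts if v.compound_id.startswith("ref")]
    subsample = config.subsample_size or len(ref_v)
    enr = subsampled_enrichment(
        act_v, ref_v, folds=config.folds,
        subsample_size=min(subsample, len(ref_v)),
        seed=config.seeds["subsample"],
    )
    enrich_json = workdir / "enrichment.json"
    enrich_json.write_text(
        json.dumps(
            {
                "frac_active_pass": enr.frac_active_pass,
                "frac_reference_pass": enr.frac_reference_pass,
                "enrichment_factor": enr.enrichment_factor,
                "fold_pass_mean": enr.fold_pass_mean,
                "fold_pass_std": enr.fold_pass_std,
                "n_folds": enr.n_folds,
            },
            indent=1,
        )
    )
    record("enrich", {"enrichment": enrich_json},
           enrichment_factor=enr.enrichment_factor)

    # 6 — consensus library
    pass_set = combined_filter(
        verdicts,
        ee_mode=config.triage.get("ee_mode", "two_lowest_clusters"),
        min_distance_score=config.triage.get("min_distance_score", 2),
    )
    # The i-th focused active (in MBI rank order) was docked under the
    # synthetic pose id act{i+1:05d}; carry the MBI ranking into that
    # namespace so consensus intersects the two stages coherently.
    from .mbi import MBIScore

    focused_active = [i for i in focused if labels[i] == "active"]
    rank_order = {i: r for r, i in enumerate(focused_active)}
    mbi_in_pose_ns = [
        MBIScore(id=f"act{rank_order[s.id]+1:05d}", mbi=s.mbi, n_passed=s.n_passed)
        for s in ranked
        if s.id in rank_order
    ]
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        consensus = consensus_select(
            mbi_in_pose_ns, pass_set, size=config.consensus_size
        )
    consensus_path = workdir / "consensus.txt"
    consensus_path.write_text("\n".join(consensus) + ("\n" if consensus else ""))
    record("consensus", {"consensus": consensus_path}, n_selected=len(consensus))

    manifest_path = workdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
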