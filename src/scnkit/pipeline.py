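"""End-to-end orchestration: tables -> group networks -> comparisons -> profiles -> clusters.

A single :class:`PipelineConfig` drives the whole analysis deterministically:
the master seed is expanded through ``numpy.random.SeedSequence`` into one
child seed per stochastic stage (simulation, each pairwise comparison,
clustering), all of which are recorded in the run manifest.  Every
intermediate artifact is written as labeled delimited text.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality_profile import CentralityProfileMatrix, build_profile_matrix
from .errors import ConfigError, ValidationError
from .network_compare import DifferenceNetwork, comparison_pairs, permutation_test, significant_region_union
from .node_clustering import ClusterResult, cluster, cluster_report
from .scn_build import GroupNetwork, build_group_networks
from .synthetic_cohort import EdgePerturbation, GroundTruth, SimulationConfig, generate_cohort
from .tabular_io import (
    ParticipantTable,
    ROIVolumeTable,
    read_participants,
    read_roi_volumes,
    write_matrix,
    write_participants,
    write_roi_volumes,
)

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "load_reference_profiles", "ReferenceProfiles"]

_REFERENCE_FILE = "eigencentrality_profiles_61x6.tsv"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the full analysis once, reproducibly."""

    seed: int
    participants_path: str | None = None
    volumes_path: str | None = None
    simulation: SimulationConfig | None = None
    covariates: tuple[str, ...] = ("age", "sex")
    alpha: float = 0.001
    n_perm: int = 10_000
    k_range: tuple[int, int] = (1, 10)
    n_init: int = 100
    out_dir: str | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha={self.alpha} outside (0, 1)")
        have_files = self.participants_path is not None and self.volumes_path is not None
        if have_files == (self.simulation is not None):
            raise ConfigError("provide either input table paths or a simulation config, not both")
        if self.k_range[0] < 1 or self.k_range[1] - self.k_range[0] < 2:
            raise ConfigError(f"k_range {self.k_range} must span at least 3 values starting at >= 1")

    @property
    def alpha_attainable(self) -> bool:
        return 1.0 / (self.n_perm + 1) < self.alpha

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            perts = tuple(EdgePerturbation(**p) for p in sim.pop("perturbations", []))
            block_rho = {
                (str(k.split("/")[0]), int(k.split("/")[1])): float(v)
                for k, v in sim.pop("block_rho", {}).items()
            }
            blocks = sim.pop("blocks", None)
            sim = SimulationConfig(
                perturbations=perts,
                block_rho=block_rho,
                blocks=None if blocks is None else tuple(tuple(b) for b in blocks),
                **sim,
            )
        for tup in ("covariates", "k_range"):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        return cls(simulation=sim, **raw)


@dataclass(frozen=True)
class ResultBundle:
    """All pipeline outputs plus the run manifest."""

    networks: Mapping[str, GroupNetwork]
    diffs: tuple[DifferenceNetwork, ...]
    region_union: tuple[str, ...]
    profiles: CentralityProfileMatrix
    clusters: ClusterResult
    report: pd.DataFrame
    manifest: dict
    participants: ParticipantTable
    volumes: ROIVolumeTable
    truth: GroundTruth | None = None


def _child_seeds(seed: int, n: int) -> list[int]:
    """Reproducible per-stage seeds derived from the master seed (all < 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    config.validate()
    t0 = time.perf_counter()
    manifest: dict = {
        "scnkit_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_perm": config.n_perm,
        "k_range": list(config.k_range),
        "n_init": config.n_init,
        "covariates": list(config.covariates),
        "stages": [],
        "warnings": [],
    }
    if not config.alpha_attainable:
        manifest["warnings"].append(
            f"alpha={config.alpha} unattainable at n_perm={config.n_perm} "
            f"(minimum p-value {1/(config.n_perm+1):.2g})"
        )

    def stage(name: str, started: float) -> None:
        manifest["stages"].append({"stage": name, "seconds": round(time.perf_counter() - started, 3)})

    truth = None
    t = time.perf_counter()
    if config.simulation is not None:
        sim_seed, cluster_seed, *pair_seed_pool = _child_seeds(config.seed, 2 + 64)
        sim_cfg = replace(config.simulation, seed=sim_seed)
        manifest["simulation_seed"] = sim_cfg.seed
        participants, volumes, truth = generate_cohort(sim_cfg)
        stage("simulate", t)
    else:
        _, cluster_seed, *pair_seed_pool = _child_seeds(config.seed, 2 + 64)
        participants = read_participants(config.participants_path)
        volumes = read_roi_volumes(config.volumes_path, participants)
        stage("load", t)

    t = time.perf_counter()
    networks = build_group_networks(participants, volumes, config.covariates)
    stage("build_networks", t)

    pairs = comparison_pairs(participants.groups)
    if len(pairs) > len(pair_seed_pool):
        raise ConfigError(f"too many groups ({len(pairs)} pairwise comparisons)")
    cov = participants.covariates(config.covariates) if config.covariates else None
    vals = volumes.values
    diffs = []
    pair_seeds = {}
    t = time.perf_counter()
    for (a, b), s in zip(pairs, pair_seed_pool):
        ia, ib = participants.group_indices(a), participants.group_indices(b)
        d = permutation_test(
            vals[ia],
            vals[ib],
            None if cov is None else cov[ia],
            None if cov is None else cov[ib],
            region_names=volumes.region_names,
            group_a=a,
            group_b=b,
            n_perm=config.n_perm,
            seed=s,
            alpha=config.alpha,
        )
        pair_seeds[d.pair] = s
        manifest["warnings"].extend(f"{d.pair}: {w}" for w in d.warnings)
        diffs.append(d)
    manifest["comparison_seeds"] = pair_seeds
    stage("compare", t)

    t = time.perf_counter()
    union = significant_region_union(diffs)
    if not union:
        raise ValidationError(
            "no significant regions in any pairwise comparison; nothing to profile "
            "(check alpha/n_perm attainability)"
        )
    profiles = build_profile_matrix(diffs, union)
    stage("profile", t)

    t = time.perf_counter()
    ks = range(config.k_range[0], config.k_range[1] + 1)
    manifest["cluster_seed"] = cluster_seed
    clusters = cluster(profiles, seed=cluster_seed, k_range=ks, n_init=config.n_init)
    report = cluster_report(clusters, profiles)
    stage("cluster", t)

    manifest["n_comparisons"] = len(diffs)
    manifest["n_significant_regions"] = len(union)
    manifest["selected_k"] = clusters.k
    manifest["total_seconds"] = round(time.perf_counter() - t0, 3)

    bundle = ResultBundle(
        networks=networks,
        diffs=tuple(diffs),
        region_union=tuple(union),
        profiles=profiles,
        clusters=clusters,
        report=report,
        manifest=manifest,
        participants=participants,
        volumes=volumes,
        truth=truth,
    )
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ResultBundle, out_dir: str | Path) -> None:
    """Write every artifact of a run as delimited text plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_participants(bundle.participants, out / "participants.tsv")
    write_roi_volumes(bundle.volumes, out / "roi_volumes.tsv")
    regions = bundle.volumes.region_names
    for g, net in bundle.networks.items():
        write_matrix(net.r, regions, regions, out / f"network_{g}.tsv")
    for d in bundle.diffs:
        write_matrix(d.delta_z, regions, regions, out / f"delta_z_{d.pair}.tsv")
        write_matrix(d.p_values, regions, regions, out / f"p_values_{d.pair}.tsv")
        write_matrix(d.mask.astype(float), regions, regions, out / f"mask_{d.pair}.tsv", precision=0)
    prof = bundle.profiles.to_frame().round(4)
    prof.to_csv(out / "centrality_profiles.tsv", sep="\t", index=False, float_format="%.4f")
    bundle.report.round(4).to_csv(out / "cluster_report.tsv", sep="\t", index=False, float_format="%.4f")
    curve = pd.DataFrame(
        sorted(bundle.clusters.inertia_curve.items()), columns=["k", "inertia"]
    )
    curve.to_csv(out / "inertia_curve.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# packaged reference profile matrix


@dataclass(frozen=True)
class ReferenceProfiles:
    """The packaged 61-region x 6-comparison reference eigencentrality matrix.

    Transcribed from the motivating transdiagnostic cohort study (HC / SCH /
    BD / MDD), with its published Average column and 4-cluster assignment.
    ``profiles.average`` is the recomputed row mean; ``printed_average`` is
    the column as published (the two can differ by up to one 4-dp rounding
    ulp because the source averaged unrounded values).
    """

    table: pd.DataFrame = field(repr=False)
    profiles: CentralityProfileMatrix
    cluster_labels: np.ndarray = field(repr=False)
    printed_average: np.ndarray = field(repr=False)


def load_reference_profiles() -> ReferenceProfiles:
    """Load the packaged reference matrix, verifying its checksum."""
    ref = resources.files("scnkit.data").joinpath(_REFERENCE_FILE)
    payload = ref.read_bytes()
    digest = hashlib.sha256(payload).hexdigest()
    expected = "c4798d9e83dd6aa841aa7df43291c98ab0da48ecfe3a38f967e30583d83de306"
    if digest != expected:
        raise ValidationError(
            f"packaged reference matrix is corrupted (sha256 {digest[:12]}... != {expected[:12]}...)"
        )
    df = pd.read_csv(ref, sep="\t")
    comparisons = tuple(df.columns[3:])
    values = df.iloc[:, 3:].to_numpy(dtype=float)
    profiles = CentralityProfileMatrix(
        region_names=tuple(df["region"]),
        comparisons=comparisons,
        values=values,
        average=values.mean(axis=1),
    )
    return ReferenceProfiles(
        table=df,
        profiles=profiles,
        cluster_labels=df["cluster"].to_numpy(dtype=int),
        printed_average=df["average"].to_numpy(dtype=float),
    )
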