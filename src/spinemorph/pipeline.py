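"""Pipeline orchestration: simulate -> (deconvolve) -> measure -> cluster -> compare.

Every run writes its outputs plus a ``manifest.json`` (config, config
hash, seed, package version, per-stage record) into a run directory, so a
fixed seed reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from spinemorph import __version__
from spinemorph import cluster as cl
from spinemorph import stats as st
from spinemorph import synth
from spinemorph.io import (
    NeuronDataset,
    read_annotations_json,
    write_annotations_json,
)
from spinemorph.morphometry import (
    DESCRIPTOR_NAMES,
    compute_descriptors,
    compute_width_profile,
)

logger = logging.getLogger("spinemorph")

__all__ = ["PipelineConfig", "run_pipeline", "measure_dataset"]


@dataclass
class PipelineConfig:
    """Flat pipeline configuration (YAML on disk; CLI flags override)."""

    out_dir: str = "run"
    annotations: str | None = None  # input JSON; None -> simulate
    seed: int = 0
    scale_nm: tuple[float, float, float] = (20.0, 20.0, 300.0)
    step_nm: float = 20.0
    resample_points: int = 100
    length_repeats: int = 75
    k_min: int = 2
    k_max: int = 8
    k_fixed: int | None = None
    alpha: float = 0.05
    shuffles: int = 1000
    skip_deconv: bool = True
    psf_fwhm_nm: float = 50.0
    reg: float | None = None
    # simulation settings (used when annotations is None)
    n_dendrites: int = 4
    spines_per_dendrite: int = 100
    mixtures: list[tuple[float, float, float, float]] | None = None

    def __post_init__(self) -> None:
        for name in ("step_nm", "resample_points", "length_repeats", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.resample_points != cl.N_PROFILE_DIMS or self.length_repeats != cl.N_LENGTH_DIMS:
            raise ValueError(
                "feature layout is fixed at 100 profile dims + 75 length repeats"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        if isinstance(cfg.scale_nm, list):
            cfg.scale_nm = tuple(cfg.scale_nm)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scale_nm"] = list(self.scale_nm)
        return d


@dataclass
class PipelineResult:
    run_dir: Path
    manifest: dict
    descriptors: pd.DataFrame
    labels: dict[str, int]
    stats: pd.DataFrame
    dataset: NeuronDataset = field(repr=False, default=None)


def measure_dataset(
    dataset: NeuronDataset, step_nm: float = 20.0
) -> tuple[list, pd.DataFrame, int]:
    """Profile + descriptors for every complete spine.

    Returns (profiles, descriptor frame indexed by spine_id, n_excluded).
    """
    profiles = []
    rows = []
    excluded = 0
    for _, _, ann in dataset.iter_spines():
        if not ann.complete:
            excluded += 1
            continue
        profile = compute_width_profile(ann, step_nm=step_nm)
        profiles.append(profile)
        rows.append(compute_descriptors(profile).to_dict())
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.set_index("spine_id")[list(DESCRIPTOR_NAMES)]
    return profiles, frame, excluded


def _default_mixtures(n: int) -> list[tuple[float, float, float, float]]:
    base = [
        (0.55, 0.25, 0.15, 0.05),
        (0.15, 0.55, 0.2, 0.1),
        (0.1, 0.15, 0.55, 0.2),
        (0.2, 0.1, 0.15, 0.55),
    ]
    return [base[i % 4] for i in range(n)]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "spinemorph_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": [],
    }

    # --- stage: simulate or load ----------------------------------------
    if config.annotations is None:
        mixtures = config.mixtures or _default_mixtures(config.n_dendrites)
        specs = [
            synth.DendriteSpec(
                neuron_id=f"n{1 + i // 4}",
                dendrite_id=f"n{1 + i // 4}d{i % 4}",
                mixture=tuple(mixtures[i]),
                n_spines=config.spines_per_dendrite,
            )
            for i in range(config.n_dendrites)
        ]
        dataset = synth.sample_dataset(
            synth.SyntheticConfig(
                dendrites=specs, seed=config.seed, scale_nm=config.scale_nm
            )
        )
        write_annotations_json(dataset, run_dir / "annotations.json")
        truth = synth.ground_truth_classes(dataset)
        pd.DataFrame(
            {"spine_id": list(truth), "true_class": list(truth.values())}
        ).to_csv(run_dir / "ground_truth.csv", index=False)
        manifest["stages"].append(
            {"stage": "simulate", "n_spines": len(truth)}
        )
        logger.info("simulate: %d spines on %d dendrites", len(truth), len(specs))
    else:
        dataset = read_annotations_json(config.annotations)
        manifest["stages"].append(
            {"stage": "load", "path": str(config.annotations)}
        )
    if not config.skip_deconv:
        # stack-based runs deconvolve images before manual segmentation; the
        # annotation-driven pipeline has no image stage to run.
        manifest["stages"].append({"stage": "deconvolve", "note": "no stack input"})

    # --- stage: measure ---------------------------------------------------
    try:
        profiles, descriptors, excluded = measure_dataset(dataset, config.step_nm)
    except Exception as exc:
        raise RuntimeError(f"stage measure failed: {exc}") from exc
    manifest["stages"].append(
        {"stage": "measure", "n_profiles": len(profiles), "n_excluded": excluded}
    )
    logger.info("measure: %d profiles, %d spines excluded", len(profiles), excluded)
    long = pd.concat(
        [
            pd.DataFrame(
                {"spine_id": p.spine_id, "s": p.s, "d": p.d, "region": p.region}
            )
            for p in profiles
        ],
        ignore_index=True,
    )
    long.to_csv(run_dir / "profiles.csv", index=False)

    # --- stage: cluster ---------------------------------------------------
    try:
        features = cl.build_feature_matrix(profiles)
        model = cl.fit_classes(
            features, k=config.k_fixed, k_range=(config.k_min, config.k_max)
        )
    except Exception as exc:
        raise RuntimeError(f"stage cluster failed: {exc}") from exc
    labels = model.labels_by_spine()
    manifest["stages"].append(
        {"stage": "cluster", "k": model.k,
         "length_scale_factor": model.length_scale_factor}
    )
    logger.info("cluster: k=%d from DB curve %s", model.k, model.db_curve)
    pd.DataFrame(
        {"spine_id": model.spine_ids, "class": model.labels}
    ).to_csv(run_dir / "labels.csv", index=False)
    pd.DataFrame(
        {"k": list(model.db_curve), "db_index": list(model.db_curve.values())}
    ).to_csv(run_dir / "db_curve.csv", index=False)
    P = np.vstack([cl.resample_profile(p) for p in profiles])
    L = np.array([p.length for p in profiles])
    means = cl.class_mean_profiles(P, L, model.labels)
    pd.DataFrame(
        {
            "class": np.repeat(list(means), cl.N_PROFILE_DIMS),
            "u": np.tile(np.linspace(0, 1, cl.N_PROFILE_DIMS), len(means)),
            "mean_diameter": np.concatenate([m for m, _ in means.values()]),
            "mean_length": np.repeat([l for _, l in means.values()],
                                     cl.N_PROFILE_DIMS),
        }
    ).to_csv(run_dir / "class_profiles.csv", index=False)

    # --- stage: compare ---------------------------------------------------
    try:
        stats_frame = _compare_stage(dataset, labels, descriptors, config, run_dir)
    except Exception as exc:
        raise RuntimeError(f"stage compare failed: {exc}") from exc
    manifest["stages"].append({"stage": "compare", "n_tests": len(stats_frame)})

    from spinemorph.io import write_results_tables

    write_results_tables(dataset, descriptors, labels, stats_frame, run_dir)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return PipelineResult(
        run_dir=run_dir,
        manifest=manifest,
        descriptors=descriptors,
        labels=labels,
        stats=stats_frame,
        dataset=dataset,
    )


def _compare_stage(
    dataset: NeuronDataset,
    labels: dict[str, int],
    descriptors: pd.DataFrame,
    config: PipelineConfig,
    run_dir: Path,
) -> pd.DataFrame:
    results: list[st.StatResult] = []
    table = st.class_count_table(dataset, labels)
    results.append(st.pearson_chi_square(table, comparison=("all_dendrites",)))
    neuron_ids = [n.neuron_id for n in dataset.neurons]
    for nid in neuron_ids:
        sub = st.class_count_table(dataset, labels, scope=nid)
        if len(sub.dendrite_ids) >= 2:
            results.append(st.pearson_chi_square(sub, comparison=(nid,)))
            results.extend(st.pairwise_dendrite_tests(sub, alpha=config.alpha))
    if len(table.dendrite_ids) >= 2:
        results.extend(st.pairwise_dendrite_tests(table, alpha=config.alpha))

    # descriptor-wise Kruskal-Wallis per neuron
    dendrite_of = {
        ann.spine_id: dendrite_id
        for _, dendrite_id, ann in dataset.iter_spines()
        if ann.complete
    }
    neuron_of = {
        ann.spine_id: neuron_id
        for neuron_id, _, ann in dataset.iter_spines()
        if ann.complete
    }
    for nid in neuron_ids:
        sids = [s for s in descriptors.index if neuron_of[s] == nid]
        dends = sorted({dendrite_of[s] for s in sids})
        if len(dends) < 2:
            continue
        for desc in DESCRIPTOR_NAMES:
            groups = {
                d: descriptors.loc[
                    [s for s in sids if dendrite_of[s] == d], desc
                ].to_numpy()
                for d in dends
            }
            try:
                omnibus, posthoc = st.kruskal_wallis_by_dendrite(
                    groups, comparison=(nid, desc)
                )
            except st.StatsError:
                continue
            results.append(omnibus)
            for r in posthoc:
                r.comparison = (nid, desc) + r.comparison
            results.extend(posthoc)

    frame = pd.DataFrame([r.to_dict() for r in results])
    frame.to_csv(run_dir / "stat_tests.csv", index=False)

    if config.shuffles > 0:
        summary = st.shuffle_control(
            dataset,
            labels,
            n_shuffles=config.shuffles,
            alpha=config.alpha,
            rng=np.random.default_rng(config.seed + 1),
            descriptors=descriptors,
        )
        pd.DataFrame(
            {
                "family": list(summary.rejection_fraction),
                "rejection_fraction": list(summary.rejection_fraction.values()),
                "n_shuffles": summary.n_shuffles,
                "alpha": summary.alpha,
            }
        ).to_csv(run_dir / "shuffle_summary.csv", index=False)
    return frame
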