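"""Pipeline configuration, stage orchestration and provenance.

A single YAML config holds per-stage parameter blocks and one global seed;
every stochastic stage receives a seed derived deterministically from it.
Stages communicate only through files in the artifact directory, never
mutate upstream artifacts, and a manifest records inputs, outputs, seeds,
durations and the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, DependencyError

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

DEFAULTS: dict = {
    "seed": 0,
    "geometry": {"n": 64},
    "simulate": {
        "kind": "melting",  # melting | zoo
        "n_averages": 200,
        "n_frames": 0,  # photon frames are optional
        "total_photons": 3.0e6,
        "n_morphs": 30,
    },
    "classify": {"n_runs": 1, "n_classes": 10, "subset_fraction": 0.8, "n_iterations": 10,
                 "n_inplane_rotations": 16},
    "clpca": {"n_angular": 180, "n_components": 3},
    "embednet": {"train_fraction": 0.8, "max_iter": 300},
    "refmatch": {"grid_level": 8, "symmetry": "O"},
    "vae": {"latent_dim": 1, "epochs": 200, "beta": 1.0, "batch_size": 100,
            "volume_n": 51, "volume_fov_nm": 130.0, "downsample": 2},
    "phasing": {"z_grid": 12, "support_nm": 56.0, "threshold_fraction": 1e-4,
                "n_dm": 100, "n_er": 50, "n_restarts": 2, "dither": 1},
}


@dataclass
class PipelineConfig:
    """Per-stage parameter blocks plus a global seed."""

    blocks: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
        for k, v in self.blocks.items():
            if isinstance(v, dict) and isinstance(merged.get(k), dict):
                merged[k].update(v)
            else:
                merged[k] = v
        self.blocks = merged

    def __getitem__(self, key):
        return self.blocks[key]

    @property
    def seed(self) -> int:
        return int(self.blocks["seed"])

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.blocks, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(blocks=data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.blocks, f, sort_keys=True)


def _geometry(cfg: PipelineConfig):
    from .geometry import make_geometry

    return make_geometry(**cfg["geometry"])


def _stage_simulate(cfg: PipelineConfig, art: Path) -> list[str]:
    from . import datasets, io

    geom = _geometry(cfg)
    block = cfg["simulate"]
    seed = cfg.stage_seed("simulate")
    outputs = []
    if block["kind"] == "melting":
        avgs, truth = datasets.melting_series_averages(
            block["n_averages"], geom, seed,
            n_morphs=block["n_morphs"], total_photons=block["total_photons"],
        )
        extra = {"morph": truth["morph"], "quat": truth["quat"]}
    else:
        avgs, labels, truth = datasets.shape_zoo_averages(
            block["n_averages"] // 4, geom, seed, total_photons=block["total_photons"]
        )
        extra = {"label": labels, "quat": truth["quat"]}
    io.write_averages(art / "averages.h5", avgs, extra=extra)
    outputs.append("averages.h5")
    if block.get("n_frames"):
        frames = datasets.planted_frames(block["n_frames"], geom, seed + 1)
        io.write_photons(art / "photons.h5", frames)
        outputs.append("photons.h5")
    return outputs


def _stage_classify(cfg: PipelineConfig, art: Path) -> list[str]:
    from . import classify2d, io

    if not (art / "photons.h5").exists():
        raise DependencyError("classify needs photons.h5 from the simulate stage")
    frames = io.read_photons(art / "photons.h5")
    block = cfg["classify"]
    ens = classify2d.bootstrap_classify(
        frames, block["n_runs"], block["n_classes"],
        subset_fraction=block["subset_fraction"], seed=cfg.stage_seed("classify"),
        n_iterations=block["n_iterations"],
        n_inplane_rotations=block["n_inplane_rotations"],
    )
    io.write_averages(art / "emc_averages.h5", ens.averages,
                      extra={"run_index": ens.run_index, "run_seeds": ens.run_seeds})
    return ["emc_averages.h5"]


def _stage_clpca(cfg: PipelineConfig, art: Path) -> list[str]:
    from . import clpca, io

    if not (art / "averages.h5").exists():
        raise DependencyError("clpca needs averages.h5 from the simulate stage")
    geom = _geometry(cfg)
    avgs, _ = io.read_averages(art / "averages.h5")
    block = cfg["clpca"]
    polars = [clpca.to_polar(a.intensity, geom, n_angular=block["n_angular"]) for a in avgs]
    mat = clpca.similarity_matrix(polars)
    emb = clpca.embed(mat, n_components=block["n_components"])
    io.write_similarity(art / "similarity.h5", mat)
    io.write_embedding(art / "embedding.h5", emb)
    return ["similarity.h5", "embedding.h5"]


def _stage_embednet(cfg: PipelineConfig, art: Path) -> list[str]:
    from . import embednet, io

    for need in ("averages.h5", "embedding.h5"):
        if not (art / need).exists():
            raise DependencyError(f"embednet needs {need} (run simulate and clpca first)")
    geom = _geometry(cfg)
    avgs, _ = io.read_averages(art / "averages.h5")
    emb = io.read_embedding(art / "embedding.h5")
    extractor = embednet.FeatureExtractor(n_radial=min(geom.shape) // 2, n_angular=180)
    feats = np.stack([embednet.extract_features(a, geom, extractor=extractor) for a in avgs])
    n = len(avgs)
    n_train = int(cfg["embednet"]["train_fraction"] * n)
    model = embednet.train_regressor(
        feats, emb, extractor, split=(n_train, n - n_train),
        seed=cfg.stage_seed("embednet"), max_iter=cfg["embednet"]["max_iter"],
    )
    np.save(art / "embednet_val_mse.npy", model.validation_mse)
    return ["embednet_val_mse.npy"]


def _stage_refmatch(cfg: PipelineConfig, art: Path) -> list[str]:
    from . import io, refmatch, simulate

    if not (art / "averages.h5").exists():
        raise DependencyError("refmatch needs averages.h5 from the simulate stage")
    geom = _geometry(cfg)
    avgs, _ = io.read_averages(art / "averages.h5")
    block = cfg["refmatch"]
    grid = refmatch.build_quaternion_grid(block["grid_level"], block["symmetry"])
    ref = simulate.reference_cube_volume(geometry=geom)
    io.write_mrc(art / "reference_cube.mrc", ref)
    est = refmatch.estimate_orientations(avgs, ref, grid, geom)
    io.write_orientations(art / "orientations.h5", est)
    return ["reference_cube.mrc", "orientations.h5"]


def _stage_vae(cfg: PipelineConfig, art: Path) -> list[str]:
    import pickle

    from . import io, vae

    for need in ("averages.h5", "orientations.h5"):
        if not (art / need).exists():
            raise DependencyError(f"vae needs {need} (run simulate and refmatch first)")
    geom = _geometry(cfg)
    avgs, _ = io.read_averages(art / "averages.h5")
    ests = io.read_orientations(art / "orientations.h5")
    block = cfg["vae"]
    inputs, pre = vae.preprocess(avgs, geom, ests, downsample=block["downsample"])
    model = vae.train(
        inputs, pre, latent_dim=block["latent_dim"], epochs=block["epochs"],
        beta=block["beta"], seed=cfg.stage_seed("vae"),
        batch_size=block["batch_size"], volume_n=block["volume_n"],
        volume_fov_nm=block["volume_fov_nm"],
    )
    with open(art / "vae_model.pkl", "wb") as f:
        pickle.dump(model, f)
    np.save(art / "latent_mu.npy", model.train_mu)
    return ["vae_model.pkl", "latent_mu.npy"]


def _stage_phasing(cfg: PipelineConfig, art: Path) -> list[str]:
    import pickle

    from . import phasing

    if not (art / "vae_model.pkl").exists():
        raise DependencyError("phasing needs vae_model.pkl from the vae stage")
    with open(art / "vae_model.pkl", "rb") as f:
        model = pickle.load(f)
    block = cfg["phasing"]
    voxel_nm = 2.0 * np.pi / (model.volume_voxel_q * model.volume_n)
    half_px = int(round(block["support_nm"] / 2.0 / voxel_nm))
    curve = phasing.volume_vs_z(
        model, block["z_grid"], half_px,
        threshold_fraction=block["threshold_fraction"], n_dm=block["n_dm"],
        n_er=block["n_er"], n_restarts=block["n_restarts"],
        seed=cfg.stage_seed("phasing"), dither=block["dither"],
    )
    table = np.array([[r["z"][0], r["volume_nm3"], r["error"], r["low_confidence"]] for r in curve])
    np.savetxt(art / "volume_curve.csv", table, delimiter=",",
               header="z,volume_nm3,residual,low_confidence", comments="")
    return ["volume_curve.csv"]


STAGES = {
    "simulate": (_stage_simulate, []),
    "classify": (_stage_classify, ["simulate"]),
    "clpca": (_stage_clpca, ["simulate"]),
    "embednet": (_stage_embednet, ["clpca"]),
    "refmatch": (_stage_refmatch, ["simulate"]),
    "vae": (_stage_vae, ["refmatch"]),
    "phasing": (_stage_phasing, ["vae"]),
}


def run_pipeline(
    config: PipelineConfig, stages: list[str], out_dir: str | Path
) -> dict:
    """Run an ordered subset of stages, writing artifacts and a manifest."""
    art = Path(out_dir)
    art.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stages": [],
    }
    for stage in stages:
        if stage not in STAGES:
            raise ConfigurationError(f"unknown stage {stage!r}")
        fn, _ = STAGES[stage]
        t0 = time.time()
        log.info("running stage %s", stage)
        outputs = fn(config, art)
        hashes = {}
        for name in outputs:
            p = art / name
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        manifest["stages"].append(
            {
                "name": stage,
                "seed": config.stage_seed(stage),
                "outputs": hashes,
                "duration_s": round(time.time() - t0, 3),
            }
        )
    with open(art / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
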