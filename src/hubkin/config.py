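"""Run and simulation configuration objects shared across the package.

All physical coordinates in this package are continuous and expressed in
micrometres (μm), with the origin at the corner of the image stack; voxel
indices are 0-based and convert through (``pixel_size``, ``voxel_z``).
Time is indexed by 0-based frame; physical time = frame × ``frame_interval``.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["SimConfig", "RunConfig", "rng_for"]


@dataclass(frozen=True)
class SimConfig:
    """Geometry, cadence and noise settings for synthetic data generation.

    Parameters
    ----------
    seed
        Master seed; identical (seed, config) pairs produce bit-identical
        output.
    frame_interval
        Time between frames / volume stacks, in seconds.
    n_frames
        Number of frames (time points) to generate.
    pixel_size
        Lateral (x, y) voxel size in μm.
    voxel_z
        Axial voxel size in μm.
    image_shape
        Stack shape in voxels, ordered (z, y, x).
    background_level
        Mean background photon count outside nuclei.
    noise_model
        ``"none"``, ``"poisson"``, or ``"gaussian"`` (uses
        ``gaussian_sigma``).
    """

    seed: int = 0
    frame_interval: float = 0.5
    n_frames: int = 100
    pixel_size: float = 0.108
    voxel_z: float = 0.3
    image_shape: tuple[int, int, int] = (16, 64, 64)
    background_level: float = 20.0
    noise_model: str = "none"
    gaussian_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.pixel_size <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    # -- unit conversions -------------------------------------------------
    @property
    def voxel_sizes_um(self) -> np.ndarray:
        """Voxel sizes as an array ordered (z, y, x), in μm."""
        return np.array([self.voxel_z, self.pixel_size, self.pixel_size])

    def um_to_voxel(self, zyx_um: np.ndarray) -> np.ndarray:
        """Continuous μm coordinates (z, y, x) → fractional voxel indices."""
        return np.asarray(zyx_um, dtype=float) / self.voxel_sizes_um

    def voxel_to_um(self, zyx_vox: np.ndarray) -> np.ndarray:
        """Voxel indices (z, y, x) → μm coordinates of the voxel centre."""
        return np.asarray(zyx_vox, dtype=float) * self.voxel_sizes_um

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG for a named stream.

    Every stochastic step in the package draws from a stream derived from the
    master seed and a stable string label, so stages can be re-run
    independently without perturbing each other's randomness.
    """
    key = zlib.crc32(stream.encode("utf-8"))
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF, spawn_key=(key,))
    return np.random.default_rng(ss)


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    Holds the master seed, IO paths, condition/replicate labels and
    per-module parameter overrides; serialized as JSON/YAML into every output
    directory so a run can be reproduced from its artefacts alone.
    """

    seed: int = 0
    out_dir: str = "hubkin_out"
    stages: tuple[str, ...] = ("simulate", "smt", "hubs", "locus")
    condition: str = "synthetic"
    replicate: str = "rep1"
    sim: SimConfig = field(default_factory=SimConfig)
    params: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        # out_dir is deliberately omitted: artefact identity must not depend
        # on where a run was written
        return {
            "seed": self.seed,
            "stages": list(self.stages),
            "condition": self.condition,
            "replicate": self.replicate,
            "sim": self.sim.to_dict(),
            "params": dict(self.params),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", None)
        if sim is not None:
            sim = dict(sim)
            if "image_shape" in sim:
                sim["image_shape"] = tuple(sim["image_shape"])
            d["sim"] = SimConfig(**sim)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
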