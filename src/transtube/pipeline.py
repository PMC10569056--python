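"""End-to-end workflow: minimize → NEB → control points → TTS → QbC.

A single :class:`RunConfig` drives the whole chain; one global seed fans
out deterministically to named per-stage random streams, so a run is
bitwise reproducible from its config file alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .calculators import Calculator, HarmonicND, ReplayCalculator, Toy2D, relax
from .constants import CONSTANTS
from .geometry import Geometry
from .harmonic import ThermalSpec
from .mep import fit_mep_spline, neb_optimize
from .qbc import CommitteeSpec, KernelRidgeModel, qbc_run
from .tts import build_control_points, tts_generate


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


_ALLOWED_KEYS = {
    "seed", "outdir", "calculator",
    "minimize", "neb", "control_xi", "tts", "qbc",
}
_ALLOWED_SUBKEYS = {
    "minimize": {"start", "end", "f_tol"},
    "neb": {"n_images", "spring_k", "climbing", "f_tol", "max_steps"},
    "tts": {"temperature", "statistics", "linear_density", "n_zero_expected"},
    "qbc": {
        "n_members", "training_fraction", "n_init", "n_iter", "k_per_iter",
        "stop_ratio", "atom_mask", "features",
    },
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "transtube_run"
    calculator: str = "toy2d"
    minimize: dict = field(default_factory=dict)
    neb: dict = field(default_factory=dict)
    control_xi: list = field(default_factory=lambda: [0.0, 0.5, 1.0])
    tts: dict = field(default_factory=dict)
    qbc: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _ALLOWED_SUBKEYS.items():
            sub = data.get(section, {})
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def resolved(self) -> dict:
        """Fully resolved config (with defaults) for the run echo."""
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "calculator": self.calculator,
            "minimize": {"f_tol": 1e-6, **self.minimize},
            "neb": {
                "n_images": 15, "spring_k": 4.86, "climbing": True,
                "f_tol": 1e-4, "max_steps": 20000, **self.neb,
            },
            "control_xi": list(self.control_xi),
            "tts": {
                "temperature": 300.0, "statistics": "classical",
                "linear_density": 200.0, **self.tts,
            },
            "qbc": {
                "n_members": 4, "training_fraction": 0.9, "n_init": 20,
                "n_iter": 5, "k_per_iter": 10, "stop_ratio": None,
                "atom_mask": None, "features": "cartesian", **self.qbc,
            },
            "constants": {k: float(v) for k, v in CONSTANTS.items()},
        }


def resolve_calculator(spec: str) -> Calculator:
    """Build a calculator from a config string.

    ``toy2d``, ``replay:<extxyz file>`` or ``harmonic:<minimum
    extxyz>:<hessian file>``.
    """
    if spec == "toy2d":
        return Toy2D()
    if spec.startswith("replay:"):
        return ReplayCalculator(io.read_geometries(spec.split(":", 1)[1]))
    if spec.startswith("harmonic:"):
        _, min_path, h_path = spec.split(":", 2)
        minimum = io.read_geometries(min_path)[0]
        return HarmonicND(minimum, io.read_hessian(h_path, minimum.n_atoms))
    raise ValueError(f"unknown calculator spec {spec!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow, persisting artifacts under ``outdir``.

    Returns a dict of artifact paths plus the in-memory results.  Any
    stage failure aborts with the stage name; artifacts produced up to
    that point remain on disk.
    """
    cfg = config.resolved()
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))

    calc = resolve_calculator(cfg["calculator"])
    stage = "minimize"
    try:
        mopts = cfg["minimize"]
        if calc.n_atoms == 1 and "start" not in mopts:
            # sensible default demo on the 2D model potential
            (ax, ay), (bx, by) = Toy2D.MINIMA
            start_guess = Geometry(["X"], [[ax, ay, 0.0]])
            end_guess = Geometry(["X"], [[bx, by, 0.0]])
        else:
            start_guess = Geometry(
                ["X"] * len(mopts["start"]), mopts["start"]
            )
            end_guess = Geometry(["X"] * len(mopts["end"]), mopts["end"])
        start = relax(calc, start_guess, f_tol=mopts["f_tol"])
        end = relax(calc, end_guess, f_tol=mopts["f_tol"])

        stage = "neb"
        nopts = cfg["neb"]
        band = neb_optimize(
            calc, start, end,
            n_images=nopts["n_images"], spring_k=nopts["spring_k"],
            climbing=nopts["climbing"], f_tol=nopts["f_tol"],
            max_steps=nopts["max_steps"],
        )
        io.write_geometries(band.frames, outdir / "mep.extxyz")
        mep = fit_mep_spline(band)

        stage = "tts"
        topts = cfg["tts"]
        thermal = ThermalSpec(topts["temperature"], topts["statistics"])
        control_points = build_control_points(
            mep, cfg["control_xi"], calc,
            n_zero_expected=topts.get("n_zero_expected"),
        )
        candidates = tts_generate(
            mep, cfg["control_xi"], calc, thermal,
            topts["linear_density"],
            seed=derive_seed(cfg["seed"], "tts"),
            control_points=control_points,
        )
        io.write_candidates(candidates, outdir / "candidates.extxyz")

        stage = "qbc"
        qopts = cfg["qbc"]
        spec = CommitteeSpec(
            model_factory=lambda s: KernelRidgeModel(
                seed=s, features=qopts["features"]
            ),
            n_members=qopts["n_members"],
            training_fraction=qopts["training_fraction"],
            seed=derive_seed(cfg["seed"], "qbc-committee"),
        )
        training = qbc_run(
            candidates, calc, spec,
            n_init=qopts["n_init"], n_iter=qopts["n_iter"],
            k_per_iter=qopts["k_per_iter"],
            seed=derive_seed(cfg["seed"], "qbc-init"),
            stopping=qopts["stop_ratio"],
            atom_mask=qopts["atom_mask"],
        )
        io.write_geometries(list(training), outdir / "training.extxyz")
        log_lines = [
            " ".join(f"{k}={v}" for k, v in entry.items())
            for entry in training.log
        ]
        (outdir / "qbc.log").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    return {
        "outdir": outdir,
        "mep": band,
        "continuous_mep": mep,
        "candidates": candidates,
        "training": training,
        "artifacts": {
            "config": outdir / "config.yaml",
            "mep": outdir / "mep.extxyz",
            "candidates": outdir / "candidates.extxyz",
            "training": outdir / "training.extxyz",
            "log": outdir / "qbc.log",
        },
    }
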