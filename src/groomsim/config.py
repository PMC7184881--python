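"""Flat key-value config parsing for the command-line interface."""

from __future__ import annotations

from typing import Mapping

from .bouts import BoutDurationModel, EmpiricalBoutModel, LogNormalBoutModel
from .dust_model import BODY_PARTS, DustState, ModelParams
from .synthetic import SynthSpec, constant_bias, logistic_bias

__all__ = ["model_params_from_config", "synth_spec_from_config"]


def _bout_model_from_config(cfg: Mapping[str, str]) -> BoutDurationModel:
    kind = cfg.get("bout_model.type", "lognormal")
    if kind == "lognormal":
        medians = {
            k[len("bout_model.median_s."):]: float(v)
            for k, v in cfg.items()
            if k.startswith("bout_model.median_s.")
        }
        return LogNormalBoutModel(
            medians_s=medians,
            sigma=float(cfg.get("bout_model.sigma", 0.6)),
        )
    if kind == "empirical":
        durations = {
            k[len("bout_model.durations."):]: [int(x) for x in v.split(",")]
            for k, v in cfg.items()
            if k.startswith("bout_model.durations.")
        }
        return EmpiricalBoutModel(durations)
    raise ValueError(f"unknown bout_model.type: {kind!r}")


def model_params_from_config(cfg: Mapping[str, str]) -> ModelParams:
    """Build simulator parameters from a flat key-value mapping.

    Recognized keys: ``initial_dust.<part>``, ``dr``, ``noise_divisor``,
    ``run_frames``, ``frame_rate_hz``, ``seed``, ``bout_model.*``.
    """
    known_prefixes = ("initial_dust.", "bout_model.", "alias.")
    known = {"dr", "noise_divisor", "run_frames", "frame_rate_hz", "seed"}
    for key in cfg:
        if key not in known and not key.startswith(known_prefixes):
            raise ValueError(f"unknown config key: {key!r}")
    dust = {
        p: float(cfg.get(f"initial_dust.{p}", 0.0))
        for p in BODY_PARTS
    }
    return ModelParams(
        initial_dust=DustState.from_mapping(dust),
        dr=float(cfg.get("dr", 0.002)),
        noise_divisor=float(cfg.get("noise_divisor", 5.0)),
        run_frames=int(cfg.get("run_frames", 50_000)),
        frame_rate_hz=float(cfg.get("frame_rate_hz", 30.0)),
        seed=int(cfg.get("seed", 0)),
        bout_model=_bout_model_from_config(cfg),
    )


def synth_spec_from_config(cfg: Mapping[str, str]) -> SynthSpec:
    """Build a synthetic-cohort spec from a flat key-value mapping.

    ``bias.type`` is ``constant`` (with ``bias.c``) or ``logistic`` (with
    ``bias.t0_s`` and ``bias.k_per_s``).
    """
    kind = cfg.get("bias.type", "constant")
    if kind == "constant":
        bias = constant_bias(float(cfg.get("bias.c", 0.5)))
    elif kind == "logistic":
        bias = logistic_bias(
            float(cfg.get("bias.t0_s", 400.0)),
            float(cfg.get("bias.k_per_s", 0.02)),
        )
    else:
        raise ValueError(f"unknown bias.type: {kind!r}")
    return SynthSpec(
        n_flies=int(cfg.get("n_flies", 10)),
        run_frames=int(cfg.get("run_frames", 50_000)),
        frame_rate_hz=float(cfg.get("frame_rate_hz", 30.0)),
        anterior_bias=bias,
        grooming_fraction=float(cfg.get("grooming_fraction", 0.9)),
        alternation_p=float(cfg.get("alternation_p", 0.8)),
        bout_model=_bout_model_from_config(cfg),
        seed=int(cfg.get("seed", 0)),
    )
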