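"""Experiment configuration: YAML schema, validation and orchestration.

An experiment file has up to five sections — ``network``, ``integration``,
``stimulus``, ``learning``, ``microcircuit`` — plus a ``name`` and a
``seed``.  Unknown keys are rejected, and every error names the offending
field path.  ``run_experiment`` executes the described experiment and writes
a trajectory file, metric CSVs, a config snapshot and a JSON summary, all
reproducible from the snapshot plus the seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .microcircuit import loop_alignment_angle, make_microcircuit, train_microcircuit
from .network import (
    Activation,
    StimulusTrace,
    make_layered_params,
    make_recurrent_params,
    simulate,
)
from .plasticity import LearningConfig, train_online
from .synthetic import (
    GeneratorConfig,
    add_bias_channel,
    gen_pattern_task,
    gen_sinusoid,
    gen_smooth_mix,
    gen_surrogate_field_traces,
    gen_teacher_targets,
)

__all__ = ["ExperimentSpec", "validate_config", "run_experiment", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid experiment configurations, with field paths."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NetworkSection(_Strict):
    kind: Literal["layered", "recurrent"] = "layered"
    sizes: Optional[list[int]] = None          # layered: [n_in, n_1, ..., n_out]
    n: Optional[int] = None                    # recurrent: network size
    n_in: int = 0
    n_out: Optional[int] = None
    tau: float = Field(10.0, gt=0, description="membrane time constant, ms")
    activation: Literal["logistic", "hard_sigmoid", "threshold_linear", "linear"] = "logistic"
    weight_sd: float = Field(0.1, ge=0)
    weight_clip: float = Field(0.3, gt=0)
    bias: bool = False


class IntegrationSection(_Strict):
    integrator: Literal["implicit", "explicit", "no_lookahead"] = "implicit"
    dt: float = Field(1.0, gt=0, description="Euler step, ms")
    warmup_tau: float = Field(10.0, ge=0)
    record_every: int = Field(1, ge=1)


class StimulusSection(_Strict):
    generator: Literal["sinusoid", "smooth_mix", "patterns", "teacher", "fields"] = "smooth_mix"
    duration: float = Field(1000.0, gt=0, description="ms (pattern tasks derive it)")
    beta: float = Field(0.0, ge=0, description="output nudging strength")
    # sinusoid / smooth_mix
    freq: float = 5.0
    amplitude: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.0
    n_channels: int = 1
    # patterns
    n_classes: int = 10
    input_dim: int = 64
    presentation_ms: float = 5.0
    n_samples: int = 100
    target_hi: float = 1.0
    target_lo: float = 0.0
    # teacher
    teacher_sizes: Optional[list[int]] = None
    teacher_weight_sd: float = 1.0
    # fields
    corr_length_ms: float = 100.0
    latent_rank: int = 3


class LearningSection(_Strict):
    eta: float = Field(1e-3, ge=0)
    eta_schedule: Optional[list[tuple[float, float]]] = None
    plasticity_on: bool = True
    update_cadence: int = Field(1, ge=1)


class MicrocircuitSection(_Strict):
    n_interneurons: list[int]
    beta_I: float = Field(0.0, ge=0, lt=1)
    eta_IP: float = Field(1e-3, ge=0)
    eta_PI: float = Field(1e-3, ge=0)
    lateral_sd: float = 0.01
    lateral_clip: float = 0.03
    eta_forward: float = Field(0.0, ge=0)


class ExperimentSpec(_Strict):
    name: str = "experiment"
    seed: int = 0
    network: NetworkSection = NetworkSection()
    integration: IntegrationSection = IntegrationSection()
    stimulus: StimulusSection = StimulusSection()
    learning: Optional[LearningSection] = None
    microcircuit: Optional[MicrocircuitSection] = None


def validate_config(text: str) -> ExperimentSpec:
    """Parse and validate a YAML experiment description.

    Raises :class:`ConfigError` listing every invalid or unknown field with
    its dotted path.
    """
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    try:
        return ExperimentSpec.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            path = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{path}: {err['msg']}")
        raise ConfigError("invalid experiment config:\n  " + "\n  ".join(lines)) from exc


def _build_network(spec: ExperimentSpec, rng: np.random.Generator):
    net = spec.network
    if net.kind == "layered":
        if not net.sizes or len(net.sizes) < 2:
            raise ConfigError("network.sizes: layered networks need at least [n_in, n_out]")
        return make_layered_params(rng, net.sizes, tau=net.tau,
                                   weight_sd=net.weight_sd,
                                   weight_clip=net.weight_clip, bias=net.bias)
    if net.n is None or net.n_out is None:
        raise ConfigError("network.n / network.n_out: required for recurrent networks")
    return make_recurrent_params(rng, net.n, net.n_in, net.n_out, tau=net.tau,
                                 weight_sd=net.weight_sd, weight_clip=net.weight_clip)


def build_stimulus(spec: ExperimentSpec, params=None, act=None) -> StimulusTrace:
    """Instantiate the stimulus a spec describes (teacher nets built on demand)."""
    s = spec.stimulus
    cfg = GeneratorConfig(seed=spec.seed + 1, dt=spec.integration.dt,
                          duration=s.duration)
    if s.generator == "sinusoid":
        stim = gen_sinusoid(s.freq, s.amplitude, s.offset, s.noise_sd, cfg,
                            n_channels=s.n_channels)
    elif s.generator == "smooth_mix":
        stim = gen_smooth_mix(cfg, n_channels=s.n_channels,
                              amplitude=s.amplitude, offset=s.offset)
    elif s.generator == "patterns":
        task = gen_pattern_task(s.n_classes, s.input_dim, s.presentation_ms,
                                s.n_samples, s.noise_sd, cfg,
                                s.target_hi, s.target_lo, beta=s.beta)
        stim = task.stimulus
    elif s.generator == "teacher":
        if s.teacher_sizes is None:
            raise ConfigError("stimulus.teacher_sizes: required for the teacher generator")
        t_rng = np.random.default_rng(spec.seed + 2)
        teacher = make_layered_params(t_rng, s.teacher_sizes,
                                      tau=spec.network.tau,
                                      weight_sd=s.teacher_weight_sd,
                                      weight_clip=3 * s.teacher_weight_sd)
        base = gen_smooth_mix(cfg, n_channels=s.teacher_sizes[0],
                              amplitude=s.amplitude, offset=s.offset)
        stim = gen_teacher_targets(teacher, act or Activation("logistic"),
                                   base.r_in, cfg.dt, beta=s.beta)
    else:
        data = gen_surrogate_field_traces(s.n_channels, s.corr_length_ms, cfg,
                                          latent_rank=s.latent_rank, beta=s.beta)
        stim = data.train
    if s.beta and stim.u_star.size:
        stim = StimulusTrace(stim.r_in, stim.u_star, stim.dt, beta=s.beta,
                             nudge_mask=stim.nudge_mask)
    if spec.network.bias:
        stim = add_bias_channel(stim)
    return stim


def run_experiment(spec: ExperimentSpec, out_dir) -> dict:
    """Execute a validated experiment spec and write its results bundle.

    Writes ``trajectory.npz``, ``metrics.csv``, ``config.yaml`` (snapshot)
    and ``summary.json``; returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    act = Activation(spec.network.activation)
    params = _build_network(spec, rng)
    stim = build_stimulus(spec, params, act)
    if stim.u_star.size and stim.u_star.shape[1] != len(params.output_indices):
        raise ConfigError(
            f"stimulus: target width {stim.u_star.shape[1]} does not match the "
            f"network's {len(params.output_indices)} output neurons"
        )
    if stim.r_in.shape[1] != params.n_in:
        raise ConfigError(
            f"stimulus: input width {stim.r_in.shape[1]} does not match the "
            f"network's {params.n_in} input channels"
        )
    integ = spec.integration
    summary: dict = {"name": spec.name, "seed": spec.seed}
    if spec.microcircuit is not None:
        mcs = spec.microcircuit
        mc = make_microcircuit(np.random.default_rng(spec.seed + 3), params,
                               mcs.n_interneurons, beta_I=mcs.beta_I,
                               eta_IP=mcs.eta_IP, eta_PI=mcs.eta_PI,
                               lateral_sd=mcs.lateral_sd,
                               lateral_clip=mcs.lateral_clip)
        p2, mc2, log = train_microcircuit(params, act, mc, stim,
                                          eta_forward=mcs.eta_forward,
                                          integrator=integ.integrator
                                          if integ.integrator != "no_lookahead"
                                          else "explicit",
                                          warmup_tau=integ.warmup_tau,
                                          record_every=integ.record_every)
        np.savez(out / "trajectory.npz", t=log.t, angles=log.angles,
                 E_IP=log.E_IP, E_PI=log.E_PI, C=log.C)
        _write_csv(out / "metrics.csv",
                   {"t": log.t, **{f"angle_l{i}": log.angles[:, i]
                                   for i in range(log.angles.shape[1])},
                    "E_IP": log.E_IP, "E_PI": log.E_PI, "C": log.C})
        summary["final_alignment_angles_deg"] = [float(a) for a in log.angles[-1]]
        summary["final_E_IP"] = float(log.E_IP[-1])
        summary["final_E_PI"] = float(log.E_PI[-1])
    elif spec.learning is not None:
        lc = LearningConfig(eta=spec.learning.eta,
                            eta_schedule=spec.learning.eta_schedule,
                            plasticity_on=spec.learning.plasticity_on,
                            update_cadence=spec.learning.update_cadence)
        p2, rec = train_online(params, act, stim, lc,
                               integrator=integ.integrator,
                               warmup_tau=integ.warmup_tau,
                               record_every=integ.record_every)
        rec.save(out / "trajectory.npz")
        np.savez(out / "weights.npz", W_in=p2.W_in, W_net=p2.W_net)
        _write_csv(out / "metrics.csv", {"t": rec.t, "L": rec.L, "E_M": rec.E_M,
                                         "C": rec.C, "residual": rec.residual})
        summary["final_cost"] = float(rec.C[-1]) if len(rec.C) else None
        summary["mean_final_cost"] = float(rec.C[-max(1, len(rec.C) // 10):].mean())
        summary["max_residual"] = float(rec.residual.max())
    else:
        rec = simulate(params, act, stim, integrator=integ.integrator,
                       warmup_tau=integ.warmup_tau,
                       record_every=integ.record_every)
        rec.save(out / "trajectory.npz")
        _write_csv(out / "metrics.csv", {"t": rec.t, "L": rec.L, "E_M": rec.E_M,
                                         "C": rec.C, "residual": rec.residual})
        summary["max_residual"] = float(rec.residual.max())
        summary["final_L"] = float(rec.L[-1])
    (out / "config.yaml").write_text(yaml.safe_dump(spec.model_dump()))
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _write_csv(path, columns: dict) -> None:
    keys = list(columns)
    arr = np.column_stack([np.asarray(columns[k], dtype=float) for k in keys])
    np.savetxt(path, arr, delimiter=",", header=",".join(keys), comments="")
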