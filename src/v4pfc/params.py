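"""Model parameters, stimulus conditions and ablation plumbing.

The network couples two shape-selective V4 units to two vlPFC units through
delayed feedforward and feedback connections.  All constants live in
:class:`NetworkParams`; the packaged defaults (``v4pfc/_config/defaults.yaml``)
hold the reference configuration used throughout the test suite.
"""

from __future__ import annotations

import copy
import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

ABLATIONS = ("no_feedback", "no_adaptation", "no_rectification", "no_gain")

#: The nine % visible area values used in the occlusion discrimination task.
OCCLUSION_LEVELS = (100.0, 99.0, 95.0, 90.0, 82.0, 72.0, 59.0, 45.0, 27.0)


@dataclass
class Ablations:
    """Flags disabling one network mechanism each (all off by default)."""

    no_feedback: bool = False
    no_adaptation: bool = False
    no_rectification: bool = False
    no_gain: bool = False

    def any(self) -> bool:
        return any(dataclasses.asdict(self).values())


@dataclass
class NetworkParams:
    """All constants of the two-layer rate model plus integration settings.

    Rate units are spikes/s, time in ms.  ``w_inf_wfb`` defaults to the
    proportionality rule ``w_inf_sfb * w_inf_wff / w_inf_sff`` so that
    feedback mirrors the feedforward asymmetry; pass an explicit value to
    override it.
    """

    # membrane/response time constants
    tau_v4: float = 50.0
    tau_pfc: float = 20.0
    # firing-rate thresholds entering the Naka-Rushton nonlinearity
    r_thr_v4: float = 20.0
    r_thr_pfc: float = 0.0
    # Naka-Rushton semi-saturation and exponent, saturation rate
    sigma_nr: float = 90.0
    n_nr: float = 2.0
    f_max: float = 100.0
    # feedback rectification threshold and adaptation trigger
    r_thr1: float = 30.0
    r_thr2: float = 10.0
    tau_a: float = 30.0
    # synaptic delays
    tau_d_ff: float = 40.0
    tau_d_fb: float = 40.0
    # steady-state connection weights (strong/weak, feedforward/feedback)
    w_inf_sff: float = 0.5
    w_inf_wff: float = 0.2
    w_inf_sfb: float = 1.3
    w_inf_wfb: float | None = None
    # occlusion-dependent gain polynomial, highest order first
    gain_coeffs: tuple[float, float, float, float] = (-0.0017, 0.39, -29.6, 806.0)
    # noise amplitude: std of the white-noise term on the rate equations,
    # expressed per Euler step as noise_std_coeff * dt
    noise_std_coeff: float = 300.0
    noise_on: bool = False
    # integration
    dt: float = 0.01
    t_total: float = 700.0
    # delay (ms) before occlusion-dependent gain reaches the vlPFC units
    gain_delay: float = 0.0
    # feedforward drive construction
    kernel_support: float = 120.0
    kernel_norm: str = "area"  # "area" | "peak" | "none"
    ablations: Ablations = field(default_factory=Ablations)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.w_inf_wfb is None:
            self.w_inf_wfb = self.w_inf_sfb * self.w_inf_wff / self.w_inf_sff
        if isinstance(self.ablations, dict):
            self.ablations = Ablations(**self.ablations)
        self.gain_coeffs = tuple(self.gain_coeffs)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        taus = (self.tau_v4, self.tau_pfc, self.tau_a)
        if any(tau <= 0 for tau in taus):
            raise ValueError("all time constants must be positive")
        if self.tau_d_ff < 0 or self.tau_d_fb < 0:
            raise ValueError("synaptic delays must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > min(taus) / 10.0:
            raise ValueError(
                f"dt={self.dt} too coarse for stability: must be <= min(tau)/10 "
                f"= {min(taus) / 10.0:g} ms"
            )
        for name in ("w_inf_sff", "w_inf_wff", "w_inf_sfb", "w_inf_wfb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if len(self.gain_coeffs) != 4:
            raise ValueError("gain_coeffs must have exactly 4 entries")
        if self.kernel_norm not in ("area", "peak", "none"):
            raise ValueError(f"unknown kernel_norm {self.kernel_norm!r}")
        if self.t_total <= 0:
            raise ValueError("t_total must be positive")

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gain_coeffs"] = list(self.gain_coeffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"model config {path} does not contain a mapping")
        return cls.from_dict(d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def replace(self, **kwargs) -> "NetworkParams":
        d = self.to_dict()
        d.update(kwargs)
        return NetworkParams.from_dict(d)


@dataclass(frozen=True)
class StimulusCondition:
    """One test stimulus: which shape is shown and its % visible area.

    ``shape_id`` 1 is the preferred shape of V4 unit 1, shape 2 the preferred
    shape of V4 unit 2.  ``c`` is the percentage of the shape area left
    uncovered by the occluding dots (100 = unoccluded).
    """

    shape_id: int
    c: float

    def __post_init__(self) -> None:
        if self.shape_id not in (1, 2):
            raise ValueError(f"shape_id must be 1 or 2, got {self.shape_id}")
        if not (0.0 < self.c <= 100.0):
            raise ValueError(f"% visible area must be in (0, 100], got {self.c}")


def default_params(**overrides) -> NetworkParams:
    """Reference parameter set (packaged ``defaults.yaml``)."""
    ref = importlib.resources.files("v4pfc") / "_config" / "defaults.yaml"
    d = yaml.safe_load(ref.read_text())
    d.update(overrides)
    return NetworkParams.from_dict(d)


def ablate(params: NetworkParams, which: str | Sequence[str]) -> NetworkParams:
    """Return a copy of ``params`` with one or more mechanisms disabled.

    ``no_feedback`` zeroes both feedback weights; ``no_adaptation`` freezes
    the feedforward weights at their steady-state values; ``no_rectification``
    removes the firing-rate threshold on the feedback signal (rectify at 0);
    ``no_gain`` fixes the vlPFC gain at its unoccluded value so it no longer
    depends on occlusion level.
    """
    names = [which] if isinstance(which, str) else list(which)
    for name in names:
        if name not in ABLATIONS:
            raise ValueError(f"unknown ablation {name!r}; expected one of {ABLATIONS}")
    out = copy.deepcopy(params)
    for name in names:
        setattr(out.ablations, name, True)
    if out.ablations.no_feedback:
        out.w_inf_sfb = 0.0
        out.w_inf_wfb = 0.0
    return out
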