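"""Pharmacological protocols and chronic impairments.

Drugs and impairments act on the respiratory-chain model purely as
multiplicative scalings of flux activity constants:

* rotenone      -> complex I activity to 20% of baseline
* antimycin A   -> complex III activity to 20% of baseline
* oligomycin    -> F1Fo ATP synthase activity to 13% of baseline
* FCCP          -> proton-leak activity to 11x baseline

Impairment presets used by the in-silico screen scale a single flux before the
protocol starts: complexes I/III/IV and the ATP synthase to 70%, the proton
leak to 150%, and the NADH delivery (dehydrogenase) flux to 95% of baseline.

Drug scales always refer to the pre-protocol baseline; when an impairment is
present the drug scale applies to the *impaired* baseline (impairment first,
then drug), and scalings on disjoint targets commute.  Nominal assay
concentrations (oligomycin 2 ug/ml, FCCP 0.5 uM, rotenone 2 uM, antimycin A
1 uM) are metadata only; the calibrated scale factors are the model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .rc_model import ACTIVITY_NAMES, ModelError, ModelParameters

__all__ = [
    "PerturbationEvent",
    "Protocol",
    "DRUG_PRESETS",
    "IMPAIRMENT_PRESETS",
    "TARGET_ACTIVITY",
    "READOUT_DELAY_S",
    "DEFAULT_SPACING_S",
    "scaled_activity",
    "apply_perturbation",
    "make_impairment",
    "make_drug_event",
    "preset_protocols",
]

#: flux targets addressable by perturbations -> activity-constant name
TARGET_ACTIVITY: dict[str, str] = {
    "DH": "X_DH",
    "C1": "X_C1",
    "C3": "X_C3",
    "C4": "X_C4",
    "F1": "X_F1",
    "Hle": "X_Hle",
}

#: calibrated drug scale factors
DRUG_PRESETS: dict[str, tuple[str, float]] = {
    "oligomycin": ("F1", 0.13),
    "fccp": ("Hle", 11.0),
    "antimycin_a": ("C3", 0.20),
    "rotenone": ("C1", 0.20),
}

#: single-flux impairment severities used by the screen
IMPAIRMENT_PRESETS: dict[str, float] = {
    "C1": 0.70,
    "C3": 0.70,
    "C4": 0.70,
    "F1": 0.70,
    "Hle": 1.50,
    "DH": 0.95,
}

#: read-out time after each drug addition (s); responses are compared 20 min
#: after addition
READOUT_DELAY_S: float = 1200.0

#: default inter-event spacing (s); long enough to reach the read-out time,
#: mirroring the plate-assay cadence
DEFAULT_SPACING_S: float = 1500.0


def scaled_activity(target: str) -> str:
    try:
        return TARGET_ACTIVITY[target]
    except KeyError:
        raise ModelError(
            f"unknown perturbation target {target!r}; "
            f"expected one of {sorted(TARGET_ACTIVITY)}") from None


@dataclass(frozen=True)
class PerturbationEvent:
    """A timed multiplicative scaling of one flux activity constant.

    ``time`` is in seconds from protocol start; impairments use
    ``time = PRE_PROTOCOL`` (applied before the first integration segment).
    """

    time: float
    target: str
    scale: float
    name: str = ""

    PRE_PROTOCOL = -1.0

    def __post_init__(self):
        scaled_activity(self.target)
        if self.scale < 0:
            raise ModelError("perturbation scale must be >= 0")
        if self.time < 0 and self.time != self.PRE_PROTOCOL:
            raise ModelError("drug events require time >= 0")


@dataclass(frozen=True)
class Protocol:
    """An ordered list of perturbation events with a name."""

    events: tuple[PerturbationEvent, ...]
    name: str = ""

    def __post_init__(self):
        ev = sorted(self.events, key=lambda e: e.time)
        times = [(e.time, e.target) for e in ev]
        if len(set(times)) != len(times):
            raise ModelError("at most one event per target per time")
        t = [e.time for e in ev]
        if any(b < a for a, b in zip(t, t[1:])):
            raise ModelError("event times must be non-decreasing")
        object.__setattr__(self, "events", tuple(ev))

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(e.target for e in self.events)

    def shifted(self, delta: float) -> "Protocol":
        return Protocol(tuple(replace(e, time=e.time + delta)
                              for e in self.events), name=self.name)

    def horizon(self, tail: float = DEFAULT_SPACING_S) -> float:
        return (self.events[-1].time if self.events else 0.0) + tail

    # --- serialisation -----------------------------------------------------
    def to_yaml(self, path=None) -> str:
        doc = {"name": self.name,
               "events": [{"time": e.time, "target": e.target,
                           "scale": e.scale, "name": e.name}
                          for e in self.events]}
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "Protocol":
        import os

        if isinstance(source, str) and os.path.exists(source):
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(source)
        events = tuple(PerturbationEvent(
            time=float(e["time"]), target=str(e["target"]),
            scale=float(e["scale"]), name=str(e.get("name", "")))
            for e in doc.get("events", []))
        return cls(events, name=str(doc.get("name", "")))


def apply_perturbation(params: ModelParameters,
                       event: PerturbationEvent) -> ModelParameters:
    """Return params with the targeted activity set to ``baseline * scale``.

    The scale refers to the activity constant of the params passed in (the
    original, or impaired, baseline); nothing else is touched.
    """
    name = scaled_activity(event.target)
    return params.replace(**{name: getattr(params, name) * event.scale})


def make_impairment(target: str, severity: float) -> PerturbationEvent:
    """A pre-protocol impairment event scaling one flux to ``severity``."""
    if severity <= 0:
        raise ModelError("impairment severity must be > 0")
    return PerturbationEvent(PerturbationEvent.PRE_PROTOCOL, target, severity,
                             name=f"impair_{target}")


def impairment_presets() -> dict[str, PerturbationEvent]:
    """The six single-flux screen impairments."""
    return {t: make_impairment(t, s) for t, s in IMPAIRMENT_PRESETS.items()}


def make_drug_event(drug: str, time: float) -> PerturbationEvent:
    try:
        target, scale = DRUG_PRESETS[drug]
    except KeyError:
        raise ModelError(f"unknown drug {drug!r}; expected one of "
                         f"{sorted(DRUG_PRESETS)}") from None
    return PerturbationEvent(time, target, scale, name=drug)


def preset_protocols(first_event: float = DEFAULT_SPACING_S,
                     spacing: float = DEFAULT_SPACING_S) -> dict[str, Protocol]:
    """Named protocol presets.

    ``mito_stress_test``: oligomycin -> FCCP -> antimycin A.
    ``dpsi_*``: the four single-drug membrane-potential panels.
    ``nadh_*``: the redox panels, including FCCP followed by rotenone.
    Event times are configurable; defaults leave 20 min of read-out time after
    each addition.
    """
    if spacing <= READOUT_DELAY_S:
        raise ModelError("spacing must exceed the read-out delay")
    t0 = first_event

    def seq(*drugs: str) -> Protocol:
        return Protocol(tuple(make_drug_event(d, t0 + k * spacing)
                              for k, d in enumerate(drugs)),
                        name="_".join(drugs))

    protos = {
        "mito_stress_test": Protocol(
            tuple(make_drug_event(d, t0 + k * spacing)
                  for k, d in enumerate(("oligomycin", "fccp", "antimycin_a"))),
            name="mito_stress_test"),
        "dpsi_oligomycin": seq("oligomycin"),
        "dpsi_rotenone": seq("rotenone"),
        "dpsi_antimycin_a": seq("antimycin_a"),
        "dpsi_fccp": seq("fccp"),
        "nadh_oligomycin": seq("oligomycin"),
        "nadh_rotenone": seq("rotenone"),
        "nadh_fccp": seq("fccp"),
        "nadh_fccp_rotenone": Protocol(
            (make_drug_event("fccp", t0),
             make_drug_event("rotenone", t0 + spacing)),
            name="fccp_rotenone"),
    }
    return protos
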