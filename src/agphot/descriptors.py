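"""Emitter descriptor documents: schema, validation, YAML I/O and fixtures.

An *emitter descriptor* collects the per-emitter excited-state quantities a
photophysics calculation needs: excitation energies of S1 and the low triplet
states at the ground-state-optimized (``S0-opt``) and S1-optimized (``S1-opt``)
geometries, oscillator strengths, the spin-orbit coupling matrix element
(SOCME) between S1 and T1, and optionally a nonadiabatic coupling magnitude
(NACME), an inventory of X-H oscillators, and externally supplied rate
constants.  Units are fixed by the schema: energies in eV, SOCME in cm^-1,
rates in s^-1, NACME in atomic units, mode frequencies in cm^-1.

Documents are plain YAML, schema version ``emitter/v1``; unknown keys are
rejected.  Four descriptors for the benchmark Ag16/Ag10 DNA-stabilized silver
cluster emitters (guanine and inosine variants) ship with the package and are
returned by :func:`load_table1_fixtures`.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

SCHEMA_ID = "emitter/v1"

S0_OPT = "S0-opt"
S1_OPT = "S1-opt"

_SINGLET_LABELS = ("S0", "S1", "S2", "S3")
_STATE_LABELS = ("S0", "S1", "S2", "S3", "T1", "T2", "T3")

RateProvenance = Literal["computed", "supplied"]


class SchemaError(ValueError):
    """Raised when a descriptor document violates the emitter/v1 schema."""


class ElectronicState(BaseModel):
    """One electronic state: label, excitation energy above S0 (eV) and,
    for singlets, an optional oscillator strength."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    label: str
    energy: float
    oscillator_strength: Optional[float] = None

    @field_validator("label")
    @classmethod
    def _known_label(cls, v: str) -> str:
        if v not in _STATE_LABELS:
            raise ValueError(f"unknown state label {v!r}; expected one of {_STATE_LABELS}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "ElectronicState":
        if self.label != "S0" and self.energy <= 0:
            raise ValueError(f"excitation energy of {self.label} must be > 0 eV, got {self.energy}")
        if self.oscillator_strength is not None:
            if self.label not in _SINGLET_LABELS:
                raise ValueError(
                    f"oscillator_strength given for triplet {self.label}; "
                    "spin-forbidden transitions carry no oscillator strength here"
                )
            if self.oscillator_strength < 0:
                raise ValueError("oscillator_strength must be >= 0")
        return self


class GeometryContext(BaseModel):
    """States evaluated at one optimized geometry (``S0-opt`` or ``S1-opt``)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    tag: Literal["S0-opt", "S1-opt"]
    states: tuple[ElectronicState, ...]

    @model_validator(mode="after")
    def _unique_labels(self) -> "GeometryContext":
        labels = [s.label for s in self.states]
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate state labels in context {self.tag}: {labels}")
        return self

    def state(self, label: str) -> Optional[ElectronicState]:
        for s in self.states:
            if s.label == label:
                return s
        return None


class XHMode(BaseModel):
    """A class of equivalent X-H oscillators: multiplicity, fundamental
    frequency (cm^-1) and dimensionless Morse anharmonicity chi."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    count: int
    frequency: float
    anharmonicity: float

    @model_validator(mode="after")
    def _check(self) -> "XHMode":
        if self.count < 0:
            raise ValueError("mode count must be >= 0")
        if not (1000.0 < self.frequency < 5000.0):
            raise ValueError(
                f"X-H stretch frequency {self.frequency} cm^-1 outside (1000, 5000)"
            )
        if not (0.0 < self.anharmonicity < 0.1):
            raise ValueError("anharmonicity chi must lie in (0, 0.1)")
        return self


class RateSet(BaseModel):
    """First-order decay rate constants of S1 (s^-1), each tagged with its
    provenance: ``computed`` by this package or ``supplied`` externally."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    k_r: Optional[float] = None
    k_isc: Optional[float] = None
    k_ic: Optional[float] = None
    provenance: dict[str, RateProvenance] = {}

    @model_validator(mode="after")
    def _check(self) -> "RateSet":
        present = {k for k in ("k_r", "k_isc", "k_ic") if getattr(self, k) is not None}
        for k in present:
            v = getattr(self, k)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{k} must be a finite rate >= 0, got {v}")
        if set(self.provenance) != present:
            raise ValueError(
                f"provenance keys {sorted(self.provenance)} do not match "
                f"present rates {sorted(present)}"
            )
        return self

    def present(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("k_r", "k_isc", "k_ic") if getattr(self, k) is not None}


class ReferenceBlock(BaseModel):
    """Experimental reference values. Never used in computation; kept so
    calculated and measured numbers cannot be conflated."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    exp_e_s1_s0opt_ev: Optional[float] = None
    exp_e_s1_s1opt_ev: Optional[float] = None
    exp_qyf_percent: Optional[float] = None
    exp_k_r: Optional[float] = None
    exp_k_isc: Optional[float] = None


class EmitterDescriptor(BaseModel):
    """Everything the rate engine needs to know about one emitter."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    contexts: tuple[GeometryContext, ...]
    socme_s1_t1: float
    socme_s1_t1_s0opt: Optional[float] = None
    nacme: Optional[float] = None
    xh_modes: Optional[tuple[XHMode, ...]] = None
    supplied_rates: Optional[RateSet] = None
    reference: Optional[ReferenceBlock] = None

    @model_validator(mode="after")
    def _check(self) -> "EmitterDescriptor":
        if not self.name:
            raise ValueError("emitter name must be non-empty")
        if self.socme_s1_t1 < 0:
            raise ValueError("SOCME magnitude must be >= 0 cm^-1")
        if self.socme_s1_t1_s0opt is not None and self.socme_s1_t1_s0opt < 0:
            raise ValueError("SOCME magnitude must be >= 0 cm^-1")
        if self.nacme is not None and self.nacme < 0:
            raise ValueError("NACME magnitude must be >= 0 a.u.")
        tags = [c.tag for c in self.contexts]
        if len(tags) != len(set(tags)):
            raise ValueError(f"duplicate geometry contexts: {tags}")
        if self.supplied_rates is not None:
            bad = [k for k, v in self.supplied_rates.provenance.items() if v != "supplied"]
            if bad:
                raise ValueError(f"supplied_rates entries must have provenance 'supplied': {bad}")
        return self

    def context(self, tag: str) -> Optional[GeometryContext]:
        for c in self.contexts:
            if c.tag == tag:
                return c
        return None


# --------------------------------------------------------------------------
# YAML document layer

_UNITS = {"energy": "eV", "socme": "cm^-1", "rate": "s^-1", "nacme": "a.u.", "frequency": "cm^-1"}


def _state_to_doc(s: ElectronicState) -> dict:
    d: dict = {"label": s.label, "energy": s.energy}
    if s.oscillator_strength is not None:
        d["oscillator_strength"] = s.oscillator_strength
    return d


def descriptor_to_doc(d: EmitterDescriptor) -> dict:
    """Render a descriptor as the plain mapping stored in the YAML file,
    with stable key order and optional keys omitted when unset."""
    doc: dict = {
        "schema": SCHEMA_ID,
        "name": d.name,
        "units": dict(_UNITS),
        "contexts": [
            {"tag": c.tag, "states": [_state_to_doc(s) for s in c.states]} for c in d.contexts
        ],
        "socme_s1_t1": d.socme_s1_t1,
    }
    if d.socme_s1_t1_s0opt is not None:
        doc["socme_s1_t1_s0opt"] = d.socme_s1_t1_s0opt
    if d.nacme is not None:
        doc["nacme"] = d.nacme
    if d.xh_modes is not None:
        doc["xh_modes"] = [
            {"count": m.count, "frequency": m.frequency, "anharmonicity": m.anharmonicity}
            for m in d.xh_modes
        ]
    if d.supplied_rates is not None:
        doc["supplied_rates"] = {k: v for k, v in d.supplied_rates.present().items()}
    if d.reference is not None:
        ref = {k: v for k, v in d.reference.model_dump().items() if v is not None}
        if ref:
            doc["reference"] = ref
    return doc


def descriptor_from_doc(doc: dict) -> EmitterDescriptor:
    """Validate a parsed YAML mapping against the emitter/v1 schema."""
    if not isinstance(doc, dict):
        raise SchemaError("descriptor document must be a mapping")
    schema = doc.get("schema")
    if schema != SCHEMA_ID:
        raise SchemaError(f"unsupported or missing schema id: {schema!r} (expected {SCHEMA_ID!r})")
    body = {k: v for k, v in doc.items() if k not in ("schema", "units")}
    units = doc.get("units", _UNITS)
    if units != _UNITS:
        raise SchemaError(f"unit declaration {units!r} differs from the schema's fixed units {_UNITS!r}")
    if "supplied_rates" in body and body["supplied_rates"] is not None:
        sr = body["supplied_rates"]
        if not isinstance(sr, dict) or "provenance" in sr:
            if not isinstance(sr, dict):
                raise SchemaError("supplied_rates must be a mapping of rate name to value")
        body["supplied_rates"] = {**sr, "provenance": {k: "supplied" for k in sr}}
    try:
        return EmitterDescriptor.model_validate(body)
    except Exception as exc:  # pydantic error -> schema error with field names
        raise SchemaError(f"invalid descriptor document: {exc}") from exc


def read_descriptor(path) -> EmitterDescriptor:
    """Read and validate an emitter descriptor YAML document."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: not valid YAML: {exc}") from exc
    return descriptor_from_doc(doc)


def write_descriptor(d: EmitterDescriptor, path) -> None:
    """Write a descriptor as YAML. Two writes of the same descriptor are
    byte-identical (fixed key ordering, no aliases)."""
    doc = descriptor_to_doc(d)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, default_flow_style=False))


FIXTURE_NAMES = ("Ag16(G)", "Ag16(I)", "Ag10(G)", "Ag10(I)")
_FIXTURE_FILES = {
    "Ag16(G)": "ag16_G.yaml",
    "Ag16(I)": "ag16_I.yaml",
    "Ag10(G)": "ag10_G.yaml",
    "Ag10(I)": "ag10_I.yaml",
}


def load_table1_fixtures() -> list[EmitterDescriptor]:
    """Load the four packaged benchmark emitters, in the fixed order
    Ag16(G), Ag16(I), Ag10(G), Ag10(I)."""
    out = []
    base = resources.files("agphot").joinpath("data/table1")
    for name in FIXTURE_NAMES:
        with resources.as_file(base.joinpath(_FIXTURE_FILES[name])) as p:
            out.append(read_descriptor(p))
    return out


def load_fixture(name: str) -> EmitterDescriptor:
    """Load one packaged benchmark emitter by name, e.g. ``"Ag16(G)"``."""
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    base = resources.files("agphot").joinpath("data/table1")
    with resources.as_file(base.joinpath(_FIXTURE_FILES[name])) as p:
        return read_descriptor(p)
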