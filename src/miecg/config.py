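"""Run configuration: YAML parsing, defaults with provenance metadata, manifests.

Every physical default that encodes a published simulation setting carries a
``note`` string naming what it is, so a config dump documents itself.  All
dimensioned values in config files must be unit-annotated strings
(``dt: "0.004 ps"``); bare numbers are rejected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .engine import EnsembleConfig, ProtocolSpec
from .ewald import EwaldConfig
from .units import UnitError, parse_quantity


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Default:
    value: object
    dimension: str
    note: str


#: defaults that encode the published simulation settings
PAPER_DEFAULTS = {
    "dt": Default(0.004, "time", "integration time step, 0.004 ps"),
    "cutoff": Default(15.0, "length", "real-space cutoff radius, 15 Å"),
    "thermostat_f": Default(0.5, "time", "Nosé–Hoover thermostat time f = 0.5 ps"),
    "thermostat_f1": Default(0.5, "time", "Nosé–Hoover thermo-barostat f1 = 0.5 ps"),
    "barostat_f2": Default(3.0, "time", "Nosé–Hoover thermo-barostat f2 = 3.0 ps"),
    "ewald_alpha": Default(0.18520, "inverse_length",
                           "Ewald convergence parameter α = 0.18520 Å⁻¹"),
    "ewald_kmax": Default((8, 8, 16), "dimensionless",
                          "reciprocal-lattice limits kmax = (8, 8, 16)"),
    "initial_T": Default(100.0, "temperature", "lattice equilibration temperature 100 K"),
    "equilibration_span": Default(800.0, "time", "lattice equilibration span 800 ps"),
    "pressure": Default(1.0, "pressure_atm", "atmospheric pressure set point, 1 atm"),
}

_KNOWN_KEYS = {
    "forcefield", "seed", "log_level", "output_dir",
    "build", "ensemble", "protocol", "ewald",
}
_ENSEMBLE_KEYS = {"kind", "T", "P", "f", "f1", "f2", "dt", "cutoff"}
_PROTOCOL_KEYS = {"initial_T", "equilibration_span", "production_T",
                  "production_span", "snapshot_stride"}
_EWALD_KEYS = {"alpha", "kmax"}


@dataclass
class RunConfig:
    forcefield_path: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "."
    build: dict = field(default_factory=dict)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    ewald: EwaldConfig = field(default_factory=lambda: EwaldConfig())

    def to_dict(self) -> dict:
        return {
            "forcefield": self.forcefield_path,
            "seed": self.seed,
            "log_level": self.log_level,
            "output_dir": self.output_dir,
            "build": self.build,
            "ensemble": vars(self.ensemble).copy()
            if not hasattr(self.ensemble, "__dataclass_fields__")
            else {k: getattr(self.ensemble, k) for k in self.ensemble.__dataclass_fields__},
            "protocol": {k: getattr(self.protocol, k)
                         for k in self.protocol.__dataclass_fields__},
            "ewald": {"alpha": self.ewald.alpha, "kmax": list(self.ewald.kmax),
                      "real_cutoff": self.ewald.real_cutoff},
        }


def _reject_unknown(section: dict, allowed: set, where: str):
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def parse_config(path=None, text=None) -> RunConfig:
    """Parse a YAML run configuration with unit validation and defaults.

    An empty config resolves every default to the published settings above.
    """
    if text is None:
        if path is None:
            doc = {}
        else:
            try:
                with open(path) as fh:
                    doc = yaml.safe_load(fh) or {}
            except FileNotFoundError as exc:
                raise ConfigError(f"config file not found: {path}") from exc
    else:
        doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(doc, _KNOWN_KEYS, "config root")

    ff_path = doc.get("forcefield")
    if ff_path is not None:
        import os
        if not os.path.exists(ff_path):
            raise ConfigError(f"forcefield file does not exist: {ff_path}")

    seed = doc.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool) or not (0 <= seed < 2**31):
        raise ConfigError(f"seed must be an integer in [0, 2^31), got {seed!r}")

    ens_doc = dict(doc.get("ensemble", {}))
    _reject_unknown(ens_doc, _ENSEMBLE_KEYS, "ensemble")
    try:
        ensemble = EnsembleConfig(
            kind=ens_doc.get("kind", "NVT"),
            T=parse_quantity(ens_doc["T"], "temperature", "ensemble.T")
            if "T" in ens_doc else 298.15,
            P=parse_quantity(ens_doc["P"], "pressure", "ensemble.P") / parse_quantity(
                "1 atm", "pressure", "ensemble.P")
            if "P" in ens_doc else PAPER_DEFAULTS["pressure"].value,
            f=parse_quantity(ens_doc["f"], "time", "ensemble.f")
            if "f" in ens_doc else PAPER_DEFAULTS["thermostat_f"].value,
            f1=parse_quantity(ens_doc["f1"], "time", "ensemble.f1")
            if "f1" in ens_doc else PAPER_DEFAULTS["thermostat_f1"].value,
            f2=parse_quantity(ens_doc["f2"], "time", "ensemble.f2")
            if "f2" in ens_doc else PAPER_DEFAULTS["barostat_f2"].value,
            dt=parse_quantity(ens_doc["dt"], "time", "ensemble.dt")
            if "dt" in ens_doc else PAPER_DEFAULTS["dt"].value,
            cutoff=parse_quantity(ens_doc["cutoff"], "length", "ensemble.cutoff")
            if "cutoff" in ens_doc else PAPER_DEFAULTS["cutoff"].value,
        )
    except (UnitError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    prot_doc = dict(doc.get("protocol", {}))
    _reject_unknown(prot_doc, _PROTOCOL_KEYS, "protocol")
    try:
        protocol = ProtocolSpec(
            initial_T=parse_quantity(prot_doc["initial_T"], "temperature",
                                     "protocol.initial_T")
            if "initial_T" in prot_doc else PAPER_DEFAULTS["initial_T"].value,
            equilibration_span=parse_quantity(prot_doc["equilibration_span"], "time",
                                              "protocol.equilibration_span")
            if "equilibration_span" in prot_doc
            else PAPER_DEFAULTS["equilibration_span"].value,
            production_T=parse_quantity(prot_doc["production_T"], "temperature",
                                        "protocol.production_T")
            if "production_T" in prot_doc else ensemble.T,
            production_span=parse_quantity(prot_doc["production_span"], "time",
                                           "protocol.production_span")
            if "production_span" in prot_doc else 100.0,
            snapshot_stride=int(prot_doc.get("snapshot_stride", 50)),
        )
    except (UnitError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    ew_doc = dict(doc.get("ewald", {}))
    _reject_unknown(ew_doc, _EWALD_KEYS, "ewald")
    kmax = tuple(ew_doc.get("kmax", PAPER_DEFAULTS["ewald_kmax"].value))
    try:
        ewald = EwaldConfig(
            alpha=parse_quantity(ew_doc["alpha"], "inverse_length", "ewald.alpha")
            if "alpha" in ew_doc else PAPER_DEFAULTS["ewald_alpha"].value,
            kmax=kmax,
            real_cutoff=ensemble.cutoff,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(
        forcefield_path=ff_path,
        seed=seed,
        log_level=str(doc.get("log_level", "INFO")),
        output_dir=str(doc.get("output_dir", ".")),
        build=dict(doc.get("build", {})),
        ensemble=ensemble,
        protocol=protocol,
        ewald=ewald,
    )


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(cfg: RunConfig, path, extra=None):
    """Reproducibility manifest: config hash, seed, package versions."""
    import numpy
    import scipy

    from . import __version__

    doc = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "versions": {"miecg": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__},
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
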