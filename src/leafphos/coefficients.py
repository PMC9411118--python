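"""Loading of published coefficient sets and kinetic configuration files.

Coefficients are data, not code: the shipped ``data/coefficients.yaml``
carries the forward predictor equations, the single-factor class lines, the
Ma model, the Jmax-Vcmax class lines and the P-acquisition sigmoid, and is
echoed into output headers for provenance.  Kinetic constants may likewise be
overridden from a user YAML/JSON file.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from .kinetics import KineticConstants

__all__ = ["load_coefficients", "load_kinetics", "kinetics_header"]


@lru_cache(maxsize=1)
def load_coefficients() -> dict:
    """Return the shipped coefficients table as a nested dict."""
    text = resources.files("leafphos.data").joinpath("coefficients.yaml").read_text()
    return yaml.safe_load(text)


def load_kinetics(path: str | Path | None = None, tgrowth: float | None = None) -> KineticConstants:
    """Build kinetic constants, optionally overridden from a YAML/JSON file.

    The file maps field names of :class:`KineticConstants` to values; unknown
    keys raise.  ``tgrowth`` overrides the growth temperature after the file.
    """
    overrides: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        overrides = (json.loads(raw) if str(path).endswith(".json")
                     else yaml.safe_load(raw)) or {}
    if tgrowth is not None:
        overrides["Tgrowth"] = tgrowth
    valid = set(KineticConstants.__dataclass_fields__)
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown kinetic constant(s): {sorted(unknown)}")
    return KineticConstants(**overrides)


def kinetics_header(kin: KineticConstants) -> str:
    """One-line provenance string naming every kinetic constant with units."""
    d = kin.to_dict()
    units = {
        "Kc25": "umol/mol", "Ko25": "mmol/mol", "GammaStar25": "umol/mol",
        "O": "mmol/mol", "Tgrowth": "degC",
        "deltaS_V": "J/mol/K", "deltaS_J": "J/mol/K",
    }
    parts = [f"{k}={v:g} {units.get(k, 'J/mol')}" for k, v in d.items()]
    return "# kinetics: " + "; ".join(parts)
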