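"""Run configuration: acquisition defaults and their file round trip."""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass, field

import yaml

from .phantom import DEFAULT_BEAD_DIAMETER_NM, DEFAULT_SECTION_THICKNESS_NM, DEFAULT_VOXEL_NM
from .tiltseries import DEFAULT_TILT_MAX_DEG, DEFAULT_TILT_STEP_DEG

_LENGTH_RE = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*(nm|um|µm)?\s*$")


def parse_length_nm(text) -> float:
    """Parse a length with an optional unit suffix; bare numbers are nm.

    Accepts e.g. ``'20nm'``, ``'50um'``, ``'1.206'`` (nm).
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = _LENGTH_RE.match(str(text))
    if not m:
        raise ValueError(f"cannot parse length {text!r} (expected e.g. '20nm', '50um')")
    value = float(m.group(1))
    unit = m.group(2)
    if unit in ("um", "µm"):
        value *= 1000.0
    return value


@dataclass
class RunConfig:
    """Toolkit-wide defaults, all overridable, round-trippable via YAML."""

    seed: int = 0
    voxel_nm: float = DEFAULT_VOXEL_NM
    section_thickness_nm: float = DEFAULT_SECTION_THICKNESS_NM
    tilt_max_deg: float = DEFAULT_TILT_MAX_DEG
    tilt_step_deg: float = DEFAULT_TILT_STEP_DEG
    bead_diameter_nm: float = DEFAULT_BEAD_DIAMETER_NM
    bead_surfaces: str = "both"
    output_dir: str = "."
    verbosity: str = "INFO"

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {k: data[k] for k in data if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)
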