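"""Registry of breathing-condition presets (normal, effort grid, ARDS, COPD).

Each preset bundles a :class:`~lungsim.mechanics.RespiratoryMechanics`
parameter set and a :class:`~lungsim.mechanics.MuscleProfile` drive.  ARDS
presets encode the restrictive archetype (compliance falls, small-airway
resistance rises with severity); COPD presets encode the obstructive
archetype (upper- and small-airway resistance rise, elastic recoil falls).
The registry can be round-tripped through a versioned YAML document.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import yaml

from .mechanics import MuscleProfile, RespiratoryMechanics

__all__ = ["DiseasePreset", "PRESETS", "get_preset", "preset_names",
           "registry_to_yaml", "registry_from_yaml", "REGISTRY_VERSION"]

REGISTRY_VERSION = 1


@dataclass(frozen=True)
class DiseasePreset:
    """A named breathing condition: mechanics plus muscle drive."""

    name: str
    severity: str
    mechanics: RespiratoryMechanics
    profile: MuscleProfile

    @property
    def key(self) -> str:
        return self.name if self.severity in ("none",) else f"{self.name}:{self.severity}"


def _preset(name, severity, Pmus_max, Ccw, Clr, Cll, Rr, Rl, Rt, r, RR):
    with warnings.catch_warnings():
        # presets intentionally include values below the advertised
        # small-airway lower range; silence the envelope advisories here
        warnings.simplefilter("ignore", UserWarning)
        mech = RespiratoryMechanics(Rt=Rt, Rl=Rl, Rr=Rr, Cll=Cll, Clr=Clr,
                                    Ccw=Ccw, r=r, RR=RR)
    return DiseasePreset(
        name=name,
        severity=severity,
        mechanics=mech,
        profile=MuscleProfile(Pmus_max=Pmus_max, RR=RR),
    )


# columns: Pmus_max, Ccw, Clr, Cll, Rr, Rl, Rt, r, RR
_TABLE = [
    ("normal", "none",      10, 200, 35.0, 35.0, 1, 1,  4, 2.84, 16),
    ("pmus1",  "none",       8, 200, 50.0, 50.0, 2, 2,  4, 2.84, 15),
    ("pmus2",  "none",      10, 200, 50.0, 50.0, 2, 2,  4, 2.84, 15),
    ("pmus3",  "none",      12, 200, 50.0, 50.0, 2, 2,  4, 2.84, 15),
    ("ards",   "mild",      10, 200, 22.5, 22.5, 1, 1,  4, 2.84, 16),
    ("ards",   "moderate",  10, 200, 20.0, 20.0, 2, 2,  4, 2.84, 16),
    ("ards",   "severe",    10, 200, 15.0, 15.0, 4, 4,  4, 2.84, 16),
    ("copd",   "mild",      10, 200, 35.0, 35.0, 1, 1,  4, 2.84, 12),
    ("copd",   "moderate",  10, 200, 35.0, 35.0, 2, 2, 10, 4.42, 12),
    ("copd",   "severe",    10, 200, 20.0, 20.0, 8, 8, 20, 5.93, 12),
]

PRESETS: dict[str, DiseasePreset] = {
    p.key: p for p in (_preset(*row) for row in _TABLE)
}


def preset_names() -> list[str]:
    return list(PRESETS)


def get_preset(key: str) -> DiseasePreset:
    """Look up a preset by key, e.g. ``"normal"`` or ``"ards:severe"``."""
    k = key.strip().lower()
    if k not in PRESETS:
        raise KeyError(f"unknown preset {key!r}; available: {', '.join(PRESETS)}")
    return PRESETS[k]


def registry_to_yaml(path=None) -> str:
    """Serialize the preset registry as a versioned YAML document."""
    doc = {"version": REGISTRY_VERSION, "presets": {}}
    for key, p in PRESETS.items():
        m, pr = p.mechanics, p.profile
        doc["presets"][key] = {
            "name": p.name, "severity": p.severity,
            "mechanics": {"Rt": m.Rt, "Rl": m.Rl, "Rr": m.Rr, "Cll": m.Cll,
                          "Clr": m.Clr, "Ccw": m.Ccw, "r": m.r, "RR": m.RR},
            "profile": {"Pmus_max": pr.Pmus_max, "RR": pr.RR,
                        "rise_fraction": pr.rise_fraction,
                        "decay_fraction": pr.decay_fraction,
                        "shape": pr.shape},
        }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def registry_from_yaml(text_or_path) -> dict[str, DiseasePreset]:
    """Parse a registry YAML document back into preset objects."""
    try:
        with open(text_or_path) as fh:
            doc = yaml.safe_load(fh)
    except (OSError, TypeError):
        doc = yaml.safe_load(text_or_path)
    if doc.get("version") != REGISTRY_VERSION:
        raise ValueError(f"unsupported registry version {doc.get('version')!r}")
    out = {}
    for key, entry in doc["presets"].items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mech = RespiratoryMechanics(**entry["mechanics"])
        out[key] = DiseasePreset(
            name=entry["name"], severity=entry["severity"],
            mechanics=mech, profile=MuscleProfile(**entry["profile"]),
        )
    return out
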