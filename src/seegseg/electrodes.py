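"""Electrode geometry catalogue.

SEEG shafts carry 5-18 platinum-iridium cylindrical contacts, each
0.8 mm in diameter and 2 mm long, separated by a 1.5 mm gap between
cylinder ends.  The center-to-center pitch ``d = contact_length + gap``
(3.5 mm for the default geometry) sizes every search step of the
segmentation algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = ["ElectrodeModel", "default_model", "load_models_config",
           "DEFAULT_CONTACT_LENGTH", "DEFAULT_CONTACT_DIAMETER",
           "DEFAULT_GAP", "DEFAULT_SPACING"]

DEFAULT_CONTACT_LENGTH = 2.0   # mm
DEFAULT_CONTACT_DIAMETER = 0.8  # mm
DEFAULT_GAP = 1.5              # mm between cylinder ends
DEFAULT_SPACING = DEFAULT_CONTACT_LENGTH + DEFAULT_GAP  # center-to-center

_CATALOGUE_RANGE = (5, 18)


@dataclass(frozen=True)
class ElectrodeModel:
    """Contact count and contact geometry of one electrode shaft (mm)."""

    n_contacts: int
    contact_length: float = DEFAULT_CONTACT_LENGTH
    contact_diameter: float = DEFAULT_CONTACT_DIAMETER
    gap: float = DEFAULT_GAP

    def __post_init__(self):
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")
        for name in ("contact_length", "contact_diameter", "gap"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def spacing(self) -> float:
        """Center-to-center contact distance ``d`` (mm)."""
        return self.contact_length + self.gap

    @property
    def span(self) -> float:
        """Tip-contact center to last-contact center distance (mm)."""
        return (self.n_contacts - 1) * self.spacing


def default_model(n_contacts: int) -> ElectrodeModel:
    """Catalogue model with the standard contact geometry.

    ``n_contacts`` must lie in the manufactured range 5-18.
    """
    lo, hi = _CATALOGUE_RANGE
    if not lo <= int(n_contacts) <= hi:
        raise ValueError(
            f"catalogue electrodes have {lo}-{hi} contacts, got {n_contacts}"
        )
    return ElectrodeModel(n_contacts=int(n_contacts))


def load_models_config(path) -> dict[str, ElectrodeModel]:
    """Read a YAML mapping of electrode label -> model parameters.

    Each entry is either a bare contact count or a mapping with
    ``n_contacts`` and optional ``contact_length`` / ``contact_diameter``
    / ``gap`` overrides::

        A: 8
        B: {n_contacts: 18, gap: 1.5}
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError(f"models config must be a mapping, got {type(raw)}")
    models = {}
    for label, entry in raw.items():
        if isinstance(entry, int):
            models[str(label)] = ElectrodeModel(n_contacts=entry)
        elif isinstance(entry, dict):
            models[str(label)] = ElectrodeModel(**entry)
        else:
            raise ValueError(
                f"model for {label!r} must be an int or mapping, got {entry!r}"
            )
    return models
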