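"""Controlled vocabulary of organelle / ultrastructure classes.

These are the eleven features quantified in foraminiferal NanoSIMS sections:
ten cellular organelles or ultrastructural features plus the embedding resin
that surrounds the cell (resin is quantified as a labeling blank).
"""

from __future__ import annotations

from enum import Enum

from .errors import VocabularyError

__all__ = ["OrganelleClass", "parse_class"]


class OrganelleClass(str, Enum):
    """Organelle / ultrastructural feature classes."""

    VACUOLE = "vacuole"
    FOOD_VACUOLE = "food_vacuole"
    MITOCHONDRION = "mitochondrion"
    PEROXISOME = "peroxisome"
    PLASTID = "plastid"
    LIPID_DROPLET = "lipid_droplet"
    POSSIBLE_ENDOBIONT = "possible_endobiont"
    ELECTRON_DENSE_BODY = "electron_dense_body"
    CYTOSOME = "cytosome"
    ORGANIC_LINING = "organic_lining"
    RESIN = "resin"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


def parse_class(name: str) -> OrganelleClass:
    """Parse a canonical class name, rejecting anything off-vocabulary."""
    try:
        return OrganelleClass(str(name))
    except ValueError:
        accepted = [c.value for c in OrganelleClass]
        raise VocabularyError(
            f"unknown organelle class {name!r}; accepted names: {accepted}"
        ) from None
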