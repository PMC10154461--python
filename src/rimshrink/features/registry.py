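"""The fixed 104-feature registry: 18 first-order (FF), 14 shape (MF),
72 texture (TF = 21 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM).

The registry is data-driven (registry.csv beside this module) so an
alternate feature set with the same class partition can be swapped in
without code changes.  Feature names are '<family>_<Name>'.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

CLASS_SIZES = {"FF": 18, "MF": 14, "TF": 72}
TOTAL_FEATURES = 104
TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "gldm", "ngtdm")


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    feature_class: str  # FF / MF / TF
    family: str  # firstorder / shape / glcm / glrlm / glszm / gldm / ngtdm


def load_registry() -> list[RegistryEntry]:
    """Load and validate the feature registry shipped with the package."""
    text = resources.files("rimshrink.features").joinpath("registry.csv").read_text()
    entries = [
        RegistryEntry(row["name"], row["class"], row["family"])
        for row in csv.DictReader(text.splitlines())
    ]
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in registry")
    counts = {c: sum(1 for e in entries if e.feature_class == c) for c in CLASS_SIZES}
    if counts != CLASS_SIZES or len(entries) != TOTAL_FEATURES:
        raise ValueError(f"registry partition {counts} != required {CLASS_SIZES}")
    return entries


def feature_names() -> list[str]:
    return [e.name for e in load_registry()]


def names_by_class() -> dict[str, list[str]]:
    reg = load_registry()
    return {c: [e.name for e in reg if e.feature_class == c] for c in CLASS_SIZES}


def names_by_family() -> dict[str, list[str]]:
    reg = load_registry()
    fams: dict[str, list[str]] = {}
    for e in reg:
        fams.setdefault(e.family, []).append(e.name)
    return fams
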