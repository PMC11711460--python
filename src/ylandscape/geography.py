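"""Region vocabulary: codes, census sizes, east-west coordinates, adjacency.

The default vocabulary covers 19 regions (18 current administrative regions
of mainland Finland plus Ceded Karelia), the reserved foreign-birth code and
the by-default-excluded island region. Users may load their own vocabulary
from a YAML file of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = ["RegionVocabulary", "default_vocabulary", "load_vocabulary"]


@dataclass(frozen=True)
class RegionVocabulary:
    """Immutable description of the regional sampling frame.

    Attributes
    ----------
    codes : list of str
        Analysis region codes, in canonical order.
    names : dict
        Region code -> full name.
    census : dict
        Region code -> census population size (positive).
    east : dict
        Region code -> east-west coordinate in [0, 1].
    adjacency : dict
        Region code -> list of geographically adjacent region codes
        (symmetric).
    foreign_code : str
        Reserved code for foreign birthplaces.
    excluded_by_default : list of str
        Recognised codes excluded from regional analyses unless overridden.
    """

    codes: list[str]
    names: dict[str, str]
    census: dict[str, int]
    east: dict[str, float]
    adjacency: dict[str, list[str]]
    foreign_code: str = "FOREIGN"
    excluded_by_default: list[str] = field(default_factory=list)
    extra_codes: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        for r, pop in self.census.items():
            if pop <= 0:
                raise ValueError(f"census size for {r} must be positive")
        # enforce symmetric adjacency
        for a, nbrs in self.adjacency.items():
            for b in nbrs:
                if a not in self.adjacency.get(b, []):
                    raise ValueError(f"adjacency not symmetric: {a}-{b}")

    @property
    def recognized_codes(self) -> set[str]:
        """All codes assign_regions accepts without a validation error."""
        return set(self.codes) | {self.foreign_code} | set(self.extra_codes)

    def census_weights(self) -> dict[str, float]:
        total = sum(self.census[r] for r in self.codes)
        return {r: self.census[r] / total for r in self.codes}


def load_vocabulary(path) -> RegionVocabulary:
    """Load a region vocabulary from a YAML file (see the bundled default)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _from_raw(raw)


def _from_raw(raw: dict) -> RegionVocabulary:
    regions = raw["regions"]
    special = raw.get("special", {})
    return RegionVocabulary(
        codes=list(regions),
        names={r: v["name"] for r, v in regions.items()},
        census={r: int(v["census"]) for r, v in regions.items()},
        east={r: float(v["east"]) for r, v in regions.items()},
        adjacency={r: list(v) for r, v in raw.get("adjacency", {}).items()},
        foreign_code=special.get("foreign_code", "FOREIGN"),
        excluded_by_default=list(special.get("excluded_by_default", [])),
        extra_codes=dict(special.get("extra_codes", {})),
    )


def default_vocabulary() -> RegionVocabulary:
    """The bundled 19-region Finnish vocabulary."""
    ref = resources.files("ylandscape.data") / "finland_regions.yaml"
    raw = yaml.safe_load(ref.read_text())
    return _from_raw(raw)
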