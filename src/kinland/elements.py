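"""Named residue-range annotation of the kinase fold.

An :class:`ElementMap` partitions a kinase chain (author numbering,
inclusive ranges) into the structural elements every conformational metric
consumes: the two lobes, the hinge, the glycine-rich P loop, the C helix,
the activation segment, the base of the N-lobe β sheet, and the regulatory
(R) and catalytic (C) hydrophobic spines.

Defaults for CDK1 and CDK2 ship as package data
(``data/element_maps.yaml``) and can be overridden per kinase and element
from a YAML/JSON config, each value an inclusive ``[start, end]`` pair, a
list of such pairs, or a residue list.

The lobe split is a configuration choice: the N-lobe runs from the chain
start to the residue preceding the hinge, the hinge is the E81–L83 region
that hydrogen-bonds ATP-mimetic inhibitor cores (81–84 by default), and the
C-lobe is everything after it. Elements counted on the C-lobe side of the
inter-lobe interface are the (extended) hinge and the activation segment;
on the N-lobe side, the C helix and the β-sheet base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigurationError

#: Which side of the inter-lobe interface each census element belongs to.
ELEMENT_LOBE_SIDE = {
    "hinge": "C",
    "activation_segment": "C",
    "c_helix": "N",
    "beta_sheet_base": "N",
}


class ResidueSet:
    """A set of author residue numbers given as inclusive ranges.

    Accepts ``(start, end)``, ``[[s1, e1], [s2, e2]]``, a plain iterable of
    residue numbers, or another ResidueSet.
    """

    def __init__(self, spec) -> None:
        self.ranges: list[tuple[int, int]] = []
        if isinstance(spec, ResidueSet):
            self.ranges = list(spec.ranges)
            return
        spec = list(spec)
        if len(spec) == 2 and all(isinstance(x, int) for x in spec):
            spec = [spec]
        for item in spec:
            if isinstance(item, int):
                self.ranges.append((item, item))
            else:
                start, end = int(item[0]), int(item[1])
                if end < start:
                    raise ConfigurationError(f"inverted range [{start}, {end}]")
                self.ranges.append((start, end))
        if not self.ranges:
            raise ConfigurationError("empty residue set")

    def __contains__(self, residue_number: int) -> bool:
        return any(s <= residue_number <= e for s, e in self.ranges)

    def __iter__(self):
        for s, e in self.ranges:
            yield from range(s, e + 1)

    def __len__(self) -> int:
        return len(set(iter(self)))

    def __eq__(self, other) -> bool:
        return isinstance(other, ResidueSet) and set(self) == set(other)

    def __repr__(self) -> str:
        return f"ResidueSet({self.ranges!r})"

    def isdisjoint(self, other: "ResidueSet") -> bool:
        return set(self).isdisjoint(set(other))

    def issubset(self, other: "ResidueSet") -> bool:
        return set(self) <= set(other)

    def shifted(self, offset: int) -> "ResidueSet":
        return ResidueSet([(s + offset, e + offset) for s, e in self.ranges])


@dataclass
class ElementMap:
    """Residue-range partition of a kinase chain, author numbering."""

    kinase: str
    n_lobe: ResidueSet
    c_lobe: ResidueSet
    hinge: ResidueSet
    p_loop: ResidueSet
    c_helix: ResidueSet
    activation_segment: ResidueSet
    beta_sheet_base: ResidueSet
    r_spine_residues: list[int] = field(default_factory=list)
    c_spine_residues: list[int] = field(default_factory=list)
    gatekeeper: int = 0
    ploop_tyrosine: int = 0
    activation_glutamate: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lobe", "c_lobe", "hinge", "p_loop", "c_helix",
                     "activation_segment", "beta_sheet_base"):
            val = getattr(self, name)
            if not isinstance(val, ResidueSet):
                setattr(self, name, ResidueSet(val))
        self.validate()

    def validate(self) -> None:
        if not self.n_lobe.isdisjoint(self.c_lobe):
            raise ConfigurationError("N-lobe and C-lobe overlap")
        if not self.p_loop.issubset(self.n_lobe):
            raise ConfigurationError("P loop must lie within the N-lobe")
        if not self.c_helix.issubset(self.n_lobe):
            raise ConfigurationError("C helix must lie within the N-lobe")
        if not self.activation_segment.issubset(self.c_lobe):
            raise ConfigurationError(
                "activation segment must lie within the C-lobe"
            )

    def element(self, name: str) -> ResidueSet:
        val = getattr(self, name, None)
        if not isinstance(val, ResidueSet):
            raise ConfigurationError(f"unknown element {name!r}")
        return val

    def census_elements(self) -> dict[str, tuple[str, ResidueSet]]:
        """Census elements as name → (lobe side, residues)."""
        return {
            name: (side, self.element(name))
            for name, side in ELEMENT_LOBE_SIDE.items()
        }

    def with_overrides(self, overrides: Mapping) -> "ElementMap":
        """New map with elements replaced from a config mapping."""
        kwargs = dict(
            kinase=self.kinase,
            n_lobe=self.n_lobe, c_lobe=self.c_lobe, hinge=self.hinge,
            p_loop=self.p_loop, c_helix=self.c_helix,
            activation_segment=self.activation_segment,
            beta_sheet_base=self.beta_sheet_base,
            r_spine_residues=list(self.r_spine_residues),
            c_spine_residues=list(self.c_spine_residues),
            gatekeeper=self.gatekeeper,
            ploop_tyrosine=self.ploop_tyrosine,
            activation_glutamate=self.activation_glutamate,
        )
        for key, value in overrides.items():
            if key not in kwargs:
                raise ConfigurationError(f"unknown element-map key {key!r}")
            if key in ("gatekeeper", "ploop_tyrosine", "activation_glutamate"):
                kwargs[key] = int(value)
            elif key in ("r_spine_residues", "c_spine_residues"):
                kwargs[key] = [int(v) for v in value]
            elif key != "kinase":
                kwargs[key] = ResidueSet(value)
        return ElementMap(**kwargs)


def _load_packaged(name: str):
    ref = resources.files("kinland.data").joinpath(name)
    return yaml.safe_load(ref.read_text())


def default_element_map(kinase: str) -> ElementMap:
    """Packaged default :class:`ElementMap` for 'CDK1' or 'CDK2'."""
    data = _load_packaged("element_maps.yaml")
    key = kinase.upper()
    if key not in data:
        raise ConfigurationError(
            f"no default element map for kinase {kinase!r}; have {sorted(data)}"
        )
    entry = data[key]
    return ElementMap(
        kinase=key,
        n_lobe=ResidueSet(entry["n_lobe"]),
        c_lobe=ResidueSet(entry["c_lobe"]),
        hinge=ResidueSet(entry["hinge"]),
        p_loop=ResidueSet(entry["p_loop"]),
        c_helix=ResidueSet(entry["c_helix"]),
        activation_segment=ResidueSet(entry["activation_segment"]),
        beta_sheet_base=ResidueSet(entry["beta_sheet_base"]),
        r_spine_residues=list(entry["r_spine_residues"]),
        c_spine_residues=list(entry["c_spine_residues"]),
        gatekeeper=int(entry["gatekeeper"]),
        ploop_tyrosine=int(entry["ploop_tyrosine"]),
        activation_glutamate=int(entry["activation_glutamate"]),
    )


def load_element_map(
    kinase: str, config: str | Path | Mapping | None = None
) -> ElementMap:
    """Default map for ``kinase`` with optional YAML/JSON config overrides.

    The config is keyed by kinase name, then element name.
    """
    emap = default_element_map(kinase)
    if config is None:
        return emap
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text) if not str(config).endswith(".json") \
            else json.loads(text)
    overrides = config.get(kinase.upper(), config.get(kinase, {}))
    return emap.with_overrides(overrides)


def packaged_annotation_table() -> list[dict]:
    """Packaged single-residue annotations used to sanity-check defaults.

    Each row asserts that a named residue of CDK1/CDK2 (identity from the
    canonical sequences) belongs to a given element of the default map.
    """
    return _load_packaged("residue_annotations.yaml")
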