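"""Reporter-gene geometry.

A :class:`GeneModel` describes one copy of the tandem reporter construct in
base-pair coordinates: ordered exons and introns, the MS2 stem-loop cassette
in the 3'UTR, the FISH probe targets, and the number of identical gene copies
in the integrated array.  Coordinates are 0-based, half-open intervals; a
polymerase "has transcribed" position ``x`` once its position is >= ``x``.

Two presets are packaged, ``E3`` (3 exons / 2 introns) and ``E6`` (6 exons /
5 introns), both with 18 MS2 repeats.  The published work does not print the
segment lengths of the constructs, so the packaged defaults use a
mini-gene-like scale and every downstream result is parameter-relative.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError, GeneValidationError

Interval = tuple[int, int]

_PRESET_COUNTS = {"E3": (3, 2), "E6": (6, 5)}


@dataclass(frozen=True)
class GeneModel:
    """Geometry of one reporter-gene copy plus array copy number."""

    name: str
    length_bp: int
    exons: tuple[Interval, ...]
    introns: tuple[Interval, ...]
    ms2_region: Interval
    n_ms2_repeats: int = 18
    exon_probe: Interval = (0, 300)
    intron_probe_indices: frozenset[int] = field(default_factory=frozenset)
    n_copies: int = 20

    def __post_init__(self):
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        object.__setattr__(self, "introns", tuple(tuple(i) for i in self.introns))
        object.__setattr__(self, "ms2_region", tuple(self.ms2_region))
        object.__setattr__(self, "exon_probe", tuple(self.exon_probe))
        object.__setattr__(
            self, "intron_probe_indices", frozenset(int(i) for i in self.intron_probe_indices)
        )

    # -- convenience geometry -------------------------------------------------
    @property
    def ms2_start(self) -> int:
        return self.ms2_region[0]

    @property
    def ms2_length(self) -> int:
        return self.ms2_region[1] - self.ms2_region[0]

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "length_bp": self.length_bp,
            "exons": [list(e) for e in self.exons],
            "introns": [list(i) for i in self.introns],
            "ms2_region": list(self.ms2_region),
            "n_ms2_repeats": self.n_ms2_repeats,
            "exon_probe": list(self.exon_probe),
            "intron_probe_indices": sorted(self.intron_probe_indices),
            "n_copies": self.n_copies,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneModel":
        return cls(
            name=d["name"],
            length_bp=int(d["length_bp"]),
            exons=tuple(tuple(e) for e in d["exons"]),
            introns=tuple(tuple(i) for i in d["introns"]),
            ms2_region=tuple(d["ms2_region"]),
            n_ms2_repeats=int(d.get("n_ms2_repeats", 18)),
            exon_probe=tuple(d.get("exon_probe", (0, 300))),
            intron_probe_indices=frozenset(d.get("intron_probe_indices", ())),
            n_copies=int(d.get("n_copies", 20)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GeneModel":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(doc)


def _interval_ok(iv: Interval, length: int) -> bool:
    return 0 <= iv[0] < iv[1] <= length


def validate_gene(g: GeneModel) -> list[str]:
    """Return every invariant violation (empty list when the model is valid).

    Never raises: this is the exhaustive checker behind :func:`build_gene`.
    """
    v: list[str] = []
    if g.length_bp <= 0:
        v.append(f"length_bp must be positive, got {g.length_bp}")
        return v
    for kind, ivs in (("exon", g.exons), ("intron", g.introns)):
        for iv in ivs:
            if not _interval_ok(iv, g.length_bp):
                v.append(f"{kind} {iv} is not a valid interval within [0, {g.length_bp})")

    # exons and introns: sorted, disjoint, strictly alternating
    tagged = sorted(
        [(iv, "exon") for iv in g.exons] + [(iv, "intron") for iv in g.introns],
        key=lambda t: t[0],
    )
    for (a, ka), (b, kb) in zip(tagged, tagged[1:]):
        if a[1] > b[0]:
            v.append(f"{ka} {a} overlaps {kb} {b}")
        if ka == kb:
            v.append(f"adjacent {ka}s {a} and {b} do not alternate with an {('intron' if ka == 'exon' else 'exon')}")

    if not _interval_ok(g.ms2_region, g.length_bp):
        v.append(f"ms2_region {g.ms2_region} is not a valid interval within [0, {g.length_bp})")
    elif g.introns and g.ms2_region[0] < max(i[1] for i in g.introns):
        v.append(f"ms2_region {g.ms2_region} is not downstream of the last intron")

    if not _interval_ok(g.exon_probe, g.length_bp):
        v.append(f"exon_probe {g.exon_probe} is not a valid interval within [0, {g.length_bp})")
    elif not any(e[0] <= g.exon_probe[0] and g.exon_probe[1] <= e[1] for e in g.exons):
        v.append(f"exon_probe {g.exon_probe} is not contained in any exon")

    bad = [i for i in g.intron_probe_indices if not (0 <= i < len(g.introns))]
    if bad:
        v.append(f"intron_probe_indices {sorted(bad)} out of range for {len(g.introns)} introns")

    if g.n_ms2_repeats < 1:
        v.append(f"n_ms2_repeats must be >= 1, got {g.n_ms2_repeats}")
    if g.n_copies < 1:
        v.append(f"n_copies must be >= 1, got {g.n_copies}")

    if g.name in _PRESET_COUNTS:
        ne, ni = _PRESET_COUNTS[g.name]
        if len(g.exons) != ne or len(g.introns) != ni:
            v.append(
                f"{g.name} must have {ne} exons and {ni} introns, "
                f"got {len(g.exons)}/{len(g.introns)}"
            )
        if g.n_ms2_repeats != 18:
            v.append(f"{g.name} must carry 18 MS2 repeats, got {g.n_ms2_repeats}")
    return v


def _load_presets() -> dict[str, dict]:
    ref = importlib.resources.files("txnkinetics.data").joinpath("gene_presets.yaml")
    return yaml.safe_load(ref.read_text())


def available_presets() -> list[str]:
    return sorted(_load_presets())


def build_gene(preset: str, overrides: dict[str, Any] | None = None) -> GeneModel:
    """Build a validated :class:`GeneModel` from a packaged preset.

    ``overrides`` replace preset fields wholesale (e.g. ``{"n_copies": 5}`` or
    a full new ``ms2_region``).  Deterministic: identical arguments always
    yield identical models.

    Raises
    ------
    ConfigurationError
        for an unknown preset label.
    GeneValidationError
        when overrides break a geometric invariant; the message names every
        offending interval.
    """
    presets = _load_presets()
    if preset not in presets:
        raise ConfigurationError(
            f"unknown gene preset {preset!r}; available: {sorted(presets)}"
        )
    doc = dict(presets[preset])
    doc["name"] = preset
    if overrides:
        unknown = set(overrides) - set(GeneModel.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown gene fields in overrides: {sorted(unknown)}")
        doc.update(overrides)
    gene = GeneModel.from_dict(doc)
    violations = validate_gene(gene)
    if violations:
        raise GeneValidationError(violations)
    return gene


def load_gene(ref: str | Path) -> GeneModel:
    """Resolve a gene reference: a preset label or a path to a JSON/YAML file."""
    if isinstance(ref, str) and ref in _load_presets():
        return build_gene(ref)
    path = Path(ref)
    if not path.exists():
        raise ConfigurationError(f"gene reference {ref!r} is neither a preset nor a file")
    gene = GeneModel.load(path)
    violations = validate_gene(gene)
    if violations:
        raise GeneValidationError(violations)
    return gene
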