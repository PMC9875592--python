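"""Reference tables of DII scoring constants.

The dietary inflammatory index scores a diet by standardising each nutrient
intake against a global reference distribution (mean, SD) and weighting it by
a literature-derived inflammatory effect score.  This module holds those
constants as data: a :class:`DIIReferenceTable` is an ordered collection of
:class:`DIIComponent` rows plus a mode flag saying whether the reference
means/SDs are expressed as raw daily intakes or as densities per 1,000 kcal
(the energy-adjusted, "E-DII" form).

Every scoring operation takes the table as an explicit argument; a default
table transcribed from the published index-development literature is bundled
as package data, but nothing in the package depends on that transcription.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import yaml

RAW = "raw"
PER_1000_KCAL = "per_1000_kcal"
_MODES = (RAW, PER_1000_KCAL)

#: Conventional name of the total-energy component.
ENERGY = "energy"


class ReferenceTableError(ValueError):
    """Raised when a reference table or one of its rows is invalid."""


@dataclass(frozen=True)
class DIIComponent:
    """One food parameter: its global reference distribution and weight.

    Parameters
    ----------
    name
        Component identifier, unique within a table (e.g. ``"fiber"``).
    global_mean
        Global daily mean intake, in `unit` per day (or per 1,000 kcal in
        density mode).
    global_sd
        Standard deviation of the global intake, same units; strictly
        positive.
    effect_score
        Signed dimensionless inflammatory weight: positive values are
        pro-inflammatory, negative anti-inflammatory.
    unit
        Free-text measurement unit, informational only.
    """

    name: str
    global_mean: float
    global_sd: float
    effect_score: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ReferenceTableError("component name must be nonempty")
        if not self.global_sd > 0:
            raise ReferenceTableError(
                f"component {self.name!r}: global_sd must be > 0, "
                f"got {self.global_sd}"
            )


@dataclass(frozen=True)
class DIIReferenceTable:
    """Ordered collection of scoring components with a mode flag.

    ``mode`` is ``"raw"`` when the reference means/SDs are daily intakes and
    ``"per_1000_kcal"`` when they are energy densities; the scoring engine
    refuses to mix modes with incompatible dietary records.
    """

    components: tuple[DIIComponent, ...]
    mode: str = RAW
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.mode not in _MODES:
            raise ReferenceTableError(
                f"mode must be one of {_MODES}, got {self.mode!r}"
            )
        if len(self.components) < 1:
            raise ReferenceTableError("table must have at least 1 component")
        seen: set[str] = set()
        for c in self.components:
            if c.name in seen:
                raise ReferenceTableError(f"duplicate component name {c.name!r}")
            seen.add(c.name)

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self) -> Iterator[DIIComponent]:
        return iter(self.components)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def get(self, name: str) -> DIIComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def bound_score(self) -> float:
        """Maximum achievable |score|: the sum of |effect_score| over rows.

        The centered percentile of any standardised intake lies in (-1, 1),
        so every score computed from this table is bounded in absolute value
        by this quantity.
        """
        return float(sum(abs(c.effect_score) for c in self.components))

    def to_density(
        self,
        reference_energy_kcal: float | None = None,
        keep_energy: bool = False,
    ) -> "DIIReferenceTable":
        """Convert a raw-intake table to per-1,000 kcal (density) mode.

        Means and SDs are divided by ``reference_energy_kcal / 1000``.  If
        ``reference_energy_kcal`` is None the table's own energy-component
        mean is used.  The energy component itself is dropped unless
        ``keep_energy`` — divided by itself it is a constant 1,000 kcal per
        1,000 kcal and carries no information.
        """
        if self.mode != RAW:
            raise ReferenceTableError("to_density requires a raw-mode table")
        if reference_energy_kcal is None:
            try:
                reference_energy_kcal = self.get(ENERGY).global_mean
            except KeyError:
                raise ReferenceTableError(
                    "no energy component; pass reference_energy_kcal explicitly"
                ) from None
        if not reference_energy_kcal > 0:
            raise ReferenceTableError("reference_energy_kcal must be > 0")
        scale = reference_energy_kcal / 1000.0
        rows = []
        for c in self.components:
            if c.name == ENERGY and not keep_energy:
                continue
            rows.append(
                replace(c, global_mean=c.global_mean / scale,
                        global_sd=c.global_sd / scale)
            )
        return DIIReferenceTable(
            components=tuple(rows),
            mode=PER_1000_KCAL,
            source=f"{self.source} [rescaled per 1000 kcal "
                   f"at {reference_energy_kcal:g} kcal]",
        )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "source": self.source,
            "components": [
                {
                    "name": c.name,
                    "unit": c.unit,
                    "global_mean": c.global_mean,
                    "global_sd": c.global_sd,
                    "effect_score": c.effect_score,
                }
                for c in self.components
            ],
        }


# backwards-friendly functional aliases used throughout the tests/spec surface
def bound_score(table: DIIReferenceTable) -> float:
    return table.bound_score()


_REQUIRED_KEYS = ("name", "global_mean", "global_sd", "effect_score")


def _table_from_mapping(doc: dict, origin: str = "<mapping>") -> DIIReferenceTable:
    if not isinstance(doc, dict) or "components" not in doc:
        raise ReferenceTableError(
            f"{origin}: expected a mapping with a 'components' list"
        )
    rows = []
    for i, rec in enumerate(doc["components"]):
        missing = [k for k in _REQUIRED_KEYS if k not in rec]
        if missing:
            name = rec.get("name", f"<row {i}>")
            raise ReferenceTableError(
                f"{origin}: component {name!r} missing field(s) {missing}"
            )
        rows.append(
            DIIComponent(
                name=str(rec["name"]),
                global_mean=float(rec["global_mean"]),
                global_sd=float(rec["global_sd"]),
                effect_score=float(rec["effect_score"]),
                unit=str(rec.get("unit", "")),
            )
        )
    return DIIReferenceTable(
        components=tuple(rows),
        mode=doc.get("mode", RAW),
        source=doc.get("source", ""),
    )


def load_reference_table(path: str | Path) -> DIIReferenceTable:
    """Load and validate a reference table from a JSON or YAML file.

    The schema is one record per component with keys ``name``, ``unit``,
    ``global_mean``, ``global_sd``, ``effect_score``, plus top-level ``mode``
    and ``source``.  Rows violating the invariants raise
    :class:`ReferenceTableError` naming the offending component.
    """
    path = Path(path)
    text = path.read_text()
    # YAML is a superset of JSON, so one parser covers both extensions
    doc = yaml.safe_load(text)
    return _table_from_mapping(doc, origin=str(path))


def write_reference_table(table: DIIReferenceTable, path: str | Path) -> None:
    """Write a table to JSON (or YAML if the suffix says so); round-trips."""
    path = Path(path)
    doc = table.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=1))


def load_default_table() -> DIIReferenceTable:
    """The bundled 27-component raw-intake table (see its ``source`` field)."""
    ref = resources.files("dii_retinopathy.data") / "dii_reference_global.json"
    with resources.as_file(ref) as p:
        return load_reference_table(p)
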