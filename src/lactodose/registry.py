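"""Transfer-rate registry for the lactating-adult iodine model.

The registry is the single in-package source for the numeric transfer
coefficients and regional deposition fractions of the three sub-models
(respiratory tract, alimentary tract, systemic lactation kinetics).  Each rate
carries a provenance note.  Users may load an alternative registry file with
:meth:`ParameterRegistry.from_yaml`.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from functools import lru_cache
from typing import Mapping

import yaml

from .errors import ConfigurationError, ValidationError

__all__ = ["ParameterRegistry", "default_registry", "FIG_COMPARTMENTS"]

#: The compartment vocabulary of the lactating-adult model graph.
FIG_COMPARTMENTS: tuple[str, ...] = (
    "ET", "BB", "bb", "AI", "LN",
    "OC", "OE", "ST", "SI", "RC", "LC", "RS", "FA", "SA", "GS",
    "IT", "OIT", "OIO", "IO", "OV", "UB", "UR", "BR", "BM", "blood", "EN",
)

#: Deposition blocks that must be present for the three intake routes.
_REQUIRED_DEPOSITION = ("ingestion", "vapour_sr1", "particulate_amad1")


@dataclasses.dataclass(frozen=True)
class TransferEntry:
    src: str
    dst: str
    rate: float
    note: str = ""


class ParameterRegistry:
    """Validated container of transfer rates, deposition fractions and half-life."""

    def __init__(
        self,
        transfers: list[TransferEntry],
        deposition: Mapping[str, Mapping[str, float]],
        half_life_days: float,
        compartments: tuple[str, ...] = FIG_COMPARTMENTS,
        sinks: tuple[str, ...] = ("UR", "FA", "BM", "EN"),
        version: int = 0,
    ) -> None:
        comp_set = set(compartments)
        if not comp_set <= set(FIG_COMPARTMENTS):
            extra = comp_set - set(FIG_COMPARTMENTS)
            raise ValidationError(f"unknown compartments in registry: {sorted(extra)}")
        for t in transfers:
            for c in (t.src, t.dst):
                if c not in comp_set:
                    raise ValidationError(
                        f"transfer {t.src}->{t.dst} references unknown compartment {c!r}"
                    )
            if not (math.isfinite(t.rate) and t.rate >= 0):
                raise ValidationError(f"transfer {t.src}->{t.dst}: bad rate {t.rate}")
        for block in _REQUIRED_DEPOSITION:
            if block not in deposition:
                raise ConfigurationError(f"registry missing deposition block {block!r}")
            tot = 0.0
            for comp, frac in deposition[block].items():
                if comp not in comp_set:
                    raise ValidationError(
                        f"deposition {block!r} references unknown compartment {comp!r}"
                    )
                if frac < 0:
                    raise ValidationError(f"deposition {block}/{comp} must be >= 0")
                tot += frac
            if tot > 1.0 + 1e-9:
                raise ValidationError(f"deposition {block!r} fractions sum to {tot} > 1")
        if half_life_days <= 0:
            raise ValidationError("half_life_days must be > 0")
        self.transfers = list(transfers)
        self.deposition = {k: dict(v) for k, v in deposition.items()}
        self.half_life_days = float(half_life_days)
        self.compartments = tuple(compartments)
        self.sinks = tuple(sinks)
        self.version = version

    @property
    def decay_constant(self) -> float:
        return math.log(2.0) / self.half_life_days

    def rate(self, src: str, dst: str) -> float:
        for t in self.transfers:
            if t.src == src and t.dst == dst:
                return t.rate
        raise ConfigurationError(f"registry has no transfer {src!r} -> {dst!r}")

    def provenance(self) -> dict[str, str]:
        return {f"{t.src}->{t.dst}": t.note for t in self.transfers}

    @classmethod
    def from_mapping(cls, d: Mapping) -> "ParameterRegistry":
        transfers = [
            TransferEntry(e["src"], e["dst"], float(e["rate"]), e.get("note", ""))
            for e in d["transfers"]
        ]
        return cls(
            transfers,
            d["deposition"],
            float(d["half_life_days"]),
            tuple(d.get("compartments", FIG_COMPARTMENTS)),
            tuple(d.get("sinks", ("UR", "FA", "BM", "EN"))),
            version=int(d.get("version", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ParameterRegistry":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def default_registry() -> ParameterRegistry:
    """The registry shipped with the package."""
    ref = importlib.resources.files("lactodose.data") / "iodine_lactation.yaml"
    with ref.open() as fh:
        return ParameterRegistry.from_mapping(yaml.safe_load(fh))
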