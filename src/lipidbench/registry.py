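"""The 10-fatty-acid membrane cluster.

Erythrocyte membrane glycerophospholipids are profiled through a fixed panel
of ten fatty acids chosen to represent the saturated (SFA), monounsaturated
(MUFA) and polyunsaturated (omega-6 / omega-3 PUFA) families: palmitic,
palmitoleic, stearic, oleic, cis-vaccenic, linoleic (LA),
dihomo-gamma-linolenic (DGLA), arachidonic (ARA), eicosapentaenoic (EPA) and
docosahexaenoic (DHA) acids, in gas-chromatographic elution order.

Each definition carries the per-member weights used by the unsaturation index
(UI: number of double bonds, 1-6) and the peroxidation index (PI:
oxidizability weights 0.025-8).  Because both indexes are linear in the
member percentages, the conventional "total MUFA x 1" formulation is stored
as a per-member weight of 1 (and 0.025 for PI) on each MUFA.

The module-level cluster is the single source of truth for every downstream
formula; all operations accept an explicit registry so an alternative panel
can be loaded from YAML (:func:`registry_from_yaml`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import SchemaError

FAMILIES = ("SFA", "MUFA", "PUFA_n6", "PUFA_n3")


@dataclass(frozen=True)
class FattyAcidDef:
    """One member of the fatty-acid cluster.

    ``code`` is the CSV/filename-safe identifier (``"9c-C18:1"``); the
    hospital-report spellings with a comma (``"9c,C18:1"``) and the PUFA
    acronyms are accepted on input through :func:`normalize_code`.
    """

    code: str
    common_name: str
    acronym: str | None
    carbons: int
    double_bonds: int
    family: str
    ui_weight: int
    pi_weight: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SchemaError(f"unknown fatty-acid family: {self.family!r}")
        if self.carbons <= 0 or self.double_bonds < 0:
            raise SchemaError(f"invalid chain description for {self.code}")
        saturated = self.double_bonds == 0
        if (self.family == "SFA") != saturated:
            raise SchemaError(
                f"{self.code}: family {self.family} inconsistent with "
                f"{self.double_bonds} double bonds"
            )
        if saturated and (self.ui_weight != 0 or self.pi_weight != 0):
            raise SchemaError(f"{self.code}: saturated acids carry zero index weights")
        if self.family == "MUFA" and (self.ui_weight != 1 or self.pi_weight != 0.025):
            raise SchemaError(f"{self.code}: MUFA weights must be (1, 0.025)")
        if self.ui_weight < 0 or self.pi_weight < 0:
            raise SchemaError(f"{self.code}: negative index weight")


_CLUSTER: tuple[FattyAcidDef, ...] = (
    FattyAcidDef("C16:0", "palmitic acid", None, 16, 0, "SFA", 0, 0.0),
    FattyAcidDef("C16:1", "palmitoleic acid", None, 16, 1, "MUFA", 1, 0.025),
    FattyAcidDef("C18:0", "stearic acid", None, 18, 0, "SFA", 0, 0.0),
    FattyAcidDef("9c-C18:1", "oleic acid", None, 18, 1, "MUFA", 1, 0.025),
    FattyAcidDef("11c-C18:1", "cis-vaccenic acid", None, 18, 1, "MUFA", 1, 0.025),
    FattyAcidDef("C18:2", "linoleic acid", "LA", 18, 2, "PUFA_n6", 2, 1.0),
    FattyAcidDef("C20:3", "dihomo-gamma-linolenic acid", "DGLA", 20, 3, "PUFA_n6", 3, 2.0),
    FattyAcidDef("C20:4", "arachidonic acid", "ARA", 20, 4, "PUFA_n6", 4, 4.0),
    FattyAcidDef("C20:5", "eicosapentaenoic acid", "EPA", 20, 5, "PUFA_n3", 5, 6.0),
    FattyAcidDef("C22:6", "docosahexaenoic acid", "DHA", 22, 6, "PUFA_n3", 6, 8.0),
)

#: Alternative spellings accepted on input (report-style commas, acronyms).
SYNONYMS: Mapping[str, str] = {
    "9c,C18:1": "9c-C18:1",
    "11c,C18:1": "11c-C18:1",
    "LA": "C18:2",
    "DGLA": "C20:3",
    "ARA": "C20:4",
    "AA": "C20:4",
    "EPA": "C20:5",
    "DHA": "C22:6",
}


def get_cluster() -> list[FattyAcidDef]:
    """Return the ten cluster definitions in GC elution order.

    The returned list is a fresh copy; the definitions themselves are frozen.
    """
    return list(_CLUSTER)


def cluster_codes(registry: Sequence[FattyAcidDef] | None = None) -> list[str]:
    return [fa.code for fa in (registry if registry is not None else _CLUSTER)]


def by_code(registry: Sequence[FattyAcidDef] | None = None) -> dict[str, FattyAcidDef]:
    return {fa.code: fa for fa in (registry if registry is not None else _CLUSTER)}


def normalize_code(
    code: str, registry: Sequence[FattyAcidDef] | None = None
) -> str:
    """Resolve ``code`` to a canonical cluster code.

    Accepts canonical codes, the comma-spelled MUFA isomer labels and the
    PUFA acronyms.  ``"other"`` (any case) passes through unchanged: it marks
    non-cluster chromatogram area.  Unknown codes raise :class:`SchemaError`.
    """
    raw = code.strip()
    if raw.lower() == "other":
        return "other"
    resolved = SYNONYMS.get(raw, raw)
    known = set(cluster_codes(registry))
    # acronyms of a custom registry
    if resolved not in known and registry is not None:
        for fa in registry:
            if fa.acronym == raw:
                return fa.code
    if resolved not in known:
        raise SchemaError(f"unknown fatty-acid code: {code!r}")
    return resolved


def validate_registry(registry: Sequence[FattyAcidDef]) -> None:
    codes = [fa.code for fa in registry]
    if len(set(codes)) != len(codes):
        raise SchemaError("duplicate fatty-acid codes in registry")
    if not registry:
        raise SchemaError("empty registry")


def registry_from_config(entries: Iterable[Mapping]) -> list[FattyAcidDef]:
    """Build a registry from a parsed YAML ``cluster:`` block."""
    regs = []
    for e in entries:
        try:
            regs.append(
                FattyAcidDef(
                    code=str(e["code"]),
                    common_name=str(e.get("common_name", e["code"])),
                    acronym=e.get("acronym"),
                    carbons=int(e["carbons"]),
                    double_bonds=int(e["double_bonds"]),
                    family=str(e["family"]),
                    ui_weight=int(e["ui_weight"]),
                    pi_weight=float(e["pi_weight"]),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"cluster entry missing field {exc}") from exc
    validate_registry(regs)
    return regs


def registry_from_yaml(path) -> list[FattyAcidDef]:
    """Load a registry from a YAML file with a top-level ``cluster:`` list."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "cluster" not in doc:
        raise SchemaError("cluster YAML must contain a top-level 'cluster:' list")
    return registry_from_config(doc["cluster"])


def default_cluster_yaml_text() -> str:
    """Text of the shipped YAML that reproduces the built-in cluster."""
    return (
        resources.files("lipidbench").joinpath("data/cluster.yaml").read_text("utf-8")
    )
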