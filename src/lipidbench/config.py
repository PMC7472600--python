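"""Run configuration (YAML-loadable)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import SchemaError
from .registry import FattyAcidDef, get_cluster, registry_from_config
from .synthetic import SyntheticCohortSpec


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the input files themselves."""

    alpha: float = 0.05
    force_zero_intercept: bool = False
    pooled_variance: bool = False
    fdr: bool = False
    coverage_threshold: float = 0.97
    percentile_min_n: int = 40
    bins: str | int = "fd"
    registry: list[FattyAcidDef] = field(default_factory=get_cluster)
    simulation: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise SchemaError("alpha must lie in (0, 1)")
        if not (0.0 < self.coverage_threshold <= 1.0):
            raise SchemaError("coverage_threshold must lie in (0, 1]")


_SIM_FIELDS = {f.name for f in dataclasses.fields(SyntheticCohortSpec)}
_CFG_FIELDS = {
    "alpha",
    "force_zero_intercept",
    "pooled_variance",
    "fdr",
    "coverage_threshold",
    "percentile_min_n",
    "bins",
}


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Recognised top-level keys: the scalar options above, a ``cluster:`` list
    (see :func:`lipidbench.registry.registry_from_yaml`) and a
    ``simulation:`` mapping overriding :class:`SyntheticCohortSpec` fields.
    Unknown keys are rejected to catch typos.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, Mapping):
        raise SchemaError("config YAML must be a mapping")
    unknown = set(doc) - _CFG_FIELDS - {"cluster", "simulation"}
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {k: doc[k] for k in _CFG_FIELDS if k in doc}
    if "cluster" in doc:
        kwargs["registry"] = registry_from_config(doc["cluster"])
    if "simulation" in doc:
        sim = doc["simulation"]
        bad = set(sim) - _SIM_FIELDS
        if bad:
            raise SchemaError(f"unknown simulation keys: {sorted(bad)}")
        sim = {
            k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()
        }
        kwargs["simulation"] = dataclasses.replace(SyntheticCohortSpec(), **sim)
    return RunConfig(**kwargs)
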