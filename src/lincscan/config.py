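"""One-document run configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .coexpression import NetworkConfig
from .synthetic_data import SimulationConfig


@dataclass
class RunConfig:
    """Every pipeline threshold in one place.

    Defaults: 200 bp minimum length, 100 aa ORF ceiling, 500 bp gene flank,
    1e-5 housekeeping E-value, 0.95 clustering identity, FPKM >= 1 expressed
    rule, tau > 0.95 tissue specificity, FPKM >= 5 "moderate and high",
    module-trait |rho| >= 0.6 at p < 0.01, per-gene FDR 0.05, 5% hubs,
    10 kb neighbor window.
    """

    seed: int = 0
    min_length: int = 200
    orf_max: int = 100
    flank_bp: int = 500
    hk_evalue: float = 1e-5
    cluster_identity: float = 0.95
    min_fpkm: float = 1.0
    tau_threshold: float = 0.95
    hi_fpkm: float = 5.0
    neighbor_window: int = 10_000
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        # one seed governs every stochastic stage
        self.simulation.seed = self.seed

    def to_yaml(self, path) -> None:
        def _plain(obj):
            if isinstance(obj, (list, tuple)):
                return [_plain(x) for x in obj]
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        own = {f.name for f in fields(cls)}
        unknown = set(doc) - own
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(doc)
        if "simulation" in kwargs:
            sim = dict(kwargs["simulation"])
            sim_fields = {f.name for f in fields(SimulationConfig)}
            bad = set(sim) - sim_fields
            if bad:
                raise ValueError(f"unknown simulation keys: {sorted(bad)}")
            if "module_spec" in sim:
                sim["module_spec"] = tuple(tuple(x) for x in sim["module_spec"])
            if "tissue_panel" in sim:
                sim["tissue_panel"] = tuple(sim["tissue_panel"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "network" in kwargs:
            net = dict(kwargs["network"])
            net_fields = {f.name for f in fields(NetworkConfig)}
            bad = set(net) - net_fields
            if bad:
                raise ValueError(f"unknown network keys: {sorted(bad)}")
            kwargs["network"] = NetworkConfig(**net)
        return cls(**kwargs)
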