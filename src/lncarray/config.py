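"""Run configuration: thresholds, input paths, seed; YAML-backed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .core import LncArrayError


@dataclass
class RunConfig:
    """All thresholds and paths a pipeline run depends on.

    Defaults are the reference analysis thresholds: candidate length floor
    200 nt, screening cut p < 0.001 on both tests, |tau| > 0.25, DE caller
    p < 0.05 with median fold change > 1.3 and >= 3 replicates beyond the
    control median, +/-10 kb neighbor window, enrichment >= 2 at p < 0.01.
    """

    seed: int = 0
    restrict: str = "non_mna"
    min_length: int = 200
    p_screen: float = 0.001
    tau_min: float = 0.25
    cut_on: str = "raw"
    p_de: float = 0.05
    fc_min: float = 1.3
    min_reps: int = 3
    window: int = 10_000
    p_go: float = 0.01
    min_enrichment: float = 2.0
    n_components: int = 3
    cutoffs_nt: tuple | None = None   # fixed class cutoffs; fitted when None
    delta_grid: tuple = (0.0, 4.0, 30)  # (start, stop, num) for NSC shrinkage
    folds: int = 10
    inputs: dict = field(default_factory=dict)
    outdir: str = "results"

    def __post_init__(self):
        checks = [
            (self.min_length >= 1, "min_length >= 1"),
            (0 < self.p_screen <= 1, "p_screen in (0, 1]"),
            (0 <= self.tau_min <= 1, "tau_min in [0, 1]"),
            (0 < self.p_de <= 1, "p_de in (0, 1]"),
            (self.fc_min >= 1, "fc_min >= 1"),
            (self.min_reps >= 1, "min_reps >= 1"),
            (self.window >= 0, "window >= 0"),
            (0 < self.p_go <= 1, "p_go in (0, 1]"),
            (self.min_enrichment >= 0, "min_enrichment >= 0"),
            (self.restrict in ("all", "non_mna"), "restrict in {all, non_mna}"),
            (self.cut_on in ("raw", "q"), "cut_on in {raw, q}"),
            (self.n_components in (1, 2, 3), "n_components in {1, 2, 3}"),
            (self.folds >= 2, "folds >= 2"),
        ]
        for ok, rule in checks:
            if not ok:
                raise LncArrayError(f"config violates {rule}")
        if self.cutoffs_nt is not None:
            self.cutoffs_nt = tuple(float(c) for c in self.cutoffs_nt)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise LncArrayError(f"unknown config keys: {sorted(unknown)}")
        if "delta_grid" in data:
            data["delta_grid"] = tuple(data["delta_grid"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
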