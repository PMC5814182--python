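"""Run configuration: every tunable of the pipeline in one flat, validated record.

The two values the method itself fixes are the discordance distance (a read
pair is "distant" when its ends map to different chromosomes or more than
30 kb apart) and the depth bin size of 1 kb. Everything else is a declared
default, overridable from a YAML config file or CLI flags. Unknown keys are
fatal so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

log = logging.getLogger("mpcin")

#: config keys that must be strictly positive numbers
_POSITIVE = (
    "bin_size",
    "discordance_distance",
    "min_support",
    "cluster_gap",
    "median_insert",
    "insert_sd",
    "window_w",
    "z_threshold",
    "merge_delta",
    "gain_cutoff",
    "loss_cutoff",
    "whole_fraction",
    "partial_min_fraction",
    "snap_distance",
    "chromoplexy_min_junctions",
    "locus_merge_distance",
    "permutations",
)


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run.

    Distances are in bases, copy numbers on the diploid (2N) scale.
    """

    # -- core detection parameters
    bin_size: int = 1000                 # depth bin width
    discordance_distance: int = 30000    # strict '>' rule for distant pairs
    min_support: int = 3                 # fragments needed to call a junction
    cluster_gap: int = 6000              # single-linkage gap, 2x median insert
    median_insert: int = 3000            # library insert median (toy scale)
    insert_sd: int = 300                 # library insert standard deviation
    expected_orientation: str = "innie"  # concordant pair orientation

    # -- copy-number stage
    window_w: int = 20                   # sliding-window half-width, in bins
    z_threshold: float = 5.0             # Welch-z needed for a changepoint
    merge_delta: float = 0.3             # merge adjacent segments closer than this (CN)
    gain_cutoff: float = 2.5             # cn >= cutoff -> gain (diploid baseline)
    loss_cutoff: float = 1.5             # cn <= cutoff -> loss
    whole_fraction: float = 0.95         # fraction of bins for a whole-chromosome call
    partial_min_fraction: float = 0.05   # min variant-segment fraction for a partial call
    snap_distance: int = 10000           # boundary-to-junction snapping radius
    panel_min_ratio: float = 0.2         # mask bins where the panel ratio drops below this
    allosome_copies: int = 1             # expected X/Y copies (male baseline)

    # -- chromoplexy stage
    chromoplexy_min_junctions: int = 4
    locus_merge_distance: int = 50000

    # -- signature stage
    permutations: int = 2000             # sign-flip permutations (B)

    # -- run plumbing
    seed: int = 0
    genome: str | None = None            # genome JSON (lengths, GC track, transgenes)
    fragments: str | None = None         # sample BEDPE
    panel: list[str] = field(default_factory=list)   # normal-sample BEDPEs
    expression: str | None = None        # counts TSV (genes x samples)
    manifest: str | None = None          # sample manifest TSV
    gene_list: str | None = None         # signature gene list (one symbol per line)
    outdir: str | None = None

    def __post_init__(self) -> None:
        for key in _POSITIVE:
            value = getattr(self, key)
            if not value > 0:
                raise ValueError(f"config parameter {key!r} must be positive, got {value!r}")
        if self.expected_orientation not in ("innie", "outie"):
            raise ValueError(
                f"expected_orientation must be 'innie' or 'outie', got {self.expected_orientation!r}"
            )
        if not self.loss_cutoff < 2 < self.gain_cutoff:
            raise ValueError(
                f"need loss_cutoff < 2 < gain_cutoff, got {self.loss_cutoff}/{self.gain_cutoff}"
            )

    # ------------------------------------------------------------------
    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        """Build a config from a mapping; unknown keys are an error."""
        known = set(cls.field_names())
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML key/value config file, apply defaults, echo the result.

    An empty file yields pure defaults (discordance_distance=30000,
    bin_size=1000, ...). Unknown keys raise rather than being ignored.
    """
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a key/value mapping")
    cfg = RunConfig.from_dict(data)
    log.info("effective config: %s", cfg.to_dict())
    return cfg
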