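"""Run configuration: one structured file holding every stage's parameters."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InvalidParameterError

_STAGE_DEFAULTS: dict[str, dict] = {
    "simulate": dict(
        length=40_000_000,
        arm_boundary=18_000_000,
        n_genes=400,
        density_gradient=1.0,
        coverage=9.0,
        insert_mean=130_000,
        purity=0.9,
        mean_tags_per_bac=20.6,
        dropout=0.02,
        n_markers=120,
        n_rh_lines=355,
        mean_breaks=8.0,
        retention_r=0.25,
        # the per-line break distribution of a real gamma-irradiated panel is
        # a modelling choice; the Poisson default is flagged here on purpose
        break_distribution="poisson",
    ),
    "assemble": dict(
        gel_length_G=None,  # default: simulated tag-universe size
        cb_unit=None,  # default: simulated site spacing
        from_end=12,
        initial_cutoff_exponent=-75,
        final_cutoff_exponent=-12,
        step_exponent=5,
        dq_fraction=0.10,
        dq_step=3,
        low_factor=0.3,
        high_factor=2.5,
    ),
    "screen": dict(margin=4, fraction=0.66, min_members=3, containment=0.8),
    "rhmap": dict(lod_min=4.0, d_max_cR=100.0, epsilon=0.0),
    "integrate": dict(gap_cR=50.0),
    "compare": dict(min_block_size=3, translocation_offset=5e6, identity=0.98),
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "wgpmap_out"
    simulate: dict = field(default_factory=dict)
    assemble: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    rhmap: dict = field(default_factory=dict)
    integrate: dict = field(default_factory=dict)
    compare: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stage, defaults in _STAGE_DEFAULTS.items():
            block = dict(defaults)
            overrides = getattr(self, stage)
            unknown = set(overrides) - set(defaults)
            if unknown:
                raise InvalidParameterError(
                    f"unknown keys in stage {stage!r}: {sorted(unknown)}"
                )
            block.update(overrides)
            setattr(self, stage, block)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
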