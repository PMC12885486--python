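"""Run configuration shared by the library pipelines and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of one analysis run.

    Defaults fix the canonical study conditions: 15-minute ST windows,
    beta = 1e4 (TI in tiu), frequencies 3-12 Hz, 20 PDF bins, db4 wavelet at
    depth 4, and exclusion of days missing at least 50% of daytime samples.
    """

    timezone: str = "UTC"
    st_minutes: float = 15.0
    beta: float = 1e4
    frequency_set: tuple[int, ...] = tuple(range(3, 13))
    nbins: int = 20
    wavelet_order: int = 4
    depth_j: int = 4
    separation_rule: str = "linear"
    missing_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.frequency_set = tuple(int(f) for f in self.frequency_set)
        if not 2 <= self.wavelet_order <= 10:
            raise ValueError("wavelet_order must be in 2..10")
        if self.separation_rule not in ("linear", "literal"):
            raise ValueError("separation_rule must be 'linear' or 'literal'")

    @property
    def wavelet(self) -> str:
        return f"db{self.wavelet_order}"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frequency_set"] = list(self.frequency_set)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def config_header(config: RunConfig) -> str:
    """Comment block embedding the resolved configuration in output files."""
    lines = [f"# {k}: {v}" for k, v in config.to_dict().items()]
    return "\n".join(["# tremorindex run configuration"] + lines) + "\n"


def write_csv_with_config(df, path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(config_header(config))
        df.to_csv(fh, index=False)
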