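"""Pipeline configuration: validated, YAML round-trippable, hashable."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class FilterConfig:
    band_low: float = 1.0
    band_high: float = 70.0
    notch: float | None = 60.0
    fir_order: int | str = "auto"

    def validate(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("filter band must satisfy 0 < low < high")
        if self.fir_order != "auto" and int(self.fir_order) < 2:
            raise ValueError("fir_order must be 'auto' or an integer >= 2")


@dataclass
class SymbolConfig:
    """Symbolization/embedding parameters: TE runs on words of ``m`` tercile
    symbols (m = 1 means the symbols themselves) with Markov orders k, l."""

    m: int = 1
    tau: int = 1
    k: int = 1
    l: int = 1

    def validate(self) -> None:
        if self.m < 1 or self.tau < 1 or self.k < 1 or self.l < 1:
            raise ValueError("symbolization parameters must be positive integers")


@dataclass
class DmstConfig:
    mode: str = "literal"
    root: str | int = "random"
    seed: int = 7

    def validate(self) -> None:
        if self.mode not in ("literal", "negate"):
            raise ValueError("dmst mode must be 'literal' or 'negate'")


@dataclass
class SpectrumConfig:
    """theta is the grid cell size on the (default z-scored) eigenvalue
    scale: 0.5 = one cell per half standard deviation."""

    theta: float = 0.5
    normalize: bool = True

    def validate(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")


@dataclass
class SdssConfig:
    draws: int = 1000
    group_size: int | None = None
    seed: int = 42

    def validate(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1")


@dataclass
class SyntheticConfig:
    participants: int = 10
    runs: int = 3
    separability: float = 1.0
    density: float = 0.03
    spectral_radius: float = 0.95
    task_gain: float = 1.5
    n_channels: int = 64
    protocol_events: int | None = None
    seed: int = 42

    def validate(self) -> None:
        if self.participants < 2:
            raise ValueError("need at least 2 synthetic participants")
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")


@dataclass
class PipelineConfig:
    """Everything a full run needs; every stage seed is explicit."""

    data_dir: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    symbols: SymbolConfig = field(default_factory=SymbolConfig)
    dmst: DmstConfig = field(default_factory=DmstConfig)
    spectrum: SpectrumConfig = field(default_factory=SpectrumConfig)
    sdss: SdssConfig = field(default_factory=SdssConfig)
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)

    def validate(self) -> None:
        if self.data_dir is None and self.synthetic is None:
            raise ValueError("config needs a data_dir or a synthetic block")
        self.filter.validate()
        self.symbols.validate()
        self.dmst.validate()
        self.spectrum.validate()
        self.sdss.validate()
        if self.synthetic is not None:
            self.synthetic.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, blob):
            if blob is None:
                return None
            known = {f.name for f in fields(klass)}
            unknown = set(blob) - known
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            return klass(**blob)

        cfg = cls(
            data_dir=raw.get("data_dir"),
            filter=build(FilterConfig, raw.get("filter", {})) or FilterConfig(),
            symbols=build(SymbolConfig, raw.get("symbols", {})) or SymbolConfig(),
            dmst=build(DmstConfig, raw.get("dmst", {})) or DmstConfig(),
            spectrum=build(SpectrumConfig, raw.get("spectrum", {})) or SpectrumConfig(),
            sdss=build(SdssConfig, raw.get("sdss", {})) or SdssConfig(),
            synthetic=build(SyntheticConfig, raw.get("synthetic"))
            if "synthetic" in raw
            else SyntheticConfig(),
        )
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
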