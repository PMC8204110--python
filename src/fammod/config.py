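"""Pipeline configuration: a flat ``key: value`` text format.

One option per line, ``key: value``; blank lines and ``#`` comments are
ignored.  The format round-trips losslessly (typed fields are parsed back
to their declared types), and the serialized text is what the run manifest
hashes, so a config file pins a run completely.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    # input tables
    meta: str = ""
    scg_counts: str = ""
    ani: str = ""
    alignment: str = ""
    rp_scaffolds: str = ""
    hits: str = ""
    subfamily_map: str = ""
    bacterial_hits: str = ""
    bacterial_meta: str = ""
    out_dir: str = "fammod_out"
    # thresholds (study defaults)
    evalue: float = 0.001
    cutoff: float = 0.95
    min_module_size: int = 20
    linkage: str = "complete"
    ani_threshold: float = 95.0
    min_completeness: float = 70.0
    max_contamination: float = 10.0
    min_aln_coverage: float = 0.5
    min_scgs: int = 22
    max_scg_duplicated: int = 4
    breadth_min_fraction: float = 1.0 / 3.0
    purity: float = 1.0
    # randomness lives entirely in the synthetic generator; the analysis path
    # is deterministic, so no stage reads this.  Kept so a config file can pin
    # the generator that produced its inputs.
    seed: int = 0

    def __post_init__(self):
        checks = [
            (0 < self.evalue, "evalue must be positive"),
            (0 <= self.cutoff <= 1, "cutoff must be in [0, 1]"),
            (self.min_module_size >= 1, "min_module_size must be >= 1"),
            (self.linkage in ("complete", "average"), "linkage must be complete|average"),
            (0 <= self.ani_threshold <= 100, "ani_threshold must be a percent"),
            (0 <= self.min_completeness <= 100, "min_completeness must be a percent"),
            (0 <= self.max_contamination <= 100, "max_contamination must be a percent"),
            (0 <= self.min_aln_coverage <= 1, "min_aln_coverage must be a fraction"),
            (0 <= self.breadth_min_fraction <= 1, "breadth_min_fraction must be a fraction"),
            (0 < self.purity <= 1, "purity must be in (0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_text(self) -> str:
        lines = [f"{f.name}: {getattr(self, f.name)}" for f in fields(self)]
        return "\n".join(lines) + "\n"

    def to_file(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_text())
        return path

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        kwargs = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"line {lineno}: expected 'key: value', got {raw!r}")
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"line {lineno}: unknown option {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return cls.from_text(path.read_text())
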