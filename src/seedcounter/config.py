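"""Run configuration: every tunable of the pipeline in one flat key-value
file (YAML), with documented defaults and lossless round-tripping.

Keys are ``<section>.<field>`` flattened into a nested mapping with the
sections ``paper``, ``sheet`` (detector), ``segmentation``, and ``output``.
Unknown keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .geometry import PaperSpec, SheetDetectConfig
from .segmentation import SegmentationConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Aggregate pipeline configuration."""

    paper: PaperSpec = field(default_factory=lambda: PaperSpec.from_string("a4"))
    sheet: SheetDetectConfig = field(default_factory=SheetDetectConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    output_tsv: bool = True
    output_xml: bool = False
    verbosity: str = "INFO"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "paper": {
                "name": self.paper.name,
                "width_mm": self.paper.width_mm,
                "height_mm": self.paper.height_mm,
            },
            "sheet": dataclasses.asdict(self.sheet),
            "segmentation": dataclasses.asdict(self.segmentation),
            "output": {
                "tsv": self.output_tsv,
                "xml": self.output_xml,
                "verbosity": self.verbosity,
                "seed": self.seed,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known_sections = {"paper", "sheet", "segmentation", "output"}
        unknown = set(data) - known_sections
        if unknown:
            raise ParameterError(f"unknown config sections: {sorted(unknown)}")
        cfg = cls()
        if "paper" in data:
            p = dict(data["paper"])
            extra = set(p) - {"name", "width_mm", "height_mm"}
            if extra:
                raise ParameterError(f"unknown paper keys: {sorted(extra)}")
            if "width_mm" in p:
                cfg.paper = PaperSpec(
                    p.get("name", "custom"), float(p["width_mm"]), float(p["height_mm"])
                )
            else:
                cfg.paper = PaperSpec.from_string(p["name"])
        for section, target_cls, attr in (
            ("sheet", SheetDetectConfig, "sheet"),
            ("segmentation", SegmentationConfig, "segmentation"),
        ):
            if section in data:
                fields = {f.name for f in dataclasses.fields(target_cls)}
                extra = set(data[section]) - fields
                if extra:
                    raise ParameterError(
                        f"unknown {section} keys: {sorted(extra)}"
                    )
                setattr(cfg, attr, target_cls(**data[section]))
        if "output" in data:
            out = dict(data["output"])
            extra = set(out) - {"tsv", "xml", "verbosity", "seed"}
            if extra:
                raise ParameterError(f"unknown output keys: {sorted(extra)}")
            cfg.output_tsv = bool(out.get("tsv", cfg.output_tsv))
            cfg.output_xml = bool(out.get("xml", cfg.output_xml))
            cfg.verbosity = str(out.get("verbosity", cfg.verbosity))
            cfg.seed = int(out.get("seed", cfg.seed))
        return cfg

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
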