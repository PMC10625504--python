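"""One YAML file for the whole pipeline: generator, preprocessing,
feature, SVM and CV settings.  Every section is optional; omitted keys
keep the package defaults.  The loaded configuration is echoed verbatim
into results manifests for provenance.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .classify import SVMConfig
from .evaluate import DEFAULT_T_GRID
from .features import DEFAULT_N_COEFFS
from .preprocess import PreprocessParams
from .synthkin import GeneratorConfig

__all__ = ["PipelineConfig", "load_config", "dump_default_config"]


@dataclasses.dataclass
class PipelineConfig:
    generator: GeneratorConfig
    preprocess: PreprocessParams
    svm: SVMConfig
    cv: dict[str, Any]
    n_coefficients: int
    T_grid: tuple

    def as_dict(self) -> dict:
        return {
            "generator": dataclasses.asdict(self.generator),
            "preprocess": dataclasses.asdict(self.preprocess),
            "svm": dataclasses.asdict(self.svm),
            "cv": dict(self.cv),
            "n_coefficients": self.n_coefficients,
            "T_grid": list(self.T_grid),
        }


def _build(cls, section: dict | None, **overrides):
    kwargs = dict(section or {})
    kwargs.update(overrides)
    if cls is GeneratorConfig and "duration_range_ms" in kwargs:
        kwargs["duration_range_ms"] = tuple(kwargs["duration_range_ms"])
    return cls(**kwargs)


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML (or defaults if ``path`` is None).

    ``seed``, when given, overrides the generator and CV seeds.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    gen_overrides = {} if seed is None else {"seed": seed}
    cv = dict(raw.get("cv") or {})
    if seed is not None:
        cv["seed"] = seed
    cv.setdefault("repetitions", 10)
    cv.setdefault("seed", 0)
    return PipelineConfig(
        generator=_build(GeneratorConfig, raw.get("generator"), **gen_overrides),
        preprocess=_build(PreprocessParams, raw.get("preprocess")),
        svm=_build(SVMConfig, raw.get("svm")),
        cv=cv,
        n_coefficients=int(raw.get("n_coefficients", DEFAULT_N_COEFFS)),
        T_grid=tuple(raw.get("T_grid", DEFAULT_T_GRID)),
    )


def dump_default_config(path: str | Path) -> None:
    """Write a fully populated default config file (a starting template)."""
    cfg = load_config(None)
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=False))
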