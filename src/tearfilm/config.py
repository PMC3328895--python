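"""Declarative run configuration with YAML round-trip.

Every run logs its fully resolved configuration so the many conventions
left open by the problem statement (grayscale weights, lowpass sigma,
filter-bank tilings, quantisation depth, CV seed, α) are pinned and
reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    colour: dict = field(default_factory=lambda: {
        "gray_weights": [0.299, 0.587, 0.114],   # ITU-R BT.601 luma
        "white_point": "D65",
        "lowpass_sigma": 2.0,
    })
    roi: dict = field(default_factory=lambda: {
        "template_sizes": [[32, 96], [48, 144], [64, 192]],
        "band_frac": 0.35,
    })
    texture: dict = field(default_factory=lambda: {
        "butterworth_bands": 9,
        "butterworth_order": 2,
        "butterworth_n_bins": 16,
        "glcm_levels": 32,
        "gabor_frequencies": [0.0625, 0.125, 0.25, 0.375],
        "gabor_orientations_deg": [0, 45, 90, 135],
    })
    classification: dict = field(default_factory=lambda: {
        "folds": 10,
        "seed": 20120405,
        "svm_C_grid": [0.1, 1.0, 10.0, 100.0, 1000.0],
        "svm_gamma_grid": [1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0],
    })
    stats: dict = field(default_factory=lambda: {
        "alpha": 0.05,
        "lilliefors_mc": 10000,
    })

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, values in raw.items():
            if not hasattr(cfg, section):
                raise ValueError(f"unknown config section {section!r}")
            getattr(cfg, section).update(values or {})
        return cfg
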