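"""Run configuration: preprocessing + retrieval parameters, JSON round-trip.

A short hash of the preprocessing parameters and mask variant is stored in
every index so that a query is never evaluated against features extracted
under different preprocessing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .masks import CENTER_NO_REPEAT, FULL_GRAYSCALE
from .preprocess import PreprocessConfig
from .retrieval import RetrievalConfig


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce an index + query run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    retrieval: RetrievalConfig = field(default_factory=RetrievalConfig)
    mask_variant: str = CENTER_NO_REPEAT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mask_variant not in (CENTER_NO_REPEAT, FULL_GRAYSCALE):
            raise ValueError(f"unknown mask_variant {self.mask_variant!r}")

    def to_dict(self) -> dict:
        return {
            "preprocess": asdict(self.preprocess),
            "retrieval": asdict(self.retrieval),
            "mask_variant": self.mask_variant,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            preprocess=PreprocessConfig(**d.get("preprocess", {})),
            retrieval=RetrievalConfig(**d.get("retrieval", {})),
            mask_variant=d.get("mask_variant", CENTER_NO_REPEAT),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    def feature_config_hash(self) -> str:
        """Hash of the parameters that determine extracted features.

        Covers preprocessing and the mask variant; retrieval thresholds do
        not affect stored features and are excluded.
        """
        payload = json.dumps(
            {"preprocess": asdict(self.preprocess), "mask_variant": self.mask_variant},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
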