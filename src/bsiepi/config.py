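"""Run configuration: table paths, window constants, lexicon override.

The window constants default to the surveillance rules' values — a 2-day
episode span, a 5-day contamination repeat-growth screen, 30-day
healthcare-association and reference-attachment windows, and a 365-day
incident lookback — and must be positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import DEFAULT_LEXICON, OrganismLexicon

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    cultures: Path | None = None
    contacts: Path | None = None
    assessments: Path | None = None
    followup: Path | None = None
    episode_span_days: int = 2
    contamination_window_days: int = 5
    hca_window_days: int = 30
    attachment_window_days: int = 30
    incident_lookback_days: int = 365
    lexicon: OrganismLexicon = field(default_factory=lambda: DEFAULT_LEXICON)
    output_dir: Path = Path(".")
    verbosity: str = "INFO"

    def validate(self) -> None:
        for name in (
            "episode_span_days",
            "contamination_window_days",
            "hca_window_days",
            "attachment_window_days",
            "incident_lookback_days",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")

    @property
    def windows(self) -> dict[str, int]:
        return {
            "episode_span_days": self.episode_span_days,
            "contamination_window_days": self.contamination_window_days,
            "hca_window_days": self.hca_window_days,
            "attachment_window_days": self.attachment_window_days,
            "incident_lookback_days": self.incident_lookback_days,
        }


def lexicon_from_dict(data: dict) -> OrganismLexicon:
    """Build a commensal lexicon from a config mapping.

    Keys (each optional, replacing the default set entirely when present):
    ``genus_prefixes``, ``exact_labels``, ``species_labels``.
    """
    kwargs = {}
    if "genus_prefixes" in data:
        kwargs["genus_prefixes"] = tuple(s.strip().lower() for s in data["genus_prefixes"])
    if "exact_labels" in data:
        kwargs["exact_labels"] = frozenset(s.strip().lower() for s in data["exact_labels"])
    if "species_labels" in data:
        kwargs["species_labels"] = frozenset(s.strip().lower() for s in data["species_labels"])
    return OrganismLexicon(**kwargs)


def load_config(path: Path | str) -> RunConfig:
    """Load a YAML (or JSON, a YAML subset) run configuration file."""
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("cultures", "contacts", "assessments", "followup", "output_dir"):
        if key in data and data[key] is not None:
            kwargs[key] = Path(data[key])
    for key in (
        "episode_span_days",
        "contamination_window_days",
        "hca_window_days",
        "attachment_window_days",
        "incident_lookback_days",
        "verbosity",
    ):
        if key in data:
            kwargs[key] = data[key]
    if "lexicon" in data and data["lexicon"]:
        kwargs["lexicon"] = lexicon_from_dict(data["lexicon"])
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg
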