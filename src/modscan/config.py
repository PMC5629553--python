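"""Run configuration shared by the pair-level statistics and the screen."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml


@dataclass
class ScreenConfig:
    """Parameters of a modulator screen.

    fraction
        Fraction of samples assigned to each of the on/off groups when a
        candidate modulator's expression is sorted (top/bottom ``fraction``).
        The per-group size is ``k = floor(fraction * N)``.
    magic_p_max, magic_score_min
        Pair-level thresholds: a gene pair is a modulated edge when its
        MAGIC p-value is below ``magic_p_max`` and its MAGIC score (absolute
        change in adjusted correlation) is at least ``magic_score_min``.
    inverse_mode
        ``"exact"`` inverts the normalizing Fisher transform algebraically;
        ``"verbatim"`` uses the published projection tanh(I)/sqrt(N'-3),
        which saturates at 1/sqrt(N'-3).
    statistic
        ``"signed"`` tests the signed difference of normalized interactions
        (exact two-sample Fisher-z test); ``"magnitude"`` tests
        ||I_on|-|I_off|| (conservative when the two groups disagree in sign).
    n_assigned
        Assigned sample size N' for the inverse projection; ``None`` uses the
        actual per-group size k.
    empirical_cutoff
        Per-parameter cutoff on the permutation empirical p-value; a key
        modulator must pass it for all four parameters.
    n_perm, seed, null_scope
        Permutation-null settings. ``null_scope="shared"`` builds one null
        reused for every candidate; ``"per-modulator"`` rebuilds the null with
        that candidate's own pairs excluded.
    include_modulator_pairs
        Whether pairs touching the candidate modulator itself enter the ACI
        average and edge calling (off by default: selection on the
        modulator's expression distorts its own correlations).
    z_log_scale
        Compute the ranking z-scores on log-transformed parameter values.
    """

    fraction: float = 0.25
    magic_p_max: float = 1e-5
    magic_score_min: float = 0.4
    inverse_mode: str = "exact"
    statistic: str = "signed"
    n_assigned: Optional[float] = None
    empirical_cutoff: float = 1e-4
    n_perm: int = 10_000
    seed: int = 0
    null_scope: str = "shared"
    include_modulator_pairs: bool = False
    z_log_scale: bool = False
    batch_size: int = 64
    n_jobs: int = 1
    genes: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 0.5:
            raise ValueError(f"fraction must be in (0, 0.5], got {self.fraction}")
        if not 0.0 < self.magic_p_max <= 1.0:
            raise ValueError(f"magic_p_max must be in (0, 1], got {self.magic_p_max}")
        if self.magic_score_min < 0.0:
            raise ValueError("magic_score_min must be >= 0")
        if self.inverse_mode not in ("exact", "verbatim"):
            raise ValueError(f"unknown inverse_mode {self.inverse_mode!r}")
        if self.statistic not in ("signed", "magnitude"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.null_scope not in ("shared", "per-modulator"):
            raise ValueError(f"unknown null_scope {self.null_scope!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.empirical_cutoff <= 1.0:
            raise ValueError("empirical_cutoff must be in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["genes"] is not None:
            d["genes"] = list(d["genes"])
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        """Load a configuration from a YAML key/value file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
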