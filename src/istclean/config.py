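"""Run configuration shared by the library and the CLI."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from ._errors import ValidationError

OFFSET_MODES = ("additive", "multiplicative")


@dataclass
class RunConfig:
    """All tunables of a denoising run.

    Attributes
    ----------
    radius_um
        Neighbourhood radius ``d`` in μm (local context and background
        scaling).
    n_hexbins
        Target number of hexagonal bins for the global background estimate.
    alpha_cutoff
        Posterior threshold: a gene count is zeroed when its posterior
        probability of endogenous expression is ``<=`` this value.
    n_restarts
        Number of EM restarts per cell, each with a fresh ``π₀ ~ U(0, 0.5)``.
    offset_mode
        ``"multiplicative"`` (component mean ``x⁺·λ``, default) or
        ``"additive"`` (component mean ``x⁺+λ``).
    seed
        Master seed; per-cell RNG streams are derived from it and the cell
        index, so results are independent of evaluation order.
    min_nonzero_genes
        Cells with fewer non-zero genes than this are passed through
        unfitted (a three-parameter mixture is unidentifiable below it).
    """

    radius_um: float = 50.0
    n_hexbins: int = 200
    alpha_cutoff: float = 0.75
    n_restarts: int = 10
    offset_mode: str = "multiplicative"
    seed: int = 0
    min_nonzero_genes: int = 3

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValidationError(f"radius_um must be positive, got {self.radius_um}")
        if self.n_hexbins < 2:
            raise ValidationError(f"n_hexbins must be >= 2, got {self.n_hexbins}")
        if not 0.0 <= self.alpha_cutoff <= 1.0:
            raise ValidationError(
                f"alpha_cutoff must be in [0, 1], got {self.alpha_cutoff}"
            )
        if self.n_restarts < 1:
            raise ValidationError(f"n_restarts must be >= 1, got {self.n_restarts}")
        if self.offset_mode not in OFFSET_MODES:
            raise ValidationError(
                f"offset_mode must be one of {OFFSET_MODES}, got {self.offset_mode!r}"
            )
        if self.min_nonzero_genes < 0:
            raise ValidationError("min_nonzero_genes must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(
                f"unknown configuration keys: {sorted(unknown)}; "
                f"known keys are {sorted(known)}"
            )
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")
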