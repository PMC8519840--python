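"""Construction of the experimental diet panel.

Diets are aqueous sucrose solutions spiked with an amino-acid (AA) blend.
Each diet is defined by a molar AA:carbohydrate (AA:C) ratio at a fixed
sucrose molarity: a 1:10 diet at 0.5 mol/L sucrose contains 0.05 mol/L total
amino acids.  The blend of individual amino acids is a named mix of
proportions summing to one; the built-in default is an equimolar mix of the
ten essential amino acids used in bumble-bee feeding work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "AAMix",
    "Diet",
    "EQUIMOLAR_AAS",
    "STANDARD_RATIOS",
    "equimolar_mix",
    "normalize_proportions",
    "aa_total_molarity",
    "per_aa_concentrations",
    "build_diet_panel",
    "total_bees",
    "diets_to_frame",
    "load_mix",
    "load_panel_config",
]

#: The ten essential amino acids used in bumble-bee liquid-diet experiments.
EQUIMOLAR_AAS: tuple[str, ...] = (
    "arginine",
    "histidine",
    "isoleucine",
    "leucine",
    "lysine",
    "methionine",
    "phenylalanine",
    "threonine",
    "tryptophan",
    "valine",
)

#: The seven AA:C molar ratios of the study design, from sucrose-only (0:1)
#: to the most AA-rich diet (1:10).
STANDARD_RATIOS: tuple[tuple[int, int], ...] = (
    (0, 1),
    (1, 250),
    (1, 100),
    (1, 75),
    (1, 50),
    (1, 25),
    (1, 10),
)

_PROPORTION_TOL = 1e-9


class InvalidMixError(ValueError):
    """Raised for amino-acid mixes that cannot be normalized."""


class InvalidRatioError(ValueError):
    """Raised for non-positive carbohydrate ratio parts."""


class PanelConfigError(ValueError):
    """Raised for malformed diet-panel configurations (e.g. duplicate ratios)."""


@dataclass(frozen=True)
class AAMix:
    """A named amino-acid blend: proportions over AA labels summing to 1."""

    name: str
    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.proportions:
            raise InvalidMixError("mix must contain at least one amino acid")
        vals = list(self.proportions.values())
        if any(v < 0 for v in vals):
            raise InvalidMixError("mix proportions must be non-negative")
        total = sum(vals)
        if abs(total - 1.0) > _PROPORTION_TOL:
            raise InvalidMixError(
                f"mix proportions must sum to 1 (got {total!r}); "
                "use normalize_proportions() on raw weights"
            )
        object.__setattr__(self, "proportions", dict(self.proportions))


@dataclass(frozen=True)
class Diet:
    """One experimental diet: an AA:C molar ratio realized at a sucrose molarity.

    ``ratio_aa``/``ratio_c`` are kept as the exact integer parts of the design
    ratio (1, 250), never pre-divided, so diet ids stay exact.
    """

    id: str
    ratio_aa: int
    ratio_c: int
    sucrose_molarity: float
    aa_total_molarity: float
    per_aa_molarity: Mapping[str, float]
    mix_name: str

    def __post_init__(self) -> None:
        if self.sucrose_molarity <= 0:
            raise InvalidRatioError("sucrose molarity must be positive")
        expected = aa_total_molarity(self.ratio_aa, self.ratio_c, self.sucrose_molarity)
        if abs(self.aa_total_molarity - expected) > _PROPORTION_TOL:
            raise ValueError(
                "aa_total_molarity inconsistent with ratio and sucrose molarity"
            )
        if abs(sum(self.per_aa_molarity.values()) - self.aa_total_molarity) > _PROPORTION_TOL:
            raise ValueError("per-AA molarities must sum to the total AA molarity")
        object.__setattr__(self, "per_aa_molarity", dict(self.per_aa_molarity))


def equimolar_mix(amino_acids: Sequence[str] = EQUIMOLAR_AAS) -> AAMix:
    """The default blend: every amino acid at the same molar proportion."""
    return normalize_proportions({aa: 1.0 for aa in amino_acids}, name="equimolar")


def normalize_proportions(raw: Mapping[str, float], name: str = "custom") -> AAMix:
    """Scale raw (non-negative) weights so they sum to one.

    Raises :class:`InvalidMixError` on an empty mix, negative weights, or an
    all-zero mix.
    """
    if not raw:
        raise InvalidMixError("mix must contain at least one amino acid")
    if any(w < 0 for w in raw.values()):
        raise InvalidMixError("mix weights must be non-negative")
    total = float(sum(raw.values()))
    if total <= 0:
        raise InvalidMixError("mix weights must not all be zero")
    return AAMix(name=name, proportions={k: v / total for k, v in raw.items()})


def aa_total_molarity(ratio_aa: float, ratio_c: float, sucrose_molarity: float) -> float:
    """Total AA molarity implied by a molar AA:C ratio at a sucrose molarity.

    Ratios are molar: a 1:10 AA:C diet at 0.5 mol/L sucrose has
    0.5 * 1/10 = 0.05 mol/L total amino acids.
    """
    if ratio_c <= 0:
        raise InvalidRatioError("carbohydrate ratio part must be positive")
    if ratio_aa < 0:
        raise InvalidRatioError("AA ratio part must be non-negative")
    if sucrose_molarity <= 0:
        raise InvalidRatioError("sucrose molarity must be positive")
    return sucrose_molarity * ratio_aa / ratio_c


def per_aa_concentrations(total: float, mix: AAMix) -> dict[str, float]:
    """Split a total AA molarity across the mix's amino acids.

    Each amino acid gets ``total * proportion``; the values sum to ``total``.
    """
    if total < 0:
        raise ValueError("total AA molarity must be non-negative")
    return {aa: total * p for aa, p in mix.proportions.items()}


def build_diet_panel(
    ratios: Iterable[tuple[int, int]],
    sucrose_molarity: float = 0.5,
    mix: AAMix | None = None,
) -> list[Diet]:
    """Build one :class:`Diet` per AA:C ratio, ids stable and ordered as given.

    Total solute (AA + C) intentionally varies across the panel; no
    normalization is applied.
    """
    if mix is None:
        mix = equimolar_mix()
    ratios = list(ratios)
    if not ratios:
        raise PanelConfigError("ratio list must be non-empty")
    if len(set(ratios)) != len(ratios):
        raise PanelConfigError(f"duplicate ratios in panel: {ratios}")
    diets = []
    for ratio_aa, ratio_c in ratios:
        total = aa_total_molarity(ratio_aa, ratio_c, sucrose_molarity)
        diets.append(
            Diet(
                id=f"{ratio_aa}:{ratio_c}",
                ratio_aa=ratio_aa,
                ratio_c=ratio_c,
                sucrose_molarity=sucrose_molarity,
                aa_total_molarity=total,
                per_aa_molarity=per_aa_concentrations(total, mix),
                mix_name=mix.name,
            )
        )
    return diets


def total_bees(n_colonies_per_diet: int, bees_per_colony: int, n_diets: int) -> int:
    """Number of bees a design commits: micro-colonies/diet x bees x diets."""
    if min(n_colonies_per_diet, bees_per_colony, n_diets) < 1:
        raise PanelConfigError("design counts must be >= 1")
    return n_colonies_per_diet * bees_per_colony * n_diets


def diets_to_frame(diets: Sequence[Diet]) -> pd.DataFrame:
    """Tabulate a panel in the diets.csv schema."""
    return pd.DataFrame(
        {
            "diet_id": [d.id for d in diets],
            "ratio_aa": [d.ratio_aa for d in diets],
            "ratio_c": [d.ratio_c for d in diets],
            "sucrose_molarity_M": [d.sucrose_molarity for d in diets],
            "aa_total_molarity_M": [d.aa_total_molarity for d in diets],
            "mix_name": [d.mix_name for d in diets],
        }
    )


def load_mix(path: str | Path, name: str | None = None) -> AAMix:
    """Read a two-column (amino_acid, proportion) table and normalize it."""
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python", comment="#")
    if table.shape[1] < 2:
        raise InvalidMixError(f"{path}: expected columns (amino_acid, proportion)")
    raw = dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(float)))
    return normalize_proportions(raw, name=name or path.stem)


def _parse_ratio(text: str) -> tuple[int, int]:
    try:
        a, c = text.split(":")
        return int(a), int(c)
    except ValueError as exc:
        raise PanelConfigError(f"cannot parse ratio {text!r} as 'aa:c'") from exc


def load_panel_config(path: str | Path, mix: AAMix | None = None) -> list[Diet]:
    """Build a panel from a YAML config: sucrose_molarity, ratios ('aa:c'), mix_file."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    ratios = [_parse_ratio(r) for r in cfg["ratios"]]
    if mix is None:
        mix_file = cfg.get("mix_file")
        mix = load_mix(path.parent / mix_file) if mix_file else equimolar_mix()
    return build_diet_panel(ratios, float(cfg.get("sucrose_molarity", 0.5)), mix)
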