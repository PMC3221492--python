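"""Formulation design and the calibration/validation experimental protocol.

The target formulation is a 120 mg tablet containing 12.50 % w/w meloxicam
(15 mg).  Concentration levels are expressed both as percent of the target
formulation (80-120 %) and as percent w/w meloxicam in the blend.  Four
excipients are held fixed; one filler (isomalt by default) compensates so
every blend totals exactly 120 mg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

TOTAL_MG = 120.0

#: per-tablet masses (mg) of the components that do not vary across levels
FIXED_COMPONENTS_MG = {
    "microcrystalline_cellulose": 45.0,
    "sodium_starch_glycolate": 6.0,
    "silicon_dioxide": 1.2,
    "magnesium_stearate": 0.6,
}

COMPONENTS = (
    "meloxicam",
    "isomalt",
    "microcrystalline_cellulose",
    "sodium_starch_glycolate",
    "silicon_dioxide",
    "magnesium_stearate",
)

#: level index -> (percent of target formulation, percent w/w meloxicam)
STANDARD_LEVELS = {
    1: (80.0, 10.00),
    2: (90.0, 11.25),
    3: (100.0, 12.50),
    4: (110.0, 13.75),
    5: (120.0, 15.00),
}


@dataclass(frozen=True)
class BlendComposition:
    """Per-tablet composition of one blend level.

    Attributes
    ----------
    level_pct_of_target:
        Concentration level as percent of the 100 % formulation.
    meloxicam_pct_ww:
        Analyte content, percent w/w of total blend mass.
    masses_mg:
        Component -> mg per tablet.
    total_mg:
        Total tablet mass (always 120.00 mg).
    """

    level_pct_of_target: float
    meloxicam_pct_ww: float
    masses_mg: dict[str, float]
    total_mg: float = TOTAL_MG

    def __post_init__(self) -> None:
        s = sum(self.masses_mg.values())
        if abs(s - self.total_mg) > 1e-9:
            raise ValueError(f"component masses sum to {s}, expected {self.total_mg}")
        if any(m < 0 for m in self.masses_mg.values()):
            raise ValueError("negative component mass")

    def mass_fractions(self) -> dict[str, float]:
        return {c: m / self.total_mg for c, m in self.masses_mg.items()}


def composition_for_level(
    meloxicam_pct_ww: float, compensator: str = "isomalt"
) -> BlendComposition:
    """Build the blend composition for a given meloxicam content.

    The analyte mass is ``1.2 * meloxicam_pct_ww`` mg (total mass 120 mg);
    the compensating filler absorbs the difference so masses sum to 120 mg
    while the remaining components stay fixed.

    Parameters
    ----------
    meloxicam_pct_ww:
        Target meloxicam content in % w/w.  Must leave the compensating
        filler non-negative.
    compensator:
        Which filler absorbs the change; ``"isomalt"`` (default, matching
        the printed compositions) or ``"microcrystalline_cellulose"``.
    """
    fixed_total = sum(FIXED_COMPONENTS_MG.values())  # 52.8 mg
    max_pct = 100.0 * (TOTAL_MG - fixed_total) / TOTAL_MG  # 56 % w/w
    if not 0.0 < meloxicam_pct_ww < max_pct:
        raise ValueError(
            f"meloxicam_pct_ww={meloxicam_pct_ww} out of feasible range "
            f"(0, {max_pct:g}) % w/w for fixed components totalling {fixed_total} mg"
        )
    if compensator == "isomalt":
        fixed = dict(FIXED_COMPONENTS_MG)
    elif compensator == "microcrystalline_cellulose":
        # swap roles: isomalt frozen at its target-formulation mass
        fixed = dict(FIXED_COMPONENTS_MG)
        del fixed["microcrystalline_cellulose"]
        fixed["isomalt"] = 52.2
    else:
        raise ValueError(f"unknown compensator {compensator!r}")

    meloxicam_mg = TOTAL_MG * meloxicam_pct_ww / 100.0
    comp_mg = TOTAL_MG - meloxicam_mg - sum(fixed.values())
    if comp_mg < 0:
        raise ValueError(
            f"compensating filler would be negative ({comp_mg:.3f} mg) "
            f"at {meloxicam_pct_ww} % w/w"
        )
    masses = {"meloxicam": meloxicam_mg, compensator: comp_mg, **fixed}
    masses = {c: masses[c] for c in COMPONENTS}
    level_pct = 100.0 * meloxicam_pct_ww / 12.50
    return BlendComposition(
        level_pct_of_target=level_pct,
        meloxicam_pct_ww=meloxicam_pct_ww,
        masses_mg=masses,
    )


@dataclass(frozen=True)
class ProtocolEntry:
    sample_id: str
    role: str  # "cal" | "val"
    series: int
    replicate: int
    level_index: int
    level_pct_of_target: float
    meloxicam_pct_ww: float


@dataclass
class ProtocolMatrix:
    """Calibration/validation design: replicate counts per (level, series)."""

    levels: list[tuple[int, float, float]]
    calibration_counts: dict[tuple[int, int], int]
    validation_counts: dict[tuple[int, int], int]
    n_series: int

    @property
    def n_calibration(self) -> int:
        return sum(self.calibration_counts.values())

    @property
    def n_validation(self) -> int:
        return sum(self.validation_counts.values())

    def _entries(self, counts: dict[tuple[int, int], int], role: str) -> Iterator[ProtocolEntry]:
        # deterministic ordering: level-major, then series, then replicate
        by_level = {idx: (pct, ww) for idx, pct, ww in self.levels}
        for level_index in sorted(by_level):
            pct, ww = by_level[level_index]
            for series in range(1, self.n_series + 1):
                for rep in range(1, counts.get((level_index, series), 0) + 1):
                    yield ProtocolEntry(
                        sample_id=f"{role}_L{level_index}_S{series}_R{rep}",
                        role=role,
                        series=series,
                        replicate=rep,
                        level_index=level_index,
                        level_pct_of_target=pct,
                        meloxicam_pct_ww=ww,
                    )

    def calibration_entries(self) -> list[ProtocolEntry]:
        return list(self._entries(self.calibration_counts, "cal"))

    def validation_entries(self) -> list[ProtocolEntry]:
        return list(self._entries(self.validation_counts, "val"))

    def to_manifest(self) -> pd.DataFrame:
        """Flat CSV-ready manifest with one row per protocol sample."""
        rows = []
        for e in self.calibration_entries() + self.validation_entries():
            comp = composition_for_level(e.meloxicam_pct_ww)
            row = {
                "sample_id": e.sample_id,
                "role": e.role,
                "series": e.series,
                "level_index": e.level_index,
                "level_pct_of_target": e.level_pct_of_target,
                "meloxicam_pct_ww": e.meloxicam_pct_ww,
            }
            row.update({f"{c}_mg": m for c, m in comp.masses_mg.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def build_protocol(
    n_series: int = 3,
    val_levels: set[int] | frozenset[int] = frozenset({1, 3, 5}),
    val_reps: int = 4,
) -> ProtocolMatrix:
    """Build the default design: 1 calibration sample per (level, series)
    over 5 levels, plus ``val_reps`` validation replicates per series at
    ``val_levels``.

    Defaults give 15 calibration and 36 validation samples.
    """
    if n_series < 2:
        raise ValueError("n_series must be >= 2 (variance components need replication)")
    if val_reps < 2:
        raise ValueError("val_reps must be >= 2 (variance components need replication)")
    val_levels = set(val_levels)
    if not val_levels <= set(STANDARD_LEVELS):
        raise ValueError(f"val_levels {val_levels} not a subset of {set(STANDARD_LEVELS)}")

    levels = [(i, pct, ww) for i, (pct, ww) in sorted(STANDARD_LEVELS.items())]
    cal = {
        (lvl, s): 1 for lvl in STANDARD_LEVELS for s in range(1, n_series + 1)
    }
    val = {
        (lvl, s): (val_reps if lvl in val_levels else 0)
        for lvl in STANDARD_LEVELS
        for s in range(1, n_series + 1)
    }
    return ProtocolMatrix(
        levels=levels, calibration_counts=cal, validation_counts=val, n_series=n_series
    )
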