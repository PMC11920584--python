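"""Root biomass and density bookkeeping.

Reconstructed volumes are nondestructive; wet/dry masses come from
destructive endpoint measurements on a calibration cohort.  Dividing wet
mass (g) by reconstructed volume (mL) gives an apparent root density
(g/mL) per plant; averaged over the cohort this calibrates subsequent
volume-only measurements to biomass.  Since roots are ~96% water and sink,
the apparent density also serves as a sanity check on the reconstruction —
values far below water's 0.997 g/mL indicate volumetric overestimation.

The longitudinal radish calibration table (18 plants, imaged in triplicate
every 5 days over 30 days; two failed reconstructions) ships as a packaged
CSV fixture, :func:`radish_calibration_table`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RootcarveError, UndefinedDensityError, ValidationError

__all__ = [
    "PlantRecord",
    "density",
    "percent_water",
    "summarize",
    "load_records",
    "records_to_frame",
    "radish_calibration_table",
    "DISPLAY_DECIMALS",
]

#: Densities and volumes are displayed at 3 decimals; computation is exact.
DISPLAY_DECIMALS = 3


@dataclass(frozen=True)
class PlantRecord:
    """One plant's measurements: reconstruction volume + endpoint masses."""

    root_id: int
    days_elapsed: int
    wet_mass_g: float
    volume_mL: float | None = None
    dry_mass_g: float | None = None
    pct_water: float | None = None

    def __post_init__(self) -> None:
        if self.wet_mass_g < 0:
            raise ValidationError("wet mass must be >= 0")
        if self.dry_mass_g is not None and self.dry_mass_g < 0:
            raise ValidationError("dry mass must be >= 0")

    @property
    def density_g_per_mL(self) -> float | None:
        if self.volume_mL is None or self.volume_mL <= 0:
            return None
        return self.wet_mass_g / self.volume_mL


def density(wet_mass_g: float, volume_mL: float) -> float:
    """Apparent root density, wet mass / reconstructed volume (g/mL).

    Raises :class:`UndefinedDensityError` for non-positive volume (failed
    reconstructions have no density).
    """
    if volume_mL is None or not np.isfinite(volume_mL) or volume_mL <= 0:
        raise UndefinedDensityError("density undefined without a positive volume")
    return wet_mass_g / volume_mL


def percent_water(wet_g: float, dry_g: float) -> float:
    """Water content by mass, 100 * (wet - dry) / wet."""
    if wet_g <= 0:
        raise ValidationError("wet mass must be positive")
    if dry_g < 0 or dry_g > wet_g:
        raise ValidationError("need 0 <= dry <= wet")
    return 100.0 * (wet_g - dry_g) / wet_g


@dataclass(frozen=True)
class DensityReport:
    """Cohort summary: overall mean density + per-timepoint aggregates."""

    mean_density_g_per_mL: float
    by_timepoint: pd.DataFrame
    n_records: int
    n_failed: int
    densities: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        self.by_timepoint.to_csv(path, index=False)

    def format_table(self) -> str:
        lines = [
            f"plants: {self.n_records}  failed reconstructions: {self.n_failed}",
            f"mean density: {self.mean_density_g_per_mL:.{DISPLAY_DECIMALS}f} g/mL",
            "",
            self.by_timepoint.to_string(index=False),
        ]
        return "\n".join(lines)


def summarize(records: list[PlantRecord]) -> DensityReport:
    """Aggregate a cohort into the density report.

    The overall mean is the unweighted arithmetic mean of per-plant
    densities (full precision).  Records without a usable volume are
    excluded from density statistics but counted as failures.
    """
    if not records:
        raise RootcarveError("no records to summarize")
    dens = [r.density_g_per_mL for r in records]
    ok = [d for d in dens if d is not None]
    if not ok:
        raise RootcarveError("no record has a reconstructed volume")
    rows = []
    for day in sorted({r.days_elapsed for r in records}):
        grp = [r for r in records if r.days_elapsed == day]
        g_ok = [r for r in grp if r.density_g_per_mL is not None]
        rows.append(
            {
                "days_elapsed": day,
                "n": len(grp),
                "mean_volume_mL": np.mean([r.volume_mL for r in g_ok]) if g_ok else np.nan,
                "mean_wet_mass_g": np.mean([r.wet_mass_g for r in grp]),
                "mean_density_g_per_mL": np.mean([r.density_g_per_mL for r in g_ok]) if g_ok else np.nan,
            }
        )
    return DensityReport(
        mean_density_g_per_mL=float(np.mean(ok)),
        by_timepoint=pd.DataFrame(rows),
        n_records=len(records),
        n_failed=sum(d is None for d in dens),
        densities=np.array(ok),
    )


def _record_from_row(row: pd.Series) -> PlantRecord:
    vol = row.get("volume_mL")
    return PlantRecord(
        root_id=int(row["root_id"]),
        days_elapsed=int(row["days_elapsed"]),
        wet_mass_g=float(row["wet_mass_g"]),
        volume_mL=None if pd.isna(vol) else float(vol),
        pct_water=float(row["pct_water"]) if "pct_water" in row and not pd.isna(row["pct_water"]) else None,
    )


def records_from_frame(df: pd.DataFrame) -> list[PlantRecord]:
    """Build records from a DataFrame with the calibration-table columns."""
    required = {"root_id", "days_elapsed", "wet_mass_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            records.append(_record_from_row(row))
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"row {i + 2}: {exc}") from exc
    return records


def load_records(path: str | Path) -> list[PlantRecord]:
    """Read plant records from a CSV with the calibration-table columns."""
    return records_from_frame(pd.read_csv(path))


def records_to_frame(records: list[PlantRecord]) -> pd.DataFrame:
    """Records as a DataFrame with densities rounded for display."""
    rows = []
    for r in records:
        d = r.density_g_per_mL
        rows.append(
            {
                "root_id": r.root_id,
                "days_elapsed": r.days_elapsed,
                "volume_mL": r.volume_mL,
                "wet_mass_g": r.wet_mass_g,
                "density_g_per_mL": None if d is None else round(d, DISPLAY_DECIMALS),
                "pct_water": r.pct_water,
            }
        )
    return pd.DataFrame(rows)


def radish_calibration_table() -> pd.DataFrame:
    """The packaged 18-plant radish calibration table."""
    ref = importlib.resources.files("rootcarve.data") / "radish_table1.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
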