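"""CSV readers and writers for the pipeline's delimited-text interfaces.

All files are UTF-8 with '.' decimal separators and a mandatory header
row. Schemas:

* profiles: ``lake_id,date,depth_m,temp_c,o2_umol_l,ch4_umol_l[,par]``
* hypsography: ``lake_id,depth_m,area_m2``
* CH4 incubations: ``flask_id,time_d,ch4_umol_l``
* O2 incubations: ``flask_id,time_h,o2_mg_l``
* censuses: ``sample_id,group,field_id,cell_area_um2``
* rates: ``sample_id,layer,mcc_ugC_l_d,hbp_ugC_l_d,hbr_ugC_l_d,hcc_ugC_l_d,k_d,r2,qc_pass``
* budgets: ``lake_id,date,total_mcc_gC_d,total_hcc_gC_d,fraction_methanotrophy_pct,anoxic_vol_frac,vol_frac_ratio_gt_0.6``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .census import CellCensus
from .column import ColumnBudget, DepthProfile, Hypsography
from .errors import InvalidDataError
from .incubations import IncubationSeries


def profiles_to_frame(profiles: list[DepthProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        df = pd.DataFrame(
            {
                "lake_id": p.lake_id,
                "date": p.date,
                "depth_m": p.depth,
                "temp_c": p.temp,
                "o2_umol_l": p.o2,
                "ch4_umol_l": p.ch4,
            }
        )
        if p.par is not None:
            df["par"] = p.par
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def write_profiles(profiles: list[DepthProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[DepthProfile]:
    df = pd.read_csv(path)
    required = {"lake_id", "date", "depth_m", "temp_c", "o2_umol_l", "ch4_umol_l"}
    if not required <= set(df.columns):
        raise InvalidDataError(f"profile CSV missing columns {sorted(required - set(df.columns))}")
    out = []
    for (lake, date), g in df.groupby(["lake_id", "date"], sort=False):
        g = g.sort_values("depth_m")
        out.append(
            DepthProfile(
                lake_id=str(lake),
                date=str(date),
                depth=g["depth_m"].to_numpy(),
                temp=g["temp_c"].to_numpy(),
                o2=g["o2_umol_l"].to_numpy(),
                ch4=g["ch4_umol_l"].to_numpy(),
                par=g["par"].to_numpy() if "par" in g.columns else None,
            )
        )
    return out


def write_hypsographies(hypsos: list[Hypsography], path: str | Path) -> None:
    pd.concat(
        [
            pd.DataFrame({"lake_id": h.lake_id, "depth_m": h.depth, "area_m2": h.area})
            for h in hypsos
        ],
        ignore_index=True,
    ).to_csv(path, index=False)


def read_hypsographies(path: str | Path) -> dict[str, Hypsography]:
    df = pd.read_csv(path)
    out = {}
    for lake, g in df.groupby("lake_id", sort=False):
        g = g.sort_values("depth_m")
        out[str(lake)] = Hypsography(
            lake_id=str(lake), depth=g["depth_m"].to_numpy(), area=g["area_m2"].to_numpy()
        )
    return out


def write_incubation(series: IncubationSeries, path: str | Path) -> None:
    time_col = "time_d" if series.time_unit == "d" else "time_h"
    conc_col = "ch4_umol_l" if series.analyte == "ch4" else "o2_mg_l"
    pd.DataFrame(
        {"flask_id": series.flask_id, time_col: series.time, conc_col: series.conc}
    ).to_csv(path, index=False)


def read_incubation(path: str | Path, sample_id: str | None = None) -> IncubationSeries:
    df = pd.read_csv(path)
    if "ch4_umol_l" in df.columns:
        analyte, conc_col, time_col, unit = "ch4", "ch4_umol_l", "time_d", "d"
    elif "o2_mg_l" in df.columns:
        analyte, conc_col, time_col, unit = "o2", "o2_mg_l", "time_h", "h"
    else:
        raise InvalidDataError("incubation CSV needs a ch4_umol_l or o2_mg_l column")
    return IncubationSeries(
        sample_id=sample_id or Path(path).stem,
        analyte=analyte,
        time=df[time_col].to_numpy(),
        conc=df[conc_col].to_numpy(),
        flask_id=df["flask_id"].to_numpy(),
        time_unit=unit,
    )


def write_census(census: CellCensus, path: str | Path) -> None:
    df = census.cells.copy()
    df.insert(0, "sample_id", census.sample_id)
    df.to_csv(path, index=False)


def read_census(
    path: str | Path,
    n_fields: int,
    filtered_volume_ml: float,
    field_area_fraction: float,
) -> CellCensus:
    df = pd.read_csv(path)
    return CellCensus(
        sample_id=str(df["sample_id"].iloc[0]),
        cells=df[["group", "field_id", "cell_area_um2"]],
        n_fields=n_fields,
        filtered_volume_ml=filtered_volume_ml,
        field_area_fraction=field_area_fraction,
    )


def budgets_to_frame(budgets: list[ColumnBudget]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lake_id": [b.lake_id for b in budgets],
            "date": [b.date for b in budgets],
            "total_mcc_gC_d": [b.total_mcc for b in budgets],
            "total_hcc_gC_d": [b.total_hcc for b in budgets],
            "fraction_methanotrophy_pct": [b.fraction_methanotrophy for b in budgets],
            "anoxic_vol_frac": [b.anoxic_volume_fraction for b in budgets],
            "vol_frac_ratio_gt_0.6": [b.volume_fraction_ratio_above for b in budgets],
        }
    )


def write_budgets(budgets: list[ColumnBudget], path: str | Path) -> None:
    budgets_to_frame(budgets).to_csv(path, index=False)


def frame_bytes(df: pd.DataFrame) -> bytes:
    """Canonical CSV serialization, for byte-for-byte determinism checks."""
    return df.to_csv(index=False, float_format="%.12g").encode()
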