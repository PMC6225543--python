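"""CSV readers and writers for the package's table formats.

All formats are plain long-format CSV:

* chamber series — ``chamber_id,time_h,conc_ppb,height_m,temp_C,pressure_kPa``
* peak tables — ``sample_id,gene,enzyme,size_bp,area,height[,truth_label]``
* flux tables — chamber series columns plus fit results
* emission series — ``plot_id,treatment,year,doy,flux,unit``
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .chamber import ChamberSeries, FluxEstimate
from .emissions import EmissionSeries
from .trflp import Peak, Profile

__all__ = [
    "read_chamber_series",
    "chamber_series_to_frame",
    "read_peak_table",
    "read_emission_series",
    "flux_estimates_to_frame",
]


def chamber_series_to_frame(series: Sequence[ChamberSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for t, c in zip(s.times, s.conc):
            rows.append(
                {
                    "chamber_id": s.chamber_id,
                    "time_h": t,
                    "conc_ppb": c,
                    "height_m": s.height,
                    "temp_C": s.temp_c,
                    "pressure_kPa": s.pressure_kpa,
                }
            )
    return pd.DataFrame(rows)


def read_chamber_series(path_or_df, default_height: float = 0.2) -> list[ChamberSeries]:
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    out = []
    for cid, grp in df.groupby("chamber_id", sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            ChamberSeries(
                chamber_id=str(cid),
                times=grp["time_h"].values,
                conc=grp["conc_ppb"].values,
                height=float(grp["height_m"].iloc[0]) if "height_m" in grp else default_height,
                temp_c=float(grp["temp_C"].iloc[0]) if "temp_C" in grp else 10.0,
                pressure_kpa=float(grp["pressure_kPa"].iloc[0]) if "pressure_kPa" in grp else 101.325,
            )
        )
    return out


def flux_estimates_to_frame(fits: Sequence[FluxEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chamber_id": f.chamber_id,
                "f0": f.f0,
                "se_f0": f.se_f0,
                "model": f.model,
                "kappa": f.kappa,
                "phi": f.phi,
                "residual_sse": f.residual_sse,
                "selection_note": f.selection_note,
            }
            for f in fits
        ]
    )


def read_peak_table(path_or_df) -> list[Profile]:
    """Parse a Peak Scanner-style peak table into Profile objects."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    profiles = []
    for (sid, gene, enzyme), grp in df.groupby(["sample_id", "gene", "enzyme"], sort=True):
        grp = grp.sort_values("size_bp")
        peaks = [
            Peak(
                float(r.size_bp),
                float(r.area),
                float(r.height),
                label=(str(r.truth_label) if "truth_label" in grp.columns else None),
            )
            for r in grp.itertuples()
        ]
        profiles.append(Profile(str(sid), str(gene), str(enzyme), peaks, normalized=False))
    return profiles


def read_emission_series(path_or_df) -> list[EmissionSeries]:
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    out = []
    for (pid, trt, year), grp in df.groupby(["plot_id", "treatment", "year"], sort=True):
        grp = grp.sort_values("doy")
        out.append(
            EmissionSeries(
                plot_id=str(pid),
                treatment=str(trt),
                year=int(year),
                dates=grp["doy"].values,
                fluxes=grp["flux"].values,
                unit=str(grp["unit"].iloc[0]),
            )
        )
    return out
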