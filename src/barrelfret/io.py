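"""Plain-text readers and writers for every data shape in the pipeline.

All files are UTF-8 CSV with a mandatory header row and '.' decimal
separator: spectra (wavelength_nm,intensity), TCSPC decays
(time_ns,counts,irf_counts), transient-absorption maps in long form
(delay_ps,wavelength_nm,delta_mOD), binding titrations
(conc_uM,f_norm,replicate), free-energy profiles
(distance_A,free_energy_kJ_mol,std_kJ_mol) and photolysis time courses
(time_min,f_norm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectra import Spectrum
from .synth import BindingSeries, FreeEnergyProfile, TimeCourse
from .ta import TAMap
from .tcspc import DecayTrace

__all__ = [
    "write_spectrum", "read_spectrum",
    "write_decay", "read_decay",
    "write_ta_map", "read_ta_map",
    "write_titration", "read_titration",
    "write_fes",
    "write_timecourse", "read_timecourse",
]


def write_spectrum(spectrum: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.values}
    ).to_csv(path, index=False)


def read_spectrum(path, kind: str = "emission") -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(), kind=kind)


def write_decay(trace: DecayTrace, path) -> None:
    pd.DataFrame(
        {"time_ns": trace.time, "counts": trace.counts, "irf_counts": trace.irf_counts}
    ).to_csv(path, index=False)


def read_decay(path) -> DecayTrace:
    df = pd.read_csv(path)
    t = df["time_ns"].to_numpy()
    dt = float(np.median(np.diff(t)))
    return DecayTrace(
        time=t,
        counts=df["counts"].to_numpy(),
        irf_counts=df["irf_counts"].to_numpy(),
        channel_width=dt,
    )


def write_ta_map(tamap: TAMap, path) -> None:
    d, w = np.meshgrid(tamap.delays, tamap.wavelengths, indexing="ij")
    pd.DataFrame(
        {
            "delay_ps": d.ravel(),
            "wavelength_nm": w.ravel(),
            "delta_mOD": tamap.delta_mOD.ravel(),
        }
    ).to_csv(path, index=False)


def read_ta_map(path) -> TAMap:
    df = pd.read_csv(path)
    delays = np.unique(df["delay_ps"].to_numpy())
    wavelengths = np.unique(df["wavelength_nm"].to_numpy())
    mat = (
        df.pivot(index="delay_ps", columns="wavelength_nm", values="delta_mOD")
        .sort_index()
        .to_numpy()
    )
    return TAMap(delays, wavelengths, mat)


def write_titration(series_list, path) -> None:
    if isinstance(series_list, BindingSeries):
        series_list = [series_list]
    frames = [
        pd.DataFrame(
            {
                "conc_uM": s.peptide_conc,
                "f_norm": s.f_norm,
                "replicate": s.replicate_id,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_titration(path, ligand_total: float = 0.5) -> list[BindingSeries]:
    df = pd.read_csv(path)
    out = []
    for rep, grp in df.groupby("replicate"):
        out.append(
            BindingSeries(
                grp["conc_uM"].to_numpy(),
                grp["f_norm"].to_numpy(),
                ligand_total=ligand_total,
                replicate_id=int(rep),
            )
        )
    return out


def write_fes(profile: FreeEnergyProfile, path) -> None:
    data = {"distance_A": profile.distance, "free_energy_kJ_mol": profile.free_energy}
    if profile.std is not None:
        data["std_kJ_mol"] = profile.std
    pd.DataFrame(data).to_csv(path, index=False)


def write_timecourse(tc: TimeCourse, path) -> None:
    pd.DataFrame({"time_min": tc.time, "f_norm": tc.f_norm}).to_csv(path, index=False)


def read_timecourse(path, label: str = "") -> TimeCourse:
    df = pd.read_csv(path)
    return TimeCourse(df["time_min"].to_numpy(), df["f_norm"].to_numpy(), label=label)
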