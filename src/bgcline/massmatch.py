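"""Dereplication of LC-MS peaks against known compounds by exact mass.

Observed positive-mode ion peaks are compared with the protonated molecule
[M+H]+ of candidate known compounds: a peak matches when its m/z is within
a ppm tolerance of candidate mass + proton mass.  Absences are reported
explicitly — in dereplication, "no known compound matches" is the finding
that marks a peak as potentially novel.  Only the [M+H]+ adduct is
modelled.  The default tolerance of 10 ppm suits high-resolution Orbitrap
data (the source peak lists were acquired at 70,000 resolution); it is a
package default, not a value stated by the survey.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

#: proton mass, Da
PROTON_MASS = 1.00728


@dataclass(frozen=True)
class PeakRecord:
    mz: float
    retention_min: float
    strain: str
    media: frozenset = frozenset()
    label: str = ""

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


@dataclass(frozen=True)
class CandidateCompound:
    name: str
    exact_mass: float

    def __post_init__(self):
        if self.exact_mass <= 0:
            raise ValueError("exact mass must be positive")


def mh_plus(exact_mass: float) -> float:
    """m/z of the protonated molecule [M+H]+ of a neutral monoisotopic mass."""
    if exact_mass <= 0:
        raise ValueError("exact mass must be positive")
    return exact_mass + PROTON_MASS


def match_peaks(
    peaks: Iterable[PeakRecord],
    candidates: Iterable[CandidateCompound],
    tolerance_ppm: float = 10.0,
) -> dict:
    """Per-candidate matched peaks; an empty list records an explicit absence."""
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    peaks = list(peaks)
    out: dict[str, list] = {}
    for cand in candidates:
        target = mh_plus(cand.exact_mass)
        out[cand.name] = [
            p for p in peaks
            if abs(p.mz - target) / target <= tolerance_ppm * 1e-6
        ]
    return out


def presence_table(peaks: Sequence[PeakRecord]) -> pd.DataFrame:
    """Strain x peak incidence matrix (True where the peak was observed)."""
    peaks = list(peaks)
    if not peaks:
        return pd.DataFrame()
    strains = list(dict.fromkeys(p.strain for p in peaks))
    labels = list(dict.fromkeys(
        p.label or f"{p.retention_min}min_{p.mz}" for p in peaks))
    tbl = pd.DataFrame(False, index=strains, columns=labels)
    for p in peaks:
        tbl.loc[p.strain, p.label or f"{p.retention_min}min_{p.mz}"] = True
    return tbl


def _read_csv(name: str) -> list[dict]:
    ref = resources.files("bgcline").joinpath(f"data/{name}")
    with resources.as_file(ref) as path, open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def packaged_peaks() -> tuple:
    """Representative ion peaks of the four-strain culture-extract survey."""
    return tuple(
        PeakRecord(
            mz=float(r["mz"]), retention_min=float(r["rt_min"]),
            strain=r["strain"], media=frozenset(r["media"].split(";")),
            label=r["peak"])
        for r in _read_csv("lcms_peaks.csv"))


def packaged_candidates() -> tuple:
    """Known compounds implied by the surveyed clusters, as (name, mass)."""
    return tuple(
        CandidateCompound(name=r["name"], exact_mass=float(r["exact_mass"]))
        for r in _read_csv("candidate_compounds.csv"))
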