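"""Comparative summaries of surface strain samples.

Finite-element analyses of the loaded tibia yield, per surface point, the
absolute maximum principal strain (in microstrain) tagged endocortical or
periosteal.  This module consumes such per-point samples (two-column CSV:
``strain_ue, surface``) and produces the comparative statistics of
interest: per-surface mean +/- SD, the periosteal-vs-endocortical percent
difference, the fraction of periosteal points strained above the
endocortical maximum, and shared-bin relative-frequency histograms.  The
FE computation itself is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PercentDifference:
    raw: float
    rounded: int


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent_difference(endo_mean_ue: float, peri_mean_ue: float
                       ) -> PercentDifference:
    """Percent difference of the periosteal relative to the endocortical
    mean strain, ``100 * (peri - endo) / endo``.

    The denominator convention (endocortical mean) makes the measure
    antisymmetric only up to that choice; it is invariant under a common
    rescaling of both means.  Reported values are rounded half-away-from-
    zero to the nearest integer percent; the raw value is retained.
    """
    if endo_mean_ue <= 0:
        raise ValueError("endocortical mean strain must be positive")
    raw = 100.0 * (peri_mean_ue - endo_mean_ue) / endo_mean_ue
    return PercentDifference(raw=raw, rounded=_round_half_away(raw))


@dataclass
class SurfaceStats:
    n: int
    mean_ue: float
    sd_ue: float
    max_ue: float


@dataclass
class StrainSummary:
    endocortical: SurfaceStats
    periosteal: SurfaceStats
    percent_difference: PercentDifference
    exceedance_fraction: float
    bin_edges_ue: np.ndarray
    frequencies: dict[str, np.ndarray]   # relative frequencies, sum to 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for surface, stats in (("endocortical", self.endocortical),
                               ("periosteal", self.periosteal)):
            rows.append({"surface": surface, "n": stats.n,
                         "mean_ue": stats.mean_ue, "sd_ue": stats.sd_ue,
                         "max_ue": stats.max_ue})
        return pd.DataFrame(rows)


def summarize_strains(samples: pd.DataFrame, bins: int | np.ndarray = 20
                      ) -> StrainSummary:
    """Summarise per-point strain samples from both surfaces.

    ``samples`` needs columns ``strain_ue`` (absolute maximum principal
    strain, microstrain, >= 0) and ``surface`` (endocortical/periosteal).
    The exceedance fraction counts periosteal points strictly above the
    endocortical maximum; it is invariant under any strictly monotone
    transform applied to all samples.  Histograms share one set of bin
    edges and report relative frequencies (sum to 1 per surface).
    """
    strains = {}
    for surface in ("endocortical", "periosteal"):
        vals = np.asarray(
            samples.loc[samples["surface"] == surface, "strain_ue"],
            dtype=float)
        if vals.size == 0:
            raise ValueError(f"no {surface} samples")
        if (vals < 0).any():
            raise ValueError("strains must be absolute values (>= 0)")
        strains[surface] = vals

    def stats(vals: np.ndarray) -> SurfaceStats:
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        return SurfaceStats(n=int(vals.size), mean_ue=float(vals.mean()),
                            sd_ue=sd, max_ue=float(vals.max()))

    endo, peri = stats(strains["endocortical"]), stats(strains["periosteal"])
    exceed = float(np.mean(strains["periosteal"] > endo.max_ue))

    all_vals = np.concatenate(list(strains.values()))
    edges = (np.asarray(bins, dtype=float) if np.ndim(bins) > 0
             else np.linspace(0.0, float(all_vals.max()) or 1.0,
                              int(bins) + 1))
    freqs = {}
    for surface, vals in strains.items():
        counts, _ = np.histogram(np.clip(vals, edges[0], edges[-1]),
                                 bins=edges)
        freqs[surface] = counts / vals.size

    return StrainSummary(
        endocortical=endo, periosteal=peri,
        percent_difference=percent_difference(endo.mean_ue, peri.mean_ue),
        exceedance_fraction=exceed, bin_edges_ue=edges, frequencies=freqs)


def read_strain_samples(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"strain_ue", "surface"} - set(df.columns)
    if missing:
        raise ValueError(f"strain CSV lacks columns: {sorted(missing)}")
    return df
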