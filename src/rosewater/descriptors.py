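"""Machine-learning input tables over a (T*, p*) grid.

Two descriptor families feed the phase-diagram pipelines:

* the ADF descriptor: the five angular distribution functions
  (distances 0.7, 1.0, 1.73, 2.0, 3.0) down-sampled to every third bin
  and concatenated - 5 x 25 = 125 dimensions, deliberately NOT
  standardized since all ADFs share one scale;
* the property vector: the 15 thermodynamic/structural/dynamic
  quantities, standardized column-wise to mean 0, variance 1.

The 125-dimension total is the fixed contract and dictates the
binning: a 3-degree walk over the +-60 degree window would keep 41
points per distance (205 total), so the native ADF binning here is 75
bins of 1.6 degrees and stride 3 keeps exactly 25 bins per distance.
Retained bins are copied verbatim - no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .observables import ADF, OBSERVABLE_NAMES, ObservableSet

__all__ = ["FeatureTable", "build_adf_descriptor", "build_adf_table",
           "build_property_table", "drop_feature", "standardize",
           "ADF_DESCRIPTOR_DIM"]

ADF_STRIDE = 3
ADF_DESCRIPTOR_DIM = 125


@dataclass
class FeatureTable:
    """Feature matrix over phase points, with provenance of scaling."""

    phase_points: list          # [(T*, p*), ...]
    features: np.ndarray        # (points, dims)
    feature_names: list
    standardized: bool = False
    raw: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2D")
        if self.features.shape[0] != len(self.phase_points):
            raise ValueError("row count != number of phase points")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("column count != number of feature names")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if self.raw is None:
            self.raw = self.features.copy()

    @property
    def n_points(self) -> int:
        return self.features.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df.insert(0, "T", [t for t, _ in self.phase_points])
        df.insert(1, "p", [p for _, p in self.phase_points])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 standardized: bool = False) -> "FeatureTable":
        df = pd.read_csv(path)
        pts = list(zip(df["T"], df["p"]))
        names = [c for c in df.columns if c not in ("T", "p")]
        return cls(pts, df[names].to_numpy(), names, standardized)


def standardize(x: np.ndarray) -> np.ndarray:
    """Column-wise z-score; constant columns map to all-zero, no NaN."""
    x = np.asarray(x, float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = np.zeros_like(x)
    ok = sd > 0
    out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return out


# -- ADF descriptor ---------------------------------------------------

def build_adf_descriptor(adfs: list[ADF],
                         stride: int = ADF_STRIDE) -> np.ndarray:
    """One 125-dimensional feature row from the five ADFs of a point."""
    ref = adfs[0].angles
    for a in adfs[1:]:
        if len(a.angles) != len(ref) or not np.allclose(a.angles, ref):
            raise ValueError("ADFs must share one angle grid")
    return np.concatenate([a.density[::stride] for a in adfs])


def build_adf_table(phase_points, adfs_per_point) -> FeatureTable:
    """Stack per-point ADF descriptor rows; not standardized."""
    rows = [build_adf_descriptor(adfs) for adfs in adfs_per_point]
    dim = len(rows[0])
    names = []
    for a in adfs_per_point[0]:
        kept = a.angles[::ADF_STRIDE]
        names += [f"adf_r{a.r_target:g}_a{ang:.1f}" for ang in kept]
    return FeatureTable(list(phase_points), np.array(rows), names[:dim],
                        standardized=False)


# -- property vector --------------------------------------------------

def build_property_table(phase_points,
                         observable_sets: list[ObservableSet],
                         ) -> FeatureTable:
    """Standardized 15-column table in the documented column order."""
    if len(phase_points) != len(observable_sets):
        raise ValueError("one ObservableSet per phase point required")
    for pt, obs in zip(phase_points, observable_sets):
        if obs is None:
            raise ValueError(f"missing observables at phase point {pt}")
    raw = np.array([obs.as_vector() for obs in observable_sets])
    return FeatureTable(list(phase_points), standardize(raw),
                        list(OBSERVABLE_NAMES), standardized=True, raw=raw)


def drop_feature(table: FeatureTable, name: str) -> FeatureTable:
    """Remove one column and re-standardize (if the table was)."""
    if name not in table.feature_names:
        raise KeyError(f"unknown feature {name!r}")
    keep = [i for i, n in enumerate(table.feature_names) if n != name]
    raw = table.raw[:, keep]
    feats = standardize(raw) if table.standardized else raw
    return FeatureTable(list(table.phase_points), feats,
                        [table.feature_names[i] for i in keep],
                        table.standardized, raw=raw)
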