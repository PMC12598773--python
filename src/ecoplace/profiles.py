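"""Depth-ordered station analytics.

Works on per-station depth profiles of normalized abundances: Simpson's
index of diversity, finite-difference depth derivatives, and the three
landmark depths the ecotype-transition analysis compares:

* the depth of the most *negative* derivative of the prd/rpoB ratio
  (where the proteorhodopsin-carrying fraction drops fastest),
* the depth of the low-light picocyanobacterial (LLI) psbD maximum,
* the onset depth at which the deep ecotype "begins to increase".

All three are expected to coincide at the ecotype transition depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SIMPSON_CUTOFF = 1.0     # presence cutoff, normalized reads
ONSET_THETA = 0.1        # onset threshold as a fraction of the profile maximum
ONSET_SUSTAIN = 2        # samples over which the rise must be sustained


def simpson_diversity(normalized_counts, presence_cutoff: float = SIMPSON_CUTOFF) -> float:
    """Simpson's Index of Diversity (1 - D) over clades passing a cutoff.

    Clades with normalized count below ``presence_cutoff`` are dropped (to
    reduce noise) and the remaining counts renormalized; returns NaN when
    nothing passes.  Bounded in [0, 1 - 1/k] for k passing clades.
    """
    x = np.asarray(pd.Series(normalized_counts, dtype=float))
    x = x[x >= presence_cutoff]
    if x.size == 0 or x.sum() <= 0:
        return float("nan")
    p = x / x.sum()
    return float(1.0 - np.sum(p ** 2))


def finite_derivative(values, depths) -> tuple[np.ndarray, np.ndarray]:
    """First differences dv/dz, reported at depth-interval midpoints.

    Returns (midpoints, derivative) with n-1 entries for n depths.
    """
    v = np.asarray(values, dtype=float)
    z = np.asarray(depths, dtype=float)
    if len(v) != len(z):
        raise ValueError("values and depths must have equal length")
    if len(z) < 2:
        raise ValueError("need at least 2 depths")
    dz = np.diff(z)
    if np.any(dz == 0):
        raise ValueError("duplicate depths")
    return (z[:-1] + z[1:]) / 2.0, np.diff(v) / dz


def negative_maximum_depth(midpoints, derivative) -> float:
    """Midpoint depth of the most negative derivative (tie -> shallowest).

    NaN if the derivative never goes negative (no decline to locate).
    """
    d = np.asarray(derivative, dtype=float)
    m = np.asarray(midpoints, dtype=float)
    if d.size == 0:
        raise ValueError("empty derivative series")
    order = np.argsort(m)
    d, m = d[order], m[order]
    if np.nanmin(d) >= 0:
        return float("nan")
    return float(m[np.nanargmin(d)])


def lli_maximum_depth(depths, values) -> float:
    """Depth of the maximum abundance (tie -> shallowest); NaN if all zero."""
    v = np.asarray(values, dtype=float)
    z = np.asarray(depths, dtype=float)
    order = np.argsort(z)
    v, z = v[order], z[order]
    if v.size == 0 or np.nanmax(v) <= 0:
        return float("nan")
    return float(z[np.nanargmax(v)])


def clade_onset_depth(depths, values, theta: float = ONSET_THETA,
                      m_sustain: int = ONSET_SUSTAIN) -> float:
    """Shallowest depth at which a clade "begins to increase".

    Operationalized as: abundance >= theta * profile maximum AND
    non-decreasing over the next ``m_sustain`` samples (vacuously true
    past the end of the profile).  NaN if never satisfied.
    """
    v = np.asarray(values, dtype=float)
    z = np.asarray(depths, dtype=float)
    order = np.argsort(z)
    v, z = v[order], z[order]
    if v.size == 0 or np.nanmax(v) <= 0:
        return float("nan")
    cutoff = theta * np.nanmax(v)
    for k in range(len(v)):
        if v[k] < cutoff:
            continue
        tail = v[k:k + m_sustain + 1]
        if np.all(np.diff(tail) >= 0):
            return float(z[k])
    return float("nan")


@dataclass
class StationProfile:
    """Depth-ordered abundance series and derived landmarks for one station."""

    station: str
    depths: np.ndarray                       # m, strictly increasing, n >= 4
    clade_abundance: pd.DataFrame            # depths x clades, normalized
    prd_rpob: np.ndarray | None = None       # ratio series per depth
    lli: np.ndarray | None = None            # normalized LLI psbD per depth

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if len(self.depths) < 4:
            raise ValueError("a station profile needs at least 4 depths")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")

    def simpson_series(self, presence_cutoff: float = SIMPSON_CUTOFF) -> pd.Series:
        vals = [simpson_diversity(self.clade_abundance.loc[z], presence_cutoff)
                for z in self.depths]
        return pd.Series(vals, index=self.depths, name="simpson_1_minus_D")

    def derivative(self, values) -> tuple[np.ndarray, np.ndarray]:
        return finite_derivative(values, self.depths)

    def _match_clade(self, clade: str) -> str | None:
        """Find a column by full path segment or terminal clade name."""
        for col in self.clade_abundance.columns:
            if col == clade or str(col).split(";")[-1] == clade:
                return col
        return None

    def landmarks(self, deep_clade: str, theta: float = ONSET_THETA,
                  m_sustain: int = ONSET_SUSTAIN) -> dict[str, float]:
        """The three transition landmarks (m); NaN where undefined."""
        out = {"z_negmax": float("nan"), "z_lli": float("nan"),
               "z_onset": float("nan")}
        if self.prd_rpob is not None:
            mids, deriv = finite_derivative(self.prd_rpob, self.depths)
            out["z_negmax"] = negative_maximum_depth(mids, deriv)
        if self.lli is not None:
            out["z_lli"] = lli_maximum_depth(self.depths, self.lli)
        col = self._match_clade(deep_clade)
        if col is not None:
            out["z_onset"] = clade_onset_depth(
                self.depths, self.clade_abundance[col].to_numpy(),
                theta, m_sustain)
        return out


def landmark_table(profiles, deep_clade: str, theta: float = ONSET_THETA,
                   m_sustain: int = ONSET_SUSTAIN) -> pd.DataFrame:
    """Landmark summary across stations (station, z_negmax, z_lli, z_onset)."""
    rows = []
    for prof in profiles:
        lm = prof.landmarks(deep_clade, theta, m_sustain)
        rows.append((prof.station, lm["z_negmax"], lm["z_lli"], lm["z_onset"]))
    return pd.DataFrame(rows, columns=["station", "z_negmax", "z_lli", "z_onset"])
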