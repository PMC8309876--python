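"""Ecosystem quantities computed from classified particle tables.

Given a per-particle table (columns ``taxon``, ``H_um``, ``M``,
``S_mm2``) and the sampling geometry, this module computes the
background quantities the holographic profiler reports:

* per-taxon concentration ``n / V0`` (individuals per m^3),
* size statistics (mean and sample SD of ``H`` per taxon),
* turbidity ``alpha_k = sum_i S_ik / S0p`` — the fraction of the
  entrance-pupil area shielded by particle sections,
* raw-weight biomass, treating each particle as an ellipsoid of water
  density: ``V = (pi/6) H^3 M^2`` and ``biomass_k = sum_i g V_i / V0``,
* size histograms and mean +- SD summaries with Student-t intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import TAXA

#: Raw-weight density: plankton density taken equal to water density.
DEFAULT_DENSITY_MG_MM3 = 1.0


@dataclass(frozen=True)
class MetricsConfig:
    """Sampling geometry for metric computation.

    ``V0_m3`` is the test volume behind one count, ``S0p_mm2`` the
    entrance-pupil area, ``g_mg_mm3`` the assumed particle density.
    """

    V0_m3: float
    S0p_mm2: float = 1477.5
    g_mg_mm3: float = DEFAULT_DENSITY_MG_MM3
    histogram_bin_edges_um: tuple[float, ...] = tuple(np.arange(100.0, 2100.0, 100.0))

    def __post_init__(self) -> None:
        if self.V0_m3 <= 0 or self.S0p_mm2 <= 0 or self.g_mg_mm3 <= 0:
            raise ValueError("V0, S0p and g must all be positive")


def concentration_by_taxon(
    particles: pd.DataFrame, V0_m3: float, taxa: tuple[str, ...] = TAXA
) -> pd.Series:
    """Per-taxon concentration in individuals per m^3 (absent taxa -> 0)."""
    if V0_m3 <= 0:
        raise ValueError("V0 must be positive")
    counts = particles["taxon"].value_counts() if len(particles) else pd.Series(dtype=int)
    return pd.Series(
        {t: counts.get(t, 0) / V0_m3 for t in taxa}, name="concentration_spp_m3"
    )


def size_statistics(particles: pd.DataFrame, taxa: tuple[str, ...] = TAXA) -> pd.DataFrame:
    """Mean and sample SD (n-1) of H per taxon; SD is NaN for n < 2."""
    rows = {}
    for t in taxa:
        h = particles.loc[particles["taxon"] == t, "H_um"] if len(particles) else pd.Series(dtype=float)
        n = len(h)
        rows[t] = dict(
            n=n,
            mean_H_um=h.mean() if n else np.nan,
            sd_H_um=h.std(ddof=1) if n >= 2 else np.nan,
        )
    return pd.DataFrame.from_dict(rows, orient="index")


def turbidity(
    particles: pd.DataFrame, S0p_mm2: float, taxa: tuple[str, ...] = TAXA
) -> tuple[pd.Series, float, int]:
    """Per-taxon shielding fraction alpha_k and total turbidity alpha.

    ``alpha_k`` sums the section areas of the taxon's particles over the
    entrance-pupil area; the total is the sum over taxa.  Particles with
    a missing section area are skipped and counted.
    """
    if S0p_mm2 <= 0:
        raise ValueError("S0p must be positive")
    if len(particles):
        ok = particles["S_mm2"].notna()
        skipped = int((~ok).sum())
        sums = particles[ok].groupby("taxon")["S_mm2"].sum()
    else:
        skipped = 0
        sums = pd.Series(dtype=float)
    alpha_k = pd.Series({t: sums.get(t, 0.0) / S0p_mm2 for t in taxa}, name="alpha_k")
    return alpha_k, float(alpha_k.sum()), skipped


def particle_volume_mm3(H_um, M) -> np.ndarray | float:
    """Ellipsoid particle volume ``(pi/6) H^3 M^2`` in mm^3 (H in um)."""
    H = np.asarray(H_um, dtype=float)
    Mv = np.asarray(M, dtype=float)
    if (H < 0).any() or (Mv < 0).any() or (Mv > 1).any():
        raise ValueError("H must be >= 0 and M in [0, 1]")
    out = np.pi / 6.0 * H**3 * Mv**2 * 1e-9
    return float(out) if out.ndim == 0 else out


def biomass(
    particles: pd.DataFrame,
    V0_m3: float,
    g_mg_mm3: float = DEFAULT_DENSITY_MG_MM3,
    taxa: tuple[str, ...] = TAXA,
) -> tuple[pd.Series, float]:
    """Raw-weight biomass per taxon and in total, mg per m^3.

    Every classified particle contributes by default, including Marine
    snow and Suspension; filter the input table to restrict the set.
    """
    if V0_m3 <= 0:
        raise ValueError("V0 must be positive")
    if len(particles):
        ww = g_mg_mm3 * particle_volume_mm3(particles["H_um"].to_numpy(), particles["M"].to_numpy())
        sums = pd.Series(ww, index=particles["taxon"].to_numpy()).groupby(level=0).sum()
    else:
        sums = pd.Series(dtype=float)
    bm = pd.Series({t: sums.get(t, 0.0) / V0_m3 for t in taxa}, name="biomass_mg_m3")
    return bm, float(bm.sum())


def size_histogram(
    particles: pd.DataFrame,
    bin_edges_um,
    taxon: str | None = None,
) -> np.ndarray:
    """Counts of H in strictly half-open bins ``[e_j, e_{j+1})``."""
    edges = np.asarray(bin_edges_um, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    h = particles["H_um"]
    if taxon is not None:
        h = particles.loc[particles["taxon"] == taxon, "H_um"]
    h = h.to_numpy(dtype=float)
    idx = np.searchsorted(edges, h, side="right") - 1
    valid = (idx >= 0) & (idx < len(edges) - 1) & (h < edges[-1])
    return np.bincount(idx[valid], minlength=len(edges) - 1)


def summarize_with_uncertainty(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean, sample SD and Student-t confidence half-width of a sample.

    Reports are conventionally formatted as mean +- SD; the half-width
    is provided for a proper confidence interval at ``level``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    t = stats.t.ppf(0.5 + level / 2.0, df=v.size - 1)
    half = float(t * sd / np.sqrt(v.size))
    return mean, sd, half


def taxon_metrics_table(particles: pd.DataFrame, cfg: MetricsConfig) -> pd.DataFrame:
    """One row per taxon: n, concentration, size stats, alpha_k, biomass_k."""
    conc = concentration_by_taxon(particles, cfg.V0_m3)
    sizes = size_statistics(particles)
    alpha_k, _, _ = turbidity(particles, cfg.S0p_mm2)
    bm, _ = biomass(particles, cfg.V0_m3, cfg.g_mg_mm3)
    out = sizes.copy()
    out["concentration_spp_m3"] = conc
    out["alpha_k"] = alpha_k
    out["biomass_mg_m3"] = bm
    out.index.name = "taxon"
    return out[["n", "concentration_spp_m3", "mean_H_um", "sd_H_um", "alpha_k", "biomass_mg_m3"]]
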