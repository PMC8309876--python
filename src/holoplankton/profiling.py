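"""Virtual-sample counts and depth profiles.

A "count" (one point of a depth profile) pools ``N`` consecutive
exposures, so the averaging volume is ``N x exposure_volume`` — e.g.
five 0.5 L exposures give a 2.5 L virtual sample.  Successive counts
are spaced by the count discreteness, ``submersion speed x processing
interval`` (0.3 m/s and 20 s give 6 m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import TAXA
from .metrics import MetricsConfig, taxon_metrics_table, turbidity, biomass


@dataclass
class CountRecord:
    """Aggregate metrics of one virtual sample."""

    count_index: int
    depth_m: float
    averaging_volume_l: float
    n_exposures: int
    metrics: pd.DataFrame  # per-taxon table from taxon_metrics_table
    alpha_total: float
    biomass_total_mg_m3: float
    n_particles: int
    direction: str = "forward"


def count_discreteness_m(speed_m_s: float, processing_interval_s: float) -> float:
    """Vertical spacing between real-time counts: speed x interval."""
    if speed_m_s <= 0 or processing_interval_s <= 0:
        raise ValueError("speed and interval must be positive")
    return speed_m_s * processing_interval_s


def form_counts(
    frames: pd.DataFrame,
    particles: pd.DataFrame,
    exposures_per_count: int,
    exposure_volume_l: float,
    s0p_mm2: float = 1477.5,
    g_mg_mm3: float = 1.0,
    direction: str = "forward",
    sliding: bool = False,
) -> list[CountRecord]:
    """Group consecutive exposures into virtual-sample counts.

    ``frames`` lists every exposure (columns ``frame``, ``depth_m``),
    including empty ones — they contribute sampled volume.  Counts are
    non-overlapping blocks of ``exposures_per_count`` frames (a sliding
    window of stride one is available but off by default); a trailing
    incomplete block is dropped with a warning.
    """
    if exposures_per_count < 1:
        raise ValueError("exposures_per_count must be >= 1")
    if exposure_volume_l <= 0:
        raise ValueError("exposure volume must be positive")
    frames = frames.sort_values("frame").reset_index(drop=True)
    n_frames = len(frames)
    if n_frames == 0:
        return []
    N = int(exposures_per_count)
    starts = range(0, n_frames - N + 1, 1 if sliding else N)
    remainder = 0 if sliding else n_frames % N
    if remainder:
        warnings.warn(
            f"dropping {remainder} trailing exposure(s) not filling a count",
            stacklevel=2,
        )
    V0_l = N * exposure_volume_l
    cfg = MetricsConfig(V0_m3=V0_l * 1e-3, S0p_mm2=s0p_mm2, g_mg_mm3=g_mg_mm3)
    records: list[CountRecord] = []
    for ci, s in enumerate(starts):
        member = frames.iloc[s : s + N]
        ids = set(member["frame"])
        sub = particles[particles["frame"].isin(ids)] if len(particles) else particles
        table = taxon_metrics_table(sub, cfg)
        _, alpha_total, _ = turbidity(sub, cfg.S0p_mm2)
        _, bm_total = biomass(sub, cfg.V0_m3, cfg.g_mg_mm3)
        records.append(
            CountRecord(
                count_index=ci,
                depth_m=float(member["depth_m"].mean()),
                averaging_volume_l=V0_l,
                n_exposures=N,
                metrics=table,
                alpha_total=alpha_total,
                biomass_total_mg_m3=bm_total,
                n_particles=int(len(sub)),
                direction=direction,
            )
        )
    return records


def build_profile(
    counts: list[CountRecord],
    hydrophysics: pd.DataFrame | None = None,
    depth_tolerance_m: float = 0.5,
) -> pd.DataFrame:
    """Depth-ordered profile table, one row per count.

    Columns: depth, per-taxon concentration, overall mean/SD of H,
    total turbidity and biomass, plus hydrophysical columns joined on
    the nearest depth within ``depth_tolerance_m``.  Forward and
    backward casts are kept apart by the ``direction`` column.
    """
    if not counts:
        raise ValueError("no counts to profile")
    rows = []
    for c in counts:
        row = dict(
            count_index=c.count_index,
            depth_m=c.depth_m,
            direction=c.direction,
            averaging_volume_l=c.averaging_volume_l,
            n_particles=c.n_particles,
            alpha_total=c.alpha_total,
            biomass_total_mg_m3=c.biomass_total_mg_m3,
        )
        for t in TAXA:
            row[f"conc_{_slug(t)}_spp_m3"] = c.metrics.loc[t, "concentration_spp_m3"]
        ntot = c.metrics["n"].sum()
        if ntot:
            means = c.metrics["mean_H_um"] * c.metrics["n"]
            row["mean_H_um"] = means.sum() / ntot
        else:
            row["mean_H_um"] = np.nan
        rows.append(row)
    prof = pd.DataFrame(rows).sort_values(["direction", "depth_m"]).reset_index(drop=True)
    if hydrophysics is not None and len(hydrophysics):
        hyd = hydrophysics.sort_values("depth_m").reset_index(drop=True)
        prof = prof.sort_values("depth_m")
        prof = pd.merge_asof(
            prof,
            hyd,
            on="depth_m",
            direction="nearest",
            tolerance=depth_tolerance_m,
        )
        prof = prof.sort_values(["direction", "depth_m"]).reset_index(drop=True)
    return prof


def _slug(taxon: str) -> str:
    return taxon.lower().replace(" ", "_")
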