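"""Verification against traditional net sampling.

A plankton net haul classified by an operator under a microscope gives
per-species concentrations; mapping each organism onto the sensor's
operational taxa and summing makes the two instruments comparable.  The
agreement measure is the relative difference with the net value as the
reference denominator, rounded to the nearest percent.

A bundled example pair (a net haul and the holographic counts averaged
over the same 7 m cast) ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

_DATA = resources.files("holoplankton") / "data"


@dataclass
class NetSample:
    """Per-organism net concentrations plus an organism -> taxon mapping."""

    table: pd.DataFrame  # columns: organism, concentration_spp_m3
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        missing = [o for o in self.table["organism"] if o not in self.mapping]
        if missing:
            raise ValueError(f"unmapped organisms: {missing}")


def load_bundled_net_sample() -> NetSample:
    """The example net haul (7 m cast) with its taxon mapping."""
    table = pd.read_csv(_DATA / "net_sample.csv")
    mp = pd.read_csv(_DATA / "net_taxon_map.csv")
    return NetSample(table, dict(zip(mp["organism"], mp["taxon"])))


def load_bundled_dhc_counts() -> pd.Series:
    """Holographic per-taxon concentrations paired with the bundled net haul."""
    df = pd.read_csv(_DATA / "holographic_counts.csv")
    return pd.Series(df["concentration_spp_m3"].to_numpy(), index=df["taxon"].to_numpy())


def aggregate_net_by_taxon(net: NetSample) -> pd.Series:
    """Sum organism concentrations within each mapped taxon."""
    taxa = net.table["organism"].map(net.mapping)
    return net.table.groupby(taxa.to_numpy())["concentration_spp_m3"].sum()


def relative_difference_pct(net_value: float, dhc_value: float) -> int | None:
    """``round(100 * |net - dhc| / net)``; undefined (None) when net = 0."""
    if net_value < 0:
        raise ValueError("net value must be non-negative")
    if net_value == 0:
        return None if dhc_value > 0 else 0
    return int(round(100.0 * abs(net_value - dhc_value) / net_value))


def comparison_report(net: NetSample, dhc: pd.Series) -> pd.DataFrame:
    """Per-taxon net vs holographic concentrations with relative differences.

    Rows cover the union of taxa plus a ``Total`` row; the maximum
    defined rounded difference is stored in ``df.attrs['max_diff_pct']``.
    """
    net_by_taxon = aggregate_net_by_taxon(net)
    taxa = sorted(set(net_by_taxon.index) | set(dhc.index))
    rows = []
    for t in taxa:
        nv = float(net_by_taxon.get(t, 0.0))
        dv = float(dhc.get(t, 0.0))
        rows.append(dict(taxon=t, net_spp_m3=nv, dhc_spp_m3=dv, diff_pct=relative_difference_pct(nv, dv)))
    nt, dt = float(net_by_taxon.sum()), float(dhc.sum())
    rows.append(dict(taxon="Total", net_spp_m3=nt, dhc_spp_m3=dt, diff_pct=relative_difference_pct(nt, dt)))
    df = pd.DataFrame(rows)
    defined = df["diff_pct"].dropna()
    df.attrs["max_diff_pct"] = int(defined.max()) if len(defined) else 0
    return df
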