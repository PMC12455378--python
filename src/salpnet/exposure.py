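"""Peer-exposure construction: baseline OS rates, peers, quartiles.

Each surgeon's baseline (T1) opportunistic-salpingectomy rate is the
proportion of their eligible T1 sterilizations that used OS.  A surgeon's
peers are the *other* physicians in the same patient-sharing network who
performed at least ``min_volume`` eligible T1 sterilizations.  The
exposure is the unweighted mean of peers' baseline rates, categorized into
quartiles over the surgeon-level empirical distribution with a
closed-right bracket convention (a value exactly on a breakpoint falls in
the lower quartile).  The T2 analysis dataset keeps only encounters whose
operating surgeon was a baseline nonuser (performed eligible T1
sterilizations but no OS) with a defined exposure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "profile_surgeons",
    "identify_peers",
    "mean_peer_os_rate",
    "compute_exposures",
    "assign_quartiles",
    "assemble_analysis_dataset",
]


def profile_surgeons(
    t1_encounters: pd.DataFrame, membership: pd.DataFrame
) -> pd.DataFrame:
    """One profile per physician with >= 1 eligible T1 sterilization.

    Columns: physician_id, network_id (NaN if unpartitioned — excluded
    downstream), t1_eligible_sterilizations, t1_os_count, t1_os_rate,
    baseline_nonuser.
    """
    grp = t1_encounters.groupby("surgeon_id")["os_flag"].agg(["size", "sum"])
    prof = grp.rename(
        columns={"size": "t1_eligible_sterilizations", "sum": "t1_os_count"}
    ).reset_index(names="physician_id")
    prof["t1_os_count"] = prof["t1_os_count"].astype(int)
    prof["t1_os_rate"] = prof["t1_os_count"] / prof["t1_eligible_sterilizations"]
    prof["baseline_nonuser"] = prof["t1_os_count"] == 0
    if len(membership) == 0:
        prof["network_id"] = np.nan
    else:
        net = membership.set_index("physician_id")["network_id"]
        prof["network_id"] = prof["physician_id"].map(net)
    return prof


def identify_peers(
    surgeon_id: str, profiles: pd.DataFrame, min_volume: int = 5
) -> pd.DataFrame:
    """Same-network physicians (excluding the surgeon) with enough volume.

    Peer candidacy imposes only the volume rule: a peer's own nonuser
    status is irrelevant.
    """
    row = profiles.loc[profiles["physician_id"] == surgeon_id]
    if row.empty or pd.isna(row["network_id"].iloc[0]):
        return profiles.iloc[0:0]
    net = row["network_id"].iloc[0]
    return profiles[
        (profiles["network_id"] == net)
        & (profiles["physician_id"] != surgeon_id)
        & (profiles["t1_eligible_sterilizations"] >= min_volume)
    ]


def mean_peer_os_rate(peers: pd.DataFrame) -> float:
    """Unweighted arithmetic mean of peers' baseline rates; NaN if none."""
    if len(peers) == 0:
        return float("nan")
    return float(peers["t1_os_rate"].mean())


def compute_exposures(profiles: pd.DataFrame, min_volume: int = 5) -> pd.DataFrame:
    """Exposure table over all profiled surgeons.

    Columns: surgeon_id, network_id, n_eligible_peers, mean_peer_os_rate
    (NaN when no eligible peer exists — such surgeons leave the analysis).
    """
    rows = []
    for sid in profiles["physician_id"]:
        peers = identify_peers(sid, profiles, min_volume)
        rows.append(
            {
                "surgeon_id": sid,
                "network_id": profiles.loc[
                    profiles["physician_id"] == sid, "network_id"
                ].iloc[0],
                "n_eligible_peers": len(peers),
                "mean_peer_os_rate": mean_peer_os_rate(peers),
            }
        )
    return pd.DataFrame(rows)


def assign_quartiles(
    exposures: pd.DataFrame, surgeons: pd.Series | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Quartile breakpoints and labels over the surgeon-level distribution.

    Breakpoints are the 25th/50th/75th percentiles (linear interpolation)
    of ``mean_peer_os_rate`` among surgeons with a defined exposure
    (optionally restricted to ``surgeons``).  Intervals follow the
    closed-right pattern Q1=[min,b1], Q2=(b1,b2], Q3=(b2,b3], Q4=(b3,max]:
    a surgeon exactly on a breakpoint takes the lower quartile.
    Breakpoints are never rounded for assignment.
    """
    exp = exposures.copy()
    pool = exp.dropna(subset=["mean_peer_os_rate"])
    if surgeons is not None:
        pool = pool[pool["surgeon_id"].isin(set(surgeons))]
    vals = pool["mean_peer_os_rate"].to_numpy()
    if len(vals) < 4 or len(np.unique(vals)) < 4:
        raise ValueError(
            "need at least 4 distinct surgeon-level exposures for quartiles"
        )
    cuts = np.percentile(vals, [25, 50, 75], method="linear")
    def label(v):
        if np.isnan(v):
            return None
        return f"Q{1 + int(np.sum(v > cuts))}"
    exp["quartile"] = exp["mean_peer_os_rate"].map(label)
    return cuts, exp


def assemble_analysis_dataset(
    t2_encounters: pd.DataFrame,
    profiles: pd.DataFrame,
    exposures: pd.DataFrame,
    setting_class: str,
) -> pd.DataFrame:
    """T2 analysis rows for one setting, restricted to baseline nonusers.

    A row requires the encounter's surgeon to (a) have a T1 profile, (b)
    be a baseline nonuser, (c) carry a defined, quartiled exposure and a
    network assignment.  ``surgeon_volume`` is the surgeon's count of
    eligible same-setting T2 encounters.
    """
    df = t2_encounters[t2_encounters["setting_class"] == setting_class].copy()
    prof = profiles.set_index("physician_id")
    exp = exposures.set_index("surgeon_id")
    keep = []
    for sid in df["surgeon_id"]:
        ok = (
            sid in prof.index
            and bool(prof.loc[sid, "baseline_nonuser"])
            and sid in exp.index
            and isinstance(exp.loc[sid, "quartile"], str)
            and not pd.isna(exp.loc[sid, "network_id"])
        )
        keep.append(ok)
    dropped = len(df) - sum(keep)
    df = df.loc[keep].copy()
    df["quartile"] = df["surgeon_id"].map(exp["quartile"])
    df["mean_peer_os_rate"] = df["surgeon_id"].map(exp["mean_peer_os_rate"])
    df["network_id"] = df["surgeon_id"].map(exp["network_id"])
    df["surgeon_volume"] = df.groupby("surgeon_id")["surgeon_id"].transform("size")
    df.attrs["n_dropped_non_analyzable"] = dropped
    return df.reset_index(drop=True)
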