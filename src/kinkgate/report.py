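"""Multi-replicate orchestration, grouping and correlation statistics.

Joins per-replicate descriptor and permeation results into one summary
table, splits replicates into high/low bent-fraction groups (the gp1/gp2
comparison), computes Pearson correlations with seeded bootstrap
confidence intervals, and resolves the crossing rate by tetramer
configuration (number of bent subunits, 0-4) — the numeric backbone of
the two-gate crosstalk picture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conformation import DescriptorSeries, StateTrace
from .permeation import PermeationRecord

__all__ = [
    "ReplicateSummary",
    "GroupSplit",
    "summarize_replicates",
    "split_replicates",
    "correlate",
    "config_resolved_conductance",
    "analyze_replicate",
]

SUMMARY_COLUMNS = [
    "replicate", "n_frames", "f_bent", "I_pA", "n_events",
    "d_ogog_nm", "d_pro19_nm", "d_cof_nm", "d_i84_t59_nm", "thickness_nm",
]


def analyze_replicate(
    frames, topology, replicate: str = "rep0", ion_expr: str = "resname K"
) -> dict:
    """One replicate through descriptors + permeation; returns a summary row."""
    from .conformation import compute_descriptors
    from .permeation import analyze_permeation
    from .profiles import membrane_thickness

    desc = compute_descriptors(frames, topology)
    records, current = analyze_permeation(frames, topology, ion_expr=ion_expr)
    try:
        thickness = membrane_thickness(frames, topology).thickness_nm
    except ValueError:
        thickness = np.nan
    return {
        "replicate": replicate,
        "n_frames": frames.n_frames,
        "f_bent": desc.states.f_bent,
        "I_pA": current,
        "n_events": len(records),
        "d_ogog_nm": float(np.mean(desc.d_ogog)),
        "d_pro19_nm": float(np.mean(desc.d_pro19)),
        "d_cof_nm": float(np.mean(desc.d_cof)),
        "d_i84_t59_nm": float(np.mean(desc.d_i84_t59)),
        "thickness_nm": thickness,
        "_descriptors": desc,
        "_records": records,
    }


@dataclass
class ReplicateSummary:
    table: pd.DataFrame  # one row per replicate
    system_mean: pd.Series
    system_sem: pd.Series


def summarize_replicates(rows) -> ReplicateSummary:
    """Join per-replicate results; append system mean +/- SEM.

    ``rows`` are dicts (missing components stay as missing fields — the
    row is kept).
    """
    clean = [{k: v for k, v in r.items() if not k.startswith("_")} for r in rows]
    df = pd.DataFrame(clean)
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[SUMMARY_COLUMNS]
    num = df.drop(columns=["replicate"]).astype(float)
    n = num.notna().sum()
    sem = num.std(ddof=1) / np.sqrt(n.where(n > 1))
    return ReplicateSummary(table=df, system_mean=num.mean(), system_sem=sem)


@dataclass
class GroupSplit:
    rule: str
    cutoff: float
    gp1: list  # high bent fraction
    gp2: list
    stats: pd.DataFrame  # per-group mean/sem of f_bent and I
    degenerate: bool = False


def split_replicates(
    summary: pd.DataFrame, rule: str = "threshold", cutoff: float = 0.125
) -> GroupSplit:
    """Divide replicates by the prevalence of the bent state.

    ``threshold`` (default): gp1 = replicates with f_bent > cutoff, the
    default cutoff 0.125 being half a subunit's worth of bent occupancy.
    ``median``: split at the median f_bent, ties to gp2.
    """
    if len(summary) < 2:
        raise ValueError("need at least 2 replicates to split")
    f = summary["f_bent"].to_numpy(dtype=float)
    if rule == "median":
        cutoff = float(np.median(f))
        hi = f > cutoff
    elif rule == "threshold":
        hi = f > cutoff
    else:
        raise ValueError(f"unknown rule {rule!r}")
    gp1 = summary.loc[hi, "replicate"].tolist()
    gp2 = summary.loc[~hi, "replicate"].tolist()
    degenerate = len(gp1) == 0 or len(gp2) == 0
    if degenerate:
        import warnings

        warnings.warn("degenerate split: all replicates in one group")
    stats = []
    for name, mask in (("gp1", hi), ("gp2", ~hi)):
        sub = summary.loc[mask, ["f_bent", "I_pA"]].astype(float)
        n = len(sub)
        stats.append(
            {
                "group": name,
                "n": n,
                "f_bent_mean": sub["f_bent"].mean() if n else np.nan,
                "f_bent_sem": sub["f_bent"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "I_mean_pA": sub["I_pA"].mean() if n else np.nan,
                "I_sem_pA": sub["I_pA"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return GroupSplit(
        rule=rule, cutoff=float(cutoff), gp1=gp1, gp2=gp2,
        stats=pd.DataFrame(stats), degenerate=degenerate,
    )


def correlate(x, y, n_boot: int = 10000, seed: int = 0, ci: float = 95.0):
    """Pearson r with a seeded percentile-bootstrap confidence interval."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    xb, yb = x[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    rb = np.where(denom > 0, (xc * yc).sum(axis=1) / np.where(denom > 0, denom, 1), np.nan)
    lo, hi = np.nanpercentile(rb, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return r, (float(lo), float(hi))


def config_resolved_conductance(
    states: StateTrace | np.ndarray, records, dt_ns: float
) -> pd.DataFrame:
    """Crossing rate by tetramer configuration (n_bent = 0..4).

    Each event is attributed to the configuration at its *entry* frame
    (events span frames); rates are normalised by the residence time of
    each configuration.  Configurations never visited are reported missing
    (NaN rate, zero residence).
    """
    labels = states.labels if isinstance(states, StateTrace) else np.asarray(states)
    n_bent = labels.sum(axis=1).astype(int)
    n_frames = len(n_bent)
    residence = np.bincount(n_bent, minlength=5).astype(float)
    counts = np.zeros(5, dtype=int)
    for r in records:
        entry = r.entry_frame if isinstance(r, PermeationRecord) else int(r["entry_frame"])
        if not 0 <= entry < n_frames:
            raise ValueError(f"event entry frame {entry} outside trajectory")
        counts[n_bent[entry]] += 1
    if counts.sum() != len(list(records)):
        raise AssertionError("event attribution lost events")
    t_us = residence * dt_ns * 1e-3
    rate = np.where(t_us > 0, counts / np.where(t_us > 0, t_us, 1), np.nan)
    return pd.DataFrame(
        {
            "n_bent": np.arange(5),
            "residence_fraction": residence / n_frames,
            "n_events": counts,
            "rate_per_us": rate,
        }
    )
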