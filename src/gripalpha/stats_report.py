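"""Alpha-power aggregation and group statistics across grip levels.

Per (subject, grip level) the cleaned trials are segmented, artifact
segments dropped, and the alpha (8-12 Hz) band power averaged over the
kept segments.  Group differences across the three grip levels are then
assessed with a classical one-way ANOVA (between/within sum-of-squares
decomposition), after a Shapiro-Wilk normality check per group; the
pairwise contrasts use Tukey's HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .preprocessing import (
    EEGRecording,
    adaptive_notch_50,
    bandpass_alpha,
    crop,
    highpass,
    reject_artifacts,
    segment,
)
from .spectral import WelchConfig, band_power, welch_psd

__all__ = [
    "AnovaResult",
    "summarize_powers",
    "one_way_anova",
    "normality_check",
    "pairwise_tukey",
    "report_text",
]


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA decomposition."""

    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict
    ss_between: float
    ss_within: float
    ss_total: float


def summarize_powers(recordings, welch: WelchConfig | None = None, *,
                     hp_cutoff: float = 0.5, notch: bool = True,
                     adaptation_rate: float = 0.005,
                     seg_len_s: float = 5.0, amplitude_limit: float = 100.0,
                     band=(8.0, 12.0),
                     analysis_window: tuple | None = None) -> pd.DataFrame:
    """Per-(subject, grip level) mean alpha band power table.

    Each recording is high-pass filtered, mains-cancelled, optionally
    cropped to an analysis window, cut into ``seg_len_s`` segments with
    peak-amplitude artifact rejection; each kept segment is alpha
    band-passed and its 8-12 Hz band power computed by the smoothed
    periodogram.  Rows aggregate the kept segments of all trials of one
    (subject, level); a cell with zero kept segments is omitted with a
    warning.

    Returns
    -------
    DataFrame
        Columns ``subject_id``, ``grip_level``, ``alpha_power``,
        ``n_segments_used``.
    """
    by_cell: dict[tuple, list[float]] = {}
    for rec in recordings:
        if welch is None:
            w = WelchConfig(fs=rec.fs, segment_length=round(rec.fs))
        else:
            w = welch
        cleaned = highpass(rec, hp_cutoff)
        if notch:
            cleaned = adaptive_notch_50(cleaned, adaptation_rate)
        if analysis_window is not None:
            cleaned = crop(cleaned, *analysis_window)
        segs = reject_artifacts(segment(cleaned, seg_len_s), amplitude_limit)
        key = (rec.subject_id, rec.grip_level)
        bucket = by_cell.setdefault(key, [])
        for seg_samples in segs.kept:
            alpha = bandpass_alpha(
                EEGRecording(samples=seg_samples, fs=rec.fs),
                lo=band[0], hi=band[1],
            )
            psd = welch_psd(alpha.samples, w)
            bucket.append(band_power(psd, band[0], band[1]).power)
    rows = []
    for (subject, level), powers in sorted(by_cell.items()):
        if len(powers) == 0:
            warnings.warn(
                f"subject {subject}, level {level}: no segments survived "
                "artifact rejection; row omitted",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "subject_id": subject,
                "grip_level": level,
                "alpha_power": float(np.mean(powers)),
                "n_segments_used": len(powers),
            }
        )
    return pd.DataFrame(
        rows, columns=["subject_id", "grip_level", "alpha_power", "n_segments_used"]
    )


def _groups_from(table_or_groups):
    """Accept a PowerTable DataFrame or an explicit sequence of samples."""
    if isinstance(table_or_groups, pd.DataFrame):
        grouped = table_or_groups.groupby("grip_level")["alpha_power"]
        labels = list(grouped.groups)
        groups = [np.asarray(grouped.get_group(g), dtype=float) for g in labels]
    else:
        groups = [np.asarray(g, dtype=float) for g in table_or_groups]
        labels = list(range(len(groups)))
    return labels, groups


def one_way_anova(table_or_groups) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    Accepts the PowerTable DataFrame (grouped by ``grip_level``) or an
    explicit list of group samples.  Requires >= 2 groups with >= 2
    observations each; raises when every observation is identical (the
    F statistic is then undefined).
    """
    labels, groups = _groups_from(table_or_groups)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    alldata = np.concatenate(groups)
    grand = alldata.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = ((alldata - grand) ** 2).sum()
    df_between = len(groups) - 1
    df_within = alldata.size - len(groups)
    ms_within = ss_within / df_within
    if ms_within == 0 and ss_between == 0:
        raise ValueError("all observations identical; F undefined")
    F = (ss_between / df_between) / ms_within
    p = float(sstats.f.sf(F, df_between, df_within))
    return AnovaResult(
        F=float(F),
        df_between=df_between,
        df_within=df_within,
        p=p,
        group_means={lab: float(g.mean()) for lab, g in zip(labels, groups)},
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
    )


def normality_check(table_or_groups) -> pd.DataFrame:
    """Shapiro-Wilk omnibus normality test per group.

    Returns a DataFrame with columns ``group``, ``n``, ``statistic``,
    ``p``.  Requires n >= 3 and non-constant samples per group.
    """
    labels, groups = _groups_from(table_or_groups)
    rows = []
    for lab, g in zip(labels, groups):
        if len(g) < 3:
            raise ValueError(f"group {lab}: need n >= 3 for the normality test")
        if np.ptp(g) == 0:
            raise ValueError(f"group {lab}: constant sample, zero variance")
        stat, p = sstats.shapiro(g)
        rows.append({"group": lab, "n": len(g), "statistic": float(stat),
                     "p": float(p)})
    return pd.DataFrame(rows)


def pairwise_tukey(table_or_groups) -> pd.DataFrame:
    """Tukey HSD pairwise contrasts between grip levels."""
    labels, groups = _groups_from(table_or_groups)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    res = sstats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": float(np.mean(groups[j]) - np.mean(groups[i])),
                    "p": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def report_text(table: pd.DataFrame, alpha_level: float = 0.05) -> str:
    """Plain-text summary: group means, ANOVA, and pairwise contrasts."""
    anova = one_way_anova(table)
    tukey = pairwise_tukey(table)
    lines = ["Alpha band (8-12 Hz) average power by grip level", ""]
    for level, mean in sorted(anova.group_means.items()):
        lines.append(f"  {level}% MVC: mean power {mean:.4g}")
    lines += [
        "",
        (
            f"One-way ANOVA: F({anova.df_between}, {anova.df_within}) = "
            f"{anova.F:.3f}, p = {anova.p:.4g}"
            + (" (significant)" if anova.p < alpha_level else " (n.s.)")
        ),
        "",
        "Tukey HSD pairwise contrasts:",
    ]
    for rec in tukey.itertuples(index=False):
        flag = "*" if rec.p < alpha_level else " "
        lines.append(
            f"  {rec.group_a}% vs {rec.group_b}%: diff = {rec.mean_diff:+.4g}, "
            f"p = {rec.p:.4g} {flag}"
        )
    return "\n".join(lines)
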