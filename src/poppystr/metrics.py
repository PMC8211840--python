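"""Internal-validation statistics for multiplexed STR assays.

Implements the standard forensic validation metrics from called profiles:

* codominant height normalization (heterozygote peaks averaged, homozygote
  peaks halved);
* inter-locus balance ``IELB_i = h_i / mean(h)`` over the loci of an assay;
* intracolour balance ``ICB = min/max`` within a dye channel;
* heterozygote balance ``Hb = phi_HMW / phi_LMW`` (oriented by allele size)
  and ``Hb' = phi_smaller / phi_larger`` (oriented by peak height, always
  <= 1);
* stutter-ratio summaries ``S_R = phi_S / phi_A`` per marker and stutter
  type, the mean + 3*SD filter threshold, allele-specific means and the
  trend of S_R versus allele repeat number;
* sensitivity/dropout reports across a dilution series;
* species cross-reactivity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import Panel, parse_allele_label

__all__ = [
    "MetricSummary", "normalize_profile", "ielb", "icb", "het_balance",
    "stutter_stats", "sensitivity_report", "cross_reactivity",
]


@dataclass(frozen=True)
class MetricSummary:
    """Five-number style summary with mean +/- 3*SD bounds."""

    mean: float
    median: float
    sd: float
    min: float
    max: float
    n: int

    @property
    def lower_3sd(self) -> float:
        return self.mean - 3 * self.sd

    @property
    def upper_3sd(self) -> float:
        return self.mean + 3 * self.sd

    @classmethod
    def from_values(cls, values) -> "MetricSummary":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("cannot summarize an empty group")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return cls(mean=float(v.mean()), median=float(np.median(v)), sd=sd,
                   min=float(v.min()), max=float(v.max()), n=int(v.size))


def normalize_profile(calls: pd.DataFrame) -> pd.DataFrame:
    """Codominant normalization of called peak heights.

    Heterozygotes contribute the mean of their two peak heights; homozygotes
    contribute half their single peak height. Calls without a genotype
    (dropouts) are omitted. Returns sample_id, variety, assay, marker,
    norm_height.
    """
    rows = []
    for call in calls.itertuples(index=False):
        heights = call.heights if isinstance(call.heights, dict) else {}
        if call.zygosity == "het" and len(heights) == 2:
            h = float(np.mean(list(heights.values())))
        elif call.zygosity == "hom" and len(heights) == 1:
            h = float(next(iter(heights.values()))) / 2.0
        else:
            continue
        rows.append({"sample_id": call.sample_id,
                     "variety": getattr(call, "variety", ""),
                     "assay": call.assay, "marker": call.marker,
                     "dose_ng": getattr(call, "dose_ng", float("nan")),
                     "norm_height": h})
    return pd.DataFrame(rows, columns=["sample_id", "variety", "assay",
                                       "marker", "dose_ng", "norm_height"])


def ielb(normalized: pd.DataFrame, mode: str = "pooled") -> pd.DataFrame:
    """Inter-locus balance records.

    For each (sample, assay) profile, ``IELB_i = h_i / mean(h over the
    amplifying loci of the assay)``. The mean of IELB over a complete
    profile is exactly 1. ``mode='complete'`` keeps only profiles in which
    every panel locus of the assay amplified is left to the caller by
    pre-filtering; here 'pooled' vs 'complete' only controls whether
    incomplete profiles (fewer loci than the assay's maximum observed) are
    kept (pooled, default) or dropped.
    """
    out = []
    n_expected = normalized.groupby("assay")["marker"].nunique()
    for (sid, assay), grp in normalized.groupby(["sample_id", "assay"]):
        if mode == "complete" and grp["marker"].nunique() < n_expected[assay]:
            continue
        mean_h = grp["norm_height"].mean()
        for row in grp.itertuples(index=False):
            out.append({"sample_id": sid, "assay": assay,
                        "marker": row.marker,
                        "norm_height": row.norm_height,
                        "ielb": row.norm_height / mean_h})
    return pd.DataFrame(out, columns=["sample_id", "assay", "marker",
                                      "norm_height", "ielb"])


def icb(normalized: pd.DataFrame, panel: Panel) -> pd.DataFrame:
    """Intracolour balance: lowest / highest normalized locus height within
    each dye channel of each (sample, assay) profile.

    A dye group with a single amplifying locus returns ICB 1.0 with an
    explicit ``single_locus`` flag rather than NA.
    """
    dye_of = {m.name: m.dye for m in panel}
    df = normalized.copy()
    df["dye"] = df["marker"].map(dye_of)
    out = []
    for (sid, assay, dye), grp in df.groupby(["sample_id", "assay", "dye"]):
        h = grp["norm_height"]
        single = len(grp) == 1
        out.append({"sample_id": sid, "assay": assay, "dye": dye,
                    "icb": 1.0 if single else float(h.min() / h.max()),
                    "single_locus": single})
    return pd.DataFrame(out, columns=["sample_id", "assay", "dye", "icb",
                                      "single_locus"])


def het_balance(calls: pd.DataFrame, panel: Panel) -> pd.DataFrame:
    """Heterozygote balance observations.

    For each heterozygous call with two distinct-size alleles:
    ``Hb = phi_HMW / phi_LMW`` (heights of the larger- vs smaller-size
    allele; may exceed 1) and ``Hb' = phi_smaller / phi_larger`` (smaller vs
    larger peak height; never exceeds 1).
    """
    rows = []
    for call in calls.itertuples(index=False):
        if call.zygosity != "het":
            continue
        heights = call.heights if isinstance(call.heights, dict) else {}
        if len(heights) != 2:
            continue
        marker = panel[call.marker]
        (a1, h1), (a2, h2) = sorted(heights.items(),
                                    key=lambda kv: marker.allele_size(kv[0]))
        # a2 is the high-molecular-weight (larger) allele
        hb = h2 / h1
        hb_prime = min(h1, h2) / max(h1, h2)
        rows.append({"sample_id": call.sample_id, "marker": call.marker,
                     "dose_ng": getattr(call, "dose_ng", float("nan")),
                     "phi_LMW": h1, "phi_HMW": h2,
                     "size_diff_bp": marker.allele_size(a2)
                     - marker.allele_size(a1),
                     "Hb": hb, "Hb_prime": hb_prime})
    return pd.DataFrame(rows, columns=["sample_id", "marker", "dose_ng",
                                       "phi_LMW", "phi_HMW", "size_diff_bp",
                                       "Hb", "Hb_prime"])


def flag_hb_outliers(het: pd.DataFrame, k: float = 1.5) -> pd.DataFrame:
    """Boxplot-rule outlier flags on Hb' per marker (k * IQR whiskers).

    Outlier exclusion before summarizing heterozygote balance is reported
    explicitly, never silent.
    """
    out = het.copy()
    out["hb_outlier"] = False
    for marker, grp in het.groupby("marker"):
        q1, q3 = grp["Hb_prime"].quantile([0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        mask = (grp["Hb_prime"] < lo) | (grp["Hb_prime"] > hi)
        out.loc[grp.index[mask], "hb_outlier"] = True
    return out


def stutter_stats(observations: pd.DataFrame) -> dict:
    """Stutter-ratio statistics grouped by marker x stutter type.

    Returns per-group :class:`MetricSummary` objects, the mean + 3*SD filter
    threshold, per-allele mean ratios, and the least-squares trend slope of
    per-allele mean S_R versus parent repeat number (alleles with no
    observed stutter are absent, which biases group means upward; reported
    as is).
    """
    if observations.empty:
        return {"groups": {}, "thresholds": {}, "allele_means": observations,
                "trend": {}}
    groups: dict[tuple[str, str], MetricSummary] = {}
    thresholds: dict[tuple[str, str], float] = {}
    trend: dict[tuple[str, str], dict] = {}
    allele_means = (observations
                    .groupby(["marker", "type", "parent_allele",
                              "parent_repeats"])["S_R"]
                    .mean().reset_index(name="mean_S_R"))
    for (marker, stype), grp in observations.groupby(["marker", "type"]):
        summ = MetricSummary.from_values(grp["S_R"])
        groups[(marker, stype)] = summ
        thresholds[(marker, stype)] = summ.upper_3sd
        am = allele_means[(allele_means["marker"] == marker)
                          & (allele_means["type"] == stype)]
        if am["parent_repeats"].nunique() >= 2:
            slope, intercept = np.polyfit(am["parent_repeats"],
                                          am["mean_S_R"], 1)
            trend[(marker, stype)] = {"slope": float(slope),
                                      "intercept": float(intercept),
                                      "n_alleles": int(len(am))}
    return {"groups": groups, "thresholds": thresholds,
            "allele_means": allele_means, "trend": trend}


def stutter_filter_thresholds(observations: pd.DataFrame,
                              stype: str = "n-k") -> dict[str, float]:
    """Per-marker stutter-filter settings (mean + 3*SD of the backward
    stutter ratio), for feeding back into genotype calling."""
    stats = stutter_stats(observations)
    return {marker: thr for (marker, t), thr in stats["thresholds"].items()
            if t == stype}


def sensitivity_report(calls: pd.DataFrame, truth_genotypes: pd.DataFrame,
                       panel: Panel) -> pd.DataFrame:
    """Dropout and balance summary across a dilution series.

    Classifies each call against the true genotype: a true heterozygote
    called as a single-allele homozygote is an allelic dropout; an expected
    marker with no called allele is a locus dropout. A full profile calls
    every panel locus. Returns one row per dose with counts and Hb / Hb'
    summary statistics.
    """
    truth_idx = truth_genotypes.set_index(["sample_id", "marker"])
    hets = het_balance(calls, panel)
    rows = []
    for dose, grp in calls.groupby("dose_ng"):
        locus_dropouts = 0
        allelic_dropouts = 0
        full_profiles = 0
        for sid, sgrp in grp.groupby("sample_id"):
            complete = True
            for call in sgrp.itertuples(index=False):
                try:
                    t = truth_idx.loc[(sid, call.marker)]
                except KeyError:
                    continue
                true_het = str(t["allele1"]) != str(t["allele2"])
                if call.allele1 is None:
                    locus_dropouts += 1
                    complete = False
                elif true_het and call.zygosity == "hom":
                    allelic_dropouts += 1
            if complete:
                full_profiles += 1
        hd = hets[hets["dose_ng"] == dose]
        row = {"dose_ng": dose, "n_samples": grp["sample_id"].nunique(),
               "full_profiles": full_profiles,
               "locus_dropouts": locus_dropouts,
               "allelic_dropouts": allelic_dropouts}
        if len(hd):
            row.update({"Hb_mean": hd["Hb"].mean(),
                        "Hb_sd": hd["Hb"].std(ddof=1),
                        "Hb_prime_mean": hd["Hb_prime"].mean(),
                        "Hb_prime_sd": hd["Hb_prime"].std(ddof=1),
                        "n_het": len(hd)})
        rows.append(row)
    return pd.DataFrame(rows).sort_values("dose_ng").reset_index(drop=True)


def cross_reactivity(peaks: pd.DataFrame, analytical_threshold: float,
                     near_factor: float = 1.5) -> pd.DataFrame:
    """Cross-species amplification summary.

    ``peaks`` carries a ``taxon`` column (non-target species profiles). For
    each taxon, counts the number of distinct markers with at least one peak
    passing the analytical threshold (a marker is counted once regardless of
    peak count) and separately the markers whose passing signal stays within
    ``near_factor`` times the threshold (near-threshold, weak
    cross-reactivity).
    """
    rows = []
    for taxon, grp in peaks.groupby("taxon"):
        passing = grp[grp["height_rfu"] >= analytical_threshold]
        markers = sorted(passing["marker"].unique())
        near = sorted(
            m for m, g in passing.groupby("marker")
            if g["height_rfu"].max() < near_factor * analytical_threshold)
        rows.append({"taxon": taxon, "n_markers_amplifying": len(markers),
                     "markers": ";".join(markers),
                     "n_markers_near_threshold": len(near),
                     "near_threshold_markers": ";".join(near)})
    return pd.DataFrame(rows, columns=["taxon", "n_markers_amplifying",
                                       "markers",
                                       "n_markers_near_threshold",
                                       "near_threshold_markers"])
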