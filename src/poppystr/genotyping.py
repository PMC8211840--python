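"""Capillary-electrophoresis genotype calling.

Turns fragment-analysis peak tables into genotypes: analytical-threshold
flagging, allelic-ladder composition by greedy set cover, +/-0.4 bp bin
calling with stutter filtering, stutter-peak classification (backward,
double-backward, forward and the 1-bp series), and ladder sizing-precision
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import Panel, parse_allele_label

__all__ = [
    "LadderDefinition", "apply_threshold", "build_ladder", "call_genotypes",
    "classify_stutters", "sizing_precision", "DEFAULT_BIN_HALF_WIDTH",
    "DEFAULT_STUTTER_FILTER",
]

DEFAULT_BIN_HALF_WIDTH = 0.4   # bp, the default binning range
DEFAULT_STUTTER_FILTER = 0.15  # fallback ratio when unestimated
STUTTER_MATCH_TOL = 0.5        # bp, stutter-position matching tolerance


@dataclass
class LadderDefinition:
    """Allelic-ladder bin set: per marker an ordered allele -> mean size
    map plus the common bin half-width.

    Within a marker adjacent bin centers must differ by more than twice the
    half-width so that bins never overlap."""

    bins: dict[str, dict[str, float]]
    half_width: float = DEFAULT_BIN_HALF_WIDTH
    missing_alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half width must be positive")
        for marker, bm in self.bins.items():
            centers = sorted(bm.values())
            for a, b in zip(centers, centers[1:]):
                if b - a <= 2 * self.half_width:
                    raise ValueError(
                        f"overlapping bins in {marker}: centers {a} and {b} "
                        f"with half width {self.half_width}")

    def assign(self, marker: str, size: float) -> str | None:
        """Allele label of the bin containing *size*, or None (off-ladder)."""
        for label, center in self.bins.get(marker, {}).items():
            if abs(size - center) <= self.half_width:
                return label
        return None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"half_width": self.half_width, "bins": self.bins,
                       "missing_alleles": [list(t) for t in
                                           self.missing_alleles]},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LadderDefinition":
        with open(path) as fh:
            d = json.load(fh)
        return cls(bins=d["bins"], half_width=d["half_width"],
                   missing_alleles=[tuple(t) for t in
                                    d.get("missing_alleles", [])])


def apply_threshold(peaks: pd.DataFrame,
                    analytical_threshold: float) -> pd.DataFrame:
    """Flag peaks under the analytical threshold; nothing is deleted."""
    if analytical_threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = peaks.copy()
    out["below_threshold"] = out["height_rfu"] < analytical_threshold
    return out


def build_ladder(
    inventory: Mapping[str, Sequence[str]],
    genotypes: pd.DataFrame,
    panel: Panel,
    half_width: float = DEFAULT_BIN_HALF_WIDTH,
) -> tuple[list[str], LadderDefinition]:
    """Compose an allelic ladder by greedy set cover over samples.

    Repeatedly picks the sample carrying the most still-uncovered inventory
    alleles (ties broken by lexicographic sample id) until no pick adds
    coverage. Alleles carried by no sample are reported in
    ``missing_alleles`` and the ladder is built from the rest.
    """
    universe = {(m, str(a)) for m, alleles in inventory.items()
                for a in alleles}
    carried: dict[str, set[tuple[str, str]]] = {}
    for row in genotypes.itertuples(index=False):
        s = carried.setdefault(row.sample_id, set())
        for a in (str(row.allele1), str(row.allele2)):
            if (row.marker, a) in universe:
                s.add((row.marker, a))
    coverable = set().union(*carried.values()) if carried else set()
    missing = sorted(universe - coverable)

    selected: list[str] = []
    uncovered = set(coverable)
    while uncovered:
        best = max(sorted(carried),
                   key=lambda s: (len(carried[s] & uncovered),))
        gain = carried[best] & uncovered
        if not gain:
            break
        selected.append(best)
        uncovered -= gain

    bins = {m: {str(a): panel.allele_size(m, str(a))
                for a in alleles if (m, str(a)) not in set(missing)}
            for m, alleles in inventory.items()}
    bins = {m: dict(sorted(bm.items(), key=lambda kv: kv[1]))
            for m, bm in bins.items() if bm}
    ladder = LadderDefinition(bins=bins, half_width=half_width,
                              missing_alleles=missing)
    return selected, ladder


def _bin_peaks(peaks: pd.DataFrame, ladder: LadderDefinition,
               panel: Panel) -> pd.DataFrame:
    """Assign each peak to a (marker, allele) bin by dye and size.

    Candidate markers share the peak's dye (and assay, when the peak table
    carries one: assays are separate injections). A peak matching two bins
    is a hard error (precluded by the ladder invariant within a marker;
    across markers it would mean overlapping same-lane size ranges)."""
    out = peaks.copy()
    has_assay = "assay" in out.columns
    markers_by_lane: dict[tuple, list[str]] = {}
    for m in panel:
        if m.name in ladder.bins:
            key = (m.assay, m.dye) if has_assay else (m.dye,)
            markers_by_lane.setdefault(key, []).append(m.name)
    assigned_marker: list[str | None] = []
    assigned_allele: list[str | None] = []
    for row in out.itertuples(index=False):
        key = (row.assay, row.dye) if has_assay else (row.dye,)
        matches = []
        for mname in markers_by_lane.get(key, []):
            label = ladder.assign(mname, row.size_bp)
            if label is not None:
                matches.append((mname, label))
        if len(matches) > 1:
            raise RuntimeError(
                f"peak at {row.size_bp:.2f} bp ({row.dye}) matches multiple "
                f"bins: {matches}")
        assigned_marker.append(matches[0][0] if matches else None)
        assigned_allele.append(matches[0][1] if matches else None)
    out["bin_marker"] = assigned_marker
    out["bin_allele"] = assigned_allele
    return out


def call_genotypes(
    peaks: pd.DataFrame,
    ladder: LadderDefinition,
    panel: Panel,
    stutter_thresholds: Mapping[str, float] | None = None,
    max_alleles: int = 2,
    low_dose_ng: float = 0.5,
) -> pd.DataFrame:
    """Call genotypes from a thresholded peak table.

    Passing peaks are assigned to ladder bins (|size - center| <= half
    width); an assigned peak one repeat unit below a taller called allele
    whose height ratio is at most the marker's stutter-filter threshold is
    removed as stutter. Zero surviving alleles at an expected marker is a
    locus dropout; one is a homozygote (with ``allelic_dropout_suspected``
    when the sample's dose metadata is below ``low_dose_ng``); more than
    ``max_alleles`` raises the ``excess_alleles`` flag.
    """
    stutter_thresholds = stutter_thresholds or {}
    binned = _bin_peaks(peaks, ladder, panel)
    calls = []
    expected = [m for m in panel.names() if m in ladder.bins]
    sample_meta = peaks.drop_duplicates("sample_id").set_index("sample_id")
    by_sample = dict(tuple(binned.groupby("sample_id")))
    for sid in sorted(by_sample):
        sub = by_sample[sid]
        dose = float(sample_meta.loc[sid, "dose_ng"]) \
            if "dose_ng" in sample_meta.columns else float("nan")
        variety = sample_meta.loc[sid, "variety"] \
            if "variety" in sample_meta.columns else ""
        for mname in expected:
            marker = panel[mname]
            mpeaks = sub[(sub["bin_marker"] == mname)
                         & ~sub["below_threshold"]]
            lane = sub["dye"] == marker.dye
            if "assay" in sub.columns:
                lane &= sub["assay"] == marker.assay
            off_ladder = bool((lane & sub["bin_marker"].isna()
                               & ~sub["below_threshold"]).any())
            flags = set()
            # tallest peak per bin
            per_bin: dict[str, float] = {}
            for row in mpeaks.itertuples(index=False):
                per_bin[row.bin_allele] = max(
                    per_bin.get(row.bin_allele, 0.0), row.height_rfu)
            thr = stutter_thresholds.get(mname, DEFAULT_STUTTER_FILTER)
            centers = ladder.bins[mname]
            surviving = dict(per_bin)
            for label, h in sorted(per_bin.items(), key=lambda kv: -kv[1]):
                if label not in surviving:
                    continue
                for other, oh in list(surviving.items()):
                    if other == label:
                        continue
                    gap = centers[label] - centers[other]
                    if (abs(gap - marker.motif_length) <= STUTTER_MATCH_TOL
                            and oh <= thr * h):
                        del surviving[other]
                        flags.add("stutter_filtered")
            alleles = sorted(surviving, key=lambda a: centers[a])
            zygosity = None
            if len(alleles) == 0:
                flags.add("locus_dropout")
                if bool(((sub["bin_marker"] == mname)
                         & sub["below_threshold"]).any()):
                    flags.add("below_threshold")
            elif len(alleles) == 1:
                zygosity = "hom"
                if not np.isnan(dose) and dose < low_dose_ng:
                    flags.add("allelic_dropout_suspected")
            elif len(alleles) <= max_alleles:
                zygosity = "het"
            else:
                flags.add("excess_alleles")
                zygosity = "error"
            if off_ladder:
                flags.add("off_ladder")
            calls.append({
                "sample_id": sid, "variety": variety, "marker": mname,
                "assay": marker.assay, "dose_ng": dose,
                "allele1": alleles[0] if alleles else None,
                "allele2": (alleles[1] if len(alleles) > 1
                            else (alleles[0] if len(alleles) == 1 else None)),
                "zygosity": zygosity,
                "heights": {a: surviving[a] for a in alleles},
                "flags": ";".join(sorted(flags)),
            })
    return pd.DataFrame(calls)


def classify_stutters(
    peaks: pd.DataFrame,
    calls: pd.DataFrame,
    panel: Panel,
    tol: float = STUTTER_MATCH_TOL,
) -> pd.DataFrame:
    """Type candidate stutter peaks against called parent alleles.

    For every called allele, peaks of the same sample and dye lying within
    ``tol`` of an expected stutter position are classified: ``n-k``,
    ``n-2k`` and ``n+k`` at one-repeat-unit offsets, plus the ``n-2bp`` /
    ``n-3bp`` / ``n-4bp`` series for markers configured with it. A peak
    taller than the parent is never classified as that parent's backward
    stutter. S_R = phi_S / phi_A.
    """
    obs = []
    peak_by_sample = dict(tuple(peaks.groupby("sample_id")))
    for call in calls.itertuples(index=False):
        if not call.allele1:
            continue
        marker = panel[call.marker]
        sub = peak_by_sample.get(call.sample_id)
        if sub is None:
            continue
        sub = sub[sub["dye"] == marker.dye]
        if "assay" in sub.columns:
            sub = sub[sub["assay"] == marker.assay]
        heights = call.heights if isinstance(call.heights, dict) else {}
        alleles = {call.allele1, call.allele2} - {None}
        for allele in sorted(alleles):
            parent_size = marker.allele_size(allele)
            phi_a = heights.get(allele)
            if not phi_a:
                continue
            offsets = {"n-k": -marker.motif_length,
                       "n-2k": -2 * marker.motif_length,
                       "n+k": marker.motif_length}
            if marker.stutter_1bp_series:
                offsets.update({f"n-{j}bp": -j for j in (2, 3, 4)})
            parent_sizes = {marker.allele_size(a) for a in alleles}
            for row in sub.itertuples(index=False):
                if abs(row.size_bp - parent_size) <= tol:
                    continue  # the parent itself
                if any(abs(row.size_bp - s) <= tol for s in parent_sizes):
                    continue  # another called allele, not a stutter
                for stype, off in offsets.items():
                    if abs(row.size_bp - (parent_size + off)) <= tol:
                        if off < 0 and row.height_rfu > phi_a:
                            continue
                        obs.append({
                            "sample_id": call.sample_id,
                            "marker": call.marker,
                            "parent_allele": allele,
                            "parent_repeats":
                                marker.allele_repeats(allele),
                            "type": stype,
                            "phi_S": row.height_rfu, "phi_A": phi_a,
                            "S_R": row.height_rfu / phi_a,
                        })
                        break
    return pd.DataFrame(obs, columns=["sample_id", "marker", "parent_allele",
                                      "parent_repeats", "type", "phi_S",
                                      "phi_A", "S_R"])


def sizing_precision(
    runs: pd.DataFrame,
    half_width: float = DEFAULT_BIN_HALF_WIDTH,
) -> dict:
    """Sizing precision of repeated allelic-ladder injections.

    ``runs`` has columns ``marker, allele, injection, size_bp`` with at
    least two injections per allele. Returns per-allele means and sample
    SDs, the averaged SD with its SEM (SD of per-allele SDs / sqrt(count)),
    the min/max SD, and a per-allele verdict flagging alleles whose 3*SD
    exceeds the bin half-width.
    """
    grouped = runs.groupby(["marker", "allele"])["size_bp"]
    counts = grouped.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"allele {bad} has fewer than 2 injections")
    per_allele = pd.DataFrame({
        "mean_size": grouped.mean(),
        "sd": grouped.std(ddof=1),
        "n_injections": counts,
    })
    per_allele["exceeds_bin"] = 3 * per_allele["sd"] > half_width
    sds = per_allele["sd"]
    return {
        "per_allele": per_allele.reset_index(),
        "mean_sd": float(sds.mean()),
        "sem": float(sds.std(ddof=1) / np.sqrt(len(sds)))
        if len(sds) > 1 else 0.0,
        "min_sd": float(sds.min()),
        "max_sd": float(sds.max()),
        "n_alleles": int(len(sds)),
    }
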