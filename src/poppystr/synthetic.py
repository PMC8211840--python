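"""Synthetic data generation for every pipeline stage.

Generates, from explicit parameters and a seed:

* genomes with planted perfect repeats (test bed for the miner);
* inbred multi-variety genotype sets with per-variety allele pools and
  near-zero heterozygosity, emulating registered pure breeding lines;
* capillary-electrophoresis peak tables with stutter, heterozygote
  imbalance, dose-dependent dropout, null alleles and Gaussian sizing noise;
* allele amplicon sequences with prescribed repeat structures and flanking
  variants (fixture source for the nomenclature engine).

All randomness flows from one seeded :func:`numpy.random.default_rng`
generator; per-sample sub-streams are derived from (seed, sample index) so
outputs are reproducible regardless of iteration order. Every emitted peak
carries exactly one provenance record in the accompanying truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mining import scan_perfect_ssrs
from .nomenclature import (FlankVariant, MarkerReference, RepeatStructure,
                           apply_variants)
from .panel import Marker, Panel, parse_allele_label

__all__ = [
    "PlantedRepeatSpec", "StutterParams", "DropoutModel", "SimulationConfig",
    "TruthTable", "generate_genome", "generate_varieties",
    "simulate_profiles", "simulate_allele_sequence",
    "engineered_variety_dataset", "genotype_matrix_from_truth",
]

PEAK_COLUMNS = ["sample_id", "variety", "assay", "marker", "dye",
                "size_bp", "height_rfu", "dose_ng", "below_threshold"]


@dataclass(frozen=True)
class PlantedRepeatSpec:
    """A perfect repeat to plant into a synthetic chromosome."""

    chrom_id: str
    start: int          # 1-based
    motif: str
    n_repeats: int

    def __post_init__(self) -> None:
        if not self.motif or any(c not in "ACGT" for c in self.motif):
            raise ValueError(f"motif must be non-empty ACGT, got "
                             f"{self.motif!r}")
        if not 2 <= len(self.motif) <= 6:
            raise ValueError("motif length must be 2-6")
        if self.n_repeats < 1 or self.start < 1:
            raise ValueError("start and n_repeats must be positive")

    @property
    def end(self) -> int:
        return self.start + len(self.motif) * self.n_repeats - 1


@dataclass(frozen=True)
class StutterParams:
    """Linear stutter-ratio model for one stutter type:
    ``S_R = base + slope * NR`` of the parent allele."""

    base: float = 0.0
    slope: float = 0.0

    def ratio(self, n_repeats: int) -> float:
        return max(0.0, self.base + self.slope * n_repeats)


@dataclass(frozen=True)
class DropoutModel:
    """Per-allele-copy dropout probability, logistic in log2(dose):
    ``P(drop) = 1 / (1 + (dose / d50) ** slope)``.

    At ``dose == d50`` each allele copy drops with probability 0.5; higher
    doses drop less. A heterozygote losing one copy becomes an apparent
    homozygote (allelic dropout); losing both copies is a locus dropout.
    """

    d50_ng: float = 0.2
    slope: float = 2.0

    def p_dropout(self, dose_ng: float) -> float:
        if dose_ng <= 0:
            raise ValueError("dose must be positive")
        return 1.0 / (1.0 + (dose_ng / self.d50_ng) ** self.slope)


@dataclass
class SimulationConfig:
    """Electrophoresis simulation parameters.

    Defaults reproduce a healthy single-source profile at the optimal
    1.25 ng dose: lognormal parent peaks around 2000 rfu, mild size-dependent
    degradation (drives heterozygote imbalance toward the smaller allele),
    backward stutter around 5-8%, sizing noise 0.06 bp SD and a 200 rfu
    analytical threshold.
    """

    seed: int = 0
    dye_gains: Mapping[str, float] = field(default_factory=dict)
    height_log_mean: float = math.log(2000.0)
    height_log_sd: float = 0.25
    # stochastic few-copy effect: height dispersion grows as the template
    # amount falls, sigma_eff = height_log_sd * (ref_dose / dose) ** exponent
    dispersion_dose_exponent: float = 0.5
    degradation_slope: float = 0.002   # decrease of log-height per bp
    stutter: Mapping[str, StutterParams] = field(
        default_factory=lambda: {"n-k": StutterParams(0.02, 0.004),
                                 "n-2k": StutterParams(0.0, 0.001),
                                 "n+k": StutterParams(0.0, 0.0005)})
    stutter_by_marker: Mapping[str, Mapping[str, StutterParams]] = field(
        default_factory=dict)
    series_1bp_ratios: tuple[float, float, float] = (0.04, 0.03, 0.02)
    dropout: DropoutModel | None = field(default_factory=DropoutModel)
    sizing_sd_bp: float = 0.06
    null_alleles: frozenset[tuple[str, str]] = frozenset()  # (variety, marker)
    analytical_threshold: float = 200.0
    reference_dose_ng: float = 1.25

    def __post_init__(self) -> None:
        if self.sizing_sd_bp < 0 or self.height_log_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for params in list(self.stutter.values()) + [
                p for d in self.stutter_by_marker.values()
                for p in d.values()]:
            if not 0 <= params.base < 0.5:
                raise ValueError("stutter base ratio must be in [0, 0.5)")

    def stutter_params(self, marker: str, stype: str) -> StutterParams:
        override = self.stutter_by_marker.get(marker, {})
        if stype in override:
            return override[stype]
        return self.stutter.get(stype, StutterParams())


@dataclass
class TruthTable:
    """Ground truth accompanying a simulated dataset."""

    genotypes: pd.DataFrame | None = None   # sample, variety, marker, a1, a2
    provenance: pd.DataFrame | None = None  # one record per emitted peak
    planted: pd.DataFrame | None = None     # planted-locus registry
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genomes


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def generate_genome(
    n_chrom: int,
    chrom_length: int,
    planted: Sequence[PlantedRepeatSpec] = (),
    gc: float = 0.4,
    seed: int = 0,
    scrub_background: Mapping[int, int] | None = None,
) -> tuple[dict[str, str], TruthTable]:
    """Generate chromosomes with planted perfect repeats.

    Background bases are i.i.d. with the given GC fraction. Each planted run
    is guaranteed maximal: the bases flanking it are resampled so they cannot
    extend the run by one motif period. ``scrub_background`` (minimum repeat
    count per motif length) optionally disrupts any background run reaching
    those thresholds, yielding a repeat-free background against which planted
    loci can be recovered with perfect precision and recall.

    Chromosomes are named ``chr1 .. chrN``. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    specs_by_chrom: dict[str, list[PlantedRepeatSpec]] = {}
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    for spec in planted:
        if spec.chrom_id not in names:
            raise ValueError(f"planted spec on unknown chromosome: {spec}")
        if spec.end > chrom_length:
            raise ValueError(f"planted spec out of bounds: {spec}")
        specs_by_chrom.setdefault(spec.chrom_id, []).append(spec)
    for specs in specs_by_chrom.values():
        specs.sort(key=lambda s: s.start)
        for a, b in zip(specs, specs[1:]):
            if a.end >= b.start:
                raise ValueError(f"planted specs overlap: {a} / {b}")

    sequences: dict[str, str] = {}
    for name in names:
        arr = _random_bases(rng, chrom_length, gc)
        for spec in specs_by_chrom.get(name, []):
            run = np.array(list(spec.motif * spec.n_repeats))
            a0 = spec.start - 1
            arr[a0:a0 + len(run)] = run
            p = len(spec.motif)
            # maximality: neighbours must break the period
            if a0 > 0:
                while arr[a0 - 1] == arr[a0 - 1 + p]:
                    arr[a0 - 1] = rng.choice(np.array(list("ACGT")))
            b0 = a0 + len(run)  # first base after the run
            if b0 < chrom_length:
                while arr[b0] == arr[b0 - p]:
                    arr[b0] = rng.choice(np.array(list("ACGT")))
        seq = "".join(arr)
        if scrub_background is not None:
            planted_spans = [(s.start - 1, s.end) for s in
                             specs_by_chrom.get(name, [])]
            for _ in range(20):
                dirty = False
                for loc in scan_perfect_ssrs(seq, scrub_background):
                    a0, b0 = loc.start - 1, loc.end
                    if any(a0 < pe and b0 > ps for ps, pe in planted_spans):
                        continue
                    mid = (a0 + b0) // 2
                    old = seq[mid]
                    new = old
                    while new == old:
                        new = str(rng.choice(np.array(list("ACGT"))))
                    seq = seq[:mid] + new + seq[mid + 1:]
                    dirty = True
                if not dirty:
                    break
        sequences[name] = seq

    registry = pd.DataFrame(
        [{"chrom": s.chrom_id, "start": s.start, "end": s.end,
          "motif": s.motif, "n_repeats": s.n_repeats} for s in planted],
        columns=["chrom", "start", "end", "motif", "n_repeats"])
    return sequences, TruthTable(planted=registry,
                                 config={"seed": seed, "gc": gc,
                                         "chrom_length": chrom_length})


# ---------------------------------------------------------------------------
# varieties and genotypes

CATEGORIES = ("culinary", "dual", "pharmaceutical", "ornamental")


def generate_varieties(
    panel: Panel,
    n_varieties: int,
    plants_per_variety: int | Sequence[int],
    allele_pool_size: int | Mapping[str, int] = 2,
    residual_het_rate: float = 0.076,
    seed: int = 0,
    pools: Mapping[tuple[str, str], Sequence[str]] | None = None,
    categories: Mapping[str, str] | None = None,
) -> TruthTable:
    """Simulate inbred variety genotype sets.

    Each variety draws a per-marker allele pool from the marker's inventory
    (``pools`` overrides individual (variety, marker) pools). Every plant is
    homozygous for one pool allele except with probability
    ``residual_het_rate``, when it carries two distinct pool alleles, so
    realized observed heterozygosity matches the residual rate in
    expectation (pools of size 1 cannot yield heterozygotes).
    """
    if not 0 <= residual_het_rate <= 1:
        raise ValueError("residual_het_rate must be a fraction")
    rng = np.random.default_rng(seed)
    var_names = [f"VAR{i + 1:02d}" for i in range(n_varieties)]
    if isinstance(plants_per_variety, int):
        counts = [plants_per_variety] * n_varieties
    else:
        counts = list(plants_per_variety)
        if len(counts) != n_varieties:
            raise ValueError("plants_per_variety length mismatch")
    cat_of = categories or {v: CATEGORIES[i % 4]
                            for i, v in enumerate(var_names)}

    var_pools: dict[tuple[str, str], list[str]] = {}
    for v in var_names:
        for m in panel:
            key = (v, m.name)
            if pools is not None and key in pools:
                pool = list(pools[key])
                if not set(pool) <= set(m.alleles):
                    raise ValueError(f"pool for {key} outside inventory")
            else:
                k = (allele_pool_size if isinstance(allele_pool_size, int)
                     else allele_pool_size[m.name])
                if k > len(m.alleles):
                    raise ValueError(
                        f"pool size {k} exceeds inventory of {m.name} "
                        f"({len(m.alleles)} alleles)")
                pool = list(rng.choice(m.alleles, size=k, replace=False))
            var_pools[key] = pool

    rows = []
    sample_no = 0
    for v, cnt in zip(var_names, counts):
        for _ in range(cnt):
            sample_no += 1
            sid = f"S{sample_no:04d}"
            for m in panel:
                pool = var_pools[(v, m.name)]
                if len(pool) > 1 and rng.random() < residual_het_rate:
                    a1, a2 = rng.choice(pool, size=2, replace=False)
                else:
                    a1 = a2 = rng.choice(pool)
                rows.append({"sample_id": sid, "variety": v,
                             "category": cat_of[v], "marker": m.name,
                             "allele1": str(a1), "allele2": str(a2)})
    gt = pd.DataFrame(rows)
    return TruthTable(genotypes=gt,
                      config={"seed": seed,
                              "residual_het_rate": residual_het_rate,
                              "pools": {f"{v}|{m}": p for (v, m), p
                                        in var_pools.items()}})


def engineered_variety_dataset(
    panel: Panel,
    n_varieties: int = 36,
    group_sizes: Sequence[int] = (4, 2),
    plants_range: tuple[int, int] = (4, 9),
    residual_het_rate: float = 0.0,
    n_mislabels: int = 2,
    seed: int = 0,
) -> TruthTable:
    """Variety set with engineered indistinguishable groups and mislabels.

    Varieties inside each engineered group share identical single-allele
    pools (so every cross-variety plant pair matches at 0 mismatches); all
    remaining varieties receive unique allele signatures at the two
    highest-allele-count markers, guaranteeing pairwise distinguishability.
    ``n_mislabels`` plants are then relabelled with another variety's name
    (their true origin is recorded in the truth config).
    """
    rng = np.random.default_rng(seed)
    var_names = [f"VAR{i + 1:02d}" for i in range(n_varieties)]
    # assign group membership: first sum(group_sizes) varieties
    units: list[list[str]] = []
    idx = 0
    for g in group_sizes:
        units.append(var_names[idx:idx + g])
        idx += g
    units.extend([[v] for v in var_names[idx:]])

    markers = sorted(panel, key=lambda m: -len(m.alleles))
    sig_a, sig_b = markers[0], markers[1]
    la, lb = len(sig_a.alleles), len(sig_b.alleles)
    if la * lb < len(units):
        raise ValueError("panel cannot encode enough unique signatures")

    pools: dict[tuple[str, str], list[str]] = {}
    for u, unit in enumerate(units):
        for v in unit:
            for mi, m in enumerate(panel):
                if m.name == sig_a.name:
                    pools[(v, m.name)] = [sig_a.alleles[u % la]]
                elif m.name == sig_b.name:
                    # (u % la, u // la) is injective for u < la * lb
                    pools[(v, m.name)] = [sig_b.alleles[(u // la) % lb]]
                else:
                    # shared within a unit, random across units; mostly a
                    # single fixed allele (pure-line realism), occasionally
                    # two segregating pool alleles. Engineered group units
                    # stay fully fixed so their plants are identical.
                    unit_rng = np.random.default_rng([seed, 7, u, mi])
                    k = 1 if (len(unit) > 1 or len(m.alleles) < 2
                              or unit_rng.random() < 0.8) else 2
                    pools[(v, m.name)] = list(
                        unit_rng.choice(m.alleles, size=k, replace=False))
    counts = [int(rng.integers(plants_range[0], plants_range[1] + 1))
              for _ in var_names]
    truth = generate_varieties(panel, n_varieties, counts,
                               residual_het_rate=residual_het_rate,
                               seed=seed + 1, pools=pools)
    gt = truth.genotypes
    # plant mislabels: relabel a plant with another (singleton) variety's
    # name, and perturb two of its non-signature markers to private alleles
    # so it is near its true variety without 0-mismatch matching it (an
    # exact copy would instead merge the two varieties under the
    # discrimination rule)
    singles = [u[0] for u in units if len(u) == 1]
    other_markers = [m.name for m in panel
                     if m.name not in (sig_a.name, sig_b.name)]
    mislabels = []
    for j in range(n_mislabels):
        src, dst = singles[2 * j], singles[2 * j + 1]
        sample = sorted(gt.loc[gt["variety"] == src, "sample_id"])[0]
        cat = gt.loc[gt["variety"] == dst, "category"].iloc[0]
        gt.loc[gt["sample_id"] == sample, "variety"] = dst
        gt.loc[gt["sample_id"] == sample, "category"] = cat
        for mname in other_markers[2 * j:2 * j + 2]:
            used = set(pools[(src, mname)]) | set(pools[(dst, mname)])
            spare = [a for a in panel[mname].alleles if a not in used]
            private = spare[0] if spare else panel[mname].alleles[0]
            mask = (gt["sample_id"] == sample) & (gt["marker"] == mname)
            gt.loc[mask, ["allele1", "allele2"]] = private
        mislabels.append({"sample_id": sample, "true_variety": src,
                          "labelled_as": dst})
    truth.config.update({"groups": [list(u) for u in units if len(u) > 1],
                         "mislabels": mislabels})
    return truth


def genotype_matrix_from_truth(truth: TruthTable) -> pd.DataFrame:
    """Pivot a truth genotype table into the wide sample x marker matrix
    (``a1/a2`` cells) used by the population-analysis stage."""
    gt = truth.genotypes.copy()
    gt["cell"] = gt["allele1"].astype(str) + "/" + gt["allele2"].astype(str)
    wide = gt.pivot_table(index=["sample_id", "variety", "category"],
                          columns="marker", values="cell",
                          aggfunc="first").reset_index()
    wide.columns.name = None
    return wide


# ---------------------------------------------------------------------------
# CE profile simulation

STUTTER_OFFSETS = {"n-k": -1, "n-2k": -2, "n+k": +1}


def simulate_profiles(
    genotypes: pd.DataFrame,
    panel: Panel,
    config: SimulationConfig,
    dose_ng: float = 1.25,
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate a CE peak table for a genotype set.

    For each surviving allele copy a parent peak is emitted (lognormal
    height, dye gain, dose scaling, size-dependent degradation), plus stutter
    peaks at one-repeat-unit offsets per the marker's stutter model (and the
    1-bp series where the marker is configured for it). (variety, marker)
    pairs in the null-allele set emit nothing. Sizes are perturbed by
    Gaussian noise; peaks below the analytical threshold are flagged, never
    deleted. Dropout acts per allele copy.

    Returns the peak table and a truth table whose provenance has exactly
    one record per emitted peak.
    """
    if dose_ng <= 0:
        raise ValueError("dose must be positive")
    peaks: list[dict] = []
    prov: list[dict] = []
    samples = sorted(genotypes["sample_id"].unique())
    by_sample = dict(tuple(genotypes.groupby("sample_id")))
    p_drop = (config.dropout.p_dropout(dose_ng)
              if config.dropout is not None else 0.0)
    sigma = config.height_log_sd * (
        (config.reference_dose_ng / dose_ng)
        ** config.dispersion_dose_exponent)
    for s_idx, sid in enumerate(samples):
        rng = np.random.default_rng([config.seed, s_idx])
        sub = by_sample[sid]
        variety = sub["variety"].iloc[0]
        for row in sub.itertuples(index=False):
            marker = panel[row.marker]
            if (variety, marker.name) in config.null_alleles:
                continue
            gain = config.dye_gains.get(marker.dye, 1.0)
            copies: dict[str, float] = {}
            for allele in (str(row.allele1), str(row.allele2)):
                if p_drop and rng.random() < p_drop:
                    continue
                size = marker.allele_size(allele)
                log_h = (rng.normal(config.height_log_mean, sigma)
                         - config.degradation_slope * (size - 100.0))
                h = math.exp(log_h) * gain * (dose_ng
                                              / config.reference_dose_ng)
                copies[allele] = copies.get(allele, 0.0) + h
            for allele, height in sorted(copies.items()):
                size = marker.allele_size(allele)
                nr = marker.allele_repeats(allele)
                emitted = [(size, height, "allele", allele)]
                for stype, units in STUTTER_OFFSETS.items():
                    r = config.stutter_params(marker.name, stype).ratio(nr)
                    if r > 0:
                        emitted.append((size + units * marker.motif_length,
                                        r * height, stype, allele))
                if marker.stutter_1bp_series:
                    for j, r in enumerate(config.series_1bp_ratios,
                                          start=2):
                        if r > 0:
                            emitted.append((size - j, r * height,
                                            f"n-{j}bp", allele))
                for true_size, h, kind, parent in emitted:
                    obs_size = true_size + (
                        rng.normal(0.0, config.sizing_sd_bp)
                        if config.sizing_sd_bp else 0.0)
                    h_rfu = int(round(h))
                    peaks.append({
                        "sample_id": sid, "variety": variety,
                        "assay": marker.assay, "marker": marker.name,
                        "dye": marker.dye, "size_bp": obs_size,
                        "height_rfu": h_rfu, "dose_ng": dose_ng,
                        "below_threshold":
                            h_rfu < config.analytical_threshold})
                    prov.append({"sample_id": sid, "marker": marker.name,
                                 "kind": kind, "parent_allele": parent,
                                 "true_size": true_size})
    peak_df = pd.DataFrame(peaks, columns=PEAK_COLUMNS)
    truth = TruthTable(genotypes=genotypes.copy(),
                       provenance=pd.DataFrame(
                           prov, columns=["sample_id", "marker", "kind",
                                          "parent_allele", "true_size"]),
                       config={"dose_ng": dose_ng, "seed": config.seed})
    return peak_df, truth


# ---------------------------------------------------------------------------
# allele amplicon sequences


def simulate_allele_sequence(
    reference: MarkerReference,
    structure: RepeatStructure,
    variants: Sequence[FlankVariant] = (),
) -> str:
    """Build an allele amplicon: upstream flank (with U variants applied),
    the serialized repeat region, and the downstream flank (with D
    variants). Raises when a variant falls outside its flank."""
    up = apply_variants(reference.upstream, "U", variants)
    down = apply_variants(reference.downstream, "D", variants)
    return up + structure.sequence + down
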