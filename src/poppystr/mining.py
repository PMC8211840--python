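"""Perfect-microsatellite mining and marker candidate selection.

Finds perfect (uninterrupted) tandem repeats with motif lengths 2-6 nt in
genomic sequence, summarizes their chromosomal distribution, and applies the
candidate-selection rules used when assembling a forensic STR panel for a
large plant genome: per-motif-length repeat-number thresholds, chromosome
placement, locus uniqueness judged from whole-genome alignment hits, minimum
inter-locus distance (linkage avoidance) and primer cross-dimer screening.

Coordinates are 1-based and inclusive on the forward strand of the supplied
sequence. Runs are reported at their shortest period: a (AG)x12 run is one
dinucleotide locus, never a tetranucleotide (AGAG)x6. Mononucleotide runs are
never reported. ``N`` terminates runs; lowercase input is uppercased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SSRLocus",
    "CandidateCriteria",
    "UniquenessThresholds",
    "scan_perfect_ssrs",
    "scan_genome",
    "canonical_motif",
    "summarize_distribution",
    "select_candidates",
    "uniqueness_filter",
    "interlocus_distances",
    "dimer_score",
    "revcomp",
]

#: default phase-1 search settings: minimum repeat count by motif length
DEFAULT_MIN_REPEATS: Mapping[int, int] = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SSRLocus:
    """One perfect microsatellite run.

    ``start``/``end`` are 1-based inclusive; ``end - start + 1`` always equals
    ``len(motif) * n_repeats`` and the run is maximal (not extendable by one
    motif period in either direction).
    """

    chrom: str
    start: int
    end: int
    motif: str
    n_repeats: int
    on_chromosome: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.n_repeats:
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with "
                f"{self.n_repeats} x {self.motif}"
            )

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def canonical_motif(self) -> str:
        return canonical_motif(self.motif)


def _is_primitive(motif: str) -> bool:
    """True when *motif* is not itself a repetition of a shorter string."""
    return motif not in (motif + motif)[1:-1]


def scan_perfect_ssrs(
    sequence: str,
    min_repeats_by_motif_length: Mapping[int, int] | None = None,
    chrom: str = "seq",
    on_chromosome: bool = True,
) -> list[SSRLocus]:
    """Scan one sequence for perfect microsatellites.

    Parameters
    ----------
    sequence
        DNA over ``{A, C, G, T, N}`` (case-insensitive). ``N`` breaks runs.
    min_repeats_by_motif_length
        Minimum repeat count per motif length (period); defaults to the
        phase-1 settings ``{2: 6, 3: 5, 4: 5, 5: 5, 6: 5}``. Motif lengths
        absent from the mapping are not searched.

    Returns
    -------
    list of :class:`SSRLocus`, sorted by start position, each reported at its
    shortest period.
    """
    minrep = dict(DEFAULT_MIN_REPEATS if min_repeats_by_motif_length is None
                  else min_repeats_by_motif_length)
    seq = sequence.upper()
    if not seq:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype="S1"))
    bad = ~valid & ~(arr == b"N")
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(f"invalid character {seq[i]!r} at position {i + 1}")

    loci: list[SSRLocus] = []
    n = len(seq)
    for p, need in sorted(minrep.items()):
        if p < 2 or p > 6 or n < p * need:
            continue
        match = (arr[p:] == arr[:-p]) & valid[p:] & valid[:-p]
        # maximal True-runs in `match`: run [a, b] means seq[a : b+p+1] has
        # period p throughout
        padded = np.concatenate(([False], match, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1) - 1
        for a, b in zip(starts, ends):
            stretch_len = b - a + 1 + p
            nr = stretch_len // p
            if nr < need:
                continue
            if not _is_primitive(seq[a:a + p]):
                continue  # shortest-period rule: found at a smaller period
            # canonical phase: a stretch with a partial remainder admits
            # several placements of the full-copy run; report the one whose
            # motif is the lexicographically smallest rotation
            r = stretch_len - nr * p
            k_off = min(range(r + 1), key=lambda k: seq[a + k:a + k + p])
            start = int(a) + k_off
            loci.append(SSRLocus(chrom, start + 1, start + p * nr,
                                 seq[start:start + p], int(nr),
                                 on_chromosome))
    loci.sort(key=lambda l: (l.start, l.motif_length))
    return loci


def scan_genome(
    sequences: Mapping[str, str],
    min_repeats_by_motif_length: Mapping[int, int] | None = None,
    chromosome_names: Iterable[str] | None = None,
) -> list[SSRLocus]:
    """Scan several sequences; sort by (chrom, start).

    ``chromosome_names``, when given, marks which sequences are placed
    chromosomes (``on_chromosome=True``); all others are unplaced scaffolds.
    """
    chrom_set = None if chromosome_names is None else set(chromosome_names)
    out: list[SSRLocus] = []
    for name in sorted(sequences):
        placed = True if chrom_set is None else name in chrom_set
        out.extend(scan_perfect_ssrs(sequences[name],
                                     min_repeats_by_motif_length,
                                     chrom=name, on_chromosome=placed))
    out.sort(key=lambda l: (l.chrom, l.start, l.motif_length))
    return out


def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif's rotation/strand class.

    Returns the lexicographically smallest string among all rotations of the
    motif and all rotations of its reverse complement. Raises for motifs that
    are themselves periodic (they must be reported at their shortest period).
    """
    motif = motif.upper()
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 2-6, got {motif!r}")
    if any(c not in "ACGT" for c in motif):
        raise ValueError(f"invalid motif {motif!r}")
    if not _is_primitive(motif):
        raise ValueError(f"motif {motif!r} is periodic; report at its "
                         "shortest period")
    rc = revcomp(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def summarize_distribution(
    loci: Sequence[SSRLocus],
    chrom_lengths: Mapping[str, int],
    chromosomes_only: bool = True,
) -> dict:
    """Density and composition summary of a mined locus set.

    Returns a dict with:

    * ``density``: loci per Mb, per chromosome (pandas Series)
    * ``by_motif_length``: counts and fractions per motif-length class
    * ``by_n_repeats``: locus counts per repeat number

    By default only loci on sequences flagged as chromosomes are counted
    (``chromosomes_only=False`` includes scaffold-placed loci too).
    """
    used = [l for l in loci if l.on_chromosome or not chromosomes_only]
    for l in used:
        if l.chrom not in chrom_lengths:
            raise KeyError(f"locus chromosome {l.chrom!r} missing from "
                           "chrom_lengths")
    counts = pd.Series([l.chrom for l in used], dtype=object).value_counts()
    density = pd.Series(
        {c: counts.get(c, 0) / (length / 1e6)
         for c, length in chrom_lengths.items()},
        name="loci_per_Mb").sort_index()
    by_len = pd.Series([l.motif_length for l in used],
                       dtype=int).value_counts().sort_index()
    frac = by_len / by_len.sum() if len(by_len) else by_len.astype(float)
    by_nr = pd.Series([l.n_repeats for l in used],
                      dtype=int).value_counts().sort_index()
    return {
        "density": density,
        "by_motif_length": pd.DataFrame({"count": by_len, "fraction": frac}),
        "by_n_repeats": by_nr,
        "n_loci": len(used),
    }


@dataclass(frozen=True)
class CandidateCriteria:
    """Phase-2 candidate rules: repeat-number window per motif length plus
    chromosome placement.

    ``nr_rules`` maps motif length -> (min NR, max NR or None). The defaults
    are the published phase-2 settings: trinucleotide NR in [10, 15],
    tetranucleotide NR >= 7, penta/hexanucleotide NR >= 8; dinucleotides are
    not considered.
    """

    nr_rules: Mapping[int, tuple[int, int | None]] = field(
        default_factory=lambda: {3: (10, 15), 4: (7, None),
                                 5: (8, None), 6: (8, None)})
    require_chromosome: bool = True

    def __post_init__(self) -> None:
        for mlen, (lo, hi) in self.nr_rules.items():
            if lo <= 0:
                raise ValueError(f"NR minimum for motif length {mlen} must "
                                 "be positive")
            if hi is not None and hi < lo:
                raise ValueError(f"empty NR range for motif length {mlen}")

    def accepts(self, locus: SSRLocus) -> bool:
        rule = self.nr_rules.get(locus.motif_length)
        if rule is None:
            return False
        lo, hi = rule
        if locus.n_repeats < lo or (hi is not None and locus.n_repeats > hi):
            return False
        if self.require_chromosome and not locus.on_chromosome:
            return False
        return True


def select_candidates(
    loci: Sequence[SSRLocus],
    criteria: CandidateCriteria | None = None,
) -> list[SSRLocus]:
    """Filter mined loci by the candidate criteria; order-preserving."""
    criteria = criteria or CandidateCriteria()
    return [l for l in loci if criteria.accepts(l)]


@dataclass(frozen=True)
class UniquenessThresholds:
    """Locus-uniqueness rules evaluated over whole-genome alignment hits.

    The published selection used an alignment-based triage (best-hit masking,
    count of significant alignments, count of high-query-cover hits) whose
    numeric settings were not released; these defaults are explicit,
    documented stand-ins.
    """

    significant_evalue: float = 1e-10
    high_cover_fraction: float = 0.80
    max_significant_hits: int = 1
    max_high_cover_hits: int = 1
    min_best_hit_gap: float = 10.0  # bitscore units

    def __post_init__(self) -> None:
        if min(self.max_significant_hits, self.max_high_cover_hits) < 0 \
                or self.min_best_hit_gap < 0:
            raise ValueError("thresholds must be non-negative")


BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore"]


def read_blast_hits(path) -> pd.DataFrame:
    """Read 12-column tabular alignment hits (optionally 13th qcovs column)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 12:
        df.columns = BLAST6_COLUMNS
    elif df.shape[1] == 13:
        df.columns = BLAST6_COLUMNS + ["qcovs"]
    else:
        raise ValueError(f"expected 12 or 13 tab-separated columns, "
                         f"got {df.shape[1]}")
    return df


def uniqueness_filter(
    candidates: Sequence[str],
    hits: pd.DataFrame,
    thresholds: UniquenessThresholds | None = None,
    query_lengths: Mapping[str, int] | None = None,
) -> tuple[list[str], list[tuple[str, list[str]]]]:
    """Partition candidate query ids into unique (kept) and rejected.

    A candidate is kept iff

    1. the count of hits with e-value below ``significant_evalue`` is at most
       ``max_significant_hits``;
    2. the count of hits with query cover >= ``high_cover_fraction`` is at
       most ``max_high_cover_hits``;
    3. the best-hit bitscore exceeds the second best by at least
       ``min_best_hit_gap`` (trivially satisfied with a single hit).

    Query cover is taken from a ``qcovs`` column (percent) when present,
    otherwise computed as ``(qend - qstart + 1) / query_length`` which then
    requires ``query_lengths``. A candidate with no hit at all (not even its
    self-hit) indicates malformed alignment input and raises.
    """
    thresholds = thresholds or UniquenessThresholds()
    kept: list[str] = []
    rejected: list[tuple[str, list[str]]] = []
    grouped = dict(tuple(hits.groupby("qseqid")))
    for cand in candidates:
        sub = grouped.get(cand)
        if sub is None or len(sub) == 0:
            raise ValueError(f"candidate {cand!r} has no alignment hit "
                             "(missing self-hit): malformed input")
        if "qcovs" in sub.columns:
            cover = sub["qcovs"].to_numpy(float) / 100.0
        else:
            if query_lengths is None or cand not in query_lengths:
                raise ValueError("query cover requires a qcovs column or "
                                 f"query_lengths for {cand!r}")
            span = (sub["qend"] - sub["qstart"]).abs() + 1
            cover = span.to_numpy(float) / query_lengths[cand]
        reasons = []
        n_sig = int((sub["evalue"] < thresholds.significant_evalue).sum())
        if n_sig > thresholds.max_significant_hits:
            reasons.append("significant-hit count")
        n_cov = int((cover >= thresholds.high_cover_fraction).sum())
        if n_cov > thresholds.max_high_cover_hits:
            reasons.append("high-query-cover count")
        scores = np.sort(sub["bitscore"].to_numpy(float))[::-1]
        if len(scores) > 1 and scores[0] - scores[1] < thresholds.min_best_hit_gap:
            reasons.append("best-hit gap")
        if reasons:
            rejected.append((cand, reasons))
        else:
            kept.append(cand)
    return kept, rejected


def interlocus_distances(
    markers: Mapping[str, tuple[str, int]],
    linkage_threshold_bp: int = 50_000_000,
) -> pd.DataFrame:
    """Pairwise marker distances with linkage flags.

    ``markers`` maps marker name -> (chromosome, 1-based position). Pairs on
    the same chromosome closer than ``linkage_threshold_bp`` (default 50 Mb)
    are flagged ``possible linkage``; all other pairs are ``independent``.
    """
    names = sorted(markers)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ca, pa = markers[a]
            cb, pb = markers[b]
            same = ca == cb
            dist = abs(pa - pb) if same else None
            flag = ("possible linkage"
                    if same and dist < linkage_threshold_bp else "independent")
            rows.append({"marker_a": a, "marker_b": b,
                         "same_chromosome": same, "distance_bp": dist,
                         "flag": flag})
    return pd.DataFrame(rows, columns=["marker_a", "marker_b",
                                       "same_chromosome", "distance_bp",
                                       "flag"])


def dimer_score(primer_a: str, primer_b: str) -> int:
    """Primer cross-dimer score: longest contiguous Watson-Crick
    complementary window over all ungapped antiparallel offsets.

    The score mirrors the AutoDimer-style screen used when composing
    multiplexes (threshold "5 or lower" for co-amplified primer pairs):
    ``dimer_score(a, revcomp(a)) == len(a)`` and the function is symmetric.
    """
    a = primer_a.upper()
    b = primer_b.upper()
    for p in (a, b):
        if len(p) < 8:
            raise ValueError("primers must be at least 8 nt")
        if any(c not in "ACGT" for c in p):
            raise ValueError(f"primer contains non-ACGT character: {p!r}")
    c = revcomp(b)
    best = 0
    for off in range(-(len(c) - 1), len(a)):
        run = 0
        for i in range(len(a)):
            j = i - off
            if 0 <= j < len(c) and a[i] == c[j]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best
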