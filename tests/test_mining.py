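"""Perfect-repeat scanner, candidate selection, uniqueness and dimer score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poppystr.mining import (CandidateCriteria, SSRLocus,
                             UniquenessThresholds, canonical_motif,
                             dimer_score, interlocus_distances, revcomp,
                             scan_perfect_ssrs, select_candidates,
                             summarize_distribution, uniqueness_filter)


def brute_force_scan(seq, minrep):
    """Independent oracle: test every (start, period) placement by direct
    string comparison. A placement survives when its motif is primitive, it
    holds enough full copies, it is not extendable by a full period, it is
    not nested in a longer-copy placement, and it is the canonical phase of
    its stretch (lexicographically smallest motif, then smallest start)."""
    seq = seq.upper()
    found = []
    for p, need in minrep.items():
        for start in range(len(seq) - p + 1):
            motif = seq[start:start + p]
            if any(c not in "ACGT" for c in motif):
                continue
            if any(motif == (motif[k:] + motif[:k]) for k in range(1, p)):
                continue  # periodic motif
            k = 0
            while seq[start + k * p: start + (k + 1) * p] == motif:
                k += 1
            if k < need:
                continue
            if start >= p and seq[start - p:start] == motif:
                continue  # extendable by a full period on the left
            end = start + k * p
            # partial periodic context around the placement
            left = 0
            while (start - left - 1 >= 0
                   and seq[start - left - 1] in "ACGT"
                   and seq[start - left - 1] == seq[start - left - 1 + p]):
                left += 1
            right = 0
            while (end + right < len(seq) and seq[end + right] in "ACGT"
                   and seq[end + right] == seq[end + right - p]):
                right += 1
            if left + right >= p:
                continue  # nested inside a placement with more copies
            phases = [(seq[start - left + j: start - left + j + p],
                       start - left + j) for j in range(left + right + 1)]
            if min(phases) != (motif, start):
                continue  # not the canonical phase of this stretch
            found.append((start + 1, end, motif, k))
    return sorted(set(found))


MINREP = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


class TestScanner:
    def test_planted_tetra_run(self):
        loci = scan_perfect_ssrs("CCT" + "AGAT" * 7 + "GGC", {4: 5})
        assert len(loci) == 1
        (l,) = loci
        assert (l.start, l.end, l.motif, l.n_repeats) == (4, 31, "AGAT", 7)

    def test_dinucleotide_below_minimum_not_reported(self):
        assert scan_perfect_ssrs("GGC" + "AG" * 5 + "TTC", {2: 6}) == []
        assert len(scan_perfect_ssrs("GGC" + "AG" * 6 + "TTC", {2: 6})) == 1

    def test_empty_sequence(self):
        assert scan_perfect_ssrs("", MINREP) == []

    def test_invalid_alphabet_reports_first_bad_character(self):
        with pytest.raises(ValueError, match="'R'"):
            scan_perfect_ssrs("ACGTRRR", MINREP)

    def test_n_breaks_runs(self):
        seq = "AG" * 4 + "N" + "AG" * 4
        assert scan_perfect_ssrs(seq, {2: 6}) == []
        assert len(scan_perfect_ssrs(seq, {2: 4})) == 2

    def test_shortest_period_rule(self):
        # an (AG)x12 run is one dinucleotide locus, never (AGAG)x6
        loci = scan_perfect_ssrs("CC" + "AG" * 12 + "TT", MINREP)
        assert [(l.motif, l.n_repeats) for l in loci] == [("AG", 12)]

    def test_lowercase_uppercased(self):
        loci = scan_perfect_ssrs("cct" + "agat" * 7, {4: 5})
        assert loci[0].motif == "AGAT"

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(200, 2000))
        # AT-rich and occasional N to provoke edge cases
        seq = "".join(rng.choice(list("ACGTN"),
                                 p=[0.32, 0.16, 0.16, 0.32, 0.04], size=n))
        got = sorted((l.start, l.end, l.motif, l.n_repeats)
                     for l in scan_perfect_ssrs(seq, MINREP))
        assert got == brute_force_scan(seq, MINREP)

    def test_locus_invariant_span(self):
        for l in scan_perfect_ssrs("A" + "CAG" * 8 + "T" + "TG" * 7, MINREP):
            assert l.end - l.start + 1 == len(l.motif) * l.n_repeats


dna_text = st.text(alphabet="ACGT", min_size=0, max_size=400)


class TestScannerProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(dna_text)
    def test_scanner_equals_oracle_on_arbitrary_dna(self, seq):
        got = sorted((l.start, l.end, l.motif, l.n_repeats)
                     for l in scan_perfect_ssrs(seq, MINREP))
        assert got == brute_force_scan(seq, MINREP)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(dna_text)
    def test_reported_runs_are_verbatim_tandems(self, seq):
        for l in scan_perfect_ssrs(seq, MINREP):
            assert seq.upper()[l.start - 1:l.end] == l.motif * l.n_repeats


class TestCanonicalMotif:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=6))
    def test_idempotent_and_symmetric(self, motif):
        if motif in (motif + motif)[1:-1]:
            return  # periodic motifs are rejected elsewhere
        canon = canonical_motif(motif)
        assert canonical_motif(canon) == canon
        assert canonical_motif(motif[1:] + motif[0]) == canon
        assert canonical_motif(revcomp(motif)) == canon

    def test_rotations_share_canonical_form(self):
        assert canonical_motif("GATA") == canonical_motif("ATAG")

    def test_reverse_complement_shares_canonical_form(self):
        assert canonical_motif("AGAT") == canonical_motif(revcomp("AGAT"))

    def test_periodic_motif_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif("ATAT")

    def test_tetranucleotide_classes_partition(self):
        # every primitive 4-mer maps into a class; classes are disjoint and
        # closed under rotation and strand flip
        from itertools import product
        classes = {}
        for m in ("".join(t) for t in product("ACGT", repeat=4)):
            if m in (m + m)[1:-1]:
                continue
            classes.setdefault(canonical_motif(m), set()).add(m)
        all_members = [m for c in classes.values() for m in c]
        assert len(all_members) == len(set(all_members))
        for canon, members in classes.items():
            assert canon in members
            for m in members:
                rots = {m[i:] + m[:i] for i in range(4)}
                rc = revcomp(m)
                rots |= {rc[i:] + rc[:i] for i in range(4)}
                assert rots <= members


class TestSelection:
    def make(self, mlen, nr, on_chrom=True):
        motif = "AGATAC"[:mlen]
        return SSRLocus("chr1", 1, mlen * nr, motif, nr, on_chrom)

    @pytest.mark.parametrize("mlen,nr,expected", [
        (3, 9, False), (3, 10, True), (3, 15, True), (3, 16, False),
        (4, 6, False), (4, 7, True),
        (5, 7, False), (5, 8, True), (6, 8, True),
        (2, 50, False),  # dinucleotides not considered in phase 2
    ])
    def test_nr_rules(self, mlen, nr, expected):
        got = select_candidates([self.make(mlen, nr)])
        assert bool(got) is expected

    def test_scaffold_loci_excluded_regardless_of_nr(self):
        assert select_candidates([self.make(4, 20, on_chrom=False)]) == []

    def test_idempotent_and_order_preserving(self):
        loci = [self.make(4, nr) for nr in (7, 9, 12)]
        once = select_candidates(loci)
        assert select_candidates(once) == once == loci


class TestDistribution:
    def test_density_definition(self):
        loci = [SSRLocus("chr1", 1 + 20 * i, 12 + 20 * i, "AG", 6)
                for i in range(55)]
        s = summarize_distribution(loci, {"chr1": 1_000_000})
        assert s["density"]["chr1"] == pytest.approx(55.0)

    def test_zero_loci(self):
        s = summarize_distribution([], {"chr1": 2_000_000})
        assert s["density"]["chr1"] == 0.0
        assert s["by_motif_length"].empty

    def test_class_fractions_sum_to_one(self):
        loci = [SSRLocus("chr1", 1, 12, "AG", 6),
                SSRLocus("chr1", 100, 114, "CAG", 5)]
        s = summarize_distribution(loci, {"chr1": 1_000_000})
        assert s["by_motif_length"]["fraction"].sum() == pytest.approx(1.0)


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident",
                                       "length", "mismatch", "gapopen",
                                       "qstart", "qend", "sstart", "send",
                                       "evalue", "bitscore", "qcovs"])


class TestUniqueness:
    def test_self_hit_only_is_kept(self):
        hits = hits_frame([("c1", "chr1", 100, 200, 0, 0, 1, 200, 1, 200,
                            1e-100, 400, 100)])
        kept, rejected = uniqueness_filter(["c1"], hits)
        assert kept == ["c1"] and rejected == []

    def test_duplicated_locus_rejected_for_best_hit_gap(self):
        hits = hits_frame([
            ("c1", "chr1", 100, 200, 0, 0, 1, 200, 1, 200, 1e-100, 400, 100),
            ("c1", "chr7", 99, 200, 1, 0, 1, 200, 5, 204, 1e-99, 398, 100)])
        kept, rejected = uniqueness_filter(["c1"], hits)
        assert kept == []
        (cand, reasons), = rejected
        assert "best-hit gap" in reasons

    def test_missing_self_hit_is_an_error(self):
        with pytest.raises(ValueError, match="self-hit"):
            uniqueness_filter(["c2"], hits_frame([
                ("c1", "chr1", 100, 200, 0, 0, 1, 200, 1, 200,
                 1e-100, 400, 100)]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_predicate_oracle(self, seed):
        rng = np.random.default_rng(seed)
        thresholds = UniquenessThresholds()
        cands = [f"c{i}" for i in range(12)]
        rows = []
        for c in cands:
            for _ in range(int(rng.integers(1, 6))):
                rows.append((c, f"chr{rng.integers(1, 12)}", 99.0, 200, 1, 0,
                             1, 200, 1, 200,
                             float(10.0 ** -rng.integers(3, 40)),
                             float(rng.integers(100, 400)),
                             float(rng.integers(30, 101))))
        hits = hits_frame(rows)
        kept, rejected = uniqueness_filter(cands, hits, thresholds)
        # literal re-evaluation of the three predicates
        for c in cands:
            sub = hits[hits["qseqid"] == c]
            p1 = (sub["evalue"] < 1e-10).sum() <= 1
            p2 = (sub["qcovs"] >= 80).sum() <= 1
            scores = sorted(sub["bitscore"], reverse=True)
            p3 = len(scores) < 2 or scores[0] - scores[1] >= 10
            assert (c in kept) == (p1 and p2 and p3)
        assert set(kept) | {c for c, _ in rejected} == set(cands)
        assert not set(kept) & {c for c, _ in rejected}


class TestDistances:
    def test_pair_within_50mb_flagged(self):
        df = interlocus_distances({"A": ("chr3", 10_000_000),
                                   "B": ("chr3", 48_000_000)})
        assert df.loc[0, "distance_bp"] == 38_000_000
        assert df.loc[0, "flag"] == "possible linkage"

    def test_different_chromosomes_independent(self):
        df = interlocus_distances({"A": ("chr1", 1), "B": ("chr2", 1)})
        assert df.loc[0, "flag"] == "independent"
        assert df.loc[0, "distance_bp"] is None

    def test_three_marker_flags(self):
        df = interlocus_distances({"A": ("chr1", 1),
                                   "B": ("chr1", 29_000_001),
                                   "C": ("chr1", 90_000_001)})
        flags = {(r.marker_a, r.marker_b): r.flag
                 for r in df.itertuples(index=False)}
        assert flags[("A", "B")] == "possible linkage"   # 29 Mb
        assert flags[("A", "C")] == "independent"        # 90 Mb
        assert flags[("B", "C")] == "independent"        # 61 Mb


class TestDimerScore:
    def test_full_reverse_complement_scores_length(self):
        a = "ACGTACGTACGTACGTACGT"
        assert dimer_score(a, revcomp(a)) == 20

    def test_no_complementarity_scores_zero(self):
        assert dimer_score("A" * 10, "C" * 10) == 0

    def test_single_5bp_overlap(self):
        # b's 3' tail pairs with a's 3' tail over exactly 5 bases
        a = "AAAAAAAAAAGCGTA"
        b = "CCCCCCCCCCTACGC"
        assert dimer_score(a, b) == 5

    def test_symmetric(self, rng):
        from conftest import random_dna
        for _ in range(20):
            a, b = random_dna(rng, 18), random_dna(rng, 22)
            assert dimer_score(a, b) == dimer_score(b, a)

    def test_exhaustive_offset_oracle(self, rng):
        from conftest import random_dna
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for _ in range(10):
            a, b = random_dna(rng, 15), random_dna(rng, 15)
            best = 0
            for off in range(-14, 15):
                run = 0
                for i in range(15):
                    # antiparallel pairing: a[i] against b[len-1-(i-off)]
                    j = 14 - (i - off)
                    if 0 <= j < 15 and comp[a[i]] == b[j]:
                        run += 1
                        best = max(best, run)
                    else:
                        run = 0
            assert dimer_score(a, b) == best

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            dimer_score("ACGTACGN", "ACGTACGT")
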