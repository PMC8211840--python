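"""Sequence-based STR allele nomenclature.

Decomposes a sequenced allele amplicon against a marker reference into a
repeat-region structure plus flanking-region variants, and emits standardized
allele names:

* **repeat-based** convention (after Gusmão and the ISFG recommendations):
  the numeric designation ``n.x`` is the total repeat count *n* plus *x*
  intermediate bases inside the repeat region; flanking indels never change
  ``n.x`` and appear only as parenthesised descriptors, e.g.
  ``8.2 (D42TCdel)``;
* **size-based** alternative: the designation is derived from the total
  amplicon-length offset, so flanking indels shift the number (and can drive
  it negative, which is reported as an error);
* a **shorthand** rule that abbreviates long descriptor sequences to their
  length, e.g. ``U11TGTTAAAATGdel`` -> ``U11-10del``;
* deterministic **SID** letter labels keyed on the full allele sequence.

Flank-variant coordinates: position 1 is the base immediately adjacent to the
repeat region, counting away from it (upstream variants count 5'-ward,
downstream variants count 3'-ward). A variant of length L at position p spans
offsets ``p .. p+L-1``; descriptor sequences are always written 5'->3'.
Indels are canonicalised to the smallest position (closest to the repeat
region) that yields the same edited sequence.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import edlib

from .mining import revcomp

__all__ = [
    "RepeatBlock", "Interruption", "RepeatStructure", "FlankVariant",
    "MarkerReference", "AlleleName", "SidRegistry",
    "decompose", "name_allele", "shorthand", "expand_shorthand",
    "sid_label", "diagnose_null", "apply_variants",
    "AmbiguousDecompositionError", "NegativeNumberingError",
    "UnalignableAmpliconError",
]


class UnalignableAmpliconError(ValueError):
    """Neither flank anchor of the reference aligns to the amplicon."""


class AmbiguousDecompositionError(ValueError):
    """Two co-optimal repeat-structure decompositions survive tie-breaking."""

    def __init__(self, structures: Sequence["RepeatStructure"]):
        self.structures = list(structures)
        super().__init__("ambiguous decomposition; co-optimal structures: "
                         + " | ".join(s.serialize() for s in structures))


class NegativeNumberingError(ValueError):
    """Size-based naming would subtract more bases than the repeat region
    contains."""


# ---------------------------------------------------------------------------
# repeat structure


@dataclass(frozen=True)
class RepeatBlock:
    motif: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1 or not self.motif:
            raise ValueError("repeat block needs a motif and count >= 1")

    @property
    def sequence(self) -> str:
        return self.motif * self.count


@dataclass(frozen=True)
class Interruption:
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty interruption")

    @property
    def sequence(self) -> str:
        return self.seq


_STRUCT_RE = re.compile(r"\(([ACGT]+)\)(\d+)|([ACGT]+)")


@dataclass(frozen=True)
class RepeatStructure:
    """Ordered repeat blocks and interruptions of a repeat region.

    Serialized canonically as e.g. ``(AAGA)7AG(AAGA)1``. ``n`` is the total
    repeat count summed over blocks, ``x`` the total length of interruption
    strings inside the region.
    """

    blocks: tuple[RepeatBlock | Interruption, ...]

    @property
    def n(self) -> int:
        return sum(b.count for b in self.blocks if isinstance(b, RepeatBlock))

    @property
    def x(self) -> int:
        return sum(len(b.seq) for b in self.blocks
                   if isinstance(b, Interruption))

    @property
    def sequence(self) -> str:
        return "".join(b.sequence for b in self.blocks)

    @property
    def motifs(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b in self.blocks:
            if isinstance(b, RepeatBlock) and b.motif not in seen:
                seen.append(b.motif)
        return tuple(seen)

    def serialize(self) -> str:
        out = []
        for b in self.blocks:
            if isinstance(b, RepeatBlock):
                out.append(f"({b.motif}){b.count}")
            else:
                out.append(b.seq)
        return "".join(out)

    @classmethod
    def parse(cls, text: str) -> "RepeatStructure":
        blocks: list[RepeatBlock | Interruption] = []
        pos = 0
        for m in _STRUCT_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse structure {text!r}")
            if m.group(1):
                blocks.append(RepeatBlock(m.group(1), int(m.group(2))))
            else:
                blocks.append(Interruption(m.group(3)))
            pos = m.end()
        if pos != len(text) or not blocks:
            raise ValueError(f"cannot parse structure {text!r}")
        return cls(tuple(blocks))


# ---------------------------------------------------------------------------
# flank variants

Side = Literal["U", "D"]
Kind = Literal["del", "ins", "sub"]

_DESCRIPTOR_RE = re.compile(
    r"^([UD])(\d+)(?:([ACGT]+)|-(\d+))(del|ins|sub)$")


@dataclass(frozen=True, order=True)
class FlankVariant:
    """A flanking-region difference from the marker reference.

    ``side`` is U (upstream of the repeats) or D (downstream); ``position``
    is the 1-based offset of the variant base closest to the repeat region,
    counting away from it. ``sequence`` holds the deleted reference bases
    (del), the inserted bases (ins) or the observed replacement bases (sub),
    written 5'->3'.
    """

    side: Side
    position: int
    kind: Kind
    sequence: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("variant position must be >= 1")
        if not self.sequence:
            raise ValueError("variant sequence must be non-empty")
        if self.side not in ("U", "D") or self.kind not in ("del", "ins",
                                                            "sub"):
            raise ValueError("invalid side/kind")

    def descriptor(self, short: bool = False) -> str:
        body = (f"-{len(self.sequence)}" if short else self.sequence)
        return f"{self.side}{self.position}{body}{self.kind}"

    @classmethod
    def parse(cls, text: str) -> "FlankVariant":
        m = _DESCRIPTOR_RE.match(text)
        if not m or m.group(4) is not None:
            raise ValueError(f"cannot parse full descriptor {text!r} "
                             "(shorthand descriptors need a reference; "
                             "see expand_shorthand)")
        return cls(m.group(1), int(m.group(2)), m.group(5), m.group(3))


def _sort_key(v: FlankVariant) -> tuple[int, int]:
    # D descriptors first (as printed in published names), then U; ascending
    # position within a side
    return (0 if v.side == "D" else 1, v.position)


def apply_variants(flank: str, side: Side,
                   variants: Iterable[FlankVariant]) -> str:
    """Apply flank variants to a reference flank sequence.

    Raises when a variant falls outside the flank or a del/sub sequence does
    not match the reference bases at its position.
    """
    edits = []  # (0-based start in flank, ref_len, replacement)
    lf = len(flank)
    for v in variants:
        if v.side != side:
            continue
        L = len(v.sequence)
        if v.kind in ("del", "sub"):
            if side == "D":
                start = v.position - 1
            else:
                start = lf - (v.position + L - 1)
            if start < 0 or start + L > lf:
                raise ValueError(f"variant {v.descriptor()} outside flank "
                                 f"(length {lf})")
            ref = flank[start:start + L]
            if v.kind == "del" and ref != v.sequence:
                raise ValueError(f"deletion {v.descriptor()} does not match "
                                 f"reference bases {ref!r}")
            edits.append((start, L, "" if v.kind == "del" else v.sequence))
        else:  # ins: inserted bases occupy offsets position..position+L-1
            if side == "D":
                start = v.position - 1
            else:
                start = lf - v.position + 1
            if start < 0 or start > lf:
                raise ValueError(f"variant {v.descriptor()} outside flank "
                                 f"(length {lf})")
            edits.append((start, 0, v.sequence))
    out = flank
    # at a shared start, apply del/sub before ins so the inserted bases end
    # up ahead of the edited reference bases
    for start, ref_len, repl in sorted(edits,
                                       key=lambda e: (-e[0], e[1] == 0)):
        out = out[:start] + repl + out[start + ref_len:]
    return out


def _canonical_position(flank: str, side: Side, v: FlankVariant,
                        others: Sequence[FlankVariant]) -> FlankVariant:
    """Slide an indel toward the repeat boundary: smallest position giving
    the same edited flank (sequence field updated for deletions)."""
    if v.kind == "sub":
        return v
    target = apply_variants(flank, side, list(others) + [v])
    best = v
    p = v.position - 1
    while p >= 1:
        if v.kind == "del":
            L = len(v.sequence)
            lf = len(flank)
            start = (p - 1) if side == "D" else lf - (p + L - 1)
            if start < 0 or start + L > lf:
                break
            cand = FlankVariant(v.side, p, "del", flank[start:start + L])
        else:
            cand = replace(v, position=p)
        try:
            if apply_variants(flank, side, list(others) + [cand]) == target:
                best = cand
                p -= 1
                continue
        except ValueError:
            pass
        break
    return best


# ---------------------------------------------------------------------------
# marker reference and allele names


@dataclass(frozen=True)
class MarkerReference:
    """Reference amplicon of one marker: upstream flank, reference repeat
    structure, downstream flank, and the pig-tail length (0 or 7 bp) that is
    added to the physical fragment size by the GTTTCTT tail on the reverse
    primer."""

    marker: str
    upstream: str
    structure: RepeatStructure
    downstream: str
    pigtail: int = 0

    def __post_init__(self) -> None:
        if not self.upstream or not self.downstream:
            raise ValueError("flanks must be non-empty")
        if not self.structure.blocks:
            raise ValueError("reference structure must be non-empty")

    @property
    def amplicon(self) -> str:
        return self.upstream + self.structure.sequence + self.downstream

    @property
    def length(self) -> int:
        """Sized fragment length of the reference allele (incl. pig tail)."""
        return len(self.amplicon) + self.pigtail

    @property
    def motif_length(self) -> int:
        for b in self.structure.blocks:
            if isinstance(b, RepeatBlock):
                return len(b.motif)
        raise ValueError("reference structure has no repeat block")


@dataclass(frozen=True)
class AlleleName:
    """Structured allele name under one convention."""

    n: int
    x: int
    variants: tuple[FlankVariant, ...]
    convention: str = "repeat_based"
    short_for: tuple[bool, ...] = ()  # per-variant shorthand flags

    @property
    def designation(self) -> str:
        return f"{self.n}.{self.x}" if self.x else str(self.n)

    @property
    def numeric(self) -> float:
        return self.n + self.x / 10.0

    def descriptors(self) -> tuple[str, ...]:
        flags = self.short_for or (False,) * len(self.variants)
        return tuple(v.descriptor(short=s)
                     for v, s in zip(self.variants, flags))

    @property
    def full(self) -> str:
        d = self.descriptors()
        return self.designation + (f" ({'; '.join(d)})" if d else "")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.full


def name_allele(
    structure: RepeatStructure,
    variants: Sequence[FlankVariant] = (),
    convention: str = "repeat_based",
    reference: MarkerReference | None = None,
) -> AlleleName:
    """Name a decomposed allele.

    Under the repeat-based convention the designation is ``n.x`` from the
    repeat structure alone; flanking indels appear only as descriptors. Under
    the size-based convention the designation encodes the total length offset
    (repeat region plus net flanking indels) in motif units, so flanking
    indels shift the number; when the net deletion exceeds the repeat-region
    length this raises :class:`NegativeNumberingError`.
    """
    ordered = tuple(sorted(variants, key=_sort_key))
    if convention == "repeat_based":
        return AlleleName(structure.n, structure.x, ordered, convention)
    if convention != "size_based":
        raise ValueError(f"unknown convention {convention!r}")
    if reference is not None:
        mlen = reference.motif_length
    else:
        mlen = len(structure.motifs[0]) if structure.motifs else 0
    if not mlen:
        raise ValueError("size-based naming needs a repeat motif")
    net_indel = sum(len(v.sequence) * (1 if v.kind == "ins" else -1)
                    for v in ordered if v.kind != "sub")
    total = mlen * structure.n + structure.x + net_indel
    if total < 0:
        raise NegativeNumberingError(
            f"size-based designation would be negative ({total} bp): "
            "flanking deletions exceed the repeat region")
    return AlleleName(total // mlen, total % mlen, ordered, convention)


def shorthand(name: AlleleName, max_seq_len: int = 5) -> AlleleName:
    """Abbreviate descriptors whose sequence exceeds ``max_seq_len`` to
    ``side + position + "-" + length + kind``; idempotent, and invertible
    given the marker reference (:func:`expand_shorthand`)."""
    flags = tuple(len(v.sequence) > max_seq_len for v in name.variants)
    prior = name.short_for or (False,) * len(name.variants)
    return replace(name, short_for=tuple(a or b for a, b in
                                         zip(flags, prior)))


def expand_shorthand(descriptor: str,
                     reference: MarkerReference) -> FlankVariant:
    """Recover the full variant from a shorthand descriptor and the marker
    reference (deletions and substitutions only; an inserted sequence is not
    recoverable from its length)."""
    m = _DESCRIPTOR_RE.match(descriptor)
    if not m:
        raise ValueError(f"cannot parse descriptor {descriptor!r}")
    side, pos, kind = m.group(1), int(m.group(2)), m.group(5)
    if m.group(3) is not None:
        return FlankVariant(side, pos, kind, m.group(3))
    length = int(m.group(4))
    if kind == "ins":
        raise ValueError("inserted sequence cannot be recovered from a "
                         "shorthand descriptor")
    flank = reference.upstream if side == "U" else reference.downstream
    lf = len(flank)
    start = (pos - 1) if side == "D" else lf - (pos + length - 1)
    if start < 0 or start + length > lf:
        raise ValueError(f"descriptor {descriptor!r} outside flank")
    return FlankVariant(side, pos, kind, flank[start:start + length])


# ---------------------------------------------------------------------------
# decomposition


# Alignment costs: primary = number of edited bases (_GE each), secondary =
# number of contiguous edit blocks (_GO per opened mismatch/insertion/
# deletion run). Plain edit distance is ambiguous between one contiguous
# indel and an equal-cost split; the block term makes the contiguous script
# canonical.
_GE = 1_000_000      # per edited base (indel base or mismatch)
_GO = 1              # per opened edit block
_BIG = 1 << 60

_STATES = ("E", "S", "D", "I")  # match / mismatch-run / del-run / ins-run


def _flank_edit_script(query: str, target: str) -> list[tuple[str, str]]:
    """Global alignment of reference flank *query* against observed flank
    *target* minimizing (edited bases, edit blocks); returns the op list
    ``[('=', base) | ('X', obs) | ('D', ref) | ('I', obs), ...]``.

    Deterministic traceback: on cost ties prefer match, then extending the
    current mismatch run, then deletion, then insertion.
    """
    n, m = len(query), len(target)
    # cost[state][i][j]; states: E = last op match, S = mismatch, D/I = gaps
    C = {s: [[_BIG] * (m + 1) for _ in range(n + 1)] for s in _STATES}
    C["E"][0][0] = 0
    for i in range(1, n + 1):
        C["D"][i][0] = _GO + _GE * i
    for j in range(1, m + 1):
        C["I"][0][j] = _GO + _GE * j
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            diag = [C[s][i - 1][j - 1] for s in _STATES]
            if qi == target[j - 1]:
                C["E"][i][j] = min(diag)
            else:
                open_ = min(C["E"][i - 1][j - 1], C["D"][i - 1][j - 1],
                            C["I"][i - 1][j - 1]) + _GO
                C["S"][i][j] = min(open_,
                                   C["S"][i - 1][j - 1]) + _GE
            C["D"][i][j] = min(C["E"][i - 1][j] + _GO,
                               C["S"][i - 1][j] + _GO,
                               C["D"][i - 1][j],
                               C["I"][i - 1][j] + _GO) + _GE
            C["I"][i][j] = min(C["E"][i][j - 1] + _GO,
                               C["S"][i][j - 1] + _GO,
                               C["I"][i][j - 1],
                               C["D"][i][j - 1] + _GO) + _GE
    ops: list[tuple[str, str]] = []
    i, j = n, m
    state = min(_STATES, key=lambda s: C[s][i][j])
    while i > 0 or j > 0:
        if state == "E":
            ops.append(("=", target[j - 1]))
            prev = [C[s][i - 1][j - 1] for s in _STATES]
            state = _STATES[prev.index(C["E"][i][j])]
            i, j = i - 1, j - 1
        elif state == "S":
            ops.append(("X", target[j - 1]))
            cur = C["S"][i][j] - _GE
            if C["S"][i - 1][j - 1] == cur:
                state = "S"
            else:
                prev = [C[s][i - 1][j - 1] + _GO if s != "S" else _BIG
                        for s in _STATES]
                state = _STATES[prev.index(cur)]
            i, j = i - 1, j - 1
        elif state == "D":
            ops.append(("D", query[i - 1]))
            cur = C["D"][i][j] - _GE
            if C["D"][i - 1][j] == cur:
                state = "D"
            else:
                prev = [C[s][i - 1][j] + _GO if s != "D" else _BIG
                        for s in _STATES]
                state = _STATES[prev.index(cur)]
            i -= 1
        else:
            ops.append(("I", target[j - 1]))
            cur = C["I"][i][j] - _GE
            if C["I"][i][j - 1] == cur:
                state = "I"
            else:
                prev = [C[s][i][j - 1] + _GO if s != "I" else _BIG
                        for s in _STATES]
                state = _STATES[prev.index(cur)]
            j -= 1
    ops.reverse()
    return ops


def _flank_variants_from_alignment(query: str, target: str, side: Side,
                                   ) -> list[FlankVariant]:
    """Variants of one flank from an affine-gap global alignment of the
    reference flank (query) against the observed flank segment (target).

    Both strings are in genomic orientation; positions are converted to
    away-from-boundary offsets.
    """
    ops = _flank_edit_script(query, target)
    lf = len(query)
    variants: list[FlankVariant] = []
    qpos = 0  # 0-based position in reference flank
    i = 0
    while i < len(ops):
        op, _ = ops[i]
        j = i
        while j < len(ops) and ops[j][0] == op:
            j += 1
        run = j - i
        payload = "".join(c for _, c in ops[i:j])
        if op == "X":
            start = qpos
            pos = (start + 1) if side == "D" else lf - (start + run - 1)
            variants.append(FlankVariant(side, pos, "sub", payload))
            qpos += run
        elif op == "D":
            start = qpos
            pos = (start + 1) if side == "D" else lf - (start + run - 1)
            variants.append(FlankVariant(side, pos, "del", payload))
            qpos += run
        elif op == "I":
            pos = (qpos + 1) if side == "D" else lf - qpos + 1
            variants.append(FlankVariant(side, pos, "ins", payload))
        else:
            qpos += run
        i = j
    return variants


def _decompose_middle(middle: str, motifs: Sequence[str]
                      ) -> RepeatStructure:
    """Tile the repeat-region segment with reference motifs, minimizing
    (interruption bases, interruption blocks) with the longest uninterrupted
    leading run as final tie-break. Raises on a residual tie."""
    n = len(middle)
    INF = (10 ** 9, 10 ** 9, 10 ** 9)
    # state: (pos, last_was_interruption); cost: (bases, blocks, -first_run)
    # where first_run is the length of the leading pure-repeat prefix
    best: dict[tuple[int, bool], tuple] = {(0, False): (0, 0, 0, None)}
    order = sorted(set(motifs), key=len, reverse=True)
    # forward DP over positions
    frontier: dict[tuple[int, bool], tuple] = {(0, False): (0, 0, 0, [])}
    done: dict[tuple[int, bool], tuple] = {}
    import heapq
    heap = [((0, 0, 0), 0, False, [])]
    seen_best: dict[tuple[int, bool], tuple] = {}
    ties: dict[tuple[int, bool], list] = {}
    while heap:
        cost, pos, last_interr, path = heapq.heappop(heap)
        key = (pos, last_interr)
        if key in seen_best:
            if cost == seen_best[key] and pos == n:
                ties.setdefault(key, []).append(path)
            continue
        seen_best[key] = cost
        ties[key] = [path]
        if pos == n:
            continue
        bases, blocks, neg_first = cost
        for m in order:
            lm = len(m)
            if middle.startswith(m, pos):
                heapq.heappush(heap, ((bases, blocks, neg_first), pos + lm,
                                      False, path + [("R", m)]))
        nb = blocks + (0 if last_interr else 1)
        nf = neg_first if (bases or neg_first) else -pos
        heapq.heappush(heap, ((bases + 1, nb, nf), pos + 1, True,
                              path + [("I", middle[pos])]))

    candidates = []
    for flag in (False, True):
        key = (n, flag)
        if key in seen_best:
            candidates.append((seen_best[key], key))
    if not candidates:
        raise UnalignableAmpliconError("repeat region cannot be decomposed")
    candidates.sort()
    best_cost, best_key = candidates[0]
    paths = [p for p in ties.get(best_key, [])]
    if len(candidates) > 1 and candidates[1][0] == best_cost:
        paths = paths + ties.get(candidates[1][1], [])
    structures = {s.serialize(): s
                  for s in (_path_to_structure(p) for p in paths)}
    if len(structures) > 1:
        raise AmbiguousDecompositionError(list(structures.values()))
    return next(iter(structures.values()))


def _path_to_structure(path) -> RepeatStructure:
    blocks: list[RepeatBlock | Interruption] = []
    for op, payload in path:
        if op == "R":
            if blocks and isinstance(blocks[-1], RepeatBlock) \
                    and blocks[-1].motif == payload:
                blocks[-1] = RepeatBlock(payload, blocks[-1].count + 1)
            else:
                blocks.append(RepeatBlock(payload, 1))
        else:
            if blocks and isinstance(blocks[-1], Interruption):
                blocks[-1] = Interruption(blocks[-1].seq + payload)
            else:
                blocks.append(Interruption(payload))
    if not blocks:
        raise UnalignableAmpliconError("empty repeat region")
    return RepeatStructure(tuple(blocks))


_INT_BASE = _GE + 10  # middle interruption base: ties resolve to the flank
_INT_OPEN = 1


def _prefix_costs(query: str, target: str) -> list[int]:
    """Alignment cost (same model as :func:`_flank_edit_script`) of *query*
    against every prefix of *target*: entry j is the cost against
    ``target[:j]``."""
    n, m = len(query), len(target)
    E = [0] + [_BIG] * m
    S = [_BIG] * (m + 1)
    D = [_BIG] * (m + 1)
    I = [_BIG] * (m + 1)
    for j in range(1, m + 1):
        I[j] = _GO + _GE * j
    for i in range(1, n + 1):
        qi = query[i - 1]
        En = [_BIG] * (m + 1)
        Sn = [_BIG] * (m + 1)
        Dn = [_BIG] * (m + 1)
        In = [_BIG] * (m + 1)
        Dn[0] = _GO + _GE * i
        for j in range(1, m + 1):
            diag = min(E[j - 1], S[j - 1], D[j - 1], I[j - 1])
            if qi == target[j - 1]:
                En[j] = diag
            else:
                Sn[j] = min(min(E[j - 1], D[j - 1], I[j - 1]) + _GO,
                            S[j - 1]) + _GE
            Dn[j] = min(E[j] + _GO, S[j] + _GO, D[j], I[j] + _GO) + _GE
            In[j] = min(En[j - 1] + _GO, Sn[j - 1] + _GO, In[j - 1],
                        Dn[j - 1] + _GO) + _GE
        E, S, D, I = En, Sn, Dn, In
    return [min(E[j], S[j], D[j], I[j]) for j in range(m + 1)]


def _tiling_costs(segment: str, motifs: Sequence[str]) -> list[int]:
    """Minimal tiling cost of every prefix of *segment*: repeats are free,
    untiled bases cost ``_INT_BASE`` plus ``_INT_OPEN`` per interruption
    block."""
    n = len(segment)
    # (cost ending after a repeat/start, cost ending inside an interruption)
    free = [_BIG] * (n + 1)
    inter = [_BIG] * (n + 1)
    free[0] = 0
    for j in range(1, n + 1):
        for m in motifs:
            lm = len(m)
            if j >= lm and segment[j - lm:j] == m:
                c = min(free[j - lm], inter[j - lm])
                if c < free[j]:
                    free[j] = c
        prev_best = min(free[j - 1] + _INT_OPEN, inter[j - 1])
        inter[j] = prev_best + _INT_BASE
    return [min(f, i) for f, i in zip(free, inter)]


def decompose(amplicon: str, reference: MarkerReference,
              boundary_slack: int = 30,
              ) -> tuple[RepeatStructure, list[FlankVariant]]:
    """Decompose an allele amplicon into repeat structure and flank variants.

    The amplicon is parsed as ``U-flank' + repeat region + D-flank'``: the
    two boundary positions are chosen to minimize the joint cost of (i)
    affine-gap alignment of the reference upstream flank to the amplicon
    prefix, (ii) motif tiling of the middle with minimal interruptions and
    (iii) alignment of the downstream flank to the suffix. Cost ties prefer
    assigning boundary bases to the flanks (so ``n.x`` counts only bases
    interior to the repeat region), then the leftmost repeat-region start
    and the maximal repeat region. The result always reconstructs the
    amplicon exactly.

    ``boundary_slack`` bounds how far (in bp) each boundary may move from
    the position implied by the reference flank lengths; flank variants
    beyond it make the amplicon unalignable.
    """
    amplicon = amplicon.upper()
    up, down = reference.upstream, reference.downstream
    L = len(amplicon)
    motifs = reference.structure.motifs

    urow = _prefix_costs(up, amplicon)
    drow_rev = _prefix_costs(down[::-1], amplicon[::-1])
    dcol = [drow_rev[L - j] for j in range(L + 1)]  # cost vs amplicon[j:]

    j1_lo = max(0, len(up) - boundary_slack)
    j1_hi = min(L, len(up) + boundary_slack)
    j2_lo = max(0, L - len(down) - boundary_slack)
    j2_hi = min(L, L - len(down) + boundary_slack)

    best = None
    for j1 in range(j1_lo, j1_hi + 1):
        if urow[j1] >= _BIG:
            continue
        tiling = _tiling_costs(amplicon[j1:min(j2_hi, L)], motifs)
        for j2 in range(max(j1, j2_lo), j2_hi + 1):
            mid = tiling[j2 - j1]
            total = urow[j1] + mid + dcol[j2]
            key = (total, j1, -j2)
            if best is None or key < best[0]:
                best = (key, j1, j2)
    if best is None:
        raise UnalignableAmpliconError(
            f"no admissible flank boundaries for {reference.marker}")
    _, j1, j2 = best
    if j2 == j1:
        raise UnalignableAmpliconError("empty repeat region between flank "
                                       "anchors")

    variants = _flank_variants_from_alignment(up, amplicon[:j1], "U")
    variants += _flank_variants_from_alignment(down, amplicon[j2:], "D")

    structure = _decompose_middle(amplicon[j1:j2], motifs)

    # canonicalise indel positions (slide toward the repeat boundary)
    for side, flank in (("U", up), ("D", down)):
        side_vs = [v for v in variants if v.side == side]
        for idx, v in enumerate(side_vs):
            others = side_vs[:idx] + side_vs[idx + 1:]
            side_vs[idx] = _canonical_position(flank, side, v, others)
        variants = [v for v in variants if v.side != side] + side_vs

    variants.sort(key=_sort_key)

    # reconstruction guarantee
    rebuilt = (apply_variants(up, "U", variants) + structure.sequence
               + apply_variants(down, "D", variants))
    if rebuilt != amplicon:
        raise UnalignableAmpliconError(
            "decomposition failed to reconstruct the amplicon")
    return structure, variants


# ---------------------------------------------------------------------------
# SID labels

_ALPHA = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class SidRegistry:
    """Registry of assigned SID labels, guarding against digest collisions
    and reporting panel-wide prefix uniqueness."""

    def __init__(self, length: int = 4):
        self.length = length
        self._labels: dict[str, str] = {}  # label -> sequence

    def labels(self) -> dict[str, str]:
        return dict(self._labels)

    def prefix_unique(self, k: int = 3) -> bool:
        """True when the first *k* letters alone identify every registered
        allele."""
        prefixes = [lab[:k] for lab in self._labels]
        return len(set(prefixes)) == len(prefixes)


def sid_label(sequence: str, registry: SidRegistry | None = None,
              length: int | None = None) -> str:
    """Deterministic letter code for an allele sequence.

    Base-26 uppercase encoding of a SHA-256 digest of the uppercased
    sequence, truncated to ``length`` letters (default: the registry's
    length, or 4). Isoalleles (same length, different sequence) receive
    distinct labels with overwhelming probability; a genuine digest collision
    at the chosen label length raises, forcing a longer label.
    """
    seq = sequence.upper()
    n = length or (registry.length if registry else 4)
    digest = int.from_bytes(hashlib.sha256(seq.encode()).digest(), "big")
    letters = []
    for _ in range(n):
        digest, r = divmod(digest, 26)
        letters.append(_ALPHA[r])
    label = "".join(letters)
    if registry is not None:
        prior = registry._labels.get(label)
        if prior is not None and prior != seq:
            raise ValueError(f"SID collision at length {n} for label "
                             f"{label!r}; use a longer label")
        registry._labels[label] = seq
    return label


# ---------------------------------------------------------------------------
# null-allele diagnosis


@dataclass(frozen=True)
class PrimerSiteReport:
    """Mismatches and indels at one primer binding site.

    Substitutions are (offset from the primer 3' end, primer base, observed
    base); offset 1 is the 3'-terminal base. ``severity`` is ``high`` when
    any substitution sits in the 3'-terminal region (offset <= 4) or any
    indel overlaps the site, else ``moderate``; ``none`` for a perfect
    match.
    """

    primer: str
    substitutions: tuple[tuple[int, str, str], ...]
    indels: tuple[str, ...]
    severity: str

    @property
    def clean(self) -> bool:
        return not self.substitutions and not self.indels


_TERMINAL_3PRIME = 4  # offsets considered 3'-critical


def _primer_site_report(primer: str, target: str,
                        three_prime_left: bool) -> PrimerSiteReport:
    """Align a primer-oriented sequence to the extended amplicon (infix) and
    collect site differences. ``three_prime_left`` marks whether the primer's
    3' end corresponds to the left end of the aligned string."""
    res = edlib.align(primer, target, mode="HW", task="path",
                      k=max(3, len(primer) // 2))
    if res["editDistance"] < 0:
        return PrimerSiteReport(primer, (), ("site not found",), "high")
    loc = res["locations"][0]
    nice = edlib.getNiceAlignment(res, primer, target[loc[0]:loc[1] + 1])
    qa, ta = nice["query_aligned"], nice["target_aligned"]
    subs: list[tuple[int, str, str]] = []
    indels: list[str] = []
    qpos = 0
    lp = len(primer)
    for qc, tc in zip(qa, ta):
        if qc != "-" and tc != "-":
            if qc != tc:
                off = (qpos + 1) if three_prime_left else (lp - qpos)
                subs.append((off, qc, tc))
            qpos += 1
        elif tc == "-":
            off = (qpos + 1) if three_prime_left else (lp - qpos)
            indels.append(f"deletion overlapping site near 3' offset {off}")
            qpos += 1
        else:
            off = (qpos + 1) if three_prime_left else (lp - qpos)
            indels.append(f"insertion in site near 3' offset {off}")
    severity = "none"
    if subs or indels:
        severity = "moderate"
    if indels or any(off <= _TERMINAL_3PRIME for off, _, _ in subs):
        severity = "high"
    subs.sort()
    return PrimerSiteReport(primer, tuple(subs), tuple(indels), severity)


def diagnose_null(extended_sequence: str, primer_f: str, primer_r: str,
                  ) -> dict[str, PrimerSiteReport]:
    """Diagnose null-allele causes from an extended amplicon spanning both
    primer sites.

    The forward primer is matched on the given strand; the reverse primer is
    matched as its reverse complement. Returns per-primer reports of
    substitutions (offset from the 3' end) and indels overlapping the site,
    classified by severity (3'-terminal region vs elsewhere).
    """
    seq = extended_sequence.upper()
    f_rep = _primer_site_report(primer_f.upper(), seq,
                                three_prime_left=False)
    # revcomp(R) appears on the forward strand; R's 3' end maps to the LEFT
    # end of that match
    r_rep = _primer_site_report(revcomp(primer_r.upper()), seq,
                                three_prime_left=True)
    r_rep = replace(r_rep, primer=primer_r.upper())
    return {"F": f_rep, "R": r_rep}
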