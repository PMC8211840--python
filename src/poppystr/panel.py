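"""Marker panel: the configuration consumed by the simulator and the
genotype caller.

A panel lists the STR markers of a multiplexed assay set: for each marker
its motif, fluorescent dye, assay membership, reference allele and fragment
size, and the inventory of known alleles. Allele labels follow the
repeat-based ``n`` / ``n.x`` convention; an allele's fragment size is the
reference size shifted by the repeat-length delta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = ["Marker", "Panel", "parse_allele_label", "default_panel"]

DYES = ("6-FAM", "VIC", "NED", "PET")


def parse_allele_label(label: str) -> tuple[int, int]:
    """Split an ``n`` or ``n.x`` allele label into (n, x)."""
    s = str(label)
    if "." in s:
        a, b = s.split(".")
        return int(a), int(b)
    return int(s), 0


@dataclass(frozen=True)
class Marker:
    """One STR marker of the panel."""

    name: str
    motif: str
    dye: str
    assay: str
    ref_allele: str          # label of the sequenced reference allele
    ref_size: float          # fragment size of the reference allele, bp
    alleles: tuple[str, ...]  # known allele inventory (labels)
    stutter_1bp_series: bool = False

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    def allele_size(self, label: str) -> float:
        """Fragment size in bp of an inventory allele."""
        n, x = parse_allele_label(label)
        rn, rx = parse_allele_label(self.ref_allele)
        return self.ref_size + self.motif_length * (n - rn) + (x - rx)

    def allele_repeats(self, label: str) -> int:
        return parse_allele_label(label)[0]


@dataclass
class Panel:
    markers: dict[str, Marker] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Marker]:
        return iter(self.markers.values())

    def __getitem__(self, name: str) -> Marker:
        return self.markers[name]

    def __len__(self) -> int:
        return len(self.markers)

    def names(self) -> list[str]:
        return sorted(self.markers)

    def add(self, marker: Marker) -> None:
        self.markers[marker.name] = marker

    def allele_size(self, marker: str, label: str) -> float:
        return self.markers[marker].allele_size(label)

    def to_json(self, path) -> None:
        data = {m.name: {
            "motif": m.motif, "dye": m.dye, "assay": m.assay,
            "ref_allele": m.ref_allele, "ref_size": m.ref_size,
            "alleles": list(m.alleles),
            "stutter_1bp_series": m.stutter_1bp_series,
        } for m in self}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Panel":
        with open(path) as fh:
            data = json.load(fh)
        panel = cls()
        for name, d in data.items():
            panel.add(Marker(name=name, motif=d["motif"], dye=d["dye"],
                             assay=d["assay"], ref_allele=d["ref_allele"],
                             ref_size=float(d["ref_size"]),
                             alleles=tuple(d["alleles"]),
                             stutter_1bp_series=d.get("stutter_1bp_series",
                                                      False)))
        return panel


_MOTIFS = {3: ("AGA", "ATC", "AAG"), 4: ("AGAT", "AAGA", "ATCT", "AAAG"),
           5: ("AGATA", "AAAGA", "ATCTC")}


def default_panel(n_markers: int = 27, seed: int = 0,
                  mean_alleles: float = 5.85) -> Panel:
    """Deterministic synthetic panel shaped like the published assay set.

    27 markers split over three multiplexes and four dyes: 15
    tetranucleotide, 9 pentanucleotide and 3 trinucleotide markers, with
    allele counts drawn between 3 and 14 (mean close to ``mean_alleles``).
    Fragment sizes per (assay, dye) lane are spaced so that marker size
    ranges never overlap. Two pentanucleotide markers emit a 1-bp stutter
    series, mirroring the anomalous loci seen in practice.
    """
    rng = np.random.default_rng(seed)
    motif_plan = ([4] * 15 + [5] * 9 + [3] * 3)[:n_markers]
    if n_markers > 27:
        motif_plan += [4] * (n_markers - 27)
    panel = Panel()
    lane_slots: dict[tuple[str, str], int] = {}
    pen_seen = 0
    for i, mlen in enumerate(motif_plan):
        assay = f"MTP{i % 3 + 1}"
        dye = DYES[(i // 3) % 4]
        slot = lane_slots.get((assay, dye), 0)
        lane_slots[(assay, dye)] = slot + 1
        motif = _MOTIFS[mlen][i % len(_MOTIFS[mlen])]
        n_alleles = int(np.clip(rng.poisson(mean_alleles - 3) + 3, 3, 14))
        ref_n = int(rng.integers(8, 13))
        prefix = {3: "TRI", 4: "TET", 5: "PEN"}[mlen]
        name = f"SYN{prefix}{i + 1:03d}"
        # inventory: contiguous ladder of repeat numbers around the
        # reference, occasionally with one intermediate allele
        lo = ref_n - n_alleles // 2
        labels = [str(lo + j) for j in range(n_alleles)]
        if n_alleles >= 6 and rng.random() < 0.5:
            labels[-1] = f"{lo + n_alleles - 2}.{int(rng.integers(1, mlen))}"
        # 80 bp per lane slot keeps same-dye markers well separated
        ref_size = 100.0 + 80.0 * slot + rng.integers(0, 15)
        series = False
        if mlen == 5 and pen_seen < 2:
            series = True
            pen_seen += 1
        panel.add(Marker(name=name, motif=motif, dye=dye, assay=assay,
                         ref_allele=str(ref_n), ref_size=float(ref_size),
                         alleles=tuple(sorted(set(labels),
                                              key=parse_allele_label)),
                         stutter_1bp_series=series))
    return panel
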