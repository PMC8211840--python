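# poppystr

A forensic STR (microsatellite) profiling toolkit for opium poppy
(*Papaver somniferum* L.), for geneticists building or validating
capillary-electrophoresis marker systems that individualize plant material —
seized opium, heroin residues, seed lots, registered cultivars.

The package covers the full computational side of such a system:

* **SSR mining** (`poppystr.mining`) — perfect tandem repeats with 2–6 nt
  motifs in genome FASTA, density/composition summaries, candidate selection
  by per-motif-length repeat-number rules and chromosome placement, locus
  uniqueness from whole-genome alignment hits, ≥ 50 Mb inter-locus distance
  screening, and an AutoDimer-style primer cross-dimer score.
* **Sequence-based allele nomenclature** (`poppystr.nomenclature`) — an
  amplicon is decomposed against a marker reference into a repeat structure
  plus flanking variants, and named `n.x` where `n` is the total repeat
  count and `x` the intermediate bases inside the repeat region; flanking
  indels never change `n.x` and appear as descriptors, e.g.
  `8.2 (D42TCdel)`. A size-based alternative convention, a shorthand rule
  (`U11TGTTAAAATGdel` → `U11-10del`), deterministic SID letter labels and a
  primer-site null-allele diagnosis are included.
* **CE genotype calling** (`poppystr.genotyping`) — analytical-threshold
  flagging, allelic-ladder composition by greedy set cover, ±0.4 bp bin
  calling with a stutter filter, stutter classification (n−k, n−2k, n+k and
  the 1-bp series), and ladder sizing-precision statistics.
* **Internal validation metrics** (`poppystr.metrics`) —

  - heterozygote balance  Hb = φ_HMW / φ_LMW  and  Hb′ = φ_smaller / φ_larger,
  - inter-locus balance  IELB_i = h_i / mean(h)  over an assay,
  - intracolour balance  ICB = min(h) / max(h)  within a dye channel,
  - stutter ratio  S_R = φ_S / φ_A  with mean + 3·SD filter thresholds and
    allele-size trends,

  plus dilution-series dropout reports and species cross-reactivity counts
  (φ and h are peak heights in rfu after codominant normalization:
  heterozygote peaks averaged, homozygote peaks halved).
* **Population analysis** (`poppystr.population`) — N_al, allele
  frequencies, observed heterozygosity, 0-mismatch identity analysis, the
  variety-discrimination rule (two varieties differ only if *all* their
  plants differ), PCA on centered allele dosages, UPGMA on the leading
  principal components with newick export, and nearest-centroid mislabel
  flagging.
* **Synthetic data** (`poppystr.synthetic`) — first-class generators for
  every input: genomes with planted repeats, inbred variety genotype sets
  with near-zero heterozygosity, and CE peak tables with stutter,
  dose-dependent dropout, null alleles, dye gains and Gaussian sizing noise,
  each with a per-peak provenance truth table.

## Worked example

Name two sequenced alleles of a tetranucleotide marker whose reference
repeat region is `(AAGA)7AG(AAGA)1` — one unaltered, one carrying a
dinucleotide deletion in the downstream flank:

```python
import numpy as np
from poppystr.nomenclature import (MarkerReference, RepeatStructure,
                                   FlankVariant, decompose, name_allele,
                                   sid_label)
from poppystr.synthetic import simulate_allele_sequence

rng = np.random.default_rng(0)
dna = lambda n: "".join(rng.choice(list("ACGT"), n))
up = dna(109)
down = list(dna(43)); down[41:43] = list("TC"); down[40] = "G"
ref = MarkerReference("DEMO", up,
                      RepeatStructure.parse("(AAGA)7AG(AAGA)1"),
                      "".join(down))

for variants in ([], [FlankVariant("D", 42, "del", "TC")]):
    amp = simulate_allele_sequence(ref, ref.structure, variants)
    structure, found = decompose(amp, ref)
    name = name_allele(structure, found)
    print(f"{len(amp)} bp  structure {structure.serialize():22s} "
          f"name {name.full:18s} SID {sid_label(amp)}")
```

prints

```
186 bp  structure (AAGA)7AG(AAGA)1       name 8.2                SID WBVQ
184 bp  structure (AAGA)7AG(AAGA)1       name 8.2 (D42TCdel)     SID ZTMF
```

Both alleles share the repeat structure, so both are named 8.2 (8 repeats,
2 intermediate bases); the 2 bp length difference is attributed to the
flanking deletion, which the descriptor records without touching the
numeric designation. Under the size-based alternative
(`name_allele(..., "size_based", reference=ref)`) the deleted variant would
instead be renamed 8 — the two conventions are both implemented precisely
so this difference is explicit.

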