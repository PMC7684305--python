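# sedaforam

Tools for analysing **sedimentary environmental DNA (sedaDNA) of
foraminifera**: planktonic foraminifera shells raining onto the seafloor
leave both microfossils and extracellular DNA in the sediment, while living
benthic foraminifera in the top ~10 cm contribute their own, much fresher
DNA. Metabarcoding of the short 37f hypervariable region of the SSU rRNA
gene (68–196 bp) recovers both pools at once, and the ratio of planktonic to
benthic amplicons changes systematically with burial depth. This package is
for micropalaeontologists and molecular ecologists who want to (a) process
tagged 37f amplicon libraries from sediment cores, (b) model the burial
signal, and (c) test whether molecular assemblages are congruent with
classical census counts of foraminiferal tests.

## What it implements

**Amplicon chain** (`sedaforam.pipeline`): quality filter (mean Phred of
each mate strictly > 30) → exact-overlap pair merging (≥ 12 bp, no
mismatch) → inline-tag demultiplexing (8-nt Latin-square tag pairs, ≤ 2
mismatches over both tagged-primer constructs, ties never guessed) →
two-parent breakpoint chimera removal → dereplication into ISUs →
Needleman–Wunsch taxonomic assignment (best identity strictly > 80%,
consensus over tied hits) → 5′-signature preclustering → average-linkage
OTU clustering (distance 1 − identity, default cut 0.03) →
planktonic/benthic classification by exclusion (planktonic iff ≥ 95%
identity to a planktonic reference) → occupancy filter (retained iff
present in > 3 samples) → optional merging of intragenomic variants.

**Burial-decay model** (`sedaforam.decay`): planktonic eDNA decays as
N(z) = N₀·e^(−λₚ·τ·z); living benthic stock declines linearly from 99 to 1
(arbitrary units) over the inhabited zone (0–10 cm) and decays with the
smaller constant λ_b = 0.9 below it. The observable planktonic fraction
P/(P+B) is 0.01 at the surface, peaks at the base of the inhabited zone and
declines slowly below — the low / peak / intermediate depth pattern seen in
sediment cores. `fit_params` recovers (λₚ, τ) from observed
depth–fraction profiles by least squares on the logit scale.

**Community statistics** (`sedaforam.stats`): cumulative sum scaling (CSS)
normalization, Bray–Curtis distances, classical PCoA, a betadisper-style
dispersion test and PERMANOVA (both seed-reproducible permutation tests
with the +1 correction), Mantel correlation, WARM-group aggregation of
census counts, and depth-binned planktonic-fraction profiles.

**Synthetic studies** (`sedaforam.simulate`): complete ground-truthed
studies — reference database, zone- and depth-structured communities
following the decay model, spinose primer-mismatch dropout, copy-number
amplification bias, surface enrichment, tagged paired-end FASTQ reads with
errors and chimeras, and coupled microfossil census counts.

## Worked example

```python
import tempfile
import sedaforam as sf
from sedaforam.simulate import default_design, simulate_reference_db, simulate_reads

design = default_design(seed=42, reads_per_sample=500, error_rate=0.0, chimera_rate=0.0)
refdb = simulate_reference_db(taxa=design.taxa, seed=42)
with tempfile.TemporaryDirectory() as tmp:
    sim = simulate_reads(design, refdb, tmp)
    result = sf.run_pipeline(
        sim["fastq_fwd"], sim["fastq_rev"], sim["tag_scheme"], refdb,
        design.fwd_primer, design.rev_primer, sf.PipelineConfig(),
    )
print(result.stage_counts)
print(len(result.retained), result.habitat.value_counts().to_dict())
```

prints

```
{'raw_pairs': 30000, 'quality_dropped': 0, 'merge_rejected': 0,
 'demux_unassigned': 0, 'demultiplexed': 30000, 'chimera_reads': 0,
 'assigned_reads': 30000, 'unassigned_reads': 0}
27 {'benthic': 20, 'planktonic': 7}
```

All 30,000 noise-free read pairs survive every stage and collapse to
exactly 27 OTUs — one per amplifiable taxon: 20 benthic plus 7 planktonic
morphospecies. The two spinose species (*G. bulloides*,
*T. quinqueloba*), simulated with forward-primer mismatches, yield no reads
at all — the characteristic spinose dropout of this assay. The depth-binned
planktonic read fractions from the same OTU table,

```python
from sedaforam.simulate import metadata_frame
from sedaforam.stats import planktonic_fraction_profile
fr, binned = planktonic_fraction_profile(result.counts, result.habitat,
                                         metadata_frame(design))
print(binned)
```

```
[0,10)     0.0283
[10,20)    0.4515
[20,30)    0.4327
```

show the burial signature: planktonic amplicons are rare where living
benthic foraminifera dominate (top 10 cm), peak just below the inhabited
zone, and stay above the surface level further down.

A CLI mirrors the library: `sedaforam simulate | process | classify |
profile | decay | compare` (see `sedaforam --help`).

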