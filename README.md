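# mpcleave

Quantitative analysis of high-throughput Microprocessor cleavage assays on
pri-miRNA hairpins, built around the *C. elegans* system, where the
Microprocessor's two subunits act as molecular rulers: the RNase III
subunit (cDrosha) measures ~16 bp up from the basal junction of the
hairpin, and its partner Pasha measures ~25 bp down from the apical
junction. When a hairpin's stem is compatible with both measurements the
complex cuts at a single site; when it is not, the two rulers produce
alternative cleavage products.

`mpcleave` turns raw paired-end sequencing of in-vitro cleavage reactions
into a per-pri-miRNA cleavage atlas, annotates the hairpin structures the
rulers act on, and ships a fully seeded synthetic-library generator so
the entire pipeline is testable for parameter recovery without any
external data.

## What it computes

For each pri-miRNA, with cleavage positions indexed CL−5..CL5 around the
annotated pre-miRNA 5′ end (CL0), product counts `N_P` normalized to a
fixed-amount spike-in (×1000) and control abundance `N_S` in counts per
million, with pseudocount 0.1:

- **global cleavage efficiency** = log₂(Σ_P N_P + 0.1) − log₂(N_S + 0.1)
- **cleavage efficiency at P** = log₂(N_P + 0.1) − log₂(N_S + 0.1)
- **cleavage accuracy at P** = N_P / Σ_P N_P, and its argmax, the
  **major cleavage site (mCL)**
- **3′ overhangs** of each cleaved fragment against the predicted duplex
  (2 nt for a canonical RNase III product)
- **K-L divergence** D(test‖ref) in bits between accuracy distributions,
  for mutant-vs-wild-type cleavage-shift comparisons
- **structure annotation**: basal/apical junctions (first ≥3-nt
  single-stranded run in the −10..−25 / +21..+30 windows), lower/upper
  stem lengths in base pairs, and the UG, UGU/GUG, CNNC, mGHG and midBMW
  motif classes

## Worked example

```python
from mpcleave.simulate import (CleavageModel, LibraryConfig,
                               random_designs, simulate_experiment)
from mpcleave.pipeline import run_experiment

designs = random_designs(3, seed=1)
model = CleavageModel()                  # 16-bp basal ruler, 2-nt overhang
lib = LibraryConfig(depth_per_ref=500, spikein_reads=25, seed=1)
sim = simulate_experiment(designs, model, lib, control_depth_per_ref=50)
atlas, stats = run_experiment(sim)

for rid, s in atlas.scores.items():
    t = sim["truth"].refs[rid]
    print(rid, "mCL", s.mCL, "(planted", str(t.planted_mcl) + ")",
          "accuracy@mCL %.2f" % s.accuracy[s.mCL])
```

prints

```
sim-000 mCL 0 (planted 0) accuracy@mCL 0.60
sim-001 mCL 2 (planted 2) accuracy@mCL 0.62
sim-002 mCL 1 (planted 1) accuracy@mCL 0.61
```

i.e. after processing the simulated raw reads end to end, the recovered
major cleavage site matches the planted one for every reference, and the
accuracy at the mCL matches the generator's 0.60 kernel weight up to
multinomial noise.

The same stages are available from the shell:

```bash
mpcleave simulate --n-refs 30 --depth 2000 --seed 1 --out sim/
mpcleave process --r1 sim/product_R1.fastq.gz --r2 sim/product_R2.fastq.gz \
    --panel-fasta sim/panel.fasta --panel-tsv sim/panel.tsv \
    --sample-type product --out product/
mpcleave score --product-alignments product/alignments.tsv \
    --control-alignments control/alignments.tsv \
    --panel-fasta sim/panel.fasta --panel-tsv sim/panel.tsv \
    --structures sim/structures.db --out scores/
mpcleave annotate --panel-fasta sim/panel.fasta --panel-tsv sim/panel.tsv \
    --structures sim/structures.db --out annotation/
```

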