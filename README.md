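# markerphylo

Phylogenomic inference from annotated genomes: capture single-copy
orthologs by profile-HMM search against a curated marker set, align and
trim them, rank them by phylogenetic informativeness, and infer a species
tree by quartet consensus or supermatrix concatenation — with a
content-hash checkpoint so samples can be added or removed without
repeating finished searches.

It is aimed at comparative and microbial genomicists who have per-sample
protein FASTA files (proteomes) or nucleotide coding sequences and a
directory of HMMER3 marker profiles (BUSCO-style single-copy ortholog
sets), and want a reproducible species phylogeny without hand-wiring a
search → align → trim → tree toolchain. A built-in simulator generates
complete study systems (known species tree, marker families evolved along
it, decoy sequences, optional paralogs, and the matching HMMER3 profiles)
so every stage can be exercised and validated offline.

## How it works

**Search.** Each marker is a profile HMM with match/insert/delete states.
Sequences are scored in glocal mode (the full model must be traversed;
flanking residues are absorbed by free loop states emitting at the null
frequencies). The reported score is the forward log-odds in bits,

    bits = log2 [ P(x | profile) / P(x | null) ],

and a hit is any (sequence, marker) pair clearing the profile's gathering
cutoff or a configurable floor (default 10 bits). Viterbi scores, state
paths, and an HMMER3 text reader/writer are part of the same module. With
fewer than 8 CPUs one search instance uses all cores; with `n >= 8`,
`floor(n/4)` four-core instances run in parallel.

**Orthology.** Any sample with multiple hits to the same profile is
excluded *for that marker* (duplicates break the single-copy assumption);
markers represented in fewer than `min_taxa` samples (default 4) are
dropped. Results are checkpointed keyed by the SHA-256 of each sample
file's bytes — not its name or path — so checkpoints are portable and
incremental reruns only search new content.

**Alignment.** Hit sequences are threaded through their Viterbi paths into
match-state coordinates (width = model length for every input), then
trimmed to parsimony-informative sites: columns with ≥ 2 states, each in
≥ 2 rows. In CDS mode the search and alignment run on translations and
codons are threaded back afterwards (`3 ×` peptide columns).

**Informativeness.** Each marker gets a neighbor-joining gene tree and a
treeness/RCV score: treeness = Σ internal branch lengths / Σ all branch
lengths; RCV = Σ_j Σ_i |c_ij − c̄_j| / (n · t) for counts c_ij of state j
in taxon i over n taxa and t sites. Markers are ranked by
treeness / max(RCV, ε); filtering to a top-n subset is opt-in (keeping
everything is the default, since aggressive filtering can hurt accuracy).

**Trees.** Consensus mode returns the topology maximising the number of
induced four-taxon (quartet) topologies shared with the gene trees —
exhaustively up to 8 taxa, greedy + NNI hill-climbing beyond. Concatenation
mode builds a supermatrix with 1-based inclusive partitions (also exported
as FASTA + RAxML-style partition file for external ML tools), infers a
distance tree, and annotates branches with nonparametric bootstrap support
and site concordance factors (sCF). Robinson–Foulds distances and
monophyly checks are included for benchmarking against reference trees.

## Worked example

```bash
python examples/03_species_tree_both_modes.py
```

simulates 8 taxa × 20 markers of 150 residues, runs the full pipeline and
prints:

```
align: 20 trimmed marker alignments

consensus tree (RF to truth = 0, normalized 0.00):
  (t1,t2,((t3,t4),(t5,(t6,(t7,t8)))));

concatenation tree (RF to truth = 0, normalized 0.00):
  (t6:0.046...,(t7:0.055...,t8:0.040...)100:0.173...,(t5:0.058...,((t3:0.021...,
  t4:0.032...)100:0.444...,(t1:0.055...,t2:0.039...)100:0.127...)100:0.124...)100:0.104...);
```

RF = 0 means both strategies recovered the generating topology exactly;
the `100`s on internal nodes are bootstrap percentages (every true split
supported in all replicates). `examples/` also shows the search step in
isolation, alignment + treeness/RCV scoring, and incremental checkpointed
reruns. The same stages are scriptable from the shell:

```bash
markerphylo simulate --n-taxa 8 --n-markers 20 -o sim
markerphylo align --markers sim/markers --input sim/samples/t1.faa ... -o run
markerphylo filter --align-dir run --top-n 10
markerphylo tree --align-dir run --mode consensus -o run
```

A `key = value` config file (`markerphylo align --config run.cfg`) can
supply any of the align flags; explicit flags win.

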