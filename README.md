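# sigdecipher

Deciphering the signatures of mutational processes from the somatic
mutations of cancer genomes.

Every cancer genome carries the accumulated imprint of the DNA damage and
repair processes that were active in its cellular lineage. Each such
process leaves a characteristic *mutational signature* — a probability
distribution over mutation types (e.g. the 96 trinucleotide substitution
classes) — but a sequenced tumor only reveals the mixture. `sigdecipher`
treats the separation as a nonnegative blind-source-separation problem:
given the K×G catalog matrix **M** of mutation-type counts across G
genomes, it recovers a K×N signature matrix **P** (columns are
probability distributions, Σₖ pₙᵏ = 1) and an N×G exposure matrix **E**
(mutations contributed by each process to each genome) such that

&nbsp;&nbsp;&nbsp;&nbsp;**M ≈ P × E**,&nbsp;&nbsp; P ≥ 0, E ≥ 0.

The factorization is solved by multiplicative-update NMF wrapped in a
bootstrap-consensus procedure: each of I iterations resamples every
genome's mutations (totals preserved), factorizes the replicate, and the
I×N resulting signatures are consensus-clustered into N clusters whose
averaged centroids form the deciphered signatures. Cluster tightness
(average silhouette width under 1 − cosine distance) measures how
reproducibly each signature is found; the Frobenius reconstruction error
‖M − P̄Ē‖²_F measures how well the solution explains the catalogs; and
the number of processes N is chosen where signatures are reproducible and
the error curve flattens. A catalog simulator with known ground truth
supports power analyses of cohort designs. See `docs/methods.md` for the
full model and the numerical choices.

The package is aimed at cancer-genomics analysts working from somatic
variant calls (MAF-like tables) or pre-built catalog matrices, and at
methodologists studying when signature extraction succeeds.

## Worked example

```python
from sigdecipher import (DecipherConfig, SimulationSpec, decipher_signatures,
                         match_signatures, simulate_truth)

spec = SimulationSpec(N=4, G=40, mutations_per_genome=("log_uniform", 1_000, 20_000), seed=42)
truth = simulate_truth(spec)                     # 96×40 catalog, known P and E
result = decipher_signatures(truth.M, DecipherConfig(N=4, I=50, seed=7))
match = match_signatures(result.P_bar, truth.P_true)
print(result.avg_silhouette, match.mean_cosine)
```

Running `python examples/simulate_and_decipher.py` (this exact analysis)
prints:

```
average silhouette width: 0.991 (1.00 = identical signatures found in every bootstrap iteration)
...
mean matched cosine similarity: 0.9922 (1.00 = the exact generating processes were extracted)
```

meaning the four generating processes were found in essentially every
bootstrap iteration (silhouette 0.991) and the recovered probability
profiles are nearly identical to the true ones (cosine 0.992 after
optimal one-to-one matching). The other scripts in `examples/` show
catalog construction with extended mutation classes (kataegis,
dinucleotides, indel subclasses), rank selection via the two
model-selection curves, and a replicate power analysis of signature
similarity.

A thin CLI mirrors the library:

```bash
sigdecipher simulate --n-signatures 10 --n-genomes 100 --seed 7 --out-dir sim/
sigdecipher decipher --catalog sim/catalog.tsv --n-signatures 10 --iterations 100 --seed 7 --out-dir out/
sigdecipher select-n --catalog sim/catalog.tsv --n-min 8 --n-max 12 --seed 7 --out curves.tsv
sigdecipher catalog  --mutations muts.tsv --scheme sbs96ext4 --reference ref.fa --out M.tsv
sigdecipher evaluate --extracted out/signatures.tsv --truth sim/truth_signatures.tsv --out report.json
```

Catalogs are plain TSV (rows = mutation types in canonical order,
columns = samples); mutation tables are MAF-lite TSV with 1-based
positions; gene footprints for transcriptional-strand annotation are
BED6. Pre-built catalog matrices from published cohorts (e.g. the 21
breast-cancer whole genomes or 100 breast-cancer exomes distributed with
the original MATLAB framework) can be converted to this TSV layout and
analyzed directly with `sigdecipher decipher` / `select-n`; they are
optional external inputs, not required by anything in this repository.

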