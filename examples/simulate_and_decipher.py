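"""Simulate a cohort with known signatures and decipher them back.

Generates 40 genomes from 4 random trinucleotide signatures with Poisson
noise, runs the bootstrap-NMF consensus extraction at the true rank, and
scores the recovered signatures and exposures against the truth.
"""

from sigdecipher import (
    DecipherConfig,
    SimulationSpec,
    decipher_signatures,
    exposure_error,
    match_signatures,
    simulate_truth,
)

spec = SimulationSpec(N=4, G=40, mutations_per_genome=("log_uniform", 1_000, 20_000), seed=42)
truth = simulate_truth(spec)
print(f"catalog: {truth.M.K} mutation types × {truth.M.G} genomes, "
      f"{truth.M.counts.sum():,} mutations")

result = decipher_signatures(truth.M, DecipherConfig(N=4, I=50, seed=7))

print(f"\naverage silhouette width: {result.avg_silhouette:.3f} "
      "(1.00 = identical signatures found in every bootstrap iteration)")
print(f"reconstruction error ‖Ṁ − P̄Ē‖²_F: {result.reconstruction_error:,.0f}")

match = match_signatures(result.P_bar, truth.P_true)
err = exposure_error(result.E_bar, truth.E_true, match.pairing)
print("\nper-signature recovery (after optimal matching):")
for i, j in enumerate(match.pairing):
    print(
        f"  deciphered {result.P_bar.names[i]} ↔ true {truth.P_true.names[j]}: "
        f"cosine {match.cosines[i]:.4f}, exposure SMAPE {err['smape'][i]:.3f}"
    )
print(f"\nmean matched cosine similarity: {match.mean_cosine:.4f} "
      "(1.00 = the exact generating processes were extracted)")
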