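"""How signature similarity affects what can be deciphered.

Repeats a simulate → decipher → score cycle for two cohort designs of 30
genomes from 4 signatures: one where two of the signatures are nearly
duplicates (cosine similarity 0.9-1.0) and one where all four are
distinct. Reports the mean ± SD deciphering accuracy over replicates —
near-duplicate processes are intrinsically harder to separate.
"""

from sigdecipher import DecipherConfig, SimulationSpec
from sigdecipher.evaluate import run_scenario
from sigdecipher.nmf import NMFConfig

cfg = DecipherConfig(N=4, I=20, nmf=NMFConfig(conv_tol=1e-4))

for label, constraints in [
    ("distinct signatures        ", []),
    ("near-duplicate pair (0.9-1)", [((2, 3), (0.9, 1.0))]),
]:
    spec = SimulationSpec(
        N=4,
        G=30,
        mutations_per_genome=("fixed", 8_000),
        similarity_constraints=constraints,
        concentration=0.1,
    )
    report = run_scenario(spec, cfg, replicates=5, seed=13)
    print(
        f"{label}: accuracy {report['accuracy_mean']:.3f} ± {report['accuracy_sd']:.3f}, "
        f"exposure SMAPE {report['exposure_smape_mean']:.3f}"
    )
# Accuracy is the mean matched cosine between deciphered and generating
# signatures (1.00 = perfect recovery).
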