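"""Build a mutation-type catalog, with extended classes, from raw mutations.

Constructs a small list of somatic mutations for one sample — a kataegis
shower, a dinucleotide substitution, an indel at a mononucleotide repeat,
and a handful of isolated substitutions — and counts them into the
100-type extended catalog (96 trinucleotide types + kataegis +
dinucleotide + 2 indel classes).
"""

from sigdecipher import MutationRecord, build_alphabet, catalog_from_records

records = [
    # six substitutions within ~500 bp: a kataegis shower
    *[
        MutationRecord("PD001", "chr6", 10_000 + 100 * i, "C", "T", context5="T", context3="A")
        for i in range(6)
    ],
    # two substitutions at consecutive bases: one dinucleotide event
    MutationRecord("PD001", "chr2", 5_000, "C", "A", context5="G", context3="C"),
    MutationRecord("PD001", "chr2", 5_001, "C", "T", context5="A", context3="G"),
    # deletion of an A next to AAT: repeat-mediated indel
    MutationRecord("PD001", "chr3", 77_000, "A", "-", context5="TCGG", context3="AATC"),
    # isolated substitutions, including one given on the purine strand
    MutationRecord("PD001", "chr1", 1_000, "C", "T", context5="T", context3="G"),
    MutationRecord("PD001", "chr1", 900_000, "G", "A", context5="C", context3="A"),
]

alphabet = build_alphabet("SBS96_EXT4")
catalog = catalog_from_records(records, alphabet)

nonzero = catalog.to_frame().loc[lambda df: df.PD001 > 0, "PD001"]
print(nonzero.to_string())
print(f"\ntotal classified mutations: {catalog.counts.sum()}")

# The kataegis shower is excluded from the trinucleotide classes, the
# adjacent pair collapses to a single dinucleotide event, and the two
# isolated substitutions share the label T[C>T]G because G>A on the
# forward strand is C>T read on the pyrimidine strand.
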