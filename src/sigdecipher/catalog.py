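"""Mutation records, extended-class calling, and catalog matrices.

A catalog matrix M is the K×G table of mutation-type counts (rows follow
the alphabet's label order, columns are samples). This module builds
catalogs from per-mutation tables (MAF-lite TSV: 1-based positions), with
optional sequence context from an indexed FASTA, transcriptional-strand
annotation from stranded gene footprints (BED6, half-open 0-based), and
the extended mutation classes: kataegis runs, dinucleotide substitutions,
and repeat- or microhomology-mediated indels.

Extended classes are assigned with deterministic precedence: kataegis
detection first (kataegis substitutions are excluded from all other
substitution classes), then dinucleotide pairing, then indel
classification, then ordinary substitution classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import (
    BASES,
    PYRIMIDINES,
    AlphabetScheme,
    MutationTypeAlphabet,
    build_alphabet,
    classify_substitution,
)

__all__ = [
    "MutationRecord",
    "CatalogMatrix",
    "StrandedInterval",
    "identify_dinucleotides",
    "detect_kataegis",
    "classify_indel",
    "annotate_strand",
    "catalog_from_records",
    "read_catalog",
    "write_catalog",
    "read_mutation_table",
    "read_footprints_bed",
]

logger = logging.getLogger(__name__)

GAP = "-"

#: default kataegis calling thresholds (intermutation distance in bp, run length)
DEFAULT_KATAEGIS_IMD = 1000
DEFAULT_KATAEGIS_RUN = 6


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation. ``pos`` is 1-based; ``ref``/``alt`` use '-' for
    the empty allele of a pure insertion/deletion (MAF convention)."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    strand_label: str | None = None  # transcribed / untranscribed / unknown
    class_override: str | None = None
    context5: str = ""
    context3: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be ≥ 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def is_substitution(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in BASES
            and self.alt in BASES
        )

    @property
    def is_indel(self) -> bool:
        return not self.is_substitution and (GAP in (self.ref, self.alt) or len(self.ref) != len(self.alt))

    @property
    def indel_seq(self) -> str:
        """Inserted or deleted sequence for a pure indel."""
        if self.ref == GAP:
            return self.alt
        if self.alt == GAP:
            return self.ref
        # shared-prefix style (e.g. ref=CA alt=C): strip the common prefix
        if self.ref.startswith(self.alt):
            return self.ref[len(self.alt):]
        if self.alt.startswith(self.ref):
            return self.alt[len(self.ref):]
        raise ValueError(f"cannot derive indel sequence from {self.ref}>{self.alt}")

    @property
    def is_deletion(self) -> bool:
        return self.is_indel and (self.alt == GAP or len(self.ref) > len(self.alt))


@dataclass
class CatalogMatrix:
    """K×G nonnegative integer mutation-type counts."""

    alphabet: MutationTypeAlphabet
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.alphabet.K, len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"K={self.alphabet.K}, G={len(self.samples)}"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if np.any(self.counts < 0):
            raise ValueError("catalog counts must be nonnegative")

    @property
    def K(self) -> int:
        return self.alphabet.K

    @property
    def G(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.alphabet.labels), columns=self.samples)


# ---------------------------------------------------------------------------
# extended mutation classes


def _substitution_runs(records: list[MutationRecord]):
    """Yield records grouped by (sample, chrom), sorted by position."""
    keyed: dict[tuple[str, str], list[MutationRecord]] = {}
    for r in records:
        keyed.setdefault((r.sample, r.chrom), []).append(r)
    for key in sorted(keyed):
        yield key, sorted(keyed[key], key=lambda r: r.pos)


def identify_dinucleotides(
    records: list[MutationRecord],
) -> tuple[list[tuple[MutationRecord, MutationRecord]], list[MutationRecord]]:
    """Pair substitutions at consecutive bases into dinucleotide events.

    Two substitutions in the same sample at adjacent positions on the same
    chromosome form one dinucleotide event; sequence context is ignored.
    Runs of ≥3 consecutive substitutions are resolved by greedy
    left-to-right pairing, so positions (100, 101, 102) give the event
    (100, 101) and leave 102 as a single substitution.
    """
    events: list[tuple[MutationRecord, MutationRecord]] = []
    remaining: list[MutationRecord] = []
    non_subs = [r for r in records if not r.is_substitution]
    subs = [r for r in records if r.is_substitution]
    for _, group in _substitution_runs(subs):
        i = 0
        while i < len(group):
            if i + 1 < len(group) and group[i + 1].pos == group[i].pos + 1:
                events.append((group[i], group[i + 1]))
                i += 2
            else:
                remaining.append(group[i])
                i += 1
    return events, remaining + non_subs


def detect_kataegis(
    records: list[MutationRecord],
    max_imd: int = DEFAULT_KATAEGIS_IMD,
    min_run: int = DEFAULT_KATAEGIS_RUN,
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Split substitutions into kataegis runs and the rest.

    A kataegis run is a maximal same-sample, same-chromosome stretch of at
    least ``min_run`` substitutions whose consecutive intermutation
    distances are all ≤ ``max_imd`` bp; sequence context plays no role.
    """
    if max_imd <= 0:
        raise ValueError("max_imd must be positive")
    if min_run < 2:
        raise ValueError("min_run must be ≥ 2")
    kataegis: list[MutationRecord] = []
    remaining: list[MutationRecord] = []
    non_subs = [r for r in records if not r.is_substitution]
    subs = [r for r in records if r.is_substitution]
    for _, group in _substitution_runs(subs):
        start = 0
        for i in range(1, len(group) + 1):
            if i == len(group) or group[i].pos - group[i - 1].pos > max_imd:
                run = group[start:i]
                (kataegis if len(run) >= min_run else remaining).extend(run)
                start = i
    return kataegis, remaining + non_subs


def classify_indel(
    record: MutationRecord,
    flank5: str,
    flank3: str,
    min_homology: int = 1,
) -> str:
    """Classify an indel as repeat-, microhomology-mediated, or other.

    ``repeat_mediated``: the inserted/deleted sequence is an exact copy of
    the immediately adjacent reference sequence on either side (a mono- or
    polynucleotide repeat unit). ``microhomology_mediated``: a deletion
    whose deleted sequence shares ≥ ``min_homology`` identical leading
    bases with the 3' flank (short homology at the breakpoint); insertions
    are never microhomology-classified. Everything else is ``other``.
    """
    if not record.is_indel:
        raise ValueError("record is not an indel")
    seq = record.indel_seq.upper()
    flank5, flank3 = flank5.upper(), flank3.upper()
    if len(flank5) < len(seq) or len(flank3) < len(seq):
        raise ValueError("flanking sequences must be at least as long as the indel")
    if flank3.startswith(seq) or flank5.endswith(seq):
        return "repeat_mediated"
    if record.is_deletion:
        hom = 0
        for a, b in zip(seq, flank3):
            if a != b:
                break
            hom += 1
        if hom >= min_homology:
            return "microhomology_mediated"
    return "other"


@dataclass(frozen=True)
class StrandedInterval:
    """Half-open, 0-based genomic interval on a known strand."""

    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def annotate_strand(
    records: list[MutationRecord],
    footprints: list[StrandedInterval],
) -> list[MutationRecord]:
    """Attach transcriptional-strand labels to substitutions in genic regions.

    Convention: a substitution is labelled ``transcribed`` when the
    pyrimidine of the mutated base pair lies on the template (transcribed)
    strand of the overlapping gene, ``untranscribed`` when it lies on the
    coding strand, and ``unknown`` outside every footprint. With a
    pyrimidine reference base on the forward strand, a '+'-strand gene
    (template = '-') therefore gives ``untranscribed`` and a '-'-strand
    gene gives ``transcribed``.
    """
    by_chrom: dict[str, list[StrandedInterval]] = {}
    for iv in footprints:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts: dict[str, np.ndarray] = {}
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda iv: iv.start)
        starts[chrom] = np.array([iv.start for iv in by_chrom[chrom]])

    out: list[MutationRecord] = []
    for r in records:
        if not r.is_substitution:
            out.append(r)
            continue
        label = "unknown"
        ivs = by_chrom.get(r.chrom)
        if ivs is not None:
            pos0 = r.pos - 1  # convert 1-based to 0-based
            j = int(np.searchsorted(starts[r.chrom], pos0, side="right")) - 1
            if j >= 0 and ivs[j].start <= pos0 < ivs[j].end:
                pyr_on_forward = r.ref in PYRIMIDINES
                gene_plus = ivs[j].strand == "+"
                # template strand is the reverse of the gene's coding strand
                label = "transcribed" if pyr_on_forward != gene_plus else "untranscribed"
        out.append(replace(r, strand_label=label))
    return out


# ---------------------------------------------------------------------------
# catalog construction


def _context_from_reference(record: MutationRecord, reference, width: int) -> tuple[str, str]:
    if record.context5 and record.context3:
        return record.context5, record.context3
    if reference is None:
        raise ValueError(
            f"no sequence context for {record.chrom}:{record.pos} and no reference given"
        )
    pos0 = record.pos - 1
    chrom_seq = reference[record.chrom]
    c5 = str(chrom_seq[max(0, pos0 - width):pos0]).upper()
    c3 = str(chrom_seq[pos0 + 1:pos0 + 1 + width]).upper()
    return c5, c3


def catalog_from_records(
    records: list[MutationRecord],
    alphabet: MutationTypeAlphabet,
    reference=None,
    strict: bool = False,
    kataegis_imd: int = DEFAULT_KATAEGIS_IMD,
    kataegis_run: int = DEFAULT_KATAEGIS_RUN,
    min_homology: int = 1,
    samples: list[str] | None = None,
) -> CatalogMatrix:
    """Count classified mutations into a K×G catalog matrix.

    ``reference`` is any mapping from chromosome name to sliceable
    sequence (e.g. a :class:`pyfaidx.Fasta`); it is only consulted for
    records lacking inline context. For SBS96_EXT4, kataegis runs are
    called first and excluded from the other substitutions, then adjacent
    substitutions are paired into dinucleotide events, then indels are
    classified, and the remaining substitutions fall through to the 96
    trinucleotide classes. Unclassifiable records raise in strict mode
    and are skipped (with a logged count) otherwise.
    """
    if samples is None:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.sample, None)
        samples = list(seen)
    counts = np.zeros((alphabet.K, len(samples)), dtype=np.int64)
    col = {s: i for i, s in enumerate(samples)}
    width = alphabet.context_width
    skipped = 0

    def add(label: str, sample: str) -> None:
        counts[alphabet.index(label), col[sample]] += 1

    def classify_or_skip(fn, record: MutationRecord) -> None:
        nonlocal skipped
        try:
            fn(record)
        except (ValueError, KeyError) as exc:
            if strict:
                raise ValueError(
                    f"unclassifiable record {record.sample} {record.chrom}:{record.pos} "
                    f"{record.ref}>{record.alt}: {exc}"
                ) from exc
            skipped += 1

    extended = alphabet.scheme is AlphabetScheme.SBS96_EXT4
    work = list(records)

    if extended:
        kataegis, work = detect_kataegis(work, kataegis_imd, kataegis_run)
        for r in kataegis:
            add("kataegis", r.sample)
        events, work = identify_dinucleotides(work)
        for a, _ in events:
            add("dinucleotide", a.sample)

    for r in work:
        if r.class_override is not None:
            classify_or_skip(lambda rec: add(rec.class_override, rec.sample), r)
        elif r.is_indel:
            if not extended:
                if strict:
                    raise ValueError(
                        f"indel {r.chrom}:{r.pos} not representable under {alphabet.scheme.value}"
                    )
                skipped += 1
                continue

            def _indel(rec: MutationRecord) -> None:
                c5, c3 = _context_from_reference(rec, reference, max(1, len(rec.indel_seq)))
                cls = classify_indel(rec, c5, c3, min_homology)
                if cls == "repeat_mediated":
                    add("indel_repeat", rec.sample)
                elif cls == "microhomology_mediated":
                    add("indel_microhomology", rec.sample)
                else:
                    raise ValueError("indel at neither repeat nor microhomology")

            classify_or_skip(_indel, r)
        else:

            def _sub(rec: MutationRecord) -> None:
                c5, c3 = ("", "") if width == 0 else _context_from_reference(rec, reference, width)
                strand = rec.strand_label
                if alphabet.scheme is AlphabetScheme.SBS192 and strand not in (
                    "transcribed",
                    "untranscribed",
                ):
                    raise ValueError("substitution outside annotated gene footprints")
                add(classify_substitution(rec.ref, rec.alt, c5, c3, alphabet, strand), rec.sample)

            classify_or_skip(_sub, r)

    if skipped:
        logger.info("skipped %d unclassifiable record(s)", skipped)
    return CatalogMatrix(alphabet=alphabet, samples=samples, counts=counts)


# ---------------------------------------------------------------------------
# I/O


def write_catalog(catalog: CatalogMatrix, path: str | Path) -> None:
    """Write a catalog as TSV: first column "MutationType", one column per sample."""
    df = catalog.to_frame()
    df.index.name = "MutationType"
    df.to_csv(path, sep="\t")


def read_catalog(path: str | Path, alphabet: MutationTypeAlphabet | None = None) -> CatalogMatrix:
    """Read a catalog TSV written by :func:`write_catalog`.

    Rows may appear in any order; they are reordered to the canonical
    alphabet order. The scheme is inferred from the number of rows when
    ``alphabet`` is not given. Unknown labels, missing labels, duplicate
    rows, and negative or non-integer counts are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if alphabet is None:
        by_k = {6: "SBS6", 96: "SBS96", 100: "SBS96_EXT4", 192: "SBS192", 1536: "SBS1536"}
        if len(df) not in by_k:
            raise ValueError(f"cannot infer alphabet scheme from {len(df)} rows")
        alphabet = build_alphabet(by_k[len(df)])
    labels = list(df.index.astype(str))
    unknown = [lab for lab in labels if lab not in alphabet]
    if unknown:
        raise ValueError(f"unknown mutation-type labels: {unknown[:5]}")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate mutation-type rows")
    if len(labels) != alphabet.K:
        raise ValueError(f"expected {alphabet.K} rows, found {len(labels)}")
    df = df.reindex(list(alphabet.labels))
    values = df.to_numpy()
    if not np.all(np.isfinite(values)):
        raise ValueError("catalog contains missing or non-numeric cells")
    if np.any(values < 0):
        raise ValueError("catalog contains negative counts")
    if np.any(values != np.floor(values)):
        raise ValueError("catalog counts must be integers")
    return CatalogMatrix(
        alphabet=alphabet,
        samples=[str(c) for c in df.columns],
        counts=values.astype(np.int64),
    )


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-lite TSV: sample, chrom, pos, ref, alt[, strand][, class]
    with optional context5/context3 columns. Positions are 1-based."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [c.lower() for c in df.columns]
    required = ["sample", "chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            MutationRecord(
                sample=d["sample"],
                chrom=d["chrom"],
                pos=int(d["pos"]),
                ref=d["ref"].upper(),
                alt=d["alt"].upper(),
                strand_label=d.get("strand") or None,
                class_override=d.get("class") or None,
                context5=(d.get("context5") or "").upper(),
                context3=(d.get("context3") or "").upper(),
            )
        )
    return records


def read_footprints_bed(path: str | Path) -> list[StrandedInterval]:
    """Read stranded gene footprints from BED6 (0-based, half-open)."""
    ivs: list[StrandedInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns")
            try:
                ivs.append(
                    StrandedInterval(
                        chrom=parts[0], start=int(parts[1]), end=int(parts[2]), strand=parts[5]
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return ivs
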