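"""Mutation-type alphabets and single-substitution classification.

A mutation-type alphabet is the ordered set of K labels over which
catalogs and signatures are defined. Substitutions are reported with the
pyrimidine of the mutated base pair as reference ("pyrimidine collapse"),
so a G>A mutation and its reverse-complement C>T context map to the same
label. Supported schemes:

========== ===== =======================================================
scheme       K   meaning
========== ===== =======================================================
SBS6          6  the six pyrimidine-reference substitution classes
SBS96        96  6 substitutions × 4 5'-bases × 4 3'-bases
SBS192      192  SBS96 split by transcriptional strand (T/U suffix)
SBS1536    1536  6 substitutions × 16 5'-dinucleotides × 16 3'-dinucleotides
SBS96_EXT4  100  SBS96 plus kataegis, dinucleotide, and two indel classes
========== ===== =======================================================

Labels follow the community convention "A[C>T]G" (trinucleotide),
"AA[C>T]GG" (pentanucleotide), "A[C>T]G:T"/":U" (stranded), ordered by
substitution class first and then lexicographically by flanking context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import product

__all__ = [
    "AlphabetScheme",
    "MutationTypeAlphabet",
    "build_alphabet",
    "classify_substitution",
    "SUBSTITUTION_CLASSES",
    "EXTENDED_CLASSES",
    "reverse_complement",
]

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six substitution classes with a pyrimidine reference base
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: extra mutation classes appended by the SBS96_EXT4 scheme
EXTENDED_CLASSES = ("kataegis", "dinucleotide", "indel_repeat", "indel_microhomology")


class AlphabetScheme(str, Enum):
    SBS6 = "SBS6"
    SBS96 = "SBS96"
    SBS192 = "SBS192"
    SBS1536 = "SBS1536"
    SBS96_EXT4 = "SBS96_EXT4"


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence {seq!r}") from exc


@dataclass(frozen=True)
class MutationTypeAlphabet:
    """Ordered set of K mutation-type labels for one classification scheme."""

    scheme: AlphabetScheme
    labels: tuple[str, ...]
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("alphabet labels must be unique")
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})

    @property
    def K(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    @property
    def context_width(self) -> int:
        """Number of flanking bases on each side used by this scheme."""
        if self.scheme is AlphabetScheme.SBS6:
            return 0
        if self.scheme is AlphabetScheme.SBS1536:
            return 2
        return 1


def _sbs96_labels() -> list[str]:
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTION_CLASSES
        for five in BASES
        for three in BASES
    ]


def _sbs1536_labels() -> list[str]:
    pairs = ["".join(p) for p in product(BASES, repeat=2)]
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTION_CLASSES
        for five in pairs
        for three in pairs
    ]


def build_alphabet(scheme: AlphabetScheme | str) -> MutationTypeAlphabet:
    """Build the ordered mutation-type alphabet for a scheme.

    Ordering is deterministic: substitution classes in the order
    C>A, C>G, C>T, T>A, T>C, T>G, then flanking context lexicographically
    (5' context major, 3' context minor); for SBS192 the transcribed (":T")
    label directly precedes the untranscribed (":U") one; SBS96_EXT4
    appends the four extended classes after the 96 substitution labels.
    """
    scheme = AlphabetScheme(scheme)
    if scheme is AlphabetScheme.SBS6:
        labels = list(SUBSTITUTION_CLASSES)
    elif scheme is AlphabetScheme.SBS96:
        labels = _sbs96_labels()
    elif scheme is AlphabetScheme.SBS192:
        labels = [f"{lab}:{s}" for lab in _sbs96_labels() for s in "TU"]
    elif scheme is AlphabetScheme.SBS1536:
        labels = _sbs1536_labels()
    elif scheme is AlphabetScheme.SBS96_EXT4:
        labels = _sbs96_labels() + list(EXTENDED_CLASSES)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unsupported alphabet scheme: {scheme}")
    return MutationTypeAlphabet(scheme=scheme, labels=tuple(labels))


def _check_base(b: str, what: str) -> None:
    if len(b) != 1 or b not in BASES:
        raise ValueError(f"{what} must be a single base in ACGT, got {b!r}")


def classify_substitution(
    ref: str,
    alt: str,
    context5: str = "",
    context3: str = "",
    alphabet: MutationTypeAlphabet | None = None,
    strand_label: str | None = None,
) -> str:
    """Map one base substitution to its alphabet label.

    ``context5``/``context3`` are the flanking reference bases immediately
    5' and 3' of the mutated base, read on the strand on which ``ref`` is
    given. If ``ref`` is a purine, the substitution and its context are
    reverse-complemented so the reported reference base is the pyrimidine
    of the mutated pair. For SBS192, ``strand_label`` must be
    ``"transcribed"`` or ``"untranscribed"``.

    Raises ``ValueError`` for non-ACGT characters, ``ref == alt``, or a
    context length that does not match the scheme.
    """
    if alphabet is None:
        alphabet = build_alphabet(AlphabetScheme.SBS96)
    _check_base(ref, "ref")
    _check_base(alt, "alt")
    if ref == alt:
        raise ValueError("ref and alt must differ")

    w = alphabet.context_width
    if len(context5) < w or len(context3) < w:
        raise ValueError(
            f"scheme {alphabet.scheme.value} needs {w} context base(s) on each side"
        )
    context5 = context5[len(context5) - w :] if w else ""
    context3 = context3[:w] if w else ""
    for b in context5 + context3:
        _check_base(b, "context base")

    if ref in PURINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context5, context3 = reverse_complement(context3), reverse_complement(context5)

    sub = f"{ref}>{alt}"
    if alphabet.scheme is AlphabetScheme.SBS6:
        label = sub
    elif alphabet.scheme is AlphabetScheme.SBS192:
        if strand_label not in ("transcribed", "untranscribed"):
            raise ValueError("SBS192 classification requires a transcribed/untranscribed strand label")
        label = f"{context5}[{sub}]{context3}:{'T' if strand_label == 'transcribed' else 'U'}"
    else:
        label = f"{context5}[{sub}]{context3}"

    if label not in alphabet:
        raise ValueError(f"label {label!r} not in alphabet {alphabet.scheme.value}")
    return label
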