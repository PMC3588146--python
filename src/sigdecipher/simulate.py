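"""Simulation of mutational catalogs with known ground truth.

Generates random mutational signatures, per-genome exposures, and
catalogs M = "P_true × E_true plus noise", the setting used to measure
how well the decipher pipeline recovers known processes. Per-genome
mutation totals default to a log-uniform draw on [500, 50000], matching
the spread of substitution counts across sequenced human cancer genomes;
each signature's mutations are typed multinomially from its probability
profile, and Poisson resampling noise is applied to the finished catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import MutationTypeAlphabet, build_alphabet
from .catalog import CatalogMatrix
from .nmf import ExposureMatrix, SignatureMatrix

__all__ = [
    "SimulationSpec",
    "SimulationTruth",
    "random_signature",
    "signature_pair_with_similarity",
    "simulate_exposures",
    "simulate_catalogs",
    "simulate_truth",
    "largest_remainder_split",
]


@dataclass
class SimulationSpec:
    """Parameters of one simulated cohort.

    ``mutations_per_genome`` is ("log_uniform", lo, hi), ("uniform", lo, hi)
    or ("fixed", n). ``similarity_constraints`` lists ((i, j), (lo, hi))
    pairs: signature j is regenerated so its cosine similarity to
    signature i lands inside [lo, hi]. Under the fixed-fraction exposure
    models, ``fixed_fraction`` is signature 1's share of mutations, either
    per genome or of the cohort total.
    """

    N: int
    G: int
    alphabet: MutationTypeAlphabet = field(default_factory=lambda: build_alphabet("SBS96"))
    mutations_per_genome: tuple = ("log_uniform", 500, 50_000)
    similarity_constraints: list[tuple[tuple[int, int], tuple[float, float]]] = field(
        default_factory=list
    )
    exposure_model: str = "uniform_random"  # | fixed_fraction_overall | fixed_fraction_per_genome
    fixed_fraction: float = 0.0
    noise_model: str = "poisson_resample"  # | additive_white | none
    white_noise_fraction: float = 0.02
    concentration: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 1 or self.G < 1:
            raise ValueError("need N ≥ 1 and G ≥ 1")
        if not 0.0 <= self.fixed_fraction <= 1.0:
            raise ValueError("fixed_fraction must lie in [0, 1]")
        if not 0.0 <= self.white_noise_fraction <= 1.0:
            raise ValueError("white_noise_fraction must lie in [0, 1]")
        if self.exposure_model not in (
            "uniform_random",
            "fixed_fraction_overall",
            "fixed_fraction_per_genome",
        ):
            raise ValueError(f"unknown exposure model {self.exposure_model!r}")
        if self.noise_model not in ("poisson_resample", "additive_white", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for (_i, _j), (lo, hi) in self.similarity_constraints:
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError("target cosine ranges must be within [0, 1]")


@dataclass
class SimulationTruth:
    """Generating signatures/exposures and the catalog simulated from them."""

    P_true: SignatureMatrix
    E_true: ExposureMatrix
    M: CatalogMatrix
    seed: int | None


def largest_remainder_split(total: int, weights: np.ndarray) -> np.ndarray:
    """Split an integer total proportionally to weights, exactly.

    Largest-remainder rounding: each part gets the floor of its ideal
    share and leftover units go to the largest fractional remainders, so
    the parts always sum to ``total``.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if total < 0:
        raise ValueError("total must be nonnegative")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    ideal = total * weights / weights.sum()
    parts = np.floor(ideal).astype(np.int64)
    short = total - int(parts.sum())
    if short:
        order = np.argsort(-(ideal - parts), kind="stable")
        parts[order[:short]] += 1
    return parts


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def random_signature(
    alphabet: MutationTypeAlphabet,
    concentration: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw one signature from a symmetric Dirichlet over the K types.

    Concentration < 1 gives peaked, signature-like profiles; as the
    concentration grows the draw approaches the uniform distribution.
    The returned vector is nonnegative and sums to 1.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.dirichlet(np.full(alphabet.K, concentration))


def signature_pair_with_similarity(
    base: np.ndarray,
    target_range: tuple[float, float],
    rng: np.random.Generator | int | None = None,
    concentration: float = 0.5,
    max_attempts: int = 50,
) -> np.ndarray:
    """Construct a signature whose cosine similarity to ``base`` falls in
    ``target_range``.

    A fresh random signature r is mixed convexly with the base,
    (1−t)·base + t·r, and the weight t is tuned by bisection until the
    similarity lands in range; new r are drawn if a draw's own similarity
    to the base already exceeds the upper target. Raises after
    ``max_attempts`` failed draws, reporting the best similarity reached.
    """
    lo, hi = target_range
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError("target_range must be a nonempty subinterval of [0, 1]")
    base = np.asarray(base, dtype=np.float64)
    if hi == 1.0 and lo == 1.0:
        return base.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    alphabet_like = base.shape[0]
    achieved = np.nan
    for _ in range(max_attempts):
        r = rng.dirichlet(np.full(alphabet_like, concentration))
        if _cosine(r, base) > hi:
            achieved = _cosine(r, base)
            continue
        t_lo, t_hi = 0.0, 1.0  # sim(t_lo)=1 ≥ hi ≥ lo; sim(t_hi) ≤ hi
        for _ in range(200):
            t = 0.5 * (t_lo + t_hi)
            v = (1.0 - t) * base + t * r
            s = _cosine(v, base)
            if s > hi:
                t_lo = t
            elif s < lo:
                t_hi = t
            else:
                return v
        achieved = s
    raise RuntimeError(
        f"could not reach cosine similarity in [{lo}, {hi}] after {max_attempts} "
        f"attempts (best achieved: {achieved:.4f})"
    )


def _draw_totals(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    kind, *params = spec.mutations_per_genome
    if kind == "log_uniform":
        lo, hi = params
        return np.round(np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.G))).astype(np.int64)
    if kind == "uniform":
        lo, hi = params
        return rng.integers(lo, hi + 1, size=spec.G)
    if kind == "fixed":
        (n,) = params
        return np.full(spec.G, int(n), dtype=np.int64)
    raise ValueError(f"unknown mutation-count distribution {kind!r}")


def simulate_exposures(
    spec: SimulationSpec, rng: np.random.Generator | int | None = None
) -> ExposureMatrix:
    """Draw integer exposures (mutations per signature per genome).

    Each genome's total is drawn from ``spec.mutations_per_genome`` and
    split across the N signatures. ``uniform_random`` splits by a flat
    Dirichlet (contributions uniformly distributed over the simplex);
    ``fixed_fraction_per_genome`` gives signature 1 exactly
    round(f × total) mutations in every genome; ``fixed_fraction_overall``
    constrains only signature 1's share of the cohort total, letting its
    per-genome contribution vary randomly. Integer splits use
    largest-remainder rounding so column totals are preserved exactly.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    totals = _draw_totals(spec, rng)
    N, G = spec.N, spec.G
    E = np.zeros((N, G), dtype=np.int64)

    if spec.exposure_model == "uniform_random":
        for g in range(G):
            E[:, g] = largest_remainder_split(int(totals[g]), rng.dirichlet(np.ones(N)))
    elif spec.exposure_model == "fixed_fraction_per_genome":
        if N == 1 and spec.fixed_fraction < 1.0:
            raise ValueError("fixed fraction < 1 is infeasible with a single signature")
        for g in range(G):
            s1 = int(round(spec.fixed_fraction * totals[g]))
            E[0, g] = s1
            if N > 1:
                E[1:, g] = largest_remainder_split(int(totals[g]) - s1, rng.dirichlet(np.ones(N - 1)))
    else:  # fixed_fraction_overall
        if N == 1 and spec.fixed_fraction < 1.0:
            raise ValueError("fixed fraction < 1 is infeasible with a single signature")
        grand = int(totals.sum())
        target = int(round(spec.fixed_fraction * grand))
        # random per-genome weights, water-filled so no genome exceeds its total
        weights = rng.random(G) * totals
        alloc = largest_remainder_split(target, weights)
        while True:
            over = alloc > totals
            if not np.any(over):
                break
            excess = int((alloc[over] - totals[over]).sum())
            alloc[over] = totals[over]
            free = ~over
            if excess == 0 or not np.any(free):
                break
            alloc[free] += largest_remainder_split(excess, weights[free])
        for g in range(G):
            E[0, g] = alloc[g]
            if N > 1:
                E[1:, g] = largest_remainder_split(
                    int(totals[g]) - int(alloc[g]), rng.dirichlet(np.ones(N - 1))
                )

    names = [f"S{i + 1}" for i in range(N)]
    samples = [f"G{i + 1}" for i in range(G)]
    return ExposureMatrix(E=E.astype(np.float64), names=names, samples=samples)


def simulate_catalogs(
    P_true: SignatureMatrix,
    E_true: ExposureMatrix,
    noise_model: str = "poisson_resample",
    white_noise_fraction: float = 0.02,
    rng: np.random.Generator | int | None = None,
) -> CatalogMatrix:
    """Type each signature's mutations multinomially and apply noise.

    For every genome g and signature n, the e_g^n mutations are assigned
    to the K mutation types by a multinomial draw from signature n's
    profile. Noise models: ``poisson_resample`` redraws every cell from a
    Poisson with the pre-noise cell as its mean; ``additive_white`` adds
    uniformly-typed extra mutations amounting to round(fraction × genome
    total); ``none`` leaves the multinomial counts untouched, so column
    sums equal the exposure column sums exactly.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if P_true.N != E_true.N:
        raise ValueError("P_true and E_true disagree on the number of signatures")
    K, N, G = P_true.K, P_true.N, E_true.G
    counts = np.zeros((K, G), dtype=np.int64)
    for g in range(G):
        for n in range(N):
            e = int(round(E_true.E[n, g]))
            if e > 0:
                counts[:, g] += rng.multinomial(e, P_true.P[:, n])

    if noise_model == "poisson_resample":
        counts = rng.poisson(counts)
    elif noise_model == "additive_white":
        for g in range(G):
            extra = int(round(white_noise_fraction * counts[:, g].sum()))
            if extra > 0:
                counts[:, g] += rng.multinomial(extra, np.full(K, 1.0 / K))
    elif noise_model != "none":
        raise ValueError(f"unknown noise model {noise_model!r}")

    alphabet = P_true.alphabet
    if alphabet is None or alphabet.K != K:
        raise ValueError("P_true must carry an alphabet matching its row count")
    return CatalogMatrix(alphabet=alphabet, samples=list(E_true.samples), counts=counts)


def simulate_truth(
    spec: SimulationSpec, rng: np.random.Generator | int | None = None
) -> SimulationTruth:
    """Generate signatures, exposures, and a noisy catalog for one cohort."""
    if rng is None:
        rng = spec.seed
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    P = np.column_stack(
        [random_signature(spec.alphabet, spec.concentration, rng) for _ in range(spec.N)]
    )
    for (i, j), rng_target in spec.similarity_constraints:
        P[:, j] = signature_pair_with_similarity(P[:, i], rng_target, rng, spec.concentration)
    P_true = SignatureMatrix(
        P=P, names=[f"S{i + 1}" for i in range(spec.N)], alphabet=spec.alphabet
    )
    E_true = simulate_exposures(spec, rng)
    M = simulate_catalogs(P_true, E_true, spec.noise_model, spec.white_noise_fraction, rng)
    return SimulationTruth(P_true=P_true, E_true=E_true, M=M, seed=spec.seed)
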