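"""Choosing the number of signatures N.

The decipher pipeline is run for a range of candidate ranks; for each N
the average silhouette width (reproducibility) and Frobenius
reconstruction error are recorded. N is chosen where the signatures are
highly reproducible and adding another signature no longer buys a
substantial drop in reconstruction error. The automated rule codifies
that visual judgement; the full curves are always kept so a human can
override the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .catalog import CatalogMatrix
from .decipher import DecipherConfig, DecipherResult, decipher_signatures, reduce_dimensions

__all__ = ["ModelSelectionResult", "sweep_N", "select_N"]

DEFAULT_SILHOUETTE_MIN = 0.85
DEFAULT_ERROR_FLATTEN_RATIO = 0.05


@dataclass
class ModelSelectionResult:
    per_N: list[tuple[int, float, float, DecipherResult]]  # (N, silhouette, error, result)
    selected_N: int | None
    rule: str

    @property
    def N_values(self) -> list[int]:
        return [n for n, *_ in self.per_N]


def sweep_N(
    M: CatalogMatrix,
    cfg: DecipherConfig,
    N_range: tuple[int, int] | None = None,
    silhouette_min: float = DEFAULT_SILHOUETTE_MIN,
    error_flatten_ratio: float = DEFAULT_ERROR_FLATTEN_RATIO,
) -> ModelSelectionResult:
    """Run the decipher pipeline over a range of candidate ranks.

    ``N_range`` is an inclusive (lo, hi) interval, by default
    [1, min(K̇, G) − 1]. Each N runs with an independent seed derived from
    ``cfg.seed`` by a fixed offset, so sweeps are reproducible and
    parallelizable. Returns curves of silhouette and reconstruction error
    plus the rank picked by :func:`select_N`.
    """
    reduced = reduce_dimensions(M, cfg.removal_threshold)
    n_max_feasible = min(reduced.M_dot.shape) - 1
    if N_range is None:
        N_range = (1, n_max_feasible)
    lo, hi = N_range
    if lo < 1 or hi > n_max_feasible or lo > hi:
        raise ValueError(f"N range [{lo}, {hi}] not within feasible [1, {n_max_feasible}]")

    base_seed = cfg.seed if cfg.seed is not None else 0
    per_N = []
    for N in range(lo, hi + 1):
        run_cfg = replace(cfg, N=N, seed=(base_seed + 7919 * N) % (2**31))
        res = decipher_signatures(M, run_cfg)
        per_N.append((N, res.avg_silhouette, res.reconstruction_error, res))

    result = ModelSelectionResult(per_N=per_N, selected_N=None, rule="")
    result.selected_N = select_N(result, silhouette_min, error_flatten_ratio)
    result.rule = (
        f"largest N with avg silhouette ≥ {silhouette_min} whose step from "
        f"N−1 reduced the reconstruction error by ≥ {error_flatten_ratio:.0%}"
    )
    return result


def select_N(
    result: ModelSelectionResult,
    silhouette_min: float = DEFAULT_SILHOUETTE_MIN,
    error_flatten_ratio: float = DEFAULT_ERROR_FLATTEN_RATIO,
) -> int | None:
    """Pick N from the sweep curves, or None if nothing qualifies.

    A rank N qualifies when its average silhouette width is at least
    ``silhouette_min``. The selected rank is the largest qualifying N
    whose own increment was worthwhile: either N−1 was not swept, or
    going from N−1 to N reduced the reconstruction error by at least
    ``error_flatten_ratio`` (relative). This mirrors reading the two
    curves by eye — climb while solutions stay reproducible and each
    added signature still buys a substantial error reduction, and stop
    where the error curve flattens or reproducibility collapses.
    """
    if not result.per_N:
        raise ValueError("empty sweep")
    by_N = {n: (sil, err) for n, sil, err, _ in result.per_N}
    qualifying = [n for n, (sil, _) in by_N.items() if sil >= silhouette_min]
    for n in sorted(qualifying, reverse=True):
        prev = by_N.get(n - 1)
        if prev is None:
            return n
        prev_err = prev[1]
        if prev_err > 0 and (prev_err - by_N[n][1]) / prev_err >= error_flatten_ratio:
            return n
    return None
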