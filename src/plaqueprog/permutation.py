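"""Permutation-based type-I-error validation of the spatial models.

Randomly permuting the WTI response over nodes destroys any association
with the baseline stress field while keeping the marginal distributions;
refitting the spatial model to each permuted response should therefore
produce p-values that follow Uniform(0, 1).  Closeness to uniformity
(one-sample Kolmogorov–Smirnov test) is the evidence that the model's
t-test controls the type I error at the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from plaqueprog.vessel_geometry import MatchedPairDataset, extract_regression_arrays
from plaqueprog.spatial_lme import fit_single, fit_pooled

ALPHA = 0.05
_MAX_FAILURE_FRACTION = 0.05


class PermutationError(RuntimeError):
    """Too many permutation refits failed for the report to be trusted."""


@dataclass
class PermutationReport:
    """Permutation p-values and their uniformity diagnostics."""

    n_permutations: int
    p_values: list[float]
    ks_statistic: float
    ks_p_value: float
    empirical_type1_at_005: float
    seed: int
    scope: str
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "p_values": list(self.p_values),
            "ks_statistic": self.ks_statistic,
            "ks_p_value": self.ks_p_value,
            "empirical_type1_at_0.05": self.empirical_type1_at_005,
            "seed": self.seed,
            "scope": self.scope,
            "n_failed": self.n_failed,
        }


def uniformity_check(p_values) -> tuple[float, float]:
    """One-sample KS statistic and p-value against Uniform(0, 1)."""
    p = np.asarray(p_values, float)
    if p.size < 5:
        raise ValueError("need at least 5 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


def permute_and_refit(
    data,
    predictor: str = "PWS",
    n_permutations: int = 200,
    seed: int = 0,
    scope: str | None = None,
    identity: bool = False,
) -> PermutationReport:
    """Permute WTI, refit, and report the p-value distribution.

    ``data`` is a single :class:`MatchedPairDataset` (or a raw
    ``(coords, x, y)`` triple), fitted with the single-patient model, or
    a list of per-patient datasets fitted with the pooled model.  Scope
    ``"global"`` shuffles all responses jointly; ``"within_patient"``
    (default for pooled input) shuffles inside each patient block so the
    patient structure is preserved.  ``identity=True`` is a debug mode
    that skips the shuffle and must reproduce the unpermuted fit.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pooled = isinstance(data, (list, tuple)) and not _is_triple(data)
    if scope is None:
        scope = "within_patient" if pooled else "global"
    if scope not in ("global", "within_patient"):
        raise ValueError(f"unknown scope {scope!r}")

    if pooled:
        parts = [_as_triple(d, predictor) for d in data]
    else:
        parts = [_as_triple(data, predictor)]

    rng = np.random.default_rng(seed)
    p_values: list[float] = []
    n_failed = 0
    for _ in range(n_permutations):
        if identity:
            permuted = [y for (_, _, y) in parts]
        elif scope == "within_patient":
            permuted = [rng.permutation(y) for (_, _, y) in parts]
        else:
            all_y = np.concatenate([y for (_, _, y) in parts])
            shuffled = rng.permutation(all_y)
            permuted, pos = [], 0
            for (_, _, y) in parts:
                permuted.append(shuffled[pos : pos + len(y)])
                pos += len(y)
        try:
            if pooled and len(parts) > 1:
                fit = fit_pooled(
                    [(c, x, yp) for (c, x, _), yp in zip(parts, permuted)]
                )
            else:
                c, x, _ = parts[0]
                fit = fit_single(c, x, permuted[0])
            p_values.append(fit.p_value)
        except Exception:
            n_failed += 1
    if n_failed > _MAX_FAILURE_FRACTION * n_permutations:
        raise PermutationError(
            f"{n_failed}/{n_permutations} permutation refits failed"
        )
    ks_stat, ks_p = (float("nan"), float("nan"))
    if len(p_values) >= 5:
        ks_stat, ks_p = uniformity_check(p_values)
    return PermutationReport(
        n_permutations=n_permutations,
        p_values=p_values,
        ks_statistic=ks_stat,
        ks_p_value=ks_p,
        empirical_type1_at_005=float(np.mean(np.asarray(p_values) < ALPHA)),
        seed=seed,
        scope=scope,
        n_failed=n_failed,
    )


def _is_triple(obj) -> bool:
    return (
        isinstance(obj, (list, tuple))
        and len(obj) == 3
        and all(isinstance(a, np.ndarray) for a in map(np.asarray, obj))
        and np.asarray(obj[0]).ndim == 2
    )


def _as_triple(d, predictor):
    if isinstance(d, MatchedPairDataset):
        arrays = extract_regression_arrays(d, predictor)
        return arrays.coords, arrays.x, arrays.y
    coords, x, y = d
    return (
        np.atleast_2d(np.asarray(coords, float)),
        np.asarray(x, float),
        np.asarray(y, float),
    )
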