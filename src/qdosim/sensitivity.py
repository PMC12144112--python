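"""Variance-based sensitivity analysis and dose-uncertainty summaries.

Sobol first/total-order indices use the Saltelli scheme (base sample n,
n*(d+2) model evaluations, Saltelli-2010 first-order and Jansen total-order
estimators) on low-discrepancy Sobol' points. FAST importance uses the
extended-FAST search curve with one driver frequency per parameter.
Posterior summaries reduce a sample of dose values to mean, sd and a
central credible interval.

The parameter space mirrors the treatment-planning factors typically
screened: beam energy, beam direction, patient anatomy (density scale) and
treatment time. Treatment time is accepted for interface fidelity even
though steady-state transport ignores it; its indices act as the built-in
dummy-parameter check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import qmc

__all__ = [
    "ParameterSpace",
    "SensitivityReport",
    "UncertaintyReport",
    "sobol_indices",
    "fast_importance",
    "posterior_summary",
]


@dataclass
class ParameterSpace:
    """Named parameters with (lower, upper) ranges, sampled uniformly."""

    parameters: dict  # name -> (low, high)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.parameters.items():
            if not lo < hi:
                raise ValueError(f"parameter {name!r}: require lower < upper, got ({lo}, {hi})")

    @classmethod
    def treatment_planning_default(cls) -> "ParameterSpace":
        return cls(
            parameters={
                "beam_energy": (4.0, 10.0),        # MV
                "beam_direction": (0.0, 0.8),      # tilt from normal incidence, rad
                "patient_anatomy": (0.8, 1.2),     # density scale
                "treatment_time": (30.0, 300.0),   # s; inert in steady state
            }
        )

    @property
    def names(self) -> list[str]:
        return list(self.parameters)

    @property
    def d(self) -> int:
        return len(self.parameters)

    def scale(self, unit_samples: np.ndarray) -> np.ndarray:
        lo = np.array([v[0] for v in self.parameters.values()])
        hi = np.array([v[1] for v in self.parameters.values()])
        return lo + unit_samples * (hi - lo)


@dataclass
class SensitivityReport:
    first_order: dict
    total_order: dict
    fast_importance: dict
    interaction_matrix: Optional[np.ndarray]
    n_samples: int
    seed: int
    zero_variance: bool = False

    def to_json_dict(self) -> dict:
        return {
            "first_order": {k: float(v) for k, v in self.first_order.items()},
            "total_order": {k: float(v) for k, v in self.total_order.items()},
            "fast_importance": {k: float(v) for k, v in self.fast_importance.items()},
            "interaction_matrix": (
                self.interaction_matrix.tolist() if self.interaction_matrix is not None else None
            ),
            "n_samples": self.n_samples,
            "seed": self.seed,
            "zero_variance": self.zero_variance,
        }


@dataclass
class UncertaintyReport:
    mean: float
    sd: float
    credible_interval_95: tuple[float, float]
    n_samples: int


# ---------------------------------------------------------------------------
# Sobol / Saltelli
# ---------------------------------------------------------------------------

def sobol_indices(
    model_fn: Callable[[np.ndarray], float],
    space: ParameterSpace,
    n_base_samples: int = 1024,
    seed: int = 0,
    compute_interactions: bool = False,
) -> SensitivityReport:
    """Saltelli-scheme Sobol first- and total-order indices.

    ``model_fn`` maps one parameter vector (ordered per ``space.names``) to
    a scalar summary (mean target dose by default elsewhere). Cost is
    ``n*(d+2)`` evaluations, plus ``n*d*(d-1)/2`` when pairwise closed
    second-order interactions are requested. Deterministic for a fixed seed.
    """
    if n_base_samples < 64:
        raise ValueError("n_base_samples must be >= 64")
    d = space.d
    sampler = qmc.Sobol(2 * d, seed=seed)
    m = int(np.ceil(np.log2(n_base_samples)))
    base = sampler.random_base2(m)[:n_base_samples]
    A_u, B_u = base[:, :d], base[:, d:]
    A = space.scale(A_u)
    B = space.scale(B_u)

    def evaluate(mat: np.ndarray) -> np.ndarray:
        return np.array([float(model_fn(row)) for row in mat])

    fA = evaluate(A)
    fB = evaluate(B)
    fABi = np.empty((d, len(A)))
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi[i] = evaluate(ABi)

    all_f = np.concatenate([fA, fB, fABi.ravel()])
    var = float(np.var(np.concatenate([fA, fB]), ddof=1))
    zero_variance = var <= 1e-30 * max(1.0, float(np.mean(all_f) ** 2))

    first, total = {}, {}
    for i, name in enumerate(space.names):
        if zero_variance:
            first[name] = 0.0
            total[name] = 0.0
            continue
        # Saltelli 2010 first-order, Jansen total-order
        first[name] = float(np.mean(fB * (fABi[i] - fA)) / var)
        total[name] = float(0.5 * np.mean((fA - fABi[i]) ** 2) / var)

    interaction = None
    if compute_interactions and not zero_variance:
        # closed second-order indices S_ij^closed - S_i - S_j
        interaction = np.zeros((d, d))
        for i in range(d):
            for j in range(i + 1, d):
                ABij = A.copy()
                ABij[:, i] = B[:, i]
                ABij[:, j] = B[:, j]
                fABij = evaluate(ABij)
                closed = float(np.mean(fB * (fABij - fA)) / var)
                sij = closed - first[space.names[i]] - first[space.names[j]]
                interaction[i, j] = interaction[j, i] = sij

    fast = fast_importance(model_fn, space, n_samples=max(65, n_base_samples // 4), seed=seed)
    return SensitivityReport(
        first_order=first,
        total_order=total,
        fast_importance=fast,
        interaction_matrix=interaction,
        n_samples=n_base_samples,
        seed=seed,
        zero_variance=zero_variance,
    )


# ---------------------------------------------------------------------------
# FAST
# ---------------------------------------------------------------------------

def fast_importance(
    model_fn: Callable[[np.ndarray], float],
    space: ParameterSpace,
    n_samples: int = 257,
    seed: int = 0,
    n_harmonics: int = 4,
    driver_frequency: int = 8,
) -> dict:
    """Extended-FAST first-order importance per parameter.

    Each parameter in turn takes the driver frequency on the search curve
    ``x(s) = 1/2 + arcsin(sin(w s + phi)) / pi``; the others share unit
    frequency. The importance is the spectral power at the driver frequency
    and its first ``n_harmonics`` harmonics over the total variance.
    Requires ``n_samples > 2 * n_harmonics * driver_frequency``.
    """
    min_n = 2 * n_harmonics * driver_frequency + 1
    if n_samples < min_n:
        raise ValueError(
            f"n_samples={n_samples} too few for frequency set; minimum {min_n}"
        )
    d = space.d
    rng = np.random.default_rng(seed)
    s = np.linspace(-np.pi, np.pi, n_samples, endpoint=False)
    importances = {}
    for i, name in enumerate(space.names):
        freqs = np.ones(d)
        freqs[i] = driver_frequency
        phases = rng.random(d) * 2 * np.pi
        unit = 0.5 + np.arcsin(np.sin(freqs[None, :] * s[:, None] + phases[None, :])) / np.pi
        X = space.scale(unit)
        y = np.array([float(model_fn(row)) for row in X])
        y = y - y.mean()
        coeffs = np.fft.rfft(y) / n_samples
        power = 2 * np.abs(coeffs) ** 2
        total_var = power[1:].sum()
        if total_var <= 0:
            importances[name] = 0.0
            continue
        idx = [driver_frequency * (p + 1) for p in range(n_harmonics)]
        idx = [k for k in idx if k < len(power)]
        importances[name] = float(power[idx].sum() / total_var)
    return importances


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def posterior_summary(samples: Sequence[float], interval_mass: float = 0.95) -> UncertaintyReport:
    """Mean, sd (n-1 denominator) and central percentile credible interval."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples for a posterior summary")
    if not (0.0 < interval_mass < 1.0):
        raise ValueError("interval_mass must lie in (0, 1)")
    alpha = (1.0 - interval_mass) / 2.0
    lo, hi = np.percentile(x, [100 * alpha, 100 * (1 - alpha)])
    return UncertaintyReport(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        credible_interval_95=(float(lo), float(hi)),
        n_samples=int(x.size),
    )
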