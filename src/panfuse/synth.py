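"""Synthetic bulk-expression cohorts with planted subtypes and linked survival.

The generator emulates the kind of normalised bulk RNA-seq cohort the pipeline
consumes: ``k`` latent molecular subtypes expressed as Gaussian mean shifts on
a subset of informative genes over a shared standard-Gaussian noise floor, and
right-censored survival times driven by a proportional-hazards linear risk
score over chosen prognostic genes. Subtype shift patterns are orthogonal sign
patterns so pairwise subtype separation scales directly with ``effect_size``.

Everything is deterministic under the seed, and every simulation emits a
manifest dict from which the fixture can be reconstructed exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .io import ExpressionMatrix, SurvivalTable


@dataclass
class SimulationConfig:
    """Parameters of the planted-subtype expression + survival simulator.

    Parameters
    ----------
    n_samples, n_genes : int
        Cohort dimensions.
    k_subtypes : int
        Number of planted subtypes (>= 2).
    n_informative : int
        How many genes carry subtype-specific mean shifts; the rest are pure
        noise. Must not exceed ``n_genes``.
    effect_size : float
        Mean shift magnitude in units of the noise standard deviation (1.0).
    mixing : sequence of float, optional
        Subtype proportions summing to 1; default equal.
    censor_rate : float
        Target fraction of right-censored samples in ``[0, 1)``.
    baseline_rate : float
        Baseline exponential event rate (events per time unit at risk 0).
    log_normal : bool
        If True, exponentiate values to emulate heavier-tailed raw intensities.
    """

    n_samples: int = 300
    n_genes: int = 200
    k_subtypes: int = 3
    n_informative: int = 40
    effect_size: float = 3.0
    mixing: Optional[Sequence[float]] = None
    censor_rate: float = 0.2
    baseline_rate: float = 0.1
    log_normal: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.k_subtypes < 2:
            raise ValueError("k_subtypes must be >= 2")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.mixing is None:
            self.mixing = [1.0 / self.k_subtypes] * self.k_subtypes
        self.mixing = [float(p) for p in self.mixing]
        if len(self.mixing) != self.k_subtypes:
            raise ValueError("mixing length must equal k_subtypes")
        if abs(sum(self.mixing) - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")

    def manifest(self) -> dict:
        return {"generator": "panfuse.synth", **asdict(self)}


def _shift_patterns(k: int, n_informative: int, rng: np.random.Generator) -> np.ndarray:
    """k orthogonal +/-1 sign patterns over the informative genes.

    Rows of a random-sign Hadamard-like construction: start from k mutually
    orthogonal sign vectors of length 2**ceil(log2 k) tiled across genes.
    Orthogonality makes inter-subtype centroid distance identical for every
    pair, so separation is controlled by effect_size alone.
    """
    m = 1
    while m < k:
        m *= 2
    # Sylvester Hadamard matrix of order m
    H = np.array([[1.0]])
    while H.shape[0] < m:
        H = np.block([[H, H], [H, -H]])
    reps = int(np.ceil(n_informative / m))
    patterns = np.tile(H[:k], (1, reps))[:, :n_informative]
    flip = rng.choice([-1.0, 1.0], size=n_informative)
    return patterns * flip


def simulate_expression(config: SimulationConfig):
    """Draw an expression matrix with planted subtype structure.

    Returns
    -------
    matrix : ExpressionMatrix
        genes x samples, gene ids ``G0001..`` and sample ids ``S0001..``.
    true_labels : ndarray of int
        Planted subtype per sample, for truth-based scoring.
    manifest : dict
        The echoed generator parameters.
    """
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_samples, config.n_genes, config.k_subtypes

    labels = rng.choice(k, size=n, p=config.mixing)
    values = rng.standard_normal((p, n))

    if config.n_informative > 0 and config.effect_size != 0:
        patterns = _shift_patterns(k, config.n_informative, rng)
        # centre patterns per gene so the shift is relative, scale to effect_size/2
        # per subtype => inter-centroid distance = effect_size per informative gene
        shifts = 0.5 * config.effect_size * patterns  # (k, n_informative)
        values[: config.n_informative, :] += shifts[labels].T

    if config.log_normal:
        values = np.exp(values)

    gene_ids = [f"G{i + 1:04d}" for i in range(p)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    return matrix, labels, config.manifest()


def simulate_survival(
    X: ExpressionMatrix,
    prognostic_genes: Sequence[str],
    surv_coefs: Sequence[float],
    baseline_rate: float = 0.1,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> SurvivalTable:
    """Exponential proportional-hazards survival linked to expression.

    Event times are exponential with per-sample rate
    ``baseline_rate * exp(sum_j coef_j * expr_j)``. Censoring is independent
    uniform on ``[0, c]`` with the cap ``c`` calibrated by root finding so the
    expected censored fraction equals ``censor_rate``.
    """
    if censor_rate >= 1 or censor_rate < 0:
        raise ValueError("censor_rate must lie in [0, 1)")
    if len(prognostic_genes) != len(surv_coefs):
        raise ValueError("prognostic_genes and surv_coefs lengths differ")
    rng = np.random.default_rng(seed)

    if prognostic_genes:
        sub = X.subset_genes(list(prognostic_genes))
        lp = np.asarray(surv_coefs, dtype=float) @ sub.values  # (n_samples,)
    else:
        lp = np.zeros(X.n_samples)

    rates = baseline_rate * np.exp(lp)
    event_times = rng.exponential(1.0 / rates)

    if censor_rate == 0:
        return SurvivalTable(list(X.sample_ids), event_times, np.ones(X.n_samples, int))

    # P(censored | cap c) for C ~ U(0,c): mean_i [ E min(T_i,...) ] — with T_i
    # known, P(C < t) = min(t/c, 1); calibrate c so the mean equals the target.
    t = event_times

    def expected_censored(c):
        return float(np.mean(np.minimum(t / c, 1.0))) - censor_rate

    lo, hi = t.min() * 1e-6, t.max() * 1e6
    cap = brentq(expected_censored, lo, hi)
    censor_times = rng.uniform(0.0, cap, size=t.size)
    observed = np.minimum(t, censor_times)
    event = (t <= censor_times).astype(int)
    # guard against numerically zero follow-up
    observed = np.maximum(observed, 1e-12)
    return SurvivalTable(list(X.sample_ids), observed, event)
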