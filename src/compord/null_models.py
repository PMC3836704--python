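"""Random-sequence null models for FT misidentification.

Under an i.i.d. letter model, the number of occurrences of a fixed triplet
in a protein of length L is approximated as Binomial(W, p) with W = L - 2
overlapping windows treated as independent trials (p = 1/8000 in the
uniform 20-letter model).  The expected number of distinct triplets reaching
the FT threshold n is then

    E(L, n) = sum over triplets t of P(X_t >= n),

which collapses to 8000 * P(X >= n) in the uniform model; E/8000 is the
per-triplet P-value for FT misidentification.  With n = 5 this P-value
stays below 1e-3 for proteins shorter than 8000 residues, which is why
n = 5 is the standard operating point.  Monte-Carlo scanning of simulated
random proteins validates the analytic curve (overlap correlations between
windows are negligible at these p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .ft_core import CANONICAL_AA, FTParams, ProteinRecord, detect_fts

__all__ = [
    "NullModelSpec",
    "ExpectationCurve",
    "expected_ft_count",
    "generate_random_protein",
    "simulate_ft_expectation",
    "estimate_aa_probs",
]

_N_AA = len(CANONICAL_AA)


@dataclass(frozen=True)
class NullModelSpec:
    """Parameters of the random-sequence model.

    model : 'uniform' (all letters 1/20) or 'unigram' (empirical letter
        frequencies supplied via ``aa_probs``).
    aa_probs : probabilities over the 20 canonical letters, in the order of
        ``CANONICAL_AA``; defaults to uniform.
    n : FT occurrence threshold.
    seed : RNG seed for simulation.
    """

    model: str = "uniform"
    aa_probs: tuple[float, ...] = tuple([1.0 / _N_AA] * _N_AA)
    n: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("uniform", "unigram"):
            raise ValueError("model must be 'uniform' or 'unigram'")
        probs = np.asarray(self.aa_probs, dtype=float)
        if probs.shape != (_N_AA,):
            raise ValueError(f"aa_probs must have {_N_AA} entries")
        if not np.isclose(probs.sum(), 1.0, atol=1e-8):
            raise ValueError("aa_probs must sum to 1")
        if np.any(probs < 0):
            raise ValueError("aa_probs must be nonnegative")

    @property
    def p_triplet_uniform(self) -> float:
        return 1.0 / _N_AA**3

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ExpectationCurve:
    """E(L) on a length grid, with the per-triplet misidentification P-value."""

    lengths: np.ndarray
    expected: np.ndarray
    pvalues: np.ndarray
    empirical: np.ndarray | None = None
    se: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "L": self.lengths,
            "E_analytic": self.expected,
            "pvalue": self.pvalues,
        }
        if self.empirical is not None:
            data["E_empirical"] = self.empirical
            data["SE"] = self.se
        return pd.DataFrame(data)


def expected_ft_count(
    L: int, n: int = 5, spec: NullModelSpec = NullModelSpec()
) -> float:
    """Expected number of distinct triplets occurring >= n times at random.

    Uses the survival function of the binomial over W = L - 2 windows;
    returns 0 for L < 3.  In the unigram model the per-triplet probability
    is the product of its three letter probabilities.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    W = L - 2
    if W < 1:
        return 0.0
    if spec.model == "uniform":
        return float(_N_AA**3 * binom.sf(n - 1, W, spec.p_triplet_uniform))
    probs = np.asarray(spec.aa_probs, dtype=float)
    # p_t for all 8000 triplets as an outer product, flattened.
    p_t = np.einsum("i,j,k->ijk", probs, probs, probs).ravel()
    return float(binom.sf(n - 1, W, p_t).sum())


def misidentification_pvalue(
    L: int, n: int = 5, spec: NullModelSpec = NullModelSpec()
) -> float:
    """Per-triplet FT misidentification P-value, E / 8000."""
    return expected_ft_count(L, n, spec) / _N_AA**3


def expectation_curve(
    lengths: Sequence[int], n: int = 5, spec: NullModelSpec = NullModelSpec()
) -> ExpectationCurve:
    """Analytic E(L) and P-value over a length grid."""
    lengths = np.asarray(lengths, dtype=int)
    expected = np.array([expected_ft_count(int(L), n, spec) for L in lengths])
    return ExpectationCurve(
        lengths=lengths, expected=expected, pvalues=expected / _N_AA**3
    )


def generate_random_protein(
    L: int,
    spec: NullModelSpec = NullModelSpec(),
    rng: np.random.Generator | None = None,
    protein_id: str = "random",
) -> ProteinRecord:
    """One i.i.d. random protein of length L drawn from ``spec.aa_probs``."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if rng is None:
        rng = spec.rng()
    letters = rng.choice(list(CANONICAL_AA), size=L, p=np.asarray(spec.aa_probs))
    return ProteinRecord(id=protein_id, seq="".join(letters))


def simulate_ft_expectation(
    spec: NullModelSpec,
    lengths: Sequence[int],
    reps: int = 200,
    params: FTParams | None = None,
) -> ExpectationCurve:
    """Monte-Carlo FT counts per length, with standard errors.

    Scans ``reps`` simulated proteins at each grid length with the given FT
    definition (regular or restrictive) and reports the mean count and its
    standard error next to the analytic curve.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if params is None:
        params = FTParams(n=spec.n)
    rng = spec.rng()
    lengths = np.asarray(lengths, dtype=int)
    means = np.empty(len(lengths))
    ses = np.empty(len(lengths))
    for j, L in enumerate(lengths):
        counts = np.empty(reps)
        for r in range(reps):
            protein = generate_random_protein(int(L), spec, rng, f"sim_{L}_{r}")
            counts[r] = detect_fts(protein, params).dft_count
        means[j] = counts.mean()
        ses[j] = counts.std(ddof=1) / np.sqrt(reps) if reps > 1 else np.nan
    analytic = expectation_curve(lengths, spec.n, spec)
    analytic.empirical = means
    analytic.se = ses
    return analytic


def estimate_aa_probs(proteins: Sequence[ProteinRecord]) -> tuple[float, ...]:
    """Empirical canonical-letter frequencies of a reference protein set.

    Non-canonical letters are ignored.  Use the result as ``aa_probs`` of a
    unigram NullModelSpec.
    """
    counts = np.zeros(_N_AA)
    index = {aa: i for i, aa in enumerate(CANONICAL_AA)}
    for rec in proteins:
        for ch in rec.seq:
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no canonical letters in reference set")
    return tuple(counts / total)
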