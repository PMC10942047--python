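"""Bayesian posterior of the reader-positive probability under a two-stage protocol.

A finding on an image is assumed to be recorded by any single physician with
an image-specific latent probability ``x`` (a Bernoulli "reader" model).  The
screening protocol produces two stages of evidence per image:

* first stage: two readers, merged by union — the record is P if at least one
  reader flags the finding, else N;
* second stage: two further readers whose individual calls are kept,
  giving PP, PN (unordered) or NN.

Conditional on ``x`` the stage likelihoods are

* first stage:  P -> ``x^2 + 2x(1-x)``,  N -> ``(1-x)^2``
* second stage: PP -> ``x^2``, PN -> ``2x(1-x)``, NN -> ``(1-x)^2``

and the six diagnosis groups D = (first, second) have likelihood equal to the
product.  With a uniform prior on ``x`` the posterior is the normalized
likelihood; all normalizers and posterior means are exact rationals obtained
from the Beta integral identity  ∫₀¹ x^a (1-x)^b dx = a! b! / (a+b+1)!.

The logit-space density (``u = logit x``) is the probability-space density
times the Jacobian ``σ(u)(1-σ(u))``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Tuple, Union

import numpy as np

__all__ = [
    "DiagnosisGroup",
    "LikelihoodPolynomial",
    "PosteriorSummary",
    "stage_likelihood",
    "group_likelihood",
    "group_likelihood_polynomial",
    "posterior_density",
    "posterior_logit_density",
    "expected_posterior",
    "posterior_table",
    "sigmoid",
    "logit",
]


class DiagnosisGroup(enum.Enum):
    """One of the six two-stage annotation outcomes, per finding."""

    P_PP = ("P", "PP")
    P_PN = ("P", "PN")
    P_NN = ("P", "NN")
    N_PP = ("N", "PP")
    N_PN = ("N", "PN")
    N_NN = ("N", "NN")

    @property
    def first_stage(self) -> str:
        return self.value[0]

    @property
    def second_stage(self) -> str:
        return self.value[1]

    @classmethod
    def from_stages(cls, first: str, second: str) -> "DiagnosisGroup":
        """Build a group from stage outcomes; second stage is unordered (NP ≡ PN)."""
        first = first.upper()
        second = "".join(sorted(second.upper(), reverse=True))  # NP -> PN
        for g in cls:
            if g.first_stage == first and g.second_stage == second:
                return g
        raise ValueError(f"invalid stage outcomes: first={first!r}, second={second!r}")

    @classmethod
    def from_calls(cls, r1_s1: int, r2_s1: int, r1_s2: int, r2_s2: int) -> "DiagnosisGroup":
        """Group implied by four individual binary reader calls (union rule in stage 1)."""
        first = "P" if (r1_s1 or r2_s1) else "N"
        second = "PN"[1 - r1_s2] + "PN"[1 - r2_s2]
        return cls.from_stages(first, second)

    def __str__(self) -> str:  # e.g. "(P,PN)"
        return f"({self.first_stage},{self.second_stage})"


# canonical paper ordering of the six groups
GROUP_ORDER: Tuple[DiagnosisGroup, ...] = (
    DiagnosisGroup.P_PP,
    DiagnosisGroup.P_PN,
    DiagnosisGroup.P_NN,
    DiagnosisGroup.N_PP,
    DiagnosisGroup.N_PN,
    DiagnosisGroup.N_NN,
)

# Stage likelihoods as lists of (coefficient, a, b) terms meaning c * x^a (1-x)^b.
_FIRST_TERMS = {
    "P": [(Fraction(1), 2, 0), (Fraction(2), 1, 1)],  # x^2 + 2x(1-x) = 1-(1-x)^2
    "N": [(Fraction(1), 0, 2)],
}
_SECOND_TERMS = {
    "PP": [(Fraction(1), 2, 0)],
    "PN": [(Fraction(2), 1, 1)],
    "NN": [(Fraction(1), 0, 2)],
}

Terms = List[Tuple[Fraction, int, int]]


def _product_terms(a: Terms, b: Terms) -> Terms:
    return [(ca * cb, pa + pb, qa + qb) for ca, pa, qa in a for cb, pb, qb in b]


def _beta_integral(a: int, b: int) -> Fraction:
    """Exact ∫₀¹ x^a (1-x)^b dx for non-negative integers a, b."""
    return Fraction(math.factorial(a) * math.factorial(b), math.factorial(a + b + 1))


def _integral(terms: Terms, moment: int = 0) -> Fraction:
    return sum((c * _beta_integral(a + moment, b) for c, a, b in terms), Fraction(0))


def _group_terms(group: DiagnosisGroup) -> Terms:
    return _product_terms(_FIRST_TERMS[group.first_stage], _SECOND_TERMS[group.second_stage])


@dataclass(frozen=True)
class LikelihoodPolynomial:
    """Exact polynomial likelihood of a group, coefficients in increasing power of x."""

    group: DiagnosisGroup
    coefficients: Tuple[Fraction, ...]

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for c in reversed(self.coefficients):
            out = out * x + float(c)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class PosteriorSummary:
    """Normalizer (reciprocal of the likelihood mass) and posterior mean, exact."""

    group: DiagnosisGroup
    normalizer: Fraction
    expectation: Fraction


def stage_likelihood(stage: str, outcome: str, x) -> Union[float, np.ndarray]:
    """Probability of a stage outcome given latent reader probability ``x``.

    ``stage`` is "first" (union of two readers, outcomes P/N) or "second"
    (two independent recorded readers, outcomes PP/PN/NN).
    """
    table = {"first": _FIRST_TERMS, "second": _SECOND_TERMS}.get(stage)
    if table is None:
        raise ValueError(f"unknown stage {stage!r}; expected 'first' or 'second'")
    outcome = outcome.upper()
    if outcome not in table:
        raise ValueError(f"outcome {outcome!r} invalid for stage {stage!r}")
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    out = np.zeros_like(x)
    for c, a, b in table[outcome]:
        out = out + float(c) * x**a * (1.0 - x) ** b
    return out if out.ndim else float(out)


def group_likelihood(group: DiagnosisGroup, x) -> Union[float, np.ndarray]:
    """p(D | x): product of the two stage likelihoods."""
    return stage_likelihood("first", group.first_stage, x) * stage_likelihood(
        "second", group.second_stage, x
    )


def group_likelihood_polynomial(group: DiagnosisGroup) -> LikelihoodPolynomial:
    """Exact degree-≤4 polynomial form of p(D | x)."""
    coeffs = [Fraction(0)] * 5
    for c, a, b in _group_terms(group):
        # expand c x^a (1-x)^b
        for k in range(b + 1):
            coeffs[a + k] += c * math.comb(b, k) * (-1) ** k
    while len(coeffs) > 1 and coeffs[-1] == 0:
        coeffs.pop()
    return LikelihoodPolynomial(group, tuple(coeffs))


def _normalizer(group: DiagnosisGroup) -> Fraction:
    return 1 / _integral(_group_terms(group))


def posterior_density(group: DiagnosisGroup, x) -> Union[float, np.ndarray]:
    """Posterior density p(x | D) under a uniform prior; integrates to 1 on [0, 1]."""
    return float(_normalizer(group)) * group_likelihood(group, x)


def sigmoid(u):
    u = np.asarray(u, dtype=float)
    out = np.where(u >= 0, 1.0 / (1.0 + np.exp(-np.clip(u, -700, None))),
                   np.exp(np.clip(u, None, 700)) / (1.0 + np.exp(np.clip(u, None, 700))))
    return out if out.ndim else float(out)


def logit(x):
    x = np.asarray(x, dtype=float)
    out = np.log(x) - np.log1p(-x)
    return out if out.ndim else float(out)


def posterior_logit_density(group: DiagnosisGroup, u) -> Union[float, np.ndarray]:
    """Posterior density of u = logit(x) given D: p(x(u)|D) · σ(u)(1-σ(u))."""
    s = sigmoid(u)
    return posterior_density(group, s) * s * (1.0 - s)


def expected_posterior(group: DiagnosisGroup) -> Fraction:
    """Exact posterior mean E[x | D] under the uniform prior."""
    terms = _group_terms(group)
    return _integral(terms, moment=1) / _integral(terms)


def posterior_table() -> Dict[DiagnosisGroup, PosteriorSummary]:
    """Normalizer and posterior mean for all six groups, exact."""
    return {
        g: PosteriorSummary(g, _normalizer(g), expected_posterior(g)) for g in GROUP_ORDER
    }
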