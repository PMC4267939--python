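"""Independent reference computations used to validate the implementation.

These deliberately avoid the package's own code paths: translation goes
through Biopython, equilibrium spectra through QUADPACK adaptive quadrature
with algebraic endpoint weights, and the non-equilibrium model through a
discrete Wright–Fisher binomial transition matrix.
"""

from __future__ import annotations

from math import comb

import numpy as np
from Bio.Seq import Seq
from scipy import integrate
from scipy.special import gammaln


def translate_bp(codon: str) -> str:
    """Biopython translation (independent of the package's code table)."""
    return str(Seq(codon).translate())


def ng_site_counts(codon: str) -> tuple[float, float]:
    """Nei–Gojobori site counts by direct enumeration of the 9 one-step
    mutants, using Biopython for translation."""
    aa = translate_bp(codon)
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if translate_bp(mut) == aa and translate_bp(mut) != "*":
                syn += 1 / 3
    return syn, 3.0 - syn


def equilibrium_sfs_quadrature(theta01, theta10, gamma, n) -> np.ndarray:
    """Expected equilibrium SFS by adaptive quadrature of the stationary
    density against the binomial kernel (QUADPACK qaws handles the algebraic
    endpoint singularities exactly)."""
    p = np.zeros(n + 1)
    for i in range(n + 1):
        val, _ = integrate.quad(
            lambda x: np.exp(gamma * x),
            0.0,
            1.0,
            weight="alg",
            wvar=(i + theta01 - 1.0, n - i + theta10 - 1.0),
        )
        p[i] = comb(n, i) * val
    return p / p.sum()


def _binom_kernel(n: int, x: np.ndarray) -> np.ndarray:
    i = np.arange(n + 1)
    lnb = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    with np.errstate(divide="ignore"):
        lnk = (
            lnb[:, None]
            + i[:, None] * np.log(np.maximum(x, 1e-300))[None, :]
            + (n - i)[:, None] * np.log(np.maximum(1 - x, 1e-300))[None, :]
        )
    K = np.exp(lnk)
    K[:, 0] = 0.0
    K[0, 0] = 1.0
    K[:, -1] = 0.0
    K[n, -1] = 1.0
    return K


def wf_expansion_sfs(theta01, theta10, gamma, g, tau, n, M: int = 400) -> np.ndarray:
    """Expected SFS under the one-step-expansion model from a Wright–Fisher
    binomial transition matrix with 2N = M haploids and rescaled rates.

    The pre-change stationary distribution is obtained as the exact
    stationary vector of the chain; the chain then runs round(tau*M)
    generations with (g*theta, g*gamma) before binomial sampling to size n.
    """
    from scipy.stats import binom

    x = np.arange(M + 1) / M

    def transition(a, b, gm):
        s = gm / (2 * M)
        mu01 = a / (2 * M)
        mu10 = b / (2 * M)
        xs = x * (1 + s) / (1 + s * x)
        xp = xs * (1 - mu10) + (1 - xs) * mu01
        j = np.arange(M + 1)
        return binom.pmf(j[None, :], M, xp[:, None])

    P0 = transition(theta01, theta10, gamma)
    A = P0.T - np.eye(M + 1)
    A[-1, :] = 1.0
    rhs = np.zeros(M + 1)
    rhs[-1] = 1.0
    pi = np.linalg.solve(A, rhs)
    pi = np.maximum(pi, 0.0)
    pi /= pi.sum()
    P1 = transition(g * theta01, g * theta10, g * gamma)
    for _ in range(int(round(tau * M))):
        pi = pi @ P1
    p = _binom_kernel(n, x) @ pi
    return p / p.sum()


def pairwise_pi_bruteforce(seqs: list[str]) -> float:
    """Mean pairwise difference count over all pairs (all sites)."""
    n = len(seqs)
    tot = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += sum(
                a != b
                for a, b in zip(seqs[i], seqs[j])
                if a in "ACGT" and b in "ACGT"
            )
            pairs += 1
    return tot / pairs


def tajimas_d_reference(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from the published constants, written independently."""
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return float((pi_total - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1)))
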