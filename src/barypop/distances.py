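"""Genetic distances from subjects to reference populations.

The distance from subject i to population j is the per-SNP mean negative log
probability of the subject's genotypes under Hardy-Weinberg equilibrium at
population j's allele frequencies::

    D_ij = -(1/S') sum_l [ g ln(p_jl) + (2-g) ln(q_jl) + g(2-g) ln 2 ]

summed over the S' SNPs with genotypes (missing SNPs contribute nothing to
either the sum or the count). D is measured in nats per SNP. Differences
D_ij - D_ik depend only on allele-frequency *ratios* (the heterozygote ln 2
term cancels), which is why the D5 - D4 score is robust to missing data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import ReferencePanel

_LN2 = float(np.log(2.0))


class NoGenotypesError(ValueError):
    """The subject has zero genotyped panel SNPs."""


@dataclass(frozen=True)
class DistanceVector:
    """Distances to the five reference populations for one subject."""

    d: np.ndarray  # (5,) nats per SNP
    s_prime: int  # genotyped SNP count


def _as_genotype_row(g) -> np.ndarray:
    g = np.asarray(g)
    if g.ndim != 1:
        raise ValueError("expected a single subject's genotype vector")
    return g.astype(np.float64)


def subject_distances(g, panel: ReferencePanel) -> DistanceVector:
    """Distances of one subject to all five reference populations.

    ``g`` is a vector of panel-reference-allele counts over panel SNPs with
    -1 marking missing calls.
    """
    g = _as_genotype_row(g)
    if g.shape[0] != panel.n_snps:
        raise ValueError("genotype vector length does not match panel")
    mask = g >= 0
    s_prime = int(mask.sum())
    if s_prime == 0:
        raise NoGenotypesError("subject has no genotyped panel SNPs")
    gm = np.where(mask, g, 0.0)
    lnp = np.log(panel.p)
    lnq = np.log(panel.q)
    sums = gm @ lnp + (2.0 * mask - gm) @ lnq  # (5,)
    n_het = float(np.count_nonzero(g == 1))
    d = -(sums + n_het * _LN2) / s_prime
    return DistanceVector(d=d, s_prime=s_prime)


def distance_difference(g, panel: ReferencePanel, j: int, k: int) -> float:
    """D_ij - D_ik computed directly from allele-frequency ratios.

    Equals ``subject_distances(g)[j] - [k]`` to floating-point tolerance but
    never forms the heterozygote term, making the cancellation explicit.
    """
    g = _as_genotype_row(g)
    mask = g >= 0
    s_prime = int(mask.sum())
    if s_prime == 0:
        raise NoGenotypesError("subject has no genotyped panel SNPs")
    gm = np.where(mask, g, 0.0)
    lr_p = np.log(panel.p[:, j] / panel.p[:, k])
    lr_q = np.log(panel.q[:, j] / panel.q[:, k])
    total = gm @ lr_p + (2.0 * mask - gm) @ lr_q
    return float(-total / s_prime)
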