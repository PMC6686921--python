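"""Synthetic panels, cohorts and missingness patterns.

The real reference panel is derived from controlled-access data, so the test
and validation surface of this package runs on synthetic data with the same
statistical structure the method assumes: unlinked biallelic autosomal SNPs,
high ancestral MAF, population-differentiated allele frequencies, and
subjects drawn genotype-by-genotype from Hardy-Weinberg equilibrium at
(possibly admixed) allele frequencies.

Population differentiation follows the Balding-Nichols model: each
population's frequency at a SNP is Beta-distributed around the ancestral
frequency with a per-population drift parameter F. Default F values are of
the magnitude seen between continental groups at ancestry-informative
high-MAF markers (EUR 0.12, AFR 0.16, EAS 0.16, SAS 0.12, LAT 0.10).
Admixture is simulated at the allele-frequency level (the method is
single-SNP; linkage plays no role in the fingerprint panel by construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeSet, MISSING
from .panel import (
    ANCHOR_GROUPS,
    DEFAULT_EPSILON,
    REF_POPULATIONS,
    ReferencePanel,
    clamp_frequencies,
)

#: Per-population Balding-Nichols drift, panel column order.
DEFAULT_FST = (0.12, 0.16, 0.16, 0.12, 0.10)
DEFAULT_MAF_FLOOR = 0.2
DEFAULT_N_SNPS = 10_000

# non-strand-ambiguous allele pairs only, so simulated filesets
# survive harmonization untouched
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of generator settings (all functions also accept these directly)."""

    n_snps: int = DEFAULT_N_SNPS
    fst: tuple = DEFAULT_FST
    maf_floor: float = DEFAULT_MAF_FLOOR
    anchor_jitter: float = 0.0
    cohorts: tuple = field(default_factory=tuple)  # of (n, alpha) pairs
    missing_mode: str = "none"  # none | mcar | platform
    missing_rate: float = 0.0
    platform_fraction: float = 1.0
    seed: int = 0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_panel(
    n_snps: int = DEFAULT_N_SNPS,
    fst=DEFAULT_FST,
    maf_floor: float = DEFAULT_MAF_FLOOR,
    anchor_jitter: float = 0.0,
    epsilon: float = DEFAULT_EPSILON,
    seed=0,
) -> ReferencePanel:
    """Generate a synthetic reference panel.

    Ancestral frequencies are uniform on [maf_floor, 1 - maf_floor]; each of
    the five populations drifts from the ancestral value under
    Balding-Nichols with its own F. Anchor-group frequencies equal the first
    three population frequencies, optionally re-drifted with a small
    ``anchor_jitter`` F to emulate anchor groups that are subsets rather than
    the whole population.
    """
    if n_snps < 3:
        raise ValueError("need at least 3 SNPs")
    if not 0.0 <= maf_floor < 0.5:
        raise ValueError("maf_floor must be in [0, 0.5)")
    fst = np.asarray(fst, dtype=float)
    if fst.shape != (len(REF_POPULATIONS),) or np.any(fst <= 0) or np.any(fst >= 1):
        raise ValueError("fst must give one drift value in (0,1) per reference population")
    rng = _rng(seed)

    anc = rng.uniform(maf_floor, 1.0 - maf_floor, size=n_snps)
    p = np.empty((n_snps, len(REF_POPULATIONS)))
    for j, f in enumerate(fst):
        a = anc * (1.0 - f) / f
        b = (1.0 - anc) * (1.0 - f) / f
        p[:, j] = rng.beta(a, b)
    p = clamp_frequencies(p, epsilon)

    u = p[:, : len(ANCHOR_GROUPS)].copy()
    if anchor_jitter > 0.0:
        for r in range(u.shape[1]):
            a = u[:, r] * (1.0 - anchor_jitter) / anchor_jitter
            b = (1.0 - u[:, r]) * (1.0 - anchor_jitter) / anchor_jitter
            u[:, r] = rng.beta(a, b)
        u = clamp_frequencies(u, epsilon)

    pairs = np.array(_ALLELE_PAIRS, dtype=object)
    picks = pairs[rng.integers(0, len(pairs), size=n_snps)]
    chrom = (np.arange(n_snps) % 22 + 1).astype(str)
    pos = np.arange(n_snps) // 22 * 50_000 + 10_000
    table = pd.DataFrame(
        {
            "snp_id": [f"snp{k + 1}" for k in range(n_snps)],
            "chrom": chrom,
            "pos": pos,
            "ref": picks[:, 0],
            "alt": picks[:, 1],
        }
    )
    return ReferencePanel(table=table, p=p, u=u, epsilon=epsilon)


def _subject_frequencies(panel: ReferencePanel, alpha) -> np.ndarray:
    """Per-SNP reference-allele frequency of an admixed individual."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or abs(alpha.sum() - 1.0) > 1e-9:
        raise ValueError("ancestry proportions must be non-negative and sum to 1")
    if alpha.shape == (3,):
        return panel.u @ alpha
    if alpha.shape == (5,):
        return panel.p @ alpha
    raise ValueError("alpha must have length 3 (anchor groups) or 5 (reference populations)")


def simulate_subjects(
    panel: ReferencePanel,
    cohorts,
    seed=0,
    id_prefix: str = "sim",
) -> GenotypeSet:
    """Draw HWE genotypes for admixed cohorts.

    ``cohorts`` is an iterable of ``(n_subjects, alpha)`` pairs where alpha
    is a length-3 ancestry vector over the anchor groups (E, F, A) or a
    length-5 vector over the reference populations. Genotypes are
    Binomial(2, f) with f the alpha-mixture of the panel frequencies,
    independent across SNPs and subjects.
    """
    rng = _rng(seed)
    blocks = []
    ids = []
    group = 0
    for n, alpha in cohorts:
        f = _subject_frequencies(panel, alpha)
        g = rng.binomial(2, f, size=(n, panel.n_snps)).astype(np.int8)
        blocks.append(g)
        ids.extend(f"{id_prefix}_g{group}_{i}" for i in range(n))
        group += 1
    if not blocks:
        raise ValueError("no cohorts requested")
    return GenotypeSet(
        subject_ids=np.asarray(ids, dtype=object),
        snp_ids=panel.snp_ids,
        genotypes=np.concatenate(blocks, axis=0),
    )


def apply_missingness(
    gs: GenotypeSet,
    mode: str = "mcar",
    rate: float = 0.0,
    fraction: float = 1.0,
    seed=0,
) -> GenotypeSet:
    """Return a copy of the cohort with a missingness pattern applied.

    mcar
        Each call independently missing with probability ``rate``.
    platform
        One seeded SNP subset of size ``ceil(fraction * S)`` is retained for
        every subject — the structured missingness produced by merging
        studies genotyped on different arrays.
    """
    rng = _rng(seed)
    g = gs.genotypes.copy()
    if mode == "none":
        pass
    elif mode == "mcar":
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")
        if rate == 1.0:
            warnings.warn("mcar rate 1.0 leaves every genotype missing", stacklevel=2)
        if rate > 0.0:
            g[rng.random(g.shape) < rate] = MISSING
    elif mode == "platform":
        if not 0.0 < fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        keep_n = int(np.ceil(fraction * gs.n_snps))
        keep = rng.choice(gs.n_snps, size=keep_n, replace=False)
        mask = np.ones(gs.n_snps, dtype=bool)
        mask[keep] = False
        g[:, mask] = MISSING
    else:
        raise ValueError(f"unknown missingness mode {mode!r}")
    return GenotypeSet(subject_ids=gs.subject_ids, snp_ids=gs.snp_ids, genotypes=g)


def simulate_fixture(out_dir, seed: int = 17, n_snps: int = 600):
    """Small deterministic panel + cohort used by the test suite and the
    ``fixtures`` CLI command. Returns (panel_path, plink_prefix)."""
    from pathlib import Path

    from .genotype_io import write_plink_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_panel, s_subj, s_miss = ss.spawn(3)
    panel = simulate_panel(n_snps=n_snps, seed=np.random.default_rng(s_panel))
    cohorts = [
        (8, (1.0, 0.0, 0.0)),
        (8, (0.0, 1.0, 0.0)),
        (8, (0.0, 0.0, 1.0)),
        (6, (0.6, 0.3, 0.1)),
    ]
    gs = simulate_subjects(panel, cohorts, seed=np.random.default_rng(s_subj))
    gs = apply_missingness(gs, mode="mcar", rate=0.1, seed=np.random.default_rng(s_miss))
    panel_path = out / "panel.tsv"
    panel.to_tsv(panel_path)
    prefix = out / "cohort"
    write_plink_cohort(gs, panel, prefix)
    return panel_path, prefix
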