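"""Subject genotype input and harmonization onto the panel orientation.

Genotypes are stored as counts of the *panel reference allele* in {0, 1, 2}
with an explicit missing state (-1). Missing calls are never imputed; every
downstream computation skips them ("ignore the SNPs with genotypes missing"
is the core contract of the method).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ReferencePanel
from .plink import MISSING, read_plink, write_plink  # noqa: F401  (re-exported)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class EmptyCohortError(ValueError):
    """Input contains no subjects."""


@dataclass
class GenotypeSet:
    """Subjects x panel-SNPs reference-allele counts.

    ``genotypes[i, l]`` is the count of the panel reference allele of subject
    ``i`` at panel SNP ``l`` (panel order), in {0, 1, 2}, or -1 for missing.
    Panel SNPs not genotyped in the source data are missing for everyone.
    """

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    genotypes: np.ndarray  # int8 (n_subjects, n_snps)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, s = self.genotypes.shape
        if n != len(self.subject_ids) or s != len(self.snp_ids):
            raise ValueError("genotype matrix shape does not match ids")
        if not np.isin(self.genotypes, [-1, 0, 1, 2]).all():
            raise ValueError("genotypes must be in {0, 1, 2} or -1 (missing)")

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def s_prime(self) -> np.ndarray:
        """Per-subject count of non-missing genotypes."""
        return (self.genotypes >= 0).sum(axis=1)


@dataclass
class HarmonizationReport:
    """Bookkeeping of how input variants mapped onto the panel."""

    n_matched: int = 0
    n_flipped: int = 0
    n_strand_flipped: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_unmatched: int = 0
    n_nondiploid_calls: int = 0

    @property
    def n_used(self) -> int:
        return self.n_matched + self.n_flipped + self.n_strand_flipped

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": [
                    "matched",
                    "allele_flipped",
                    "strand_flipped",
                    "dropped_ambiguous",
                    "dropped_unmatched",
                ],
                "count": [
                    self.n_matched,
                    self.n_flipped,
                    self.n_strand_flipped,
                    self.n_dropped_ambiguous,
                    self.n_dropped_unmatched,
                ],
            }
        )


def read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Read diploid GT calls from a VCF.

    Returns ``(variants, genotypes, n_nondiploid)`` where ``genotypes`` counts
    the VCF REF allele (A1 = REF, A2 = ALT), -1 for missing. Half-calls,
    ``./.`` and non-diploid GTs become missing. Multi-allelic records are
    skipped (fingerprint SNPs are biallelic).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = np.asarray(vcf.samples, dtype=object)
    if len(subject_ids) == 0:
        raise EmptyCohortError(f"VCF {path} contains no samples")
    rows = []
    cols = []
    n_nondiploid = 0
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        snp_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        rows.append((snp_id, str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
        g = np.full(len(subject_ids), MISSING, dtype=np.int8)
        for i, call in enumerate(v.genotypes):
            alleles = call[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                n_nondiploid += 1
                continue
            a, b = alleles
            if a < 0 or b < 0:
                continue
            g[i] = np.int8((a == 0) + (b == 0))  # REF-allele count
        cols.append(g)
    if n_nondiploid:
        warnings.warn(f"{n_nondiploid} non-diploid GT calls set to missing", stacklevel=2)
    variants = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "a1", "a2"])
    genotypes = (
        np.stack(cols, axis=1) if cols else np.zeros((len(subject_ids), 0), dtype=np.int8)
    )
    variants.attrs["subject_ids"] = subject_ids
    return variants, genotypes, n_nondiploid


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize_to_panel(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    subject_ids,
    panel: ReferencePanel,
    drop_ambiguous: bool = True,
    position_fallback: bool = False,
) -> tuple[GenotypeSet, HarmonizationReport]:
    """Re-express raw A1-allele counts as panel-reference-allele counts.

    Matching is by snp_id (optionally falling back to chrom:pos). Exact
    allele match keeps genotypes; swapped alleles complement them
    (g -> 2 - g); alleles matching only after strand complementation are
    flipped then matched; strand-ambiguous SNPs (A/T, C/G) are dropped by
    default. Missing stays missing — harmonization never imputes.
    """
    subject_ids = np.asarray(subject_ids, dtype=object)
    if len(subject_ids) == 0:
        raise EmptyCohortError("no subjects to harmonize")
    g_raw = np.asarray(genotypes, dtype=np.int8)
    n = len(subject_ids)
    report = HarmonizationReport()

    panel_index = {sid: k for k, sid in enumerate(panel.snp_ids)}
    pos_index = {}
    if position_fallback:
        pos_index = {
            (str(c), int(p)): k
            for k, (c, p) in enumerate(zip(panel.table["chrom"], panel.table["pos"]))
        }

    out = np.full((n, panel.n_snps), MISSING, dtype=np.int8)
    seen = np.zeros(panel.n_snps, dtype=bool)
    ref = panel.table["ref"].to_numpy()
    alt = panel.table["alt"].to_numpy()

    a1s = variants["a1"].to_numpy()
    a2s = variants["a2"].to_numpy()
    ids = variants["snp_id"].to_numpy()
    chroms = variants["chrom"].to_numpy() if "chrom" in variants else np.full(len(ids), "")
    poss = variants["pos"].to_numpy() if "pos" in variants else np.zeros(len(ids), dtype=int)

    for v in range(len(variants)):
        k = panel_index.get(ids[v])
        if k is None and position_fallback:
            k = pos_index.get((str(chroms[v]), int(poss[v])))
        if k is None or seen[k]:
            report.n_dropped_unmatched += 1
            continue
        a1, a2 = str(a1s[v]).upper(), str(a2s[v]).upper()
        r, a = ref[k], alt[k]
        if drop_ambiguous and _is_ambiguous(a1, a2):
            report.n_dropped_ambiguous += 1
            continue
        if (a1, a2) == (r, a):
            col, flip = g_raw[:, v], False
            report.n_matched += 1
        elif (a1, a2) == (a, r):
            col, flip = g_raw[:, v], True
            report.n_flipped += 1
        else:
            c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
            if (c1, c2) == (r, a):
                col, flip = g_raw[:, v], False
                report.n_strand_flipped += 1
            elif (c1, c2) == (a, r):
                col, flip = g_raw[:, v], True
                report.n_strand_flipped += 1
            else:
                report.n_dropped_unmatched += 1
                continue
        if flip:
            col = np.where(col >= 0, 2 - col, MISSING).astype(np.int8)
        out[:, k] = col
        seen[k] = True

    gs = GenotypeSet(subject_ids=subject_ids, snp_ids=panel.snp_ids, genotypes=out)
    return gs, report


def load_plink_cohort(
    prefix, panel: ReferencePanel, **harmonize_kwargs
) -> tuple[GenotypeSet, HarmonizationReport]:
    """Read a PLINK fileset and harmonize it onto the panel."""
    variants, samples, genotypes = read_plink(prefix)
    return harmonize_to_panel(
        variants, genotypes, samples["iid"].to_numpy(dtype=object), panel, **harmonize_kwargs
    )


def load_vcf_cohort(
    path, panel: ReferencePanel, **harmonize_kwargs
) -> tuple[GenotypeSet, HarmonizationReport]:
    """Read a VCF and harmonize it onto the panel."""
    variants, genotypes, n_nondiploid = read_vcf(path)
    gs, report = harmonize_to_panel(
        variants, genotypes, variants.attrs["subject_ids"], panel, **harmonize_kwargs
    )
    report.n_nondiploid_calls = n_nondiploid
    return gs, report


def write_plink_cohort(gs: GenotypeSet, panel: ReferencePanel, prefix) -> None:
    """Write a GenotypeSet as bed/bim/fam with A1 = panel ref, A2 = panel alt.

    Round-trips exactly: reading the fileset back and harmonizing against the
    same panel reproduces the genotype matrix bit for bit.
    """
    variants = pd.DataFrame(
        {
            "chrom": panel.table["chrom"].to_numpy(),
            "snp_id": panel.snp_ids,
            "pos": panel.table["pos"].to_numpy(),
            "a1": panel.table["ref"].to_numpy(),
            "a2": panel.table["alt"].to_numpy(),
        }
    )
    write_plink(prefix, list(gs.subject_ids), variants, gs.genotypes)


def mask_high_missingness_snps(gs: GenotypeSet, max_rate: float) -> GenotypeSet:
    """Exclude SNPs whose cohort missingness exceeds ``max_rate``.

    Exclusion marks the SNP missing for every subject, which is equivalent to
    removing it from the panel for every downstream distance (missing SNPs
    contribute nothing). Off by default in the pipeline.
    """
    miss_rate = (gs.genotypes < 0).mean(axis=0)
    g = gs.genotypes.copy()
    g[:, miss_rate > max_rate] = MISSING
    return GenotypeSet(subject_ids=gs.subject_ids, snp_ids=gs.snp_ids, genotypes=g)
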