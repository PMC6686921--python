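"""Reference allele-frequency panel.

The panel is the fixed coordinate system of the method: for each of ~10,000
unlinked, autosomal, biallelic, high-MAF "fingerprint" SNPs it stores the
reference-allele frequency in five reference populations (European, African,
East Asian, South Asian, Mexican/Latino) and in three anchor subject groups
(E, F, A) whose expected-distance centroids become the vertices of the
reference triangle.

The panel file is a plain TSV with a mandatory header::

    snp_id  chrom  pos  ref  alt  p_eur  p_afr  p_eas  p_sas  p_lat  u_E  u_F  u_A

All frequencies are clamped into [epsilon, 1 - epsilon] on load so that the
log-likelihood distance of any single SNP is finite and bounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reference populations, in the fixed column order used throughout.
REF_POPULATIONS = ("eur", "afr", "eas", "sas", "lat")
#: Anchor subject groups forming the triangle vertices (order E, F, A).
ANCHOR_GROUPS = ("E", "F", "A")

FREQ_COLUMNS = tuple(f"p_{p}" for p in REF_POPULATIONS)
ANCHOR_COLUMNS = tuple(f"u_{g}" for g in ANCHOR_GROUPS)
META_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt")
PANEL_COLUMNS = META_COLUMNS + FREQ_COLUMNS + ANCHOR_COLUMNS

DEFAULT_EPSILON = 1e-6

_LN2 = float(np.log(2.0))


class PanelFormatError(ValueError):
    """The panel file cannot be parsed (missing columns, bad header)."""


class PanelValidationError(ValueError):
    """The panel content violates an invariant (duplicates, empty)."""


def clamp_frequencies(freqs: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Clamp allele frequencies into [epsilon, 1 - epsilon].

    Idempotent; bounds any per-SNP log-likelihood term to ``-2 ln(epsilon)``.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    return np.clip(np.asarray(freqs, dtype=np.float64), epsilon, 1.0 - epsilon)


@dataclass
class ReferencePanel:
    """Validated, clamped panel of per-SNP allele frequencies.

    Attributes
    ----------
    table
        Per-SNP metadata (snp_id, chrom, pos, ref, alt), one row per SNP.
    p
        (S, 5) reference-allele frequency per reference population.
    u
        (S, 3) reference-allele frequency per anchor group (E, F, A).
    epsilon
        Clamp bound applied to ``p`` and ``u``.
    n_dropped
        Number of input rows discarded for unparseable/out-of-range values.
    """

    table: pd.DataFrame
    p: np.ndarray
    u: np.ndarray
    epsilon: float = DEFAULT_EPSILON
    n_dropped: int = 0
    _contribution: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.p = clamp_frequencies(self.p, self.epsilon)
        self.u = clamp_frequencies(self.u, self.epsilon)
        if self.p.shape != (self.n_snps, len(REF_POPULATIONS)):
            raise PanelValidationError(
                f"p has shape {self.p.shape}, expected ({self.n_snps}, {len(REF_POPULATIONS)})"
            )
        if self.u.shape != (self.n_snps, len(ANCHOR_GROUPS)):
            raise PanelValidationError(
                f"u has shape {self.u.shape}, expected ({self.n_snps}, {len(ANCHOR_GROUPS)})"
            )
        ids = self.table["snp_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].iloc[0]
            raise PanelValidationError(f"duplicate snp_id in panel (e.g. {dups!r})")
        if self.n_snps == 0:
            raise PanelValidationError("panel contains no usable SNPs")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def q(self) -> np.ndarray:
        """Alternate-allele frequencies, always derived as 1 - p."""
        return 1.0 - self.p

    def contribution_table(self) -> np.ndarray:
        """Per-SNP expected-distance contributions, shape (S, 3, 3).

        ``c[l, r, j]`` is the expected negative log genotype probability at
        SNP ``l`` for an individual drawn from anchor group ``r`` (E, F, A)
        scored against reference population ``j`` (first three populations)::

            c = -(u^2 ln(p^2) + 2 u v ln(2 p q) + v^2 ln(q^2))

        The mean of ``c[:, r, j]`` over any SNP subset is the expected
        genetic distance from group r to population j on that subset; over
        the full panel it gives the reference-triangle vertices. Cached.
        """
        if self._contribution is None:
            p = self.p[:, :3]  # (S, 3) first three reference populations
            q = 1.0 - p
            u = self.u  # (S, 3)
            v = 1.0 - u
            lnp = np.log(p)
            lnq = np.log(q)
            # broadcast anchor groups (axis 1) against populations (axis 2)
            u_ = u[:, :, None]
            v_ = v[:, :, None]
            lnp_ = lnp[:, None, :]
            lnq_ = lnq[:, None, :]
            c = -(
                u_**2 * (2.0 * lnp_)
                + 2.0 * u_ * v_ * (_LN2 + lnp_ + lnq_)
                + v_**2 * (2.0 * lnq_)
            )
            self._contribution = c
        return self._contribution

    def expected_distance_triples(self, snp_mask: np.ndarray | None = None) -> np.ndarray:
        """Expected-distance triples for the three anchor groups, shape (3, 3).

        Row r is the 3-space point (E[D to pop1], E[D to pop2], E[D to pop3])
        for anchor group r, averaged over ``snp_mask`` (boolean over SNPs) or
        the full panel when ``snp_mask`` is None.
        """
        c = self.contribution_table()
        if snp_mask is None:
            return c.mean(axis=0)
        snp_mask = np.asarray(snp_mask, dtype=bool)
        if snp_mask.shape != (self.n_snps,):
            raise ValueError("snp_mask must be a boolean vector over panel SNPs")
        if not snp_mask.any():
            raise ValueError("empty SNP subset: cannot form expected distances")
        return c[snp_mask].mean(axis=0)

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        for k, col in enumerate(FREQ_COLUMNS):
            df[col] = self.p[:, k]
        for k, col in enumerate(ANCHOR_COLUMNS):
            df[col] = self.u[:, k]
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def expected_distances(
    table: np.ndarray, group: int | str, refpop: int, snp_subset: np.ndarray
) -> float:
    """Mean expected-distance contribution over a SNP subset.

    Parameters
    ----------
    table
        (S, 3, 3) contribution table from :meth:`ReferencePanel.contribution_table`.
    group
        Anchor group index 0..2 or label "E"/"F"/"A".
    refpop
        Reference population index 0..2.
    snp_subset
        Integer indices or boolean mask selecting a non-empty SNP subset.
    """
    if isinstance(group, str):
        group = ANCHOR_GROUPS.index(group)
    sub = np.asarray(table)[snp_subset]
    if sub.size == 0:
        raise ValueError("empty SNP subset")
    return float(sub[:, group, refpop].mean())


def load_panel(path, epsilon: float = DEFAULT_EPSILON) -> ReferencePanel:
    """Load and validate a panel TSV, clamping frequencies into [eps, 1-eps].

    Rows whose frequencies do not parse to [0, 1] are dropped (the count is
    logged and recorded on the panel). Missing columns raise
    :class:`PanelFormatError`; duplicate snp_ids or an empty usable panel
    raise :class:`PanelValidationError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PanelFormatError(f"cannot read panel file {path}: {exc}") from exc
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"panel file {path} is missing columns: {missing}")

    freq_cols = list(FREQ_COLUMNS + ANCHOR_COLUMNS)
    freqs = df[freq_cols].apply(pd.to_numeric, errors="coerce")
    ok = freqs.notna().all(axis=1) & (freqs >= 0.0).all(axis=1) & (freqs <= 1.0).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d panel rows with unparseable/out-of-range frequencies", n_dropped)
    df = df.loc[ok].reset_index(drop=True)
    freqs = freqs.loc[ok]
    if len(df) == 0:
        raise PanelValidationError(f"panel file {path} has zero usable SNPs")

    return ReferencePanel(
        table=df[list(META_COLUMNS)].copy(),
        p=freqs[list(FREQ_COLUMNS)].to_numpy(dtype=np.float64),
        u=freqs[list(ANCHOR_COLUMNS)].to_numpy(dtype=np.float64),
        epsilon=epsilon,
        n_dropped=n_dropped,
    )
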