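"""Per-subject ancestry scoring pipeline.

For each subject: compute distances to the five reference populations over
the genotyped SNP subset, build the subject-specific expected-distance
triangle over that same subset, planarize it together with the subject's
point, take barycentric coordinates, and re-express them on the full-panel
reference triangle. The re-expressed in-plane coordinates are the GD1/GD2
scores, the out-of-plane coordinate of the subject's point in its own subset
frame is GD3, and D5 - D4 is GD4. Ancestry proportions are the clamped,
renormalized barycentric coordinates.

Because the subset triangle is rebuilt per subject from the panel's expected
contributions, the scores are unbiased under arbitrary (random or
platform-structured) missingness, and each subject's scores depend only on
that subject's genotypes and the panel — never on the rest of the cohort.

Each subject's reductions over SNPs run as fixed-order vector operations, so
a subject's scores are bit-identical no matter which other subjects are in
the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .genotype_io import GenotypeSet
from .panel import ReferencePanel

_LN2 = float(np.log(2.0))

#: Fixed output column order of the scores table.
SCORE_COLUMNS = [
    "subject_id",
    "s_prime",
    "d1",
    "d2",
    "d3",
    "d4",
    "d5",
    "gd1",
    "gd2",
    "gd3",
    "gd4",
    "lambda_e",
    "lambda_f",
    "lambda_a",
    "p_e",
    "p_f",
    "p_a",
    "flags",
]

#: S' below which scores get a low-SNP-count warning flag.
LOW_SNP_WARN = 1000
#: S' at or above which scores carry the high-confidence annotation.
HIGH_CONFIDENCE_SNPS = 4000

FLAG_NO_GENOTYPES = "no_genotypes"
FLAG_UNSTABLE_FRAME = "unstable_frame"
FLAG_LOW_SNPS = "low_snps"
FLAG_HIGH_CONFIDENCE = "high_confidence"


@dataclass(frozen=True)
class AncestryScores:
    """Full score record for one subject."""

    subject_id: str
    s_prime: int
    d: np.ndarray  # (5,)
    gd1: float
    gd2: float
    gd3: float
    gd4: float
    lam: np.ndarray  # (3,) barycentric (e, f, a)
    p: np.ndarray  # (3,) ancestry proportions (e, f, a)
    flags: str


def build_reference_frame(panel: ReferencePanel) -> geometry.PlanarFrame:
    """Planarized full-panel reference triangle (the fixed frame all scores
    are re-expressed in). Deterministic per panel; degenerate anchor
    frequencies raise (the panel populations are insufficiently separated).
    """
    triples = panel.expected_distance_triples()  # rows E, F, A
    tri = geometry.build_triangle(triples[0], triples[1], triples[2])
    return geometry.planarize(tri)


def _flags_for(s_prime: int, unstable: bool) -> str:
    tokens = []
    if s_prime == 0:
        tokens.append(FLAG_NO_GENOTYPES)
    elif s_prime < LOW_SNP_WARN:
        tokens.append(FLAG_LOW_SNPS)
    elif s_prime >= HIGH_CONFIDENCE_SNPS:
        tokens.append(FLAG_HIGH_CONFIDENCE)
    if unstable:
        tokens.append(FLAG_UNSTABLE_FRAME)
    return ",".join(tokens)


def _subject_raw(g_row: np.ndarray, lnp: np.ndarray, lnq: np.ndarray, c9: np.ndarray):
    """Distances and subset expected-triples for one subject (fixed-order
    vector reductions only)."""
    mask = g_row >= 0
    s_prime = int(mask.sum())
    if s_prime == 0:
        return 0, None, None
    maskf = mask.astype(np.float64)
    gm = np.where(mask, g_row, 0).astype(np.float64)
    sums = gm @ lnp + (2.0 * maskf - gm) @ lnq  # (5,)
    n_het = float(np.count_nonzero(g_row == 1))
    d = -(sums + n_het * _LN2) / s_prime
    e_t = (maskf @ c9).reshape(3, 3) / s_prime  # rows E, F, A
    return s_prime, d, e_t


def compute_cohort_scores(
    gs: GenotypeSet,
    panel: ReferencePanel,
    frame0: geometry.PlanarFrame | None = None,
) -> pd.DataFrame:
    """Score every subject; one row per subject, SCORE_COLUMNS order.

    Subjects with no genotyped panel SNPs are flagged, not dropped. Subjects
    whose subset triangle is numerically degenerate keep their distances and
    GD3/GD4 but have barycentric coordinates, proportions and GD1/GD2
    withheld (NaN) under the unstable-frame flag.
    """
    if frame0 is None:
        frame0 = build_reference_frame(panel)
    c = panel.contribution_table()
    c9 = np.ascontiguousarray(c.reshape(panel.n_snps, 9))
    lnp = np.log(panel.p)
    lnq = np.log(panel.q)

    n = gs.n_subjects
    s_prime = np.zeros(n, dtype=np.int64)
    d_all = np.full((n, 5), np.nan)
    v_e = np.full((n, 3), np.nan)
    v_f = np.full((n, 3), np.nan)
    v_a = np.full((n, 3), np.nan)

    for i in range(n):
        sp, d, e_t = _subject_raw(gs.genotypes[i], lnp, lnq, c9)
        s_prime[i] = sp
        if sp:
            d_all[i] = d
            v_e[i], v_f[i], v_a[i] = e_t

    has_g = s_prime > 0
    q3 = d_all[:, :3]
    vertices2d, q2d, z, _det, valid = geometry.batch_planarize(v_e, v_f, v_a, q3)
    valid &= has_g

    lam = np.full((n, 3), np.nan)
    if valid.any():
        lam[valid] = geometry.batch_barycentric(vertices2d[valid], q2d[valid])
    props = np.full((n, 3), np.nan)
    if valid.any():
        props[valid] = geometry.proportions(lam[valid])
    gd12 = np.full((n, 2), np.nan)
    if valid.any():
        gd12[valid] = geometry.barycentric_to_cartesian(lam[valid], frame0)

    gd3 = np.where(valid, z, np.nan)
    gd4 = np.where(has_g, d_all[:, 4] - d_all[:, 3], np.nan)

    flags = [
        _flags_for(int(sp), bool(h and not v))
        for sp, h, v in zip(s_prime, has_g, valid)
    ]

    df = pd.DataFrame(
        {
            "subject_id": gs.subject_ids,
            "s_prime": s_prime,
            "d1": d_all[:, 0],
            "d2": d_all[:, 1],
            "d3": d_all[:, 2],
            "d4": d_all[:, 3],
            "d5": d_all[:, 4],
            "gd1": gd12[:, 0],
            "gd2": gd12[:, 1],
            "gd3": gd3,
            "gd4": gd4,
            "lambda_e": lam[:, 0],
            "lambda_f": lam[:, 1],
            "lambda_a": lam[:, 2],
            "p_e": props[:, 0],
            "p_f": props[:, 1],
            "p_a": props[:, 2],
            "flags": flags,
        }
    )
    return df[SCORE_COLUMNS]


def compute_subject_scores(
    g,
    panel: ReferencePanel,
    frame0: geometry.PlanarFrame | None = None,
    subject_id: str = "subject",
) -> AncestryScores:
    """Score a single subject (convenience wrapper over the cohort path)."""
    gs = GenotypeSet(
        subject_ids=np.array([subject_id], dtype=object),
        snp_ids=panel.snp_ids,
        genotypes=np.asarray(g, dtype=np.int8)[None, :],
    )
    row = compute_cohort_scores(gs, panel, frame0=frame0).iloc[0]
    return AncestryScores(
        subject_id=row["subject_id"],
        s_prime=int(row["s_prime"]),
        d=row[["d1", "d2", "d3", "d4", "d5"]].to_numpy(dtype=float),
        gd1=float(row["gd1"]),
        gd2=float(row["gd2"]),
        gd3=float(row["gd3"]),
        gd4=float(row["gd4"]),
        lam=row[["lambda_e", "lambda_f", "lambda_a"]].to_numpy(dtype=float),
        p=row[["p_e", "p_f", "p_a"]].to_numpy(dtype=float),
        flags=row["flags"],
    )


def write_scores(df: pd.DataFrame, path) -> None:
    """Write the scores table as TSV, floats at 6 decimals."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    df["flags"] = df.get("flags", pd.Series([""] * len(df))).fillna("")
    return df
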