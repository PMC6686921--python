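"""Nine-way population assignment from ancestry proportions and GD scores.

Assignment is rule-based and deterministic. The proportion cutoffs place a
subject in one of: European, African, East Asian, African American, Latin
American 1, a three-way region (Latin American 2 / Asian-Pacific Islander /
South Asian), or Other. Within the three-way region two quadratic curves in
the (GD1, GD4) plane plus the sign of GD4 separate South Asians,
Asian-Pacific Islanders and Latin American 2. All cutoff constants are
configuration, defaulting to the published suggested standard; users are
expected to inspect their own cohorts in GD space and may substitute their
own cutoffs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

POP_LABELS = {
    0: "Unassigned",
    1: "European",
    2: "African",
    3: "East Asian",
    4: "African American",
    5: "Latin American 1",
    6: "Latin American 2",
    7: "Asian-Pacific Islander",
    8: "South Asian",
    9: "Other",
}


@dataclass(frozen=True)
class CutoffConfig:
    """All classification constants (proportions as fractions, not %)."""

    pe_european: float = 0.87  # PopID 1: P_e >= this
    pf_african: float = 0.95  # PopID 2: P_f >= this
    pa_east_asian: float = 0.95  # PopID 3: P_a >= this
    pf_afr_amer_lo: float = 0.40  # PopID 4: this <= P_f < pf_african
    p_admix: float = 0.13  # the recurring 13% threshold on P_a / P_f
    # South Asian curve: GD4 > sa_coeff * (GD1 - sa_center)^2 + sa_offset
    sa_coeff: float = 5.0
    sa_center: float = 1.69
    sa_offset: float = 0.042
    # Asian-Pacific Islander curve: GD1 > api_coeff * GD4^2 + api_offset
    api_coeff: float = 30.0
    api_offset: float = 1.73
    # PopID for the region where GD4 >= 0 and neither curve fires
    residual_pop_id: int = 7

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CutoffConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _assign_one(pe, pf, pa, gd1, gd4, c: CutoffConfig) -> tuple[int, str]:
    # proportion rules, evaluated in the printed row order
    if pe >= c.pe_european:
        return 1, "prop_european"
    if pf >= c.pf_african:
        return 2, "prop_african"
    if pa >= c.pa_east_asian:
        return 3, "prop_east_asian"
    if c.pf_afr_amer_lo <= pf < c.pf_african and pa < c.p_admix:
        return 4, "prop_african_american"
    if pf < c.pf_afr_amer_lo and pe < c.pe_european and pa < c.p_admix and pf >= pa:
        return 5, "prop_latin_american_1"
    if pa < c.pa_east_asian and pe < c.pe_european and pf < c.p_admix and pf < pa:
        # three-way region resolved on the (GD1, GD4) plane
        if not (np.isfinite(gd1) and np.isfinite(gd4)):
            return 0, "missing_gd_scores"
        if gd4 > c.sa_coeff * (gd1 - c.sa_center) ** 2 + c.sa_offset:
            return 8, "curve_south_asian"
        if gd1 > c.api_coeff * gd4**2 + c.api_offset:
            return 7, "curve_asian_pacific"
        if gd4 < 0:
            return 6, "curve_latin_american_2"
        return c.residual_pop_id, "curve_residual"
    if pa >= c.p_admix and pf >= c.p_admix:
        return 9, "prop_other"
    # unreachable for valid proportions summing to 1 (covered by tests)
    return 9, "fallback"


def assign_population(
    p_e, p_f, p_a, gd1=np.nan, gd4=np.nan, cutoffs: CutoffConfig | None = None
) -> tuple[int, str, str]:
    """Assign one subject a PopID; returns (pop_id, label, rule_fired)."""
    c = cutoffs or CutoffConfig()
    total = p_e + p_f + p_a
    if not np.isfinite(total) or abs(total - 1.0) > 1e-6:
        raise ValueError(f"ancestry proportions must sum to 1, got {total}")
    pop_id, rule = _assign_one(p_e, p_f, p_a, gd1, gd4, c)
    return pop_id, POP_LABELS[pop_id], rule


def classify_scores(scores: pd.DataFrame, cutoffs: CutoffConfig | None = None) -> pd.DataFrame:
    """Append pop_id, label, rule_fired columns to a scores table.

    Subjects whose proportions were withheld (unstable frame, no genotypes)
    get PopID 0 / "Unassigned".
    """
    c = cutoffs or CutoffConfig()
    pop_ids = np.zeros(len(scores), dtype=int)
    rules = np.empty(len(scores), dtype=object)
    for idx, (pe, pf, pa, gd1, gd4) in enumerate(
        zip(scores["p_e"], scores["p_f"], scores["p_a"], scores["gd1"], scores["gd4"])
    ):
        if not np.isfinite(pe):
            pop_ids[idx], rules[idx] = 0, "unassigned_no_proportions"
            continue
        pop_ids[idx], rules[idx] = _assign_one(pe, pf, pa, gd1, gd4, c)
    out = scores.copy()
    out["pop_id"] = pop_ids
    out["label"] = [POP_LABELS[k] for k in pop_ids]
    out["rule_fired"] = rules
    return out
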