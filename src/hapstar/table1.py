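"""Published descriptive counts from the 2018 Nigeria DHS birth-outcome study.

The microdata are restricted (available from the DHS Program on request),
but the published descriptive table prints the full cross-tabulated counts
of each characteristic against clean/unclean cooking fuel. Those counts are
inputs here: every prevalence ratio, odds ratio and percentage of the
descriptive analysis is recomputed from them, which gives an exact check of
the estimators without any microdata.

Counts are laid out per characteristic level as (unclean, clean).
"""

from __future__ import annotations

import numpy as np

from .descriptives import (
    ContingencyTable2x2,
    RatioEstimate,
    odds_ratio,
    pearson_chi_square,
    prevalence_ratio,
)

__all__ = ["NDHS2018_COUNTS", "published_descriptives"]

NDHS2018_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    # mother/household level, n = 41,821 (565 missing fuel)
    "fuel": {"unclean": (36_846, 0), "clean": (0, 4_410)},
    "education": {
        "none": (14_173, 115),
        "primary": (6_062, 252),
        "secondary": (14_219, 2_189),
        "higher": (2_392, 1_854),
    },
    "smoking": {"smoker": (75, 18), "non_smoker": (36_771, 4_392)},
    # birth level, n = 127,545
    "birth_status": {"alive": (100_669, 7_626), "stillbirth": (17_598, 503)},
    "birth_weight": {"normal": (5_373, 1_633), "lbw": (442, 113)},
    "pregnancy_duration": {"term": (35_972, 2_856), "preterm": (345, 59)},
}

# printed overall totals not recoverable from the fuel columns alone
N_BIRTHS_TOTAL = 127_545
N_STILLBIRTHS_TOTAL = 18_220
N_LBW_TOTAL = 562
N_BW_OBSERVED_TOTAL = 7_728  # 7166 normal + 562 low
N_PRETERM_TOTAL = 408
N_DURATION_OBSERVED_TOTAL = 39_738


def _pr_table(char: str, present: str, absent: str) -> ContingencyTable2x2:
    (a, c) = NDHS2018_COUNTS[char][present]
    (b, d) = NDHS2018_COUNTS[char][absent]
    return ContingencyTable2x2(a, b, c, d)


def published_descriptives() -> dict[str, float]:
    """Recompute the published descriptive statistics from printed counts.

    Returns a flat dict of the headline quantities: prevalence ratios with
    their 95% CI endpoints for the binary rows, odds ratios for education
    levels (reference: no education), the chi-square p-value for birth
    status vs fuel, and the marginal percentages. Ratios are on the printed
    scale (2 dp before comparison), percentages in percent.
    """
    out: dict[str, float] = {}

    def put(prefix: str, est: RatioEstimate) -> None:
        out[f"{prefix}"] = est.estimate
        out[f"{prefix}_ci_low"] = est.ci_low
        out[f"{prefix}_ci_high"] = est.ci_high

    put("stillbirth_pr",
        prevalence_ratio(_pr_table("birth_status", "stillbirth", "alive")))
    put("lbw_pr", prevalence_ratio(_pr_table("birth_weight", "lbw", "normal")))
    put("preterm_pr",
        prevalence_ratio(_pr_table("pregnancy_duration", "preterm", "term")))
    put("smoker_pr", prevalence_ratio(_pr_table("smoking", "smoker", "non_smoker")))

    ref_u, ref_c = NDHS2018_COUNTS["education"]["none"]
    for level in ("primary", "secondary", "higher"):
        a, b = NDHS2018_COUNTS["education"][level]
        put(f"education_{level}_or",
            odds_ratio(ContingencyTable2x2(a, b, ref_u, ref_c)))

    sb = _pr_table("birth_status", "stillbirth", "alive")
    out["stillbirth_fuel_chi2_p"] = pearson_chi_square(sb.as_array()).p_value

    n_unclean = sum(u for u, _ in NDHS2018_COUNTS["fuel"].values())
    n_clean = sum(c for _, c in NDHS2018_COUNTS["fuel"].values())
    out["unclean_prevalence_pct"] = 100 * n_unclean / (n_unclean + n_clean)
    out["stillbirth_pct_of_pregnancies"] = (
        100 * N_STILLBIRTHS_TOTAL / N_BIRTHS_TOTAL)
    u_sb, c_sb = NDHS2018_COUNTS["birth_status"]["stillbirth"]
    out["unclean_pct_among_stillbirths"] = 100 * u_sb / (u_sb + c_sb)
    out["preterm_pct_of_observed"] = (
        100 * N_PRETERM_TOTAL / N_DURATION_OBSERVED_TOTAL)
    u_lbw, _ = NDHS2018_COUNTS["birth_weight"]["lbw"]
    u_nw, _ = NDHS2018_COUNTS["birth_weight"]["normal"]
    out["lbw_pct_among_unclean"] = 100 * u_lbw / (u_lbw + u_nw)
    out["lbw_pct_of_observed"] = 100 * N_LBW_TOTAL / N_BW_OBSERVED_TOTAL
    return out
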