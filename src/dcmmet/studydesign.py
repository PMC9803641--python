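"""Reference cohort design the synthetic generator emulates.

The numbers below are the published study-design counts for the 75-dog
cohort (four groups crossed on disease and baseline diet), the congestive
heart failure (CHF) prevalence within the two DCM groups, and the 9-month
follow-up survival counts.  They serve two purposes: they seed the default
:class:`~dcmmet.synthdata.SimConfig`, and the simple cohort arithmetic on
them (overall CHF percentage, follow-up survival percentage) is exposed as
functions so reports recompute rather than restate it.
"""

from __future__ import annotations

#: baseline group sizes: DCM-NT, DCM-T, C-NT, C-T
GROUP_SIZES = (38, 8, 12, 17)
GROUP_LABELS = ("DCM-NT", "DCM-T", "C-NT", "C-T")

#: congestive heart failure at diagnosis within each DCM group: (with CHF, group n)
CHF_COUNTS = {"DCM-NT": (31, 38), "DCM-T": (6, 8)}

#: alive with a follow-up sample at 9 months: (survivors, enrolled at baseline)
#: the published survival denominator for the NT group is 37
FOLLOWUP_COUNTS = {"DCM-NT": (20, 37), "DCM-T": (2, 8)}


def percentage(numerator: int, denominator: int) -> float:
    """Plain percentage, as used throughout the cohort summaries."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator


def overall_chf_percentage() -> float:
    """CHF prevalence across both DCM groups combined (percent)."""
    k = sum(v[0] for v in CHF_COUNTS.values())
    n = sum(v[1] for v in CHF_COUNTS.values())
    return percentage(k, n)


def followup_survival_percentage(group: str = "DCM-NT") -> float:
    """Percent of a DCM group alive with a 9-month follow-up sample."""
    k, n = FOLLOWUP_COUNTS[group]
    return percentage(k, n)
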