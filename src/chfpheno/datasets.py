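"""Small bundled tables used by the worked examples and the acceptance script."""

from __future__ import annotations

from .cohort import ScreeningGroup
from .evaluation import GroupErrorTable, GroupStats

__all__ = ["screening_error_table"]


def screening_error_table() -> GroupErrorTable:
    """Reference stratified counts for the population-error worked example.

    Per screening group: misclassification counts in a ~2,800-note annotated
    two-site modelling sample, and CHF-positive counts among a random
    1,000-patient sample from the same hospitals.  Feeding this table to
    :func:`chfpheno.evaluation.estimate_population_error` reproduces the
    headline unselected-population error rate of 1.6%.
    """
    return GroupErrorTable(
        groups={
            ScreeningGroup.ICD_POS_MED_POS: GroupStats(
                error_count=52, n_annotated=700, positive_count=14, n_random=140
            ),
            ScreeningGroup.ICD_POS_MED_NEG: GroupStats(
                error_count=26, n_annotated=350, positive_count=4, n_random=41
            ),
            ScreeningGroup.ICD_NEG_MED_POS: GroupStats(
                error_count=83, n_annotated=1050, positive_count=3, n_random=342
            ),
            ScreeningGroup.ICD_NEG_MED_NEG: GroupStats(
                error_count=66, n_annotated=700, positive_count=1, n_random=477
            ),
        }
    )
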