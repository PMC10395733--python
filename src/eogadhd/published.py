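"""Published group-level tracking statistics and their arithmetic.

The clinical study this pipeline re-implements reported, for drug-free
ADHD children (``ADHD_pre``), the same children after six months of
treatment (``ADHD_post``) and healthy controls (``HC``):

* mean matched-stimulus counts per stage and direction, with the per-cell
  reference stimulus counts (40 horizontal / 30 vertical per stage);
* the derived per-cell success percentages, per-direction accuracies and
  their plain averages;
* the 16/9-weighted overall tracking score per group; and
* the colour-rule (CGD) report rates.

These numbers seed the synthetic cohort defaults and let
:func:`reproduce_summary` re-derive every downstream cell from the mean
counts, confirming the summary arithmetic end to end.  The published
tables round intermediate quantities inconsistently (some rows derive
from rounded cells, others from unrounded ones); each recomputed quantity
follows the chain its source row used, and :func:`verify_summary` checks
agreement at the appropriate precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .features import round2, weighted_success
from .stimulus import DIRECTIONS

__all__ = [
    "GROUPS",
    "REFERENCE_COUNTS",
    "MEAN_MATCHED_COUNTS",
    "PUBLISHED_CELL_SUCCESS",
    "PUBLISHED_DIRECTION_ACCURACY",
    "PUBLISHED_GROUP_AVERAGE",
    "PUBLISHED_WEIGHTED_RSOT",
    "PUBLISHED_CGD_RATE",
    "reproduce_summary",
    "verify_summary",
]

GROUPS = ("ADHD_pre", "ADHD_post", "HC")

#: Stimuli per direction in every stage (success-rate denominators).
REFERENCE_COUNTS = pd.Series({"left": 40, "right": 40, "up": 30, "down": 30})

_STAGES = [1, 2, 3]


def _table(left, right, up, down) -> pd.DataFrame:
    df = pd.DataFrame(
        {"left": left, "right": right, "up": up, "down": down}, index=_STAGES
    )
    df.index.name = "stage"
    return df


#: Mean number of matched stimuli per (stage, direction) cell.
MEAN_MATCHED_COUNTS: dict[str, pd.DataFrame] = {
    "ADHD_pre": _table(
        left=[13.05, 11.87, 13.15], right=[10.97, 9.87, 10.03],
        up=[7.23, 8.67, 8.64], down=[6.72, 8.03, 9.15],
    ),
    "ADHD_post": _table(
        left=[13.36, 13.51, 12.77], right=[11.28, 11.10, 10.13],
        up=[7.82, 8.49, 8.54], down=[8.08, 7.90, 8.08],
    ),
    "HC": _table(
        left=[15.00, 14.41, 14.31], right=[12.84, 12.06, 11.06],
        up=[8.06, 10.28, 9.84], down=[7.50, 9.56, 10.56],
    ),
}

#: Published per-cell success percentages (rounded to two decimals).
PUBLISHED_CELL_SUCCESS: dict[str, pd.DataFrame] = {
    "ADHD_pre": _table(
        left=[32.63, 29.68, 32.88], right=[27.44, 24.68, 25.06],
        up=[24.10, 28.89, 28.80], down=[22.39, 26.75, 30.51],
    ),
    "ADHD_post": _table(
        left=[33.40, 33.78, 31.92], right=[28.21, 27.76, 25.32],
        up=[26.07, 28.29, 28.46], down=[26.92, 26.32, 26.92],
    ),
    "HC": _table(
        left=[37.50, 36.02, 35.78], right=[32.11, 30.16, 27.66],
        up=[26.88, 34.27, 32.81], down=[25.00, 31.88, 35.21],
    ),
}

#: Published per-direction accuracies (stage means of the cell rates).
PUBLISHED_DIRECTION_ACCURACY = pd.DataFrame(
    {
        "ADHD_pre": [31.73, 25.73, 27.26, 26.55],
        "ADHD_post": [33.03, 27.10, 27.61, 26.72],
        "HC": [36.43, 29.98, 31.32, 30.70],
    },
    index=list(DIRECTIONS),
)

#: Published plain four-direction averages per group.
PUBLISHED_GROUP_AVERAGE = pd.Series(
    {"ADHD_pre": 27.82, "ADHD_post": 28.62, "HC": 32.10}
)

#: Published 16/9-weighted overall tracking score per group.
PUBLISHED_WEIGHTED_RSOT = pd.Series(
    {"ADHD_pre": 28.07, "ADHD_post": 29.02, "HC": 32.41}
)

#: Published colour-rule report rates per group (percent).
PUBLISHED_CGD_RATE = pd.Series(
    {"ADHD_pre": 4.62, "ADHD_post": 45.00, "HC": 39.02}
)


@dataclass
class SummaryReproduction:
    """Recomputed summary quantities, one table per derivation step."""

    cell_success: dict[str, pd.DataFrame]
    direction_accuracy: pd.DataFrame
    group_average: pd.Series
    weighted_rsot: pd.Series


def reproduce_summary() -> SummaryReproduction:
    """Re-derive the summary tables from the bundled mean counts.

    * per-cell success = 100 x mean matched count / reference count;
    * per-direction accuracy = stage mean of the *published* (two-decimal)
      cell rates, matching the rounding chain of the accuracy table;
    * group average = plain four-direction mean computed on the unrounded
      count-derived accuracies, matching the chain of the average row;
    * weighted score = 16/9-weighted combination of the two-decimal
      direction accuracies.
    """
    cell_success = {
        g: 100.0 * MEAN_MATCHED_COUNTS[g].div(REFERENCE_COUNTS, axis=1)
        for g in GROUPS
    }
    direction_accuracy = pd.DataFrame(
        {
            g: PUBLISHED_CELL_SUCCESS[g].mean(axis=0).map(round2)
            for g in GROUPS
        }
    ).loc[list(DIRECTIONS)]
    group_average = pd.Series(
        {g: round2(float(cell_success[g].mean(axis=0).mean())) for g in GROUPS}
    )
    weighted_rsot = pd.Series(
        {
            g: round2(
                weighted_success(
                    direction_accuracy.loc["left", g],
                    direction_accuracy.loc["right", g],
                    direction_accuracy.loc["up", g],
                    direction_accuracy.loc["down", g],
                )
            )
            for g in GROUPS
        }
    )
    return SummaryReproduction(
        cell_success=cell_success,
        direction_accuracy=direction_accuracy,
        group_average=group_average,
        weighted_rsot=weighted_rsot,
    )


def verify_summary() -> list[str]:
    """Compare every recomputed quantity against its published value.

    Returns a list of human-readable mismatches (empty when everything
    agrees).  Cell success rates recomputed from two-decimal mean counts
    carry up to ~0.02 percentage points of input rounding error and are
    checked at 0.025; all other quantities must agree exactly at two
    decimals.
    """
    rep = reproduce_summary()
    problems: list[str] = []
    for g in GROUPS:
        diff = (rep.cell_success[g].round(2) - PUBLISHED_CELL_SUCCESS[g]).abs()
        for d in DIRECTIONS:
            for s in _STAGES:
                if diff.loc[s, d] > 0.025:
                    problems.append(
                        f"cell success {g}/{d}/stage{s}: computed "
                        f"{rep.cell_success[g].loc[s, d]:.3f} vs published "
                        f"{PUBLISHED_CELL_SUCCESS[g].loc[s, d]:.2f}"
                    )
        for d in DIRECTIONS:
            got = rep.direction_accuracy.loc[d, g]
            want = PUBLISHED_DIRECTION_ACCURACY.loc[d, g]
            if abs(got - want) > 1e-9:
                problems.append(
                    f"direction accuracy {g}/{d}: computed {got:.2f} vs {want:.2f}"
                )
        if abs(rep.group_average[g] - PUBLISHED_GROUP_AVERAGE[g]) > 1e-9:
            problems.append(
                f"group average {g}: computed {rep.group_average[g]:.2f} "
                f"vs {PUBLISHED_GROUP_AVERAGE[g]:.2f}"
            )
        if abs(rep.weighted_rsot[g] - PUBLISHED_WEIGHTED_RSOT[g]) > 1e-9:
            problems.append(
                f"weighted score {g}: computed {rep.weighted_rsot[g]:.2f} "
                f"vs {PUBLISHED_WEIGHTED_RSOT[g]:.2f}"
            )
    return problems
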