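"""Stage-resolved ¹⁵N fate accounting within a clonal fragment.

Turns per-replicate isotope results into: organ allocation shares of the
applied dose (with unrecovered "loss"), dual-labelling source
contributions (the parent-ramet vs rhizome-root supply split for the
offspring ramet), treatment fold ratios, and between-stage backflow (net
withdrawal of previously allocated label).

Organ-to-ramet assignment follows the field design: leaf and culm belong
to the parent ramet, shoot and nascent leaf to the offspring ramet, the
rhizome connects them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .isotope_core import ORGANS, STAGE_ORDER, OverRecoveryWarning

__all__ = [
    "OFFSPRING_ORGANS",
    "PARENT_ORGANS",
    "allocation_fractions",
    "source_contribution",
    "backflow",
    "treatment_fold_ratio",
    "fate_panel",
    "contribution_table",
    "backflow_series",
]

PARENT_ORGANS = ("leaf", "culm")
OFFSPRING_ORGANS = ("shoot", "nascent_leaf")


@dataclass(frozen=True)
class Contribution:
    """Offspring N supply split between the two labelled sources, percent."""

    parent_share: float
    rhizome_share: float


def allocation_fractions(
    contents: dict[str, float], labelled_mass_g: float
) -> dict[str, float]:
    """Per-organ share of the applied dose plus the unrecovered loss.

    Returns a dict over the five organs plus ``"loss"``; entries sum to
    100 exactly. Shares summing above 100 raise an over-recovery warning
    (loss then goes negative) rather than an error — mass balance is the
    caller's diagnostic.
    """
    if labelled_mass_g <= 0:
        raise ValueError(f"labelled_mass_g must be positive, got {labelled_mass_g}")
    shares = {o: 100.0 * contents.get(o, 0.0) / labelled_mass_g for o in ORGANS}
    total = sum(shares.values())
    if total > 100.0 + 1e-9:
        warnings.warn(
            f"organ shares sum to {total:.4f}% > 100% of the dose",
            OverRecoveryWarning,
            stacklevel=2,
        )
    shares["loss"] = 100.0 - total
    return shares


def source_contribution(
    offspring_pl: float, offspring_rl: float
) -> Contribution:
    """Split offspring ¹⁵N between parent ramet and rhizome roots.

    With equal tracer doses in the two labelling treatments, the
    offspring ramet's label under parent labelling (PL) and rhizosphere
    labelling (RL) partition the supply:

        parent_share = 100 · PL / (PL + RL)

    The inputs may be contents (g) or dose-normalised recoveries (%), as
    long as both are on the same scale. The result is scale-invariant.
    """
    if offspring_pl < 0 or offspring_rl < 0:
        raise ValueError("offspring label quantities must be non-negative")
    total = offspring_pl + offspring_rl
    if total == 0:
        raise ValueError(
            "source contribution undefined: no label reached the offspring "
            "ramet in either treatment"
        )
    parent = 100.0 * offspring_pl / total
    return Contribution(parent_share=parent, rhizome_share=100.0 - parent)


def backflow(content_before: float, content_after: float) -> float:
    """Net withdrawal of label from a compartment between two stages, percent.

    100 · (before − after) / before. Negative values mean net gain and
    are returned as such.
    """
    if content_before <= 0:
        raise ValueError(
            f"content_before must be positive, got {content_before}"
        )
    return 100.0 * (content_before - content_after) / content_before


def treatment_fold_ratio(
    value_pl: float, value_rl: float, *, orientation: str = "pl_over_rl"
) -> float:
    """Fold ratio between the two labelling treatments.

    ``orientation`` selects the direction: ``"pl_over_rl"`` (default) or
    ``"rl_over_pl"``.
    """
    if orientation not in ("pl_over_rl", "rl_over_pl"):
        raise ValueError(f"unknown orientation {orientation!r}")
    num, den = (
        (value_pl, value_rl) if orientation == "pl_over_rl" else (value_rl, value_pl)
    )
    if den == 0:
        raise ZeroDivisionError("fold ratio denominator is zero")
    return num / den


# ---------------------------------------------------------------------------
# table-level accounting
# ---------------------------------------------------------------------------


def _mean_contents(results: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean ¹⁵N content (g) per (treatment, stage, organ)."""
    return (
        results.groupby(["treatment", "stage", "organ"], observed=True)[
            "n15_content_g"
        ]
        .mean()
        .reset_index()
    )


def fate_panel(results: pd.DataFrame, labelled_mass_g: float) -> pd.DataFrame:
    """Stage-by-treatment ¹⁵N fate: organ shares, loss, ramet recoveries.

    One row per (treatment, stage) with each organ's percentage of the
    dose, the unrecovered loss, and the parent / offspring / rhizome
    recoveries (sums of their organs' shares). Built from replicate-mean
    contents.
    """
    mean_contents = _mean_contents(results)
    rows = []
    for (treatment, stage), sub in mean_contents.groupby(
        ["treatment", "stage"], observed=True
    ):
        contents = dict(zip(sub["organ"], sub["n15_content_g"]))
        shares = allocation_fractions(contents, labelled_mass_g)
        row = {"treatment": treatment, "stage": stage, **shares}
        row["parent_recovery"] = sum(shares[o] for o in PARENT_ORGANS)
        row["offspring_recovery"] = sum(shares[o] for o in OFFSPRING_ORGANS)
        row["rhizome_recovery"] = shares["rhizome"]
        row["recovery"] = 100.0 - shares["loss"]
        rows.append(row)
    panel = pd.DataFrame(rows)
    panel["stage"] = pd.Categorical(panel["stage"], STAGE_ORDER, ordered=True)
    return panel.sort_values(["treatment", "stage"]).reset_index(drop=True)


def contribution_table(
    panel: pd.DataFrame, *, normalize_by_recovery: bool = False
) -> pd.DataFrame:
    """Per-stage parent vs rhizome-root contribution to the offspring ramet.

    Uses the dose-normalised offspring recoveries of the PL and RL rows
    of a fate panel (so unequal doses are already accounted for). With
    ``normalize_by_recovery`` the offspring recovery is first divided by
    the whole-fragment recovery of its treatment, i.e. loss is excluded
    before the split; the default compares shares of the applied dose.
    """
    wide = panel.pivot(index="stage", columns="treatment")
    rows = []
    for stage in [s for s in STAGE_ORDER if s in wide.index]:
        off_pl = wide.loc[stage, ("offspring_recovery", "PL")]
        off_rl = wide.loc[stage, ("offspring_recovery", "RL")]
        if normalize_by_recovery:
            off_pl /= wide.loc[stage, ("recovery", "PL")] / 100.0
            off_rl /= wide.loc[stage, ("recovery", "RL")] / 100.0
        contrib = source_contribution(off_pl, off_rl)
        rows.append(
            {
                "stage": stage,
                "parent_share": contrib.parent_share,
                "rhizome_share": contrib.rhizome_share,
            }
        )
    return pd.DataFrame(rows)


def backflow_series(
    panel: pd.DataFrame,
    treatment: str,
    compartment_organs: tuple[str, ...] = OFFSPRING_ORGANS,
) -> pd.DataFrame:
    """Between-stage net withdrawal from a compartment, percent per transition.

    Computed on replicate-mean label content (here: dose shares) of the
    organs forming the compartment, for consecutive stage pairs. A stage
    pair whose "before" content is zero is skipped.
    """
    sub = panel[panel["treatment"] == treatment].set_index("stage")
    totals = sum(sub[o] for o in compartment_organs)
    rows = []
    for before, after in zip(STAGE_ORDER[:-1], STAGE_ORDER[1:]):
        if before not in totals.index or after not in totals.index:
            continue
        if totals[before] <= 0:
            continue
        rows.append(
            {
                "from_stage": before,
                "to_stage": after,
                "backflow_pct": backflow(totals[before], totals[after]),
            }
        )
    return pd.DataFrame(rows)
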