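"""Per-neuron target/side selectivity taxonomy.

Trial firing rates with a 3-level target factor (E: empty, O: object,
S: social) and a 2-level side factor (L/R) are analysed with a two-way
ANOVA; the three target pairs are compared post hoc with Tukey's HSD, and
the left-right flag comes from the side main effect.  A unit is
X-specific when both pairwise comparisons involving target X are
significant.  The information number counts the significant pairs among
{S-E, S-O, E-O, L-R}.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .spikes import d_prime

__all__ = [
    "SelectivityRecord",
    "classify_selectivity",
    "venn_summary",
    "discrimination_profile",
]

TARGET_PAIRS = (("S", "E"), ("S", "O"), ("E", "O"))
SIDE_PAIR = ("L", "R")


@dataclass
class SelectivityRecord:
    unit_id: str
    pair_significant: dict[tuple[str, str], bool]
    specific_labels: set[str]
    information_number: int

    def __post_init__(self) -> None:
        if self.information_number != sum(self.pair_significant.values()):
            raise ValueError("information number must equal the count of "
                             "significant pairs")


def _pair_key(a: str, b: str) -> tuple[str, str]:
    for pair in TARGET_PAIRS + (SIDE_PAIR,):
        if {a, b} == set(pair):
            return pair
    raise KeyError((a, b))


def classify_selectivity(trial_rates: pd.DataFrame, alpha: float = 0.05,
                         unit_id: str = "") -> SelectivityRecord:
    """Classify one unit's target/side selectivity from its trial rates.

    ``trial_rates`` has columns (target, side, rate_hz) with one row per
    valid trial.  Pairwise target comparisons use Tukey's HSD at ``alpha``;
    the L-R flag uses the side main effect of a type-II two-way ANOVA.
    Comparisons with fewer than 2 trials in a required cell are marked
    non-significant with a warning.
    """
    df = trial_rates.copy()
    flags: dict[tuple[str, str], bool] = {p: False for p in TARGET_PAIRS}
    flags[SIDE_PAIR] = False

    target_counts = df.groupby("target")["rate_hz"].count()
    side_counts = df.groupby("side")["rate_hz"].count()

    evaluable_targets = [t for t in ("E", "O", "S")
                         if target_counts.get(t, 0) >= 2]
    if len(evaluable_targets) < len(("E", "O", "S")):
        warnings.warn(f"unit {unit_id!r}: insufficient trials for some "
                      "target levels; affected comparisons marked "
                      "non-significant", stacklevel=2)
    if len(evaluable_targets) >= 2:
        sub = df[df["target"].isin(evaluable_targets)]
        if sub["rate_hz"].nunique() > 1:
            tk = pairwise_tukeyhsd(sub["rate_hz"].to_numpy(),
                                   sub["target"].to_numpy(), alpha=alpha)
            for (g1, g2), rej in zip(
                    itertools.combinations(tk.groupsunique, 2), tk.reject):
                flags[_pair_key(g1, g2)] = bool(rej)

    side_ok = all(side_counts.get(s, 0) >= 2 for s in SIDE_PAIR)
    if not side_ok:
        warnings.warn(f"unit {unit_id!r}: insufficient trials per side; "
                      "L-R comparison marked non-significant", stacklevel=2)
    elif df["rate_hz"].nunique() > 1:
        try:
            model = smf.ols("rate_hz ~ C(target) + C(side)", data=df).fit()
            table = sm.stats.anova_lm(model, typ=2)
            p_side = float(table.loc["C(side)", "PR(>F)"])
            flags[SIDE_PAIR] = bool(p_side < alpha)
        except (ValueError, KeyError):
            warnings.warn(f"unit {unit_id!r}: side ANOVA not evaluable",
                          stacklevel=2)

    labels = set()
    if flags[("S", "E")] and flags[("S", "O")]:
        labels.add("S-specific")
    if flags[("S", "O")] and flags[("E", "O")]:
        labels.add("O-specific")
    if flags[("S", "E")] and flags[("E", "O")]:
        labels.add("E-specific")
    if flags[SIDE_PAIR]:
        labels.add("side")
    return SelectivityRecord(unit_id=unit_id, pair_significant=flags,
                             specific_labels=labels,
                             information_number=sum(flags.values()))


def venn_summary(records: list[SelectivityRecord]) -> pd.DataFrame:
    """Population proportions (%) over the three target-pair flags.

    Returns one row per Venn region of {S-E, S-O, E-O} (keys like
    ``S-E&S-O``; ``none`` is the outside region), each with the percentage
    of units in the region and, as the parenthetical overlay, the percentage
    additionally significant for side.  Marginal rows report the
    S/O/E-specific, side, side-only, and target-specific (any target pair)
    proportions.
    """
    if not records:
        raise ValueError("record list must be non-empty")
    n = len(records)
    rows = []
    names = ["S-E", "S-O", "E-O"]
    for combo in itertools.product([False, True], repeat=3):
        members = [r for r in records
                   if tuple(r.pair_significant[p] for p in TARGET_PAIRS)
                   == combo]
        label = "&".join(nm for nm, on in zip(names, combo) if on) or "none"
        with_side = sum(r.pair_significant[SIDE_PAIR] for r in members)
        rows.append({"region": label, "kind": "venn",
                     "proportion_pct": 100.0 * len(members) / n,
                     "side_overlay_pct": 100.0 * with_side / n})
    marg = {
        "S-specific": sum("S-specific" in r.specific_labels
                          for r in records),
        "O-specific": sum("O-specific" in r.specific_labels
                          for r in records),
        "E-specific": sum("E-specific" in r.specific_labels
                          for r in records),
        "side": sum(r.pair_significant[SIDE_PAIR] for r in records),
        "side-only": sum(r.pair_significant[SIDE_PAIR]
                         and not any(r.pair_significant[p]
                                     for p in TARGET_PAIRS)
                         for r in records),
        "target-specific": sum(any(r.pair_significant[p]
                                   for p in TARGET_PAIRS) for r in records),
    }
    for k, v in marg.items():
        rows.append({"region": k, "kind": "marginal",
                     "proportion_pct": 100.0 * v / n,
                     "side_overlay_pct": np.nan})
    return pd.DataFrame(rows)


def discrimination_profile(trial_rates: pd.DataFrame,
                           pair: tuple[str, str]) -> float:
    """d' between the trial-rate distributions of two targets."""
    g1 = trial_rates.loc[trial_rates["target"] == pair[0], "rate_hz"]
    g2 = trial_rates.loc[trial_rates["target"] == pair[1], "rate_hz"]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need at least 2 trials")
    return d_prime(g1.mean(), g1.std(ddof=1), g2.mean(), g2.std(ddof=1))
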