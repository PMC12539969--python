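"""Multi-species shield-length comparison.

The carapace shield length (SL) is the standard body-size index in pagurid
taxonomy.  This module implements the comparison protocol used to ask
whether a carcinoecium-hosting hermit crab grows larger than its congeners:
specimens are grouped by sex and ovigerous state, species with too few
individuals in a group are excluded, every remaining species is compared
with the focal species by Welch's t-test, and the significance threshold is
Bonferroni-adjusted by the number of comparisons within each group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError, UndefinedTestError
from .stats import sample_summary, welch_t

__all__ = [
    "GROUPS",
    "MIN_GROUP_N",
    "group_mask",
    "eligibility_filter",
    "comparison_counts",
    "pairwise_compare",
    "group_summary",
    "source_contrast",
    "plot_group_sizes",
]

GROUPS = ("nonovig_female", "ovig_female", "all_female", "male")

#: "more than two individuals": a species needs at least this many records
#: in a group to enter that group's comparisons
MIN_GROUP_N = 3

_REQUIRED = {"species", "sex", "ovigerous", "shield_length"}


def _check(records: pd.DataFrame):
    missing = _REQUIRED - set(records.columns)
    if missing:
        raise SchemaError(f"records table missing column(s): {sorted(missing)}")


def group_mask(records: pd.DataFrame, group: str) -> pd.Series:
    """Row mask of a sex/ovigery group."""
    if group == "male":
        return records["sex"] == "male"
    if group == "all_female":
        return records["sex"] == "female"
    if group == "nonovig_female":
        return (records["sex"] == "female") & (~records["ovigerous"].astype(bool))
    if group == "ovig_female":
        return (records["sex"] == "female") & (records["ovigerous"].astype(bool))
    raise SchemaError(f"unknown group {group!r}")


def eligibility_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Species × group table of record counts and eligibility.

    A species enters a group's comparison set only with more than two
    individuals in that group (n >= 3; the literal reading of the protocol,
    made explicit because a Welch test would technically run on n = 2).
    """
    _check(records)
    rows = []
    for species, sub in records.groupby("species", sort=True):
        for group in GROUPS:
            n = int(group_mask(sub, group).sum())
            rows.append({"species": species, "group": group, "n": n,
                         "eligible": n >= MIN_GROUP_N})
    return pd.DataFrame(rows)


def comparison_counts(records: pd.DataFrame, focal_species: str) -> dict:
    """Number of comparison species m per group, and the Bonferroni
    thresholds family_alpha/m they imply (reported at 3 d.p. elsewhere)."""
    elig = eligibility_filter(records)
    if focal_species not in set(records["species"]):
        raise SchemaError(f"focal species {focal_species!r} absent from records")
    out = {}
    for group in GROUPS:
        e = elig[(elig["group"] == group) & elig["eligible"]]
        species = set(e["species"])
        out[group] = len(species - {focal_species}) if focal_species in species else 0
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """One focal-vs-other Welch comparison within a group."""

    focal_species: str
    other_species: str
    group: str
    t: float
    df: float
    p_raw: float
    alpha_bonferroni: float
    significant: bool
    flag: str = ""


def pairwise_compare(records: pd.DataFrame, focal_species: str,
                     family_alpha: float = 0.05) -> pd.DataFrame:
    """All focal-vs-other Welch tests with per-group Bonferroni thresholds.

    The threshold within a group is ``family_alpha / m`` with m the number
    of eligible comparison species in that group (data-driven, never
    hard-coded).  Species pairs on which the test is undefined (both
    variances zero) are flagged, not dropped silently.  Output ordering is
    deterministic: group order, then species alphabetically.
    """
    _check(records)
    counts = comparison_counts(records, focal_species)
    elig = eligibility_filter(records)
    rows = []
    for group in GROUPS:
        m = counts[group]
        if m == 0:
            continue
        alpha = family_alpha / m
        gmask = group_mask(records, group)
        focal = records.loc[gmask & (records["species"] == focal_species),
                            "shield_length"].to_numpy()
        others = sorted(
            set(elig[(elig["group"] == group) & elig["eligible"]]["species"])
            - {focal_species})
        for sp in others:
            other = records.loc[gmask & (records["species"] == sp),
                                "shield_length"].to_numpy()
            try:
                res = welch_t(focal, other)
                rows.append(ComparisonResult(
                    focal_species, sp, group, res.t, res.df, res.p,
                    alpha, res.p <= alpha))
            except UndefinedTestError as exc:
                rows.append(ComparisonResult(
                    focal_species, sp, group, float("nan"), float("nan"),
                    float("nan"), alpha, False, flag=str(exc)))
    return pd.DataFrame([r.__dict__ for r in rows])


def group_summary(records: pd.DataFrame, species: str, group: str) -> dict:
    """n, mean, s.d., min, median, max (mm) for one species × group."""
    _check(records)
    vals = records.loc[
        group_mask(records, group) & (records["species"] == species),
        "shield_length"].to_numpy()
    if vals.size == 0:
        raise UndefinedTestError(f"no records for {species} in group {group}")
    s = sample_summary(vals)
    s["report"] = {k: round(s[k], 2) for k in ("mean", "sd", "min", "median", "max")
                   if not np.isnan(s[k])}
    return s


def source_contrast(records: pd.DataFrame, species: str) -> pd.DataFrame:
    """This-study vs literature Welch contrast for one species, per group.

    Compares the shield lengths of newly examined specimens (confirmed
    symbiotic association) with literature records of the same species.
    """
    _check(records)
    if "source" not in records.columns:
        raise SchemaError("records table missing column(s): ['source']")
    sub = records[records["species"] == species]
    rows = []
    for group in GROUPS:
        gmask = group_mask(sub, group)
        a = sub.loc[gmask & (sub["source"] == "this_study"), "shield_length"]
        b = sub.loc[gmask & (sub["source"] == "literature"), "shield_length"]
        if len(a) < 2 or len(b) < 2:
            continue
        res = welch_t(a.to_numpy(), b.to_numpy())
        rows.append({"group": group, "n_this_study": len(a),
                     "n_literature": len(b), "t": res.t, "df": res.df,
                     "p": res.p})
    return pd.DataFrame(rows)


def plot_group_sizes(records: pd.DataFrame, focal_species: str, path=None):
    """Violin plot of shield lengths per species, females and males.

    A plain overview figure (no publication styling); returns the
    matplotlib figure, optionally saving it to ``path``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _check(records)
    fig, axes = plt.subplots(2, 1, figsize=(10, 7), sharex=True)
    for ax, group in zip(axes, ("all_female", "male")):
        sub = records[group_mask(records, group)]
        species = sorted(sub["species"].unique())
        data = [sub.loc[sub["species"] == sp, "shield_length"].to_numpy()
                for sp in species]
        data = [d for d in data if d.size > 0]
        kept = [sp for sp in species
                if (sub["species"] == sp).any()]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(kept) + 1))
        ax.set_xticklabels(kept, rotation=75, fontsize=6)
        ax.set_ylabel("shield length (mm)")
        ax.set_title(group)
        if focal_species in kept:
            ax.axvline(kept.index(focal_species) + 1, color="pink", lw=8,
                       alpha=0.4, zorder=0)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
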