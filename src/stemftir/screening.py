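"""Bulk compound screening: linking cell-wall chemistry to rooting ability.

Per genotype, relative compound absorbances from the EMSC fits of its
bulk ATR spectra are averaged; compounds are then screened against the
rooting phenotype of the genotype panel (easy- vs difficult-to-root
groups, three adventitious-root formation percentages per genotype).

A compound is *eligible* for the group test when
(1) the relative percent difference (RPD) between group means exceeds
    the threshold (default 3), and
(2) its Pearson correlation with the rooting percentage is significant
    (two-sided p < alpha, default 0.05) for at least two of the three
    rooting traits.
Only eligible compounds receive a Mann-Whitney easy-vs-difficult test on
genotype-level means. The genotype, not the spectrum, is the observation
unit throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .emsc import EMSCFit
from .group_stats import mann_whitney, pearson
from .io_spectra import TRAIT_NAMES, SpectrumTable

__all__ = [
    "ScreeningRecord",
    "relative_percent_difference",
    "genotype_mean_relative_absorbance",
    "genotype_groups_and_traits",
    "screen_compounds",
    "correlation_matrix",
    "records_to_frame",
]


def relative_percent_difference(
    mean_a: float, mean_b: float, mode: str = "mean"
) -> float:
    """RPD between two group means, as a percentage.

    ``mean`` (default): 100 |a - b| / ((a + b) / 2) — the standard
    relative percent difference. ``reference``: 100 |a - b| / b.
    """
    if mode == "mean":
        denom = (mean_a + mean_b) / 2.0
    elif mode == "reference":
        denom = mean_b
    else:
        raise ValueError(f"unknown RPD mode {mode!r}")
    if denom == 0:
        raise ZeroDivisionError("zero denominator in RPD")
    return 100.0 * abs(mean_a - mean_b) / denom


@dataclass
class ScreeningRecord:
    compound: str
    mean_easy: float
    mean_difficult: float
    rpd: float
    r_by_trait: dict[str, tuple[float, float]]  # trait -> (r, p)
    n_significant_traits: int
    eligible: bool
    U: float | None = None
    p_mw: float | None = None
    group_difference: str = "none"  # higher_in_easy | higher_in_difficult | none
    predictive_performance: str = ""  # reserved reporting column, not computed


def genotype_mean_relative_absorbance(
    table: SpectrumTable, fits: list[EMSCFit]
) -> pd.DataFrame:
    """Genotype x compound matrix of mean relative absorbance.

    Averages per-spectrum relative absorbances over each genotype's
    (non-degenerate) spectra. Row order follows first appearance.
    """
    if len(fits) != table.n_samples:
        raise ValueError("one fit per spectrum required")
    names = list(fits[0].relative_absorbance.keys())
    rows = []
    for meta, fit in zip(table.meta, fits):
        if fit.degenerate:
            continue
        rows.append(
            {"genotype": meta.genotype, **{n: fit.relative_absorbance[n] for n in names}}
        )
    df = pd.DataFrame(rows)
    order = list(dict.fromkeys(df["genotype"]))
    return df.groupby("genotype", sort=False).mean().loc[order]


def _safe_pearson(x, y) -> tuple[float, float]:
    """Pearson (r, p); a constant input gives (nan, 1.0) — an undefined
    correlation can never count as a significant trait association."""
    try:
        return pearson(x, y)
    except ValueError:
        return math.nan, 1.0


def genotype_groups_and_traits(
    table: SpectrumTable,
) -> tuple[pd.Series, pd.DataFrame]:
    """(genotype -> group, genotype x trait matrix) from sample metadata."""
    rows = {}
    for m in table.meta:
        entry = rows.setdefault(m.genotype, {"group": m.group, **m.traits})
        if entry["group"] != m.group:
            raise ValueError(f"genotype {m.genotype} assigned to multiple groups")
    df = pd.DataFrame.from_dict(rows, orient="index")
    groups = df["group"]
    traits = df[[t for t in TRAIT_NAMES if t in df.columns]]
    return groups, traits


def screen_compounds(
    genotype_means: pd.DataFrame,
    groups: pd.Series,
    traits: pd.DataFrame,
    rpd_thresh: float = 3.0,
    alpha: float = 0.05,
    rpd_mode: str = "mean",
) -> list[ScreeningRecord]:
    """Screen every compound; records sorted by descending RPD.

    ``genotype_means``: genotype x compound relative absorbances.
    ``groups``: genotype -> 'easy' / 'difficult'. ``traits``: genotype x
    rooting-percentage matrix (three traits). Mann-Whitney (exact for
    the tie-free 15-genotype panel) is run only for eligible compounds.
    """
    groups = groups.reindex(genotype_means.index)
    traits = traits.reindex(genotype_means.index)
    if groups.isna().any():
        raise ValueError("missing group assignment for some genotypes")
    if traits.isna().any().any():
        raise ValueError("missing trait values for some genotypes")
    easy = genotype_means.index[groups == "easy"]
    difficult = genotype_means.index[groups == "difficult"]
    if len(easy) < 2 or len(difficult) < 2:
        raise ValueError("need at least 2 genotypes per rooting group")

    records = []
    for compound in genotype_means.columns:
        values = genotype_means[compound]
        mean_easy = float(values.loc[easy].mean())
        mean_difficult = float(values.loc[difficult].mean())
        rpd = relative_percent_difference(mean_easy, mean_difficult, mode=rpd_mode)
        r_by_trait = {}
        n_sig = 0
        for trait in traits.columns:
            r, p = _safe_pearson(values.to_numpy(), traits[trait].to_numpy())
            r_by_trait[trait] = (r, p)
            if p < alpha:
                n_sig += 1
        eligible = (rpd > rpd_thresh) and (n_sig >= 2)
        rec = ScreeningRecord(
            compound=compound,
            mean_easy=mean_easy,
            mean_difficult=mean_difficult,
            rpd=rpd,
            r_by_trait=r_by_trait,
            n_significant_traits=n_sig,
            eligible=eligible,
        )
        if eligible:
            U, p_mw = mann_whitney(
                values.loc[easy].to_numpy(), values.loc[difficult].to_numpy(), "auto"
            )
            rec.U, rec.p_mw = U, p_mw
            if p_mw < alpha:
                rec.group_difference = (
                    "higher_in_easy" if mean_easy > mean_difficult else "higher_in_difficult"
                )
        records.append(rec)
    records.sort(key=lambda r: -r.rpd)
    return records


def correlation_matrix(
    genotype_means: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Compound x trait matrix with (r, p) per cell, pairwise deletion."""
    traits = traits.reindex(genotype_means.index)
    out = {}
    for trait in traits.columns:
        col = {}
        t = traits[trait]
        for compound in genotype_means.columns:
            v = genotype_means[compound]
            ok = v.notna() & t.notna()
            col[compound] = _safe_pearson(v[ok].to_numpy(), t[ok].to_numpy())
        out[trait] = col
    return pd.DataFrame(out)


def records_to_frame(records: list[ScreeningRecord]) -> pd.DataFrame:
    """Flat screening table: one row per compound, RPD/r/p per trait/MW columns."""
    rows = []
    for r in records:
        row = {
            "compound": r.compound,
            "mean_easy": r.mean_easy,
            "mean_difficult": r.mean_difficult,
            "rpd": r.rpd,
            "n_significant_traits": r.n_significant_traits,
            "eligible": r.eligible,
            "U": r.U if r.U is not None else math.nan,
            "p_mw": r.p_mw if r.p_mw is not None else math.nan,
            "group_difference": r.group_difference,
            "predictive_performance": r.predictive_performance,
        }
        for trait, (rr, pp) in r.r_by_trait.items():
            row[f"r_{trait}"] = rr
            row[f"p_{trait}"] = pp
        rows.append(row)
    return pd.DataFrame(rows)
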