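"""Genotype comparison: normality check, one-way ANOVA, Tukey HSD, letters.

Reproduces the standard mutant-comparison table: per genotype a germination
index (%), a mean growth rate (mm/h), a compact letter display (two
genotypes share a letter iff their Tukey-adjusted p-value is >= alpha) and
the number N of roots actually measured.  Letters are assigned with the
insertion-absorption algorithm and verified against the pairwise matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .measurement import GrowthSummary

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonTable",
    "shapiro_normality",
    "anova_tukey",
    "compact_letter_display",
    "summarize_genotypes",
]


@dataclass
class ComparisonTable:
    """One comparison across genotypes.

    ``table`` has one row per genotype in input order with columns
    ``genotype``, ``germination_index`` (may be NaN when unknown),
    ``mean_rate_mm_per_h``, ``letters`` and ``n``.  ``pairwise`` is the
    symmetric matrix of Tukey-adjusted p-values.
    """

    table: pd.DataFrame
    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame
    alpha: float = 0.05

    def to_text(self) -> str:
        lines = [f"{'Genotype':<16}{'GI (%)':>8}{'Rate (mm/h)':>14}{'':>4}{'N':>5}"]
        for _, r in self.table.iterrows():
            gi = "" if pd.isna(r.germination_index) else f"{r.germination_index:.0f}"
            lines.append(
                f"{r.genotype:<16}{gi:>8}{r.mean_rate_mm_per_h:>14.5f}"
                f"{r.letters:>4}{r.n:>5d}"
            )
        lines.append(
            f"one-way ANOVA F = {self.anova_F:.4g}, p = {self.anova_p:.4g}; "
            f"Tukey HSD at alpha = {self.alpha}; genotypes sharing a letter "
            "are not significantly different"
        )
        return "\n".join(lines)


def shapiro_normality(sample) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for one sample."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def compact_letter_display(
    names: list[str], pairwise_p: np.ndarray, alpha: float = 0.05
) -> dict[str, str]:
    """Letters such that two groups share one iff adjusted p >= alpha.

    Insertion-absorption: start with every group in one letter column; for
    each significant pair split every column containing both; absorb
    subset columns; finally drop columns whose pairs and members are all
    covered elsewhere, so no letter can be deleted without breaking the
    sharing rule.
    """
    k = len(names)
    cols: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if pairwise_p[i, j] < alpha:
                for col in [c for c in cols if i in c and j in c]:
                    if col not in cols:
                        continue
                    cols.remove(col)
                    a, b = col - {i}, col - {j}
                    for new in (a, b):
                        if new and not any(new <= c for c in cols):
                            cols.append(new)
                    cols = [c for c in cols if not any(c < d for d in cols)]
    # minimality: drop columns that cover nothing unique
    changed = True
    while changed:
        changed = False
        for col in list(cols):
            others = [c for c in cols if c is not col]
            pairs_covered = all(
                any(i in c and j in c for c in others)
                for i in col
                for j in col
                if i < j
            )
            members_covered = all(any(i in c for c in others) for i in col)
            if others and pairs_covered and members_covered:
                cols.remove(col)
                changed = True
                break
    cols.sort(key=lambda c: min(c))
    letters = {name: "" for name in names}
    for letter_idx, col in enumerate(cols):
        ch = chr(ord("a") + letter_idx)
        for i in sorted(col):
            letters[names[i]] += ch
    return letters


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> ComparisonTable:
    """One-way ANOVA plus Tukey HSD with a compact letter display.

    ``groups`` maps group names to samples (each n >= 2, at least two
    groups).  Degenerate all-equal data yields F = 0 and all p = 1.
    """
    names = list(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for name, s in zip(names, samples):
        if len(s) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    k = len(names)
    if np.ptp(np.concatenate(samples)) == 0:
        F, p = 0.0, 1.0
        pmat = np.ones((k, k))
    else:
        F, p = sps.f_oneway(*samples)
        res = sps.tukey_hsd(*samples)
        pmat = np.asarray(res.pvalue)
    letters = compact_letter_display(names, pmat, alpha)
    table = pd.DataFrame(
        {
            "genotype": names,
            "germination_index": np.nan,
            "mean_rate_mm_per_h": [s.mean() for s in samples],
            "letters": [letters[n] for n in names],
            "n": [len(s) for s in samples],
        }
    )
    pairwise = pd.DataFrame(pmat, index=names, columns=names)
    return ComparisonTable(table, float(F), float(p), pairwise, alpha)


def summarize_genotypes(
    genotype_summaries: dict[str, list[GrowthSummary]],
    alpha: float = 0.05,
    check_normality: bool = True,
) -> ComparisonTable:
    """Tables-style comparison from per-seed growth summaries by genotype.

    The germination index counts every sown seed; N and the rate statistics
    count only seeds with a defined growth rate (germinated, >= 3 fit
    samples), which is why N can be below the plated count.  Genotypes with
    fewer than 2 measurable seeds are excluded with a warning.  Normality
    failures warn but do not abort.
    """
    rates: dict[str, np.ndarray] = {}
    gi: dict[str, float] = {}
    for name, summaries in genotype_summaries.items():
        if not summaries:
            warnings.warn(f"genotype {name!r} has no seeds; excluded", stacklevel=2)
            continue
        r = np.array(
            [s.rate_mm_per_h for s in summaries if s.rate_mm_per_h is not None]
        )
        if len(r) < 2:
            warnings.warn(
                f"genotype {name!r} has {len(r)} measurable seeds; excluded",
                stacklevel=2,
            )
            continue
        rates[name] = r
        gi[name] = 100.0 * sum(
            1 for s in summaries if s.germ_h is not None
        ) / len(summaries)
        if check_normality and np.ptp(r) > 0 and len(r) >= 3:
            _, p_norm = shapiro_normality(r)
            if p_norm < 0.05:
                warnings.warn(
                    f"growth rates of {name!r} fail Shapiro-Wilk "
                    f"normality (p = {p_norm:.3g})",
                    stacklevel=2,
                )
    if not rates:
        raise ValueError("no genotype has enough measurable seeds")
    if len(rates) == 1:
        (name, r), = rates.items()
        table = pd.DataFrame(
            {
                "genotype": [name],
                "germination_index": [gi[name]],
                "mean_rate_mm_per_h": [r.mean()],
                "letters": ["a"],
                "n": [len(r)],
            }
        )
        pairwise = pd.DataFrame([[1.0]], index=[name], columns=[name])
        return ComparisonTable(table, float("nan"), float("nan"), pairwise, alpha)
    result = anova_tukey(rates, alpha)
    result.table["germination_index"] = [gi[n] for n in result.table.genotype]
    return result
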