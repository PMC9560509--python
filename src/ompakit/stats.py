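"""Cohort statistics for allele-phenotype and allele-distribution analysis.

The statistical conventions follow the source study exactly: single-factor
ANOVA; two-tailed Student's (pooled-variance) t-tests with a severe fixed
significance cutoff of p < 0.005 and compact-letter-display grouping;
correlations judged significant when the 95% confidence interval of the
least-squares slope excludes zero; Fisher's exact test (two-tailed,
"probability at most that of the observed table" convention) at p < 1e-5 for
allele-distribution enrichment; and the chi-square test of homogeneity for
the r x c comparison attributed to prior work. No multiple-testing
correction is applied anywhere — the fixed cutoffs are the control.

Count tables can be reconstructed from printed percentage summaries; such
tables are labelled as reconstructions and percentage -> count conversion
rounds half away from zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio

DEFAULT_ALPHA = 0.005
ENRICHMENT_ALPHA = 1e-5
LUMP_THRESHOLD = 10


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def one_way_anova(groups) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA.

    `groups` is a sequence (or dict) of replicate arrays, one per level.
    Degenerate input where every observation is identical returns
    ``(F=0, p=1)``.
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 replicates")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    if all(np.ptp(g) == 0 for g in arrays):
        # zero within-group variance with distinct means: F is infinite
        return math.inf, 0.0
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def pooled_t_test(a, b) -> float:
    """Two-tailed Student's t-test p-value (pooled variance).

    A zero-variance pair with equal means is treated as non-significant
    (p = 1); zero variance with different means gives p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


# ---------------------------------------------------------------------------
# Compact letter display
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LetterGrouping:
    """Compact letter display: two groups share a letter iff their pairwise
    test was non-significant at `alpha`."""

    letters: dict[str, str]            # group -> concatenated letters
    alpha: float
    test: str
    pvalues: pd.DataFrame = field(repr=False, default=None)

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))

    def n_groups(self) -> int:
        return len({letter for s in self.letters.values() for letter in s})


def pairwise_letter_groups(groups: dict, alpha: float = DEFAULT_ALPHA) -> LetterGrouping:
    """All-pairs pooled-variance t-tests with insert-and-absorb letter
    assignment, so that sharing a letter is exactly equivalent to
    non-significance at `alpha`."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    pmat = pd.DataFrame(1.0, index=names, columns=names, dtype=float)
    for a, b in itertools.combinations(names, 2):
        p = pooled_t_test(groups[a], groups[b])
        pmat.loc[a, b] = pmat.loc[b, a] = p

    # insert-and-absorb: start from one all-inclusive set; for each
    # significant pair split every set containing both, then absorb subsets.
    sets: list[set[str]] = [set(names)]
    for a, b in itertools.combinations(names, 2):
        if pmat.loc[a, b] >= alpha:
            continue
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        sets = [s for s in new_sets if s]
        sets = [s for s in sets if not any(s < t for t in sets)]
        # drop duplicates, keep deterministic order
        seen, uniq = set(), []
        for s in sets:
            key = frozenset(s)
            if key not in seen:
                seen.add(key)
                uniq.append(s)
        sets = uniq

    sets.sort(key=lambda s: min(names.index(m) for m in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {n: "" for n in names}
    for i, s in enumerate(sets):
        for member in names:
            if member in s:
                letters[member] += alphabet[i % len(alphabet)]

    grouping = LetterGrouping(letters=letters, alpha=alpha, test="pooled-t", pvalues=pmat)
    for a, b in itertools.combinations(names, 2):  # soundness biconditional
        assert grouping.share_letter(a, b) == (pmat.loc[a, b] >= alpha), (a, b)
    return grouping


# ---------------------------------------------------------------------------
# Slope-CI association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlopeAssociation:
    slope: float
    intercept: float
    ci: tuple[float, float]
    conf: float
    significant: bool     # CI excludes zero
    stderr: float
    n: int


def slope_ci_association(x, y, conf: float = 0.95) -> SlopeAssociation:
    """Ordinary least-squares slope with a t-based confidence interval;
    the association is significant iff the CI excludes zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    res = stats.linregress(x, y)
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    tcrit = stats.t.ppf(1.0 - (1.0 - conf) / 2.0, x.size - 2)
    lo, hi = res.slope - tcrit * stderr, res.slope + tcrit * stderr
    significant = bool(lo > 0 or hi < 0)
    return SlopeAssociation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci=(float(lo), float(hi)),
        conf=conf,
        significant=significant,
        stderr=stderr,
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# Sequence-position vs phenotype scan
# ---------------------------------------------------------------------------

def position_phenotype_scan(
    allele_values: dict,
    scheme,
    level: str = "replicate",
) -> pd.DataFrame:
    """Test each classification site for association with a phenotype.

    `allele_values` maps ``(nterm, cterm)`` tuples to replicate arrays. Each
    site partitions the alleles into residue classes through the scheme's
    patterns; two classes are compared by a pooled t-test, more by one-way
    ANOVA, and single-class sites are reported untestable. ``level`` selects
    whether replicate values are pooled (default) or first collapsed to
    allele means.
    """
    if level not in ("replicate", "allele_mean"):
        raise ValueError(f"unknown level {level!r}")
    rows = []
    sites: list[tuple[str, object]] = [("nterm", s.name) for s in scheme.nterm_sites]
    sites += [("cterm", pos) for pos in scheme.cterm_sites]
    for domain, site in sites:
        classes: dict[str, list[float]] = {}
        for (nterm, cterm), values in allele_values.items():
            residue = (
                scheme.nterm_patterns[nterm][site]
                if domain == "nterm"
                else scheme.cterm_patterns[cterm][site]
            )
            vals = list(np.atleast_1d(np.asarray(values, dtype=float)))
            if level == "allele_mean":
                vals = [float(np.mean(vals))]
            classes.setdefault(residue, []).extend(vals)
        label = f"{site}" if domain == "nterm" else f"pos{site}"
        if len(classes) < 2:
            rows.append({"site": label, "n_classes": len(classes), "p": np.nan, "testable": False})
            continue
        arrays = list(classes.values())
        n_total = sum(len(a) for a in arrays)
        # residual degrees of freedom must remain after fitting class means
        df_ok = (n_total - len(arrays) >= 1) if level == "allele_mean" else all(
            len(a) >= 2 for a in arrays)
        if not df_ok:
            rows.append({"site": label, "n_classes": len(classes), "p": np.nan, "testable": False})
            continue
        if len(arrays) == 2:
            if level == "allele_mean":
                p = float(stats.ttest_ind(arrays[0], arrays[1], equal_var=True).pvalue)
            else:
                p = pooled_t_test(arrays[0], arrays[1])
        elif level == "allele_mean":
            p = float(stats.f_oneway(*arrays).pvalue)
        else:
            _, p = one_way_anova(arrays)
        rows.append({"site": label, "n_classes": len(classes), "p": p, "testable": True})
    return pd.DataFrame(rows, columns=["site", "n_classes", "p", "testable"])


# ---------------------------------------------------------------------------
# Exact and chi-square tests on count tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FisherResult:
    p: float
    odds_ratio: float        # conditional MLE
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False # a zero margin; p = 1 by convention


def fisher_2x2(table) -> FisherResult:
    """Two-tailed Fisher's exact test with conditional odds ratio.

    Two-tailed p sums the probabilities of all tables (same margins) whose
    hypergeometric probability does not exceed the observed one. A zero
    margin yields p = 1, flagged degenerate.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    tup = ((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1])))
    if 0 in (*t.sum(axis=0), *t.sum(axis=1)):
        return FisherResult(p=1.0, odds_ratio=math.nan, table=tup, degenerate=True)
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    orat = float(_conditional_odds_ratio(t, kind="conditional").statistic)
    return FisherResult(p=min(p, 1.0), odds_ratio=orat, table=tup)


def chi_square_homogeneity(table) -> tuple[float, int, float, bool]:
    """Pearson chi-square test of homogeneity on an r x c table.

    Returns ``(chi2, df, p, adequate)`` where `adequate` is False when more
    than 20% of expected counts fall below 5 (the classical rule of thumb).
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, df, expected = stats.chi2_contingency(t, correction=False)
    adequate = bool((expected < 5).mean() <= 0.20)
    return float(chi2), int(df), float(p), adequate


# ---------------------------------------------------------------------------
# Count tables and enrichment
# ---------------------------------------------------------------------------

def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class CountTable:
    """Isolate carrier counts per group x allele, with known group sizes.

    `counts.loc[group, allele]` is the number of isolates in `group` carrying
    `allele`; `group_sizes[group]` is the cohort size, so non-carriers are
    ``group_sizes[group] - counts.loc[group, allele]``.
    """

    counts: pd.DataFrame
    group_sizes: pd.Series
    reconstructed: bool = False

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for g in self.counts.index:
            if g not in self.group_sizes.index:
                raise ValueError(f"no group size for {g}")
            if self.counts.loc[g].sum() > self.group_sizes[g]:
                raise ValueError(f"counts in group {g} exceed its size")

    @classmethod
    def from_calls(cls, df: pd.DataFrame, group_col: str = "group", allele_col: str = "allele"):
        counts = df.groupby([group_col, allele_col]).size().unstack(fill_value=0)
        return cls(counts=counts, group_sizes=counts.sum(axis=1), reconstructed=False)

    @classmethod
    def from_group_percentages(cls, percentages: dict, group_sizes: dict):
        """Reconstruct counts from per-group percentages: `percentages` maps
        allele -> {group: percent of the group carrying it}."""
        sizes = pd.Series(group_sizes, dtype=int)
        groups = list(sizes.index)
        alleles = list(percentages)
        counts = pd.DataFrame(0, index=groups, columns=alleles, dtype=int)
        for allele, by_group in percentages.items():
            for group, pct in by_group.items():
                if pct < 0 or pct > 100:
                    raise ValueError(f"percentage out of range for {allele}/{group}: {pct}")
                counts.loc[group, allele] = round_half_away(pct / 100.0 * sizes[group])
        for g in groups:
            listed_pct = sum(by_group.get(g, 0) for by_group in percentages.values())
            if listed_pct > 100:
                raise ValueError(f"percentages in group {g} sum above 100%")
        return cls(counts=counts, group_sizes=sizes, reconstructed=True)

    @classmethod
    def from_allele_percentages(cls, allele_n: dict, percentages: dict, group_sizes: dict):
        """Reconstruct counts from per-allele shares: `percentages` maps
        allele -> {group: percent of the allele's isolates found there}."""
        sizes = pd.Series(group_sizes, dtype=int)
        counts = pd.DataFrame(0, index=list(sizes.index), columns=list(allele_n), dtype=int)
        for allele, by_group in percentages.items():
            for group, pct in by_group.items():
                if group not in sizes.index:
                    continue
                counts.loc[group, allele] = round_half_away(pct / 100.0 * allele_n[allele])
        return cls(counts=counts, group_sizes=sizes, reconstructed=True)

    def lump_rare(self, threshold: int = LUMP_THRESHOLD, label: str = "other") -> "CountTable":
        """Pool alleles whose total count falls below `threshold`."""
        totals = self.counts.sum(axis=0)
        rare = [a for a in self.counts.columns if totals[a] < threshold]
        if not rare:
            return self
        kept = self.counts.drop(columns=rare)
        kept[label] = self.counts[rare].sum(axis=1)
        return CountTable(counts=kept, group_sizes=self.group_sizes, reconstructed=self.reconstructed)

    def carrier_table(self, allele: str, group_a: str, group_b: str) -> np.ndarray:
        """2x2 carrier/non-carrier table for one allele and two groups."""
        ca = int(self.counts.loc[group_a, allele])
        cb = int(self.counts.loc[group_b, allele])
        return np.array(
            [[ca, int(self.group_sizes[group_a]) - ca],
             [cb, int(self.group_sizes[group_b]) - cb]]
        )


@dataclass(frozen=True)
class EnrichmentResult:
    allele: str
    group_a: str
    group_b: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    significant: bool
    enriched_in: str       # group with the higher carrier frequency


def enrichment_scan(table: CountTable, alpha: float = ENRICHMENT_ALPHA) -> pd.DataFrame:
    """Fisher's exact test for every allele and every unordered group pair.

    Returns a DataFrame sorted by p with the 2x2 cells, conditional odds
    ratio, exact p, and a significance flag at `alpha`.
    """
    groups = list(table.counts.index)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for allele in table.counts.columns:
        for ga, gb in itertools.combinations(groups, 2):
            t = table.carrier_table(allele, ga, gb)
            res = fisher_2x2(t)
            fa = t[0, 0] / table.group_sizes[ga]
            fb = t[1, 0] / table.group_sizes[gb]
            rows.append(
                {
                    "allele": allele,
                    "group_a": ga,
                    "group_b": gb,
                    "a_carriers": int(t[0, 0]),
                    "a_noncarriers": int(t[0, 1]),
                    "b_carriers": int(t[1, 0]),
                    "b_noncarriers": int(t[1, 1]),
                    "odds_ratio": res.odds_ratio,
                    "p": res.p,
                    "significant": bool(res.p < alpha),
                    "enriched_in": ga if fa >= fb else gb,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values("p", kind="stable").reset_index(drop=True)
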