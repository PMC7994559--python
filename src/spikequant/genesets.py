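"""Gene-set overlap enrichment and target-set fold-change comparisons.

Overlap enrichment follows the ChEA/Enrichr convention: a one-sided
Fisher exact (hypergeometric tail) test of the 2x2 membership table of a
query list against each annotation set, restricted to a declared gene
universe, with BH adjustment across annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class DegenerateInputError(ValueError):
    pass


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]

    def __init__(self, name: str, members) -> None:
        self.name = name
        self.members = frozenset(members)

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(self.name, self.members & other.members)


def fisher_overlap(
    query: GeneSet,
    annotations: Sequence[GeneSet],
    universe: GeneSet,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher-exact overlap enrichment of a query list against annotation sets.

    Per annotation (intersected with the universe first), the 2x2 table
    of query membership x set membership is tested one-sided for
    enrichment (hypergeometric upper tail); the odds ratio comes from the
    same table and p-values are BH-adjusted across annotations.  An
    annotation disjoint from the universe yields a degenerate row
    (k = K = 0, p = 1).
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    if not query.members <= universe.members:
        raise ValueError("query is not a subset of the universe")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for annotation in annotations:
        ann = annotation.members & universe.members
        k = len(query.members & ann)
        K = len(ann)
        table = np.array(
            [
                [k, n_query - k],
                [K - k, n_universe - n_query - (K - k)],
            ]
        )
        if K == 0:
            odds, p, degenerate = np.nan, 1.0, True
        else:
            odds, p = stats.fisher_exact(table, alternative=alternative)
            degenerate = False
        rows.append(
            {
                "set": annotation.name,
                "overlap": k,
                "query_size": n_query,
                "set_size": K,
                "universe_size": n_universe,
                "odds_ratio": odds,
                "pvalue": p,
                "degenerate": degenerate,
            }
        )
    result = pd.DataFrame(rows).set_index("set")
    _, padj, _, _ = multipletests(result["pvalue"], method="fdr_bh")
    result["padj"] = padj
    return result.sort_values("padj")


def percent_overlap(a: GeneSet, b: GeneSet) -> float:
    """Percentage of a's members found in b (0-100, unrounded)."""
    if len(a) == 0:
        raise DegenerateInputError("percent overlap of an empty set is undefined")
    return 100.0 * len(a.members & b.members) / len(a)


def percent_overlap_report(a: GeneSet, b: GeneSet) -> int:
    """Reporting helper: percent overlap rounded to the nearest whole percent."""
    return int(round(percent_overlap(a, b)))


def random_subset(universe: GeneSet, n: int, seed: int) -> GeneSet:
    """Uniform sample of n members without replacement, reproducible given seed."""
    members = sorted(universe.members)
    if n > len(members):
        raise ValueError(f"cannot draw {n} genes from a universe of {len(members)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(members), size=n, replace=False)
    return GeneSet(f"{universe.name}_subset{n}", {members[i] for i in chosen})


def _box_summary(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
        "n": int(values.size),
    }


def geneset_shift(
    fc: pd.Series,
    target: GeneSet,
    background: GeneSet,
    extra_sets: Optional[Sequence[GeneSet]] = None,
) -> dict:
    """Compare fold-change distributions of a target gene set against background.

    ``fc`` maps gene -> log2 fold-change.  Returns boxplot summaries
    (median/quartile hinges, +/-1.5*IQR whiskers) per group, a one-way
    ANOVA across groups, and pairwise two-sided Wilcoxon rank-sum tests.
    """
    groups: dict[str, np.ndarray] = {}
    for gs in [target, background, *(extra_sets or [])]:
        members = [g for g in gs.members if g in fc.index]
        if not members:
            raise DegenerateInputError(
                f"gene set {gs.name!r} has no members with fold-changes"
            )
        groups[gs.name] = fc.loc[members].to_numpy(dtype=float)

    names = list(groups)
    summaries = {name: _box_summary(vals) for name, vals in groups.items()}
    if len(names) >= 2:
        _, anova_p = stats.f_oneway(*groups.values())
    else:
        anova_p = np.nan
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.array_equal(np.sort(groups[a]), np.sort(groups[b])):
                pairwise[(a, b)] = 1.0
            else:
                _, p = stats.ranksums(groups[a], groups[b])
                pairwise[(a, b)] = float(p)
    return {"summaries": summaries, "anova_p": float(anova_p), "pairwise": pairwise}


def read_gene_set(path, name: Optional[str] = None) -> GeneSet:
    """Read a one-column gene list (or two-column set/gene TSV filtered by name)."""
    genes = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                genes.append(fields[0])
            else:
                if name is None or fields[0] == name:
                    genes.append(fields[1])
    return GeneSet(name or "genes", genes)
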