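"""Statistical tests for selection: directional coherence and niche
enrichment.

The directional (sign) test asks whether trait-increasing alleles of
nearby QTLs come from the same parent more often than the fair-coin
expectation under neutrality — positive selection on a trait in one
lineage enriches that lineage for alleles of coherent effect.  The niche
test asks whether the carriers of a rare shared variant (present in two or
three strains) are drawn from one ecological niche more often than
expected under neutral, branch-length-proportional placement of variants
on the strain tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .trees import PhyloTree

__all__ = [
    "CoherenceResult",
    "NicheSharingResult",
    "NicheNullResult",
    "coherence_vs_distance",
    "niche_sharing_fraction",
    "niche_null_distribution",
]

_QTL_COLUMNS = {"trait", "chrom", "marker_index", "high_parent"}


@dataclass(frozen=True)
class CoherenceResult:
    """Per-distance-bin coherence of QTL effect direction."""

    per_bin: pd.DataFrame = field(repr=False)
    # pooled across all pairs within max_distance
    pooled_fraction: float = float("nan")
    pooled_p: float = float("nan")
    n_pairs: int = 0


def _pairs_for_trait(df: pd.DataFrame, max_distance: int) -> pd.DataFrame:
    rows = []
    for chrom, grp in df.groupby("chrom", observed=True):
        idx = grp["marker_index"].to_numpy()
        par = grp["high_parent"].to_numpy()
        k = len(idx)
        for i in range(k):
            for j in range(i + 1, k):
                d = abs(int(idx[i]) - int(idx[j]))
                if 0 < d <= max_distance:
                    rows.append((d, par[i] == par[j]))
    return pd.DataFrame(rows, columns=["distance", "coherent"])


def coherence_vs_distance(
    qtls: pd.DataFrame,
    max_distance: int = 500,
    bin_edges: Sequence[int] | None = None,
) -> CoherenceResult:
    """Fraction of same-parent (coherent) QTL pairs by genetic distance.

    ``qtls`` needs columns trait, chrom, marker_index (genome-ordered
    marker units) and high_parent (which parent contributes the
    trait-increasing allele).  Pairs are formed within trait and
    chromosome; distance is measured in markers.  Each bin reports the
    pooled coherent fraction, the across-trait mean +/- s.e.m., and a
    two-sided binomial test against the no-coherence expectation of 0.5.
    Coherence is about sameness of origin, so the result is invariant to
    relabeling the two parents.
    """
    if not _QTL_COLUMNS <= set(qtls.columns):
        raise ValueError(f"qtls needs columns {sorted(_QTL_COLUMNS)}")
    if len(qtls) < 2:
        raise ValueError("need at least two QTLs")
    if bin_edges is None:
        step = max(1, max_distance // 5)
        bin_edges = list(range(0, max_distance + step, step))
    bin_edges = list(bin_edges)

    per_trait = {
        trait: _pairs_for_trait(grp, max_distance)
        for trait, grp in qtls.groupby("trait", observed=True)
    }
    all_pairs = pd.concat(
        [p.assign(trait=t) for t, p in per_trait.items() if len(p)],
        ignore_index=True,
    ) if any(len(p) for p in per_trait.values()) else pd.DataFrame(
        columns=["distance", "coherent", "trait"]
    )

    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sel = all_pairs[(all_pairs["distance"] > lo) & (all_pairs["distance"] <= hi)]
        n = len(sel)
        if n == 0:
            rows.append(
                {
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "n_pairs": 0,
                    "fraction": np.nan,
                    "trait_mean": np.nan,
                    "trait_sem": np.nan,
                    "p_binomial": np.nan,
                }
            )
            continue
        k = int(sel["coherent"].sum())
        frac_by_trait = sel.groupby("trait", observed=True)["coherent"].mean()
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n_pairs": n,
                "fraction": k / n,
                "trait_mean": float(frac_by_trait.mean()),
                "trait_sem": float(frac_by_trait.sem()) if len(frac_by_trait) > 1 else np.nan,
                "p_binomial": stats.binomtest(k, n, 0.5).pvalue,
            }
        )
    n_all = len(all_pairs)
    if n_all:
        k_all = int(all_pairs["coherent"].sum())
        pooled_p = stats.binomtest(k_all, n_all, 0.5).pvalue
        pooled_frac = k_all / n_all
    else:
        pooled_p = float("nan")
        pooled_frac = float("nan")
    return CoherenceResult(
        per_bin=pd.DataFrame(rows),
        pooled_fraction=pooled_frac,
        pooled_p=pooled_p,
        n_pairs=n_all,
    )


@dataclass(frozen=True)
class NicheSharingResult:
    fraction: float
    n_variants: int
    n_same_niche: int
    multiplicity: int


def niche_sharing_fraction(
    m: GenotypeMatrix,
    niches: Mapping[str, str],
    multiplicity: int,
    *,
    synonymous_only: bool = False,
) -> NicheSharingResult:
    """Fraction of k-occurrence variants whose carriers share one niche.

    Only variants whose alternate allele occurs in exactly ``multiplicity``
    (2 or 3) strains are considered; variants in four or more strains are
    excluded upstream because too few niches have that many isolates for a
    fair null.  Every carrier must have a niche label.
    """
    if multiplicity not in (2, 3):
        raise ValueError("multiplicity must be 2 or 3")
    calls = m.calls
    keep = np.ones(m.n_loci, dtype=bool)
    if synonymous_only:
        keep &= (m.variants["functional_class"] == "synonymous").to_numpy()
    k_alt = (calls == 1).sum(axis=0)
    keep &= k_alt == multiplicity
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        raise ValueError(f"no variants with multiplicity {multiplicity}")
    labels = []
    for s in m.strains:
        if s not in niches or not niches[s]:
            raise ValueError(f"strain {s!r} has no niche label")
        labels.append(niches[s])
    labels = np.array(labels)
    same = 0
    for j in idx:
        carriers = labels[calls[:, j] == 1]
        if len(set(carriers)) == 1:
            same += 1
    return NicheSharingResult(
        fraction=same / len(idx),
        n_variants=int(len(idx)),
        n_same_niche=int(same),
        multiplicity=multiplicity,
    )


@dataclass(frozen=True)
class NicheNullResult:
    """Neutral expectation for niche sharing plus permutation p-values.

    ``p_values[k]`` uses the add-one convention (never exactly zero) and
    is the probability, under neutral branch-proportional placement, of a
    sharing fraction at least as large as observed.
    """

    replicates: pd.DataFrame = field(repr=False)
    null_means: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    observed: dict = field(default_factory=dict)


def niche_null_distribution(
    tree: PhyloTree,
    niches: Mapping[str, str],
    n_variants: int,
    n_reps: int = 50,
    rng: np.random.Generator | None = None,
    *,
    multiplicities: Sequence[int] = (2, 3),
    observed: Mapping[int, float] | None = None,
) -> NicheNullResult:
    """Null distribution of same-niche sharing under neutral placement.

    Each replicate drops ``n_variants`` on the strain tree with
    probability proportional to branch length and propagates them to all
    descendant leaves; a branch with exactly k descendant leaves therefore
    yields k-occurrence variants whose carriers (and hence niche
    concordance) are fixed by the topology, so only the per-branch
    multinomial counts need simulating.  The permutation p-value for an
    observed fraction is (1 + #{replicates >= observed}) / (n_reps + 1).
    """
    rng = rng if rng is not None else np.random.default_rng()
    strains = sorted(tree.leaf_names)
    for s in strains:
        if s not in niches or not niches[s]:
            raise ValueError(f"strain {s!r} has no niche label")
    lengths, desc = tree.edge_descendants(strain_order=strains)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("tree must have positive total branch length")
    labels = np.array([niches[s] for s in strains])
    k_branch = np.array([len(d) for d in desc])
    same_branch = np.array([len(set(labels[d])) == 1 for d in desc])

    rows = []
    for rep in range(n_reps):
        counts = rng.multinomial(n_variants, lengths / total)
        for k in multiplicities:
            mask = k_branch == k
            denom = int(counts[mask].sum())
            numer = int(counts[mask & same_branch].sum())
            rows.append(
                {
                    "replicate": rep,
                    "multiplicity": k,
                    "n_variants": denom,
                    "fraction": numer / denom if denom else np.nan,
                }
            )
    df = pd.DataFrame(rows)
    null_means = {
        int(k): float(g["fraction"].mean())
        for k, g in df.groupby("multiplicity")
    }
    p_values: dict = {}
    obs_out: dict = {}
    if observed is not None:
        for k, frac in observed.items():
            null = df[df["multiplicity"] == k]["fraction"].dropna().to_numpy()
            p_values[int(k)] = (1 + int((null >= frac).sum())) / (len(null) + 1)
            obs_out[int(k)] = float(frac)
    return NicheNullResult(
        replicates=df, null_means=null_means, p_values=p_values, observed=obs_out
    )
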