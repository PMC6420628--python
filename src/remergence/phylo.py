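"""SNP distances, neighbor joining, and sliding-window local phylogeny.

Admixed genomes have no single phylogeny: different chromosomal segments
descend from different parents.  The scan machinery therefore rebuilds a
neighbor-joining tree for every variant from a window of surrounding
variants (default 500), truncated at chromosome boundaries because
mosaicism is per-chromosome.  Local trees are midpoint-rooted: the
emergence rules need a rooted binary tree and no outgroup exists within a
window.

Determinism: NJ joins and modal-genotype ties are broken by fixed rules
(lowest strain-name pair; ties toward the reference allele), so identical
inputs always produce identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from .genotypes import MISSING, GenotypeMatrix
from .trees import PhyloTree

__all__ = [
    "DistanceMatrix",
    "WindowSpec",
    "snp_distance_matrix",
    "neighbor_joining",
    "local_tree_for_variant",
    "identity_track",
    "collapse_clade_to_modal",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window configuration: ``width`` is measured in variants."""

    width: int = 500

    def __post_init__(self) -> None:
        if self.width < 4:
            raise ValueError("window width must be >= 4 variants")

    def bounds(self, idx: int, chrom_start: int, chrom_end: int) -> tuple[int, int]:
        """Window [lo, hi) of up to ``width`` variants centered on ``idx``,
        truncated (never wrapped) at the chromosome boundaries."""
        lo = max(chrom_start, idx - self.width // 2)
        hi = lo + self.width
        if hi > chrom_end:
            hi = chrom_end
            lo = max(chrom_start, hi - self.width)
        return lo, hi


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise SNP-difference counts."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.names):
            raise ValueError("distance matrix shape inconsistent with names")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v


def snp_distance_matrix(
    m: GenotypeMatrix, *, normalize: bool = False
) -> DistanceMatrix:
    """Pairwise SNP differences: loci where both strains are called and the
    calls differ.  Loci missing in either member of a pair are excluded for
    that pair only.

    With ``normalize=True`` each entry is divided by the pair's co-called
    locus count (a per-site difference rate); raw counts are the default.
    """
    if m.n_strains < 3:
        raise ValueError("need at least 3 strains")
    D = K.pair_differences(m.calls)
    if normalize:
        called = (m.calls != MISSING).astype(np.float64)
        cocalled = called @ called.T
        np.fill_diagonal(cocalled, 1.0)
        D = D / np.maximum(cocalled, 1.0)
    return DistanceMatrix(list(m.strains), D)


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Taxa are processed in name-sorted order so that Q-criterion ties join
    the lowest strain-name pair first; negative branch-length estimates are
    clamped to zero.  Returns an unrooted tree.
    """
    n = len(d.names)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    order = np.argsort(np.array(d.names))
    names = [d.names[i] for i in order]
    D = d.values[np.ix_(order, order)]
    eu, ev, el = K.nj_edges(np.ascontiguousarray(D, dtype=np.float64))
    return PhyloTree.unrooted_from_edges(eu, ev, el, names)


def _sorted_strain_view(m: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    order = sorted(range(m.n_strains), key=lambda i: m.strains[i])
    names = [m.strains[i] for i in order]
    return names, np.ascontiguousarray(m.calls[order])


def local_tree_for_variant(
    m: GenotypeMatrix, idx: int, window: WindowSpec | int = WindowSpec()
) -> PhyloTree:
    """Midpoint-rooted NJ tree from the window around variant ``idx``.

    The focal variant is part of its own window.  Windows narrower than 4
    variants (or fewer than 3 called strains) are flagged by setting the
    returned tree's ``low_confidence`` attribute; the tree is still built.
    """
    if isinstance(window, int):
        window = WindowSpec(window)
    if m.n_strains < 3:
        raise ValueError("need at least 3 strains")
    bounds = m.chromosome_bounds()
    c = int(np.searchsorted(bounds, idx, side="right") - 1)
    lo, hi = window.bounds(idx, int(bounds[c]), int(bounds[c + 1]))
    names, calls = _sorted_strain_view(m)
    D = K.pair_differences(np.ascontiguousarray(calls[:, lo:hi]))
    eu, ev, el = K.nj_edges(D)
    left, right, blen, root, _post, flag = K.midpoint_root(eu, ev, el, len(names))
    tree = PhyloTree.from_arrays(left, right, blen, root, names)
    tree.low_confidence = bool(hi - lo < 4) or bool(flag)
    return tree


def identity_track(
    query: str,
    reference: str,
    m: GenotypeMatrix,
    window: WindowSpec | int = WindowSpec(),
    stride: int = 1,
) -> pd.DataFrame:
    """Sliding-window sequence identity of ``query`` to ``reference``.

    Returns one row per window center (every ``stride`` variants):
    chromosome, center position, fraction of co-called loci with equal
    calls (NaN where no locus is co-called), and the co-called count.
    To compare against a clade's modal genotype, collapse the clade first
    and pass the pseudo-strain name.
    """
    if isinstance(window, int):
        window = WindowSpec(window)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    qi = m.strain_index(query)
    ri = m.strain_index(reference)
    centers, ident, ncoc = K.identity_fractions(
        m.calls[qi], m.calls[ri], m.chromosome_bounds(), window.width, stride
    )
    v = m.variants
    return pd.DataFrame(
        {
            "chrom": v["chrom"].to_numpy()[centers],
            "center_pos": v["pos"].to_numpy()[centers],
            "identity": ident,
            "n_cocalled": ncoc,
        }
    )


def collapse_clade_to_modal(
    m: GenotypeMatrix,
    members: Sequence[str],
    pseudo_name: str = "clade_modal",
) -> GenotypeMatrix:
    """Replace a set of strains by one pseudo-strain carrying their modal
    genotype.

    At each locus the pseudo-strain gets the most frequent non-missing call
    among members (ties toward the reference allele; all-missing stays
    missing).  Used for clades too closely related and mosaic for their
    internal phylogeny to be resolved, whose modal genotype stands in for
    the clade root.
    """
    members = list(members)
    if not members:
        raise ValueError("member set must not be empty")
    rows = [m.strain_index(s) for s in members]
    sub = m.calls[rows]
    n_alt = (sub == 1).sum(axis=0)
    n_ref = (sub == 0).sum(axis=0)
    modal = np.where(n_alt > n_ref, 1, 0).astype(np.int8)
    modal[(n_alt == 0) & (n_ref == 0)] = MISSING
    keep = [i for i in range(m.n_strains) if i not in set(rows)]
    strains = [m.strains[i] for i in keep] + [pseudo_name]
    calls = np.vstack([m.calls[keep], modal[None, :]])
    return GenotypeMatrix(strains, m.variants, calls, validate=False)
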