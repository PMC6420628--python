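"""Inference of independent allele-emergence events (homoplasy).

A shared variant whose carriers are not monophyletic on the local tree must
either have arisen more than once or have been maintained as a balanced
ancestral polymorphism; this module counts the apparent independent
emergence events per variant and aggregates them genome-wide.

The per-variant rule set operates on a rooted binary local tree, in
post-order.  Each node is assigned a state from its two children:

* two equal genotypes -> that genotype;
* two unequal genotypes -> an independent emergence event is assigned to
  the node (state ``event``);
* an event child plus a genotype child -> the called genotype;
* two event children -> ``event``, without assigning a further event (a
  conservative resolution: the method never inflates the event count, which
  is why it mildly underestimates true homoplasy).

Leaves with missing calls are pruned (absorbed) before the rules apply.
``n_events`` is the number of nodes assigned a new event; it equals the
binary Fitch small-parsimony change count whenever no event-event merge
occurs, and never falls below zero.  The rules are symmetric in ref/alt, so
``n_events`` is 0 exactly when the called leaves are monomorphic, and a
singleton always yields 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from .genotypes import MISSING, GenotypeMatrix, VariantLocus
from .phylo import WindowSpec, collapse_clade_to_modal, local_tree_for_variant, _sorted_strain_view
from .simulate import GenomeModel, SimulatedPopulation, place_neutral_variants_on_tree
from .trees import PhyloTree

__all__ = [
    "EmergenceCall",
    "ScanSummary",
    "ScanResult",
    "NeutralExpectation",
    "infer_emergence_events",
    "classify_variant",
    "genome_scan",
    "neutral_expectation",
    "compare_true_vs_inferred",
]

_STATE_NAMES = {0: "ref", 1: "alt", 2: "event", 3: "absent"}


@dataclass(frozen=True)
class EmergenceCall:
    """Per-variant emergence classification."""

    locus: VariantLocus
    sharing: str  # "singleton" | "shared"
    n_events: int
    multiple: bool
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sharing == "singleton" and self.n_events > 1:
            raise ValueError("a singleton cannot have more than one emergence")
        if self.multiple != (self.n_events >= 2):
            raise ValueError("multiple must equal n_events >= 2")


@dataclass(frozen=True)
class ScanSummary:
    n_total_variants: int
    n_shared: int
    n_multiple: int
    per_chromosome: pd.DataFrame = field(repr=False)
    total_events_beyond_first: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_multiple <= self.n_shared <= self.n_total_variants:
            raise ValueError("scan counts must satisfy multiple <= shared <= total")


@dataclass
class ScanResult:
    summary: ScanSummary
    calls: pd.DataFrame  # chrom, pos, n_alt, n_called, sharing, n_events, multiple, flags


@dataclass(frozen=True)
class NeutralExpectation:
    mean_shared: float
    sd_shared: float
    mean_multiple: float
    sd_multiple: float
    replicates: pd.DataFrame = field(repr=False)


def infer_emergence_events(
    tree: PhyloTree, leaf_calls: Mapping[str, int]
) -> tuple[int, dict]:
    """Count independent emergence events for one variant on a rooted tree.

    ``leaf_calls`` maps leaf name to 0/1/missing(-1); leaves with missing
    calls are pruned.  Returns the event count and a per-node state
    annotation (dendropy node -> "ref"/"alt"/"event"/"absent"); pruned
    subtrees are annotated "absent".

    Raises on unrooted trees and on internal nodes with more than two
    children (the NJ tie rule guarantees binary trees; resolve
    multifurcations before calling).
    """
    if not tree.is_rooted:
        raise ValueError("emergence inference needs a rooted tree")
    dtree = tree.dendropy_tree
    states: dict = {}
    n_events = 0
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            call = leaf_calls.get(node.taxon.label, MISSING)
            states[node] = 3 if call == MISSING else int(call)
            continue
        kids = node.child_nodes()
        if len(kids) > 2:
            raise ValueError(
                f"internal node with {len(kids)} children: resolve the "
                "multifurcation before emergence inference"
            )
        if len(kids) == 1:  # unifurcation (e.g. after external pruning)
            states[node] = states[kids[0]]
            continue
        a, b = states[kids[0]], states[kids[1]]
        if a == 3:
            states[node] = b
        elif b == 3:
            states[node] = a
        elif a == 2 and b == 2:
            states[node] = 2
        elif a == 2:
            states[node] = b
        elif b == 2:
            states[node] = a
        elif a == b:
            states[node] = a
        else:
            states[node] = 2
            n_events += 1
    return n_events, {nd: _STATE_NAMES[s] for nd, s in states.items()}


def _flag_names(flag: int) -> tuple[str, ...]:
    out = []
    if flag & K.FLAG_NARROW_WINDOW:
        out.append("low_coverage_window")
    if flag & K.FLAG_DEGENERATE_ROOT:
        out.append("unresolved_root")
    return tuple(out)


def classify_variant(
    m: GenotypeMatrix,
    idx: int,
    window: WindowSpec | int = WindowSpec(),
    clade_collapse: Sequence[str] | None = None,
) -> EmergenceCall:
    """Classify one variant: sharing class plus inferred emergence count.

    Sharing is counted on the original matrix (a variant is *shared* when
    at least two strains carry the alternate allele), while the emergence
    count runs on the clade-collapsed matrix when a collapse is configured.
    """
    if isinstance(window, int):
        window = WindowSpec(window)
    n_alt = int((m.calls[:, idx] == 1).sum())
    work = (
        collapse_clade_to_modal(m, clade_collapse) if clade_collapse else m
    )
    tree = local_tree_for_variant(work, idx, window)
    calls = {s: int(c) for s, c in zip(work.strains, work.calls[:, idx])}
    n_events, _states = infer_emergence_events(tree, calls)
    flags = ("low_coverage_window",) if tree.low_confidence else ()
    return EmergenceCall(
        locus=m.locus(idx),
        sharing="shared" if n_alt >= 2 else "singleton",
        n_events=n_events,
        multiple=n_events >= 2,
        flags=flags,
    )


def genome_scan(
    m: GenotypeMatrix,
    window: WindowSpec | int = WindowSpec(),
    clade_collapse: Sequence[str] | None = None,
) -> ScanResult:
    """Classify every variant with a per-variant local tree.

    Equivalent to calling :func:`classify_variant` at each locus, but runs
    through the incremental-window kernel.  Sharing is always counted on
    the pre-collapse matrix.
    """
    if isinstance(window, int):
        window = WindowSpec(window)
    work = (
        collapse_clade_to_modal(m, clade_collapse) if clade_collapse else m
    )
    names, calls = _sorted_strain_view(work)
    bounds = work.chromosome_bounds()
    n_events, _n_alt_w, n_called_w, flags = K.scan_events(
        calls, bounds, window.width
    )
    n_alt = m.alt_counts()  # pre-collapse sharing
    shared = n_alt >= 2
    multiple = n_events >= 2
    v = m.variants
    table = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "pos": v["pos"],
            "n_alt": n_alt,
            "n_called": m.called_counts(),
            "sharing": np.where(shared, "shared", "singleton"),
            "n_events": n_events,
            "multiple": multiple,
            "flags": [";".join(_flag_names(f)) for f in flags],
        }
    )
    per_chrom = (
        table.assign(shared=shared)
        .groupby("chrom", observed=True)
        .agg(
            n_total=("pos", "size"),
            n_shared=("shared", "sum"),
            n_multiple=("multiple", "sum"),
        )
        .reset_index()
    )
    summary = ScanSummary(
        n_total_variants=int(len(table)),
        n_shared=int(shared.sum()),
        n_multiple=int(multiple.sum()),
        per_chromosome=per_chrom,
        total_events_beyond_first=int(np.maximum(n_events - 1, 0).sum()),
    )
    return ScanResult(summary=summary, calls=table)


def neutral_expectation(
    tree: PhyloTree,
    n_variants: int,
    n_reps: int,
    window: WindowSpec | int = WindowSpec(),
    rng: np.random.Generator | None = None,
    genome: GenomeModel | None = None,
) -> NeutralExpectation:
    """Distribution of (shared, multiple) counts under neutral placement.

    Each replicate drops ``n_variants`` on the tree proportionally to
    branch length, propagates them to descendants, and runs the genome
    scan; the mean and SD across replicates give the no-selection
    expectation against which observed scans are compared.
    """
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    for rep in range(n_reps):
        if n_variants == 0:
            rows.append({"replicate": rep, "n_shared": 0, "n_multiple": 0})
            continue
        pop = place_neutral_variants_on_tree(tree, n_variants, genome, rng)
        res = genome_scan(pop.matrix, window)
        rows.append(
            {
                "replicate": rep,
                "n_shared": res.summary.n_shared,
                "n_multiple": res.summary.n_multiple,
            }
        )
    df = pd.DataFrame(rows)
    return NeutralExpectation(
        mean_shared=float(df["n_shared"].mean()),
        sd_shared=float(df["n_shared"].std(ddof=1)) if n_reps > 1 else 0.0,
        mean_multiple=float(df["n_multiple"].mean()),
        sd_multiple=float(df["n_multiple"].std(ddof=1)) if n_reps > 1 else 0.0,
        replicates=df,
    )


def compare_true_vs_inferred(
    pop: SimulatedPopulation, window: WindowSpec | int = WindowSpec()
) -> tuple[int, int]:
    """True homoplasy count vs inferred multiple-emergence count.

    Truth comes from the simulation's event log; inference sees only the
    blinded genotype matrix.  Returns (number of loci with >= 2 true
    origination events, number of loci inferred to have emerged more than
    once).
    """
    true_count = pop.true_homoplasy_count()
    res = genome_scan(pop.matrix, window)
    return true_count, res.summary.n_multiple
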