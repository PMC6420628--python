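"""QTL detection and single-nucleotide fine mapping on inbred cross panels.

The mapping model is ordinary least squares on a standardized phenotype:
greedy forward selection over marker genotypes (plus non-genetic
"pseudo-genotype" covariates encoding plate number and plate position),
with partial F-tests for inclusion (p_enter, default 1e-3) and a final
leave-one-out screen (p_retain, default 1e-5).  Selected loci are
fine-mapped by in-silico allele swaps: candidate causal variants in the
linkage neighborhood are compared through nested model F-tests whose
information comes exactly from the progeny whose genotypes separate the
candidates (the statistical analog of reciprocal hemizygotes).  False
discovery is estimated empirically by rerunning the whole selection on
permuted phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "PhenotypePanel",
    "Design",
    "QTLModel",
    "QTNScoreProfile",
    "FdrEstimate",
    "normalize_phenotypes",
    "append_pseudo_genotypes",
    "forward_select",
    "variance_explained",
    "fine_map_qtn",
    "permutation_fdr",
]

_COLLINEAR_TOL = 1e-10


@dataclass
class PhenotypePanel:
    """Replicate colony sizes with plate layout.

    ``data`` columns: progeny, replicate, plate, row, col, colony_size.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"progeny", "colony_size"}
        if not need <= set(self.data.columns):
            raise ValueError(f"phenotype table needs columns {sorted(need)}")
        if not np.isfinite(self.data["colony_size"].to_numpy(float)).all():
            raise ValueError("colony sizes must be finite")
        if self.data.groupby("progeny").size().min() < 1:
            raise ValueError("every progeny needs at least one replicate")

    def progeny_means(self) -> pd.Series:
        return self.data.groupby("progeny", sort=False)["colony_size"].mean()


def normalize_phenotypes(panel: PhenotypePanel) -> pd.Series:
    """Mean of replicates per progeny, then Z-scored across progeny.

    The result has mean 0 and SD 1, so downstream effect sizes are in
    phenotype standard deviations.  Affine transformations of the raw
    sizes leave the output unchanged.
    """
    means = panel.progeny_means()
    sd = means.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("phenotypes have zero variance; cannot Z-score")
    return (means - means.mean()) / sd


@dataclass
class Design:
    """Regression design: genetic marker columns plus non-genetic
    pseudo-genotype covariates, aligned to a progeny order."""

    X: np.ndarray
    names: list[str]
    is_genetic: np.ndarray
    marker_index: np.ndarray
    progeny: list[str]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]


def append_pseudo_genotypes(m: GenotypeMatrix, panel: PhenotypePanel) -> Design:
    """Build the design matrix: one column per marker plus plate/position
    pseudo-genotypes.

    Plate membership is encoded per progeny as the fraction of its
    replicates on each plate (one indicator dropped against the intercept;
    constant indicators dropped entirely, so a single-plate panel
    contributes nothing).  Plate row/column positions enter as scaled
    means.  Pseudo-genotypes are flagged non-genetic and are never
    reported as QTLs.
    """
    if (m.calls == MISSING).any():
        raise ValueError("design matrix requires fully called genotypes")
    progeny = list(m.strains)
    X_gen = m.calls.astype(np.float64)  # strains (progeny) are rows
    names = [
        f"{c}:{p}" for c, p in zip(m.variants["chrom"].astype(str), m.variants["pos"])
    ]
    marker_index = np.arange(m.n_loci)

    cols = [X_gen]
    extra_names: list[str] = []
    df = panel.data
    grouped = df.groupby("progeny", sort=False)
    order = pd.Index(progeny)
    if set(df["progeny"]) != set(progeny):
        raise ValueError("phenotype panel and genotype matrix progeny differ")
    if "plate" in df.columns:
        plate_share = (
            pd.crosstab(df["progeny"], df["plate"], normalize="index")
            .reindex(order)
            .to_numpy(float)
        )
        keep = plate_share.std(axis=0) > 0
        plate_share = plate_share[:, keep]
        if plate_share.shape[1] > 0:
            plate_share = plate_share[:, 1:]  # one level absorbed by intercept
        for k in range(plate_share.shape[1]):
            cols.append(plate_share[:, [k]])
            extra_names.append(f"plate_{k + 1}")
    for poscol in ("row", "col"):
        if poscol in df.columns:
            v = grouped[poscol].mean().reindex(order).to_numpy(float)
            if v.std() > 0:
                vmax = np.abs(v).max()
                cols.append((v / (vmax if vmax else 1.0))[:, None])
                extra_names.append(f"pos_{poscol}")

    X = np.concatenate(cols, axis=1)
    n_extra = len(extra_names)
    return Design(
        X=X,
        names=names + extra_names,
        is_genetic=np.concatenate(
            [np.ones(m.n_loci, bool), np.zeros(n_extra, bool)]
        ),
        marker_index=np.concatenate(
            [marker_index, np.full(n_extra, -1, dtype=np.int64)]
        ),
        progeny=progeny,
    )


@dataclass
class QTLModel:
    """Result of forward selection: retained terms with effects (in
    phenotype SD), leave-one-out p-values and sequential variance
    explained."""

    terms: pd.DataFrame  # name, column, marker_index, is_genetic, effect, p_value, variance_explained
    p_enter: float
    p_retain: float
    n_obs: int
    selection_order: list[int] = field(default_factory=list)

    @property
    def genetic_terms(self) -> pd.DataFrame:
        return self.terms[self.terms["is_genetic"]].reset_index(drop=True)

    @property
    def n_qtls(self) -> int:
        return int(self.terms["is_genetic"].sum())


def _loo_pvalues(Xs: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out (each term last) partial-F p-values and effects for a
    fitted OLS with intercept."""
    n, k = Xs.shape
    X1 = np.column_stack([np.ones(n), Xs])
    beta, _, rank, _ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    sse_full = float(resid @ resid)
    df_full = n - (k + 1)
    pvals = np.empty(k)
    for j in range(k):
        Xr = np.delete(X1, j + 1, axis=1)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rr = y - Xr @ br
        sse_r = float(rr @ rr)
        if df_full <= 0 or sse_full <= 0:
            pvals[j] = 0.0
            continue
        F = (sse_r - sse_full) / (sse_full / df_full)
        pvals[j] = stats.f.sf(max(F, 0.0), 1, df_full)
    return pvals, beta[1:]


def forward_select(
    design: Design,
    y: np.ndarray | pd.Series,
    p_enter: float = 1e-3,
    p_retain: float = 1e-5,
) -> QTLModel:
    """Greedy forward selection with partial F-tests, then a final
    leave-one-out screen.

    At each step the candidate with the smallest inclusion p-value (<=
    ``p_enter``) is added; ties break toward the lowest column index, i.e.
    the lowest genomic coordinate.  After the forward pass, terms whose
    leave-one-out p-value exceeds ``p_retain`` are dropped (worst first,
    refitting).  Collinear candidates are skipped.  Deterministic given
    its input.
    """
    y = np.asarray(y, dtype=np.float64)
    X = design.X
    n, p = X.shape
    if len(y) != n:
        raise ValueError("phenotype and design lengths differ")

    Xc = X - X.mean(axis=0)
    yr = y - y.mean()
    rX = Xc.copy()
    ss0 = (Xc**2).sum(axis=0)
    selected: list[int] = []
    in_model = np.zeros(p, bool)

    while True:
        k = len(selected)
        dfree = n - k - 2
        if dfree < 1:
            break
        ssy = float(yr @ yr)
        if ssy <= 1e-12:
            break
        ssx = (rX**2).sum(axis=0)
        cov = rX.T @ yr
        ok = ~in_model & (ssx > _COLLINEAR_TOL * np.maximum(ss0, 1.0))
        if not ok.any():
            break
        ssr = np.zeros(p)
        ssr[ok] = cov[ok] ** 2 / ssx[ok]
        denom = np.maximum(ssy - ssr, 1e-300) / dfree
        F = np.where(ok, ssr / denom, -np.inf)
        pvals = np.where(ok, stats.f.sf(np.maximum(F, 0.0), 1, dfree), np.inf)
        j = int(np.argmin(pvals))  # ties -> lowest column index
        if pvals[j] > p_enter:
            break
        selected.append(j)
        in_model[j] = True
        q = rX[:, j] / np.sqrt(float(rX[:, j] @ rX[:, j]))
        yr = yr - q * float(q @ yr)
        rX = rX - np.outer(q, q @ rX)
        rX[:, j] = 0.0

    order = list(selected)
    # backward screen at p_retain (worst term dropped first, refit)
    while order:
        pv, _ = _loo_pvalues(X[:, order], y)
        worst = int(np.argmax(pv))
        if pv[worst] <= p_retain:
            break
        del order[worst]

    if order:
        pv, eff = _loo_pvalues(X[:, order], y)
    else:
        pv = np.empty(0)
        eff = np.empty(0)
    terms = pd.DataFrame(
        {
            "name": [design.names[j] for j in order],
            "column": order,
            "marker_index": design.marker_index[order],
            "is_genetic": design.is_genetic[order],
            "effect": eff,
            "p_value": pv,
        }
    )
    model = QTLModel(
        terms=terms,
        p_enter=p_enter,
        p_retain=p_retain,
        n_obs=n,
        selection_order=[j for j in selected if j in set(order)],
    )
    model.terms["variance_explained"] = variance_explained(model, design, y).to_numpy()
    return model


def variance_explained(
    model: QTLModel, design: Design, y: np.ndarray | pd.Series
) -> pd.Series:
    """Sequential (type-I, selection-order) sum-of-squares fraction of the
    total phenotype variance, per retained term."""
    y = np.asarray(y, dtype=np.float64)
    yr = y - y.mean()
    sst = float(yr @ yr)
    out = {}
    cols_in_order = [c for c in model.selection_order] + [
        c for c in model.terms["column"] if c not in model.selection_order
    ]
    Q: list[np.ndarray] = []
    for c in cols_in_order:
        x = design.X[:, c] - design.X[:, c].mean()
        for q in Q:
            x = x - q * float(q @ x)
        nx = np.sqrt(float(x @ x))
        if nx <= 1e-12:
            out[c] = 0.0
            continue
        q = x / nx
        out[c] = float(q @ yr) ** 2 / sst if sst > 0 else 0.0
        yr = yr - q * float(q @ yr)
        Q.append(q)
    return pd.Series(
        [out.get(c, 0.0) for c in model.terms["column"]],
        index=model.terms["name"],
        name="variance_explained",
    )


@dataclass
class QTNScoreProfile:
    """Allele-swap fine-mapping profile around one QTL.

    ``score`` is -log10 of the worst-case p-value of the test that the
    candidate explains the phenotype beyond each alternative nearby
    variant; only its ranking and the resolved/unresolved call are
    contractual, not its absolute scale.
    """

    qtl_marker: int
    candidates: np.ndarray
    positions: np.ndarray
    scores: np.ndarray
    resolved: bool
    best_marker: int | None
    resolution_width_bp: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_index": self.candidates,
                "pos": self.positions,
                "qtn_score": self.scores,
            }
        )


def _r2_with(x: np.ndarray, other: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    oc = other - other.mean(axis=0)
    den = np.sqrt((xc @ xc) * (oc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, (oc.T @ xc) / den, 0.0)
    return r**2


def fine_map_qtn(
    model: QTLModel,
    qtl_marker: int,
    m: GenotypeMatrix,
    y: np.ndarray | pd.Series,
    design: Design,
    *,
    window_bp: int | None = None,
    r2_min: float = 0.5,
    alpha: float = 0.05,
) -> QTNScoreProfile:
    """Fine-map a selected QTL to a single causal nucleotide.

    Candidates are the variants in the QTL's linkage neighborhood (markers
    on the same chromosome with r^2 >= ``r2_min`` to the selected marker,
    or within ``window_bp`` if given).  For each candidate the null "this
    variant is not causal relative to each nearby alternative" is tested
    by a nested-model F-test of the candidate added to a model already
    containing the alternative (plus the other model terms); only progeny
    whose genotypes separate the two variants inform that test.  A locus
    is resolved when a unique candidate attains the maximal score and its
    worst-case p-value clears ``alpha``; candidates in perfect linkage are
    never resolved against one another.
    """
    if qtl_marker not in set(model.terms["marker_index"]):
        raise ValueError("qtl_marker is not a term of the fitted model")
    y = np.asarray(y, dtype=np.float64)
    v = m.variants
    chrom = v["chrom"].cat.codes.to_numpy()
    pos = v["pos"].to_numpy()
    same = chrom == chrom[qtl_marker]
    if window_bp is not None:
        cand_mask = same & (np.abs(pos - pos[qtl_marker]) <= window_bp)
    else:
        r2 = np.zeros(m.n_loci)
        r2[same] = _r2_with(
            m.calls[:, qtl_marker].astype(float), m.calls[:, same].astype(float)
        )
        cand_mask = same & (r2 >= r2_min)
    cand_mask[qtl_marker] = True
    candidates = np.flatnonzero(cand_mask)

    cand_set = set(candidates.tolist())
    cov_cols = [
        c
        for c, mk in zip(model.terms["column"], model.terms["marker_index"])
        if mk not in cand_set
    ]
    n = len(y)
    # orthonormal basis of intercept + covariates
    basis = [np.ones(n) / np.sqrt(n)]
    for c in cov_cols:
        x = design.X[:, c].astype(float)
        for q in basis:
            x = x - q * float(q @ x)
        nx = np.sqrt(float(x @ x))
        if nx > 1e-10:
            basis.append(x / nx)
    Q = np.column_stack(basis)

    def residualize(x: np.ndarray) -> np.ndarray:
        return x - Q @ (Q.T @ x)

    ry = residualize(y)
    rg = {c: residualize(m.calls[:, c].astype(float)) for c in candidates}
    dfree = n - Q.shape[1] - 2
    if dfree < 1:
        raise ValueError("not enough observations for fine mapping")

    def add_p(rc: np.ndarray, ra: np.ndarray | None) -> float:
        """p-value for adding candidate rc to covariates (+ alternative ra)."""
        yv = ry.copy()
        x = rc.copy()
        if ra is not None:
            na = float(ra @ ra)
            if na > 1e-10:
                qa = ra / np.sqrt(na)
                yv = yv - qa * float(qa @ yv)
                x = x - qa * float(qa @ x)
        ssx = float(x @ x)
        if ssx <= 1e-10:  # perfect linkage: no separating progeny
            return 1.0
        ssy = float(yv @ yv)
        ssr = float(x @ yv) ** 2 / ssx
        df = dfree if ra is not None else dfree + 1
        if ssy - ssr <= 0:
            return 0.0
        F = ssr / ((ssy - ssr) / df)
        return float(stats.f.sf(F, 1, df))

    scores = np.empty(len(candidates))
    for i, c in enumerate(candidates):
        if len(candidates) == 1:
            worst = add_p(rg[c], None)
        else:
            worst = max(
                add_p(rg[c], rg[a]) for a in candidates if a != c
            )
        scores[i] = -np.log10(max(worst, 1e-300))

    top = float(scores.max())
    n_top = int((scores >= top - 1e-9).sum())
    resolved = n_top == 1 and top >= -np.log10(alpha)
    best = int(candidates[int(np.argmax(scores))]) if resolved else None
    width = int(pos[candidates].max() - pos[candidates].min()) if len(candidates) else 0
    return QTNScoreProfile(
        qtl_marker=int(qtl_marker),
        candidates=candidates,
        positions=pos[candidates],
        scores=scores,
        resolved=resolved,
        best_marker=best,
        resolution_width_bp=width,
    )


@dataclass(frozen=True)
class FdrEstimate:
    fdr: float
    n_real: int
    perm_counts: np.ndarray
    degenerate: bool  # no QTLs on the real data: FDR is uninformative


def permutation_fdr(
    design: Design,
    y: np.ndarray | pd.Series,
    n_perms: int = 20,
    rng: np.random.Generator | None = None,
    p_enter: float = 1e-3,
    p_retain: float = 1e-5,
) -> FdrEstimate:
    """Empirical false-discovery rate of the QTL selection.

    The phenotype is permuted across progeny and the complete forward
    selection rerun; the FDR estimate is the mean number of (genetic) QTLs
    found on permuted data divided by the count on the real data.
    """
    if n_perms < 10:
        raise ValueError("use at least 10 permutations")
    rng = rng if rng is not None else np.random.default_rng()
    y = np.asarray(y, dtype=np.float64)
    real = forward_select(design, y, p_enter, p_retain).n_qtls
    counts = np.empty(n_perms, dtype=np.int64)
    for i in range(n_perms):
        yp = rng.permutation(y)
        counts[i] = forward_select(design, yp, p_enter, p_retain).n_qtls
    if real == 0:
        return FdrEstimate(fdr=1.0, n_real=0, perm_counts=counts, degenerate=True)
    return FdrEstimate(
        fdr=float(counts.mean() / real),
        n_real=real,
        perm_counts=counts,
        degenerate=False,
    )
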