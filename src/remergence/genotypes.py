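"""Core data types and file I/O for strain panels of biallelic variants.

The universal exchange object is :class:`GenotypeMatrix`: strains x loci over
{0 = reference allele, 1 = alternate allele, -1 = missing}.  Loci are
1-based, VCF-style coordinates; heterozygous or otherwise ambiguous calls in
source VCFs are treated as missing (never imputed).  Only biallelic SNPs are
represented; additional alternate alleles at a locus are dropped with a
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing call in a genotype matrix
MISSING: int = -1

FUNCTIONAL_CLASSES = ("synonymous", "missense", "regulatory", "other", "unknown")

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantLocus:
    """A single biallelic variant site.

    Parameters
    ----------
    chromosome : str
        Chromosome identifier (e.g. ``"chrII"``).
    position : int
        1-based coordinate of the variant.
    ref_allele, alt_allele : str
        Reference and alternate nucleotide; must differ.
    functional_class : str
        One of :data:`FUNCTIONAL_CLASSES`; defaults to ``"unknown"``.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    functional_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref and alt alleles are identical at "
                f"{self.chromosome}:{self.position}"
            )
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional class {self.functional_class!r}")


@dataclass(frozen=True)
class StrainMetadata:
    """Ecological annotation for one strain."""

    name: str
    niche: str
    clade: str | None = None


class GenotypeMatrix:
    """Strains x loci matrix of biallelic calls.

    Calls are stored as ``int8`` with 0 = ref, 1 = alt, -1 = missing.  Loci
    are kept sorted by (chromosome, position) and must be unique; chromosome
    order is the order of first appearance (or the genome model's order for
    simulated data).
    """

    def __init__(
        self,
        strains: Sequence[str],
        variants: pd.DataFrame,
        calls: np.ndarray,
        *,
        validate: bool = True,
    ) -> None:
        self.strains: list[str] = list(strains)
        self.variants = variants.reset_index(drop=True)
        self.calls = np.asarray(calls, dtype=np.int8)
        if validate:
            self._validate()

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_loci(
        cls, strains: Sequence[str], loci: Iterable[VariantLocus], calls: np.ndarray
    ) -> "GenotypeMatrix":
        loci = list(loci)
        chrom_order = list(dict.fromkeys(l.chromosome for l in loci))
        variants = pd.DataFrame(
            {
                "chrom": pd.Categorical(
                    [l.chromosome for l in loci], categories=chrom_order, ordered=True
                ),
                "pos": np.array([l.position for l in loci], dtype=np.int64),
                "ref": [l.ref_allele for l in loci],
                "alt": [l.alt_allele for l in loci],
                "functional_class": [l.functional_class for l in loci],
            }
        )
        calls = np.asarray(calls, dtype=np.int8)
        order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].cat.codes))
        if not np.array_equal(order, np.arange(len(loci))):
            variants = variants.iloc[order]
            calls = calls[:, order]
        return cls(strains, variants, calls)

    def _validate(self) -> None:
        v = self.variants
        if set(v.columns) < {"chrom", "pos", "ref", "alt"}:
            raise ValueError("variants frame needs chrom/pos/ref/alt columns")
        if "functional_class" not in v.columns:
            v["functional_class"] = "unknown"
        if not isinstance(v["chrom"].dtype, pd.CategoricalDtype):
            order = list(dict.fromkeys(v["chrom"]))
            self.variants["chrom"] = pd.Categorical(
                v["chrom"], categories=order, ordered=True
            )
            v = self.variants
        if self.calls.shape != (len(self.strains), len(v)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.strains)} strains x {len(v)} loci"
            )
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain names")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1 or missing (-1)")
        codes = v["chrom"].cat.codes.to_numpy()
        pos = v["pos"].to_numpy()
        key = codes.astype(np.int64) * (pos.max(initial=0) + 1) + pos
        if len(key) and not (np.diff(key) > 0).all():
            if (np.diff(key) == 0).any():
                raise ValueError("duplicate (chromosome, position) pair")
            raise ValueError("loci must be sorted by (chromosome, position)")

    # -- basic properties ----------------------------------------------------

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_loci(self) -> int:
        return len(self.variants)

    @property
    def loci(self) -> list[VariantLocus]:
        v = self.variants
        return [
            VariantLocus(c, int(p), r, a, f)
            for c, p, r, a, f in zip(
                v["chrom"].astype(str),
                v["pos"],
                v["ref"],
                v["alt"],
                v["functional_class"],
            )
        ]

    def locus(self, idx: int) -> VariantLocus:
        row = self.variants.iloc[idx]
        return VariantLocus(
            str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"],
            row["functional_class"],
        )

    def strain_index(self, name: str) -> int:
        return self.strains.index(name)

    def alt_counts(self) -> np.ndarray:
        """Number of strains carrying the alternate allele, per locus."""
        return (self.calls == 1).sum(axis=0)

    def called_counts(self) -> np.ndarray:
        """Number of non-missing calls per locus."""
        return (self.calls != MISSING).sum(axis=0)

    def chromosome_bounds(self) -> np.ndarray:
        """Start offsets of each chromosome block plus the total length.

        Loci are sorted, so each chromosome occupies one contiguous slice
        ``[bounds[c], bounds[c+1])``.
        """
        codes = self.variants["chrom"].cat.codes.to_numpy()
        present = np.unique(codes)
        starts = np.searchsorted(codes, present)
        return np.append(starts, len(codes)).astype(np.int64)

    # -- subsetting ----------------------------------------------------------

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.strains, self.variants.iloc[idx], self.calls[:, idx], validate=False
        )

    def take_strains(self, names: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.strain_index(n) for n in names]
        return GenotypeMatrix(
            list(names), self.variants, self.calls[rows], validate=False
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_strains} strains x {self.n_loci} loci)"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.strains == other.strains
            and np.array_equal(self.calls, other.calls)
            and self.variants["pos"].equals(other.variants["pos"])
            and list(self.variants["chrom"]) == list(other.variants["chrom"])
            and list(self.variants["ref"]) == list(other.variants["ref"])
            and list(self.variants["alt"]) == list(other.variants["alt"])
        )


# -- tab-separated variant tables ---------------------------------------------

_FIXED_COLS = ("CHROM", "POS", "REF", "ALT")


def read_variant_table(path) -> tuple[list[VariantLocus], GenotypeMatrix]:
    """Read the canonical tab-separated variant table.

    Columns: CHROM, POS, REF, ALT, [CLASS,] then one column per strain with
    calls coded 0 / 1 / ``.`` (missing).  Returns the loci plus the full
    matrix (loci sorted; missing preserved).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_FIXED_COLS)] != list(_FIXED_COLS):
            raise ValueError(f"{path}: header must start with {','.join(_FIXED_COLS)}")
        rest = header[len(_FIXED_COLS):]
        has_class = bool(rest) and rest[0] == "CLASS"
        strains = rest[1:] if has_class else rest
        if not strains:
            raise ValueError(f"{path}: no strain columns in header")
        n_fixed = len(_FIXED_COLS) + has_class
        chroms, poss, refs, alts, classes, rows = [], [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_fixed + len(strains):
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_fixed + len(strains)} "
                    f"fields, got {len(parts)}"
                )
            try:
                poss.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad POS {parts[1]!r}") from exc
            chroms.append(parts[0])
            refs.append(parts[2])
            alts.append(parts[3])
            classes.append(parts[4] if has_class else "unknown")
            try:
                rows.append(
                    [MISSING if c == "." else int(c) for c in parts[n_fixed:]]
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: bad genotype call"
                ) from exc
        calls = (
            np.array(rows, dtype=np.int8).T
            if rows
            else np.empty((len(strains), 0), dtype=np.int8)
        )
        loci = [
            VariantLocus(c, p, r, a, f)
            for c, p, r, a, f in zip(chroms, poss, refs, alts, classes)
        ]
    gm = GenotypeMatrix.from_loci(strains, loci, calls)
    return gm.loci, gm


def write_variant_table(m: GenotypeMatrix, path, *, with_class: bool = False) -> None:
    """Write a matrix in the canonical tab-separated format (lossless)."""
    v = m.variants
    with open(path, "w") as fh:
        cols = list(_FIXED_COLS) + (["CLASS"] if with_class else []) + m.strains
        fh.write("\t".join(cols) + "\n")
        call_strs = np.where(m.calls == MISSING, ".", m.calls.astype(str))
        for j in range(m.n_loci):
            fixed = [
                str(v["chrom"].iloc[j]),
                str(int(v["pos"].iloc[j])),
                v["ref"].iloc[j],
                v["alt"].iloc[j],
            ]
            if with_class:
                fixed.append(v["functional_class"].iloc[j])
            fh.write("\t".join(fixed + list(call_strs[:, j])) + "\n")


def read_vcf(path, *, min_qual: float | None = None) -> tuple[list[VariantLocus], GenotypeMatrix]:
    """Read biallelic SNPs from a VCF into a genotype matrix.

    Requires ``cyvcf2``.  Anything that is not a confident homozygous (or
    haploid) ref/alt call is treated as missing.  Records with more than one
    alternate allele keep only the first; the rest are dropped with a warning.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("read_vcf requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path), gts012=True)
    strains = list(vcf.samples)
    loci: list[VariantLocus] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if rec.is_indel or not rec.is_snp:
            continue
        if min_qual is not None and (rec.QUAL is None or rec.QUAL < min_qual):
            continue
        if len(rec.ALT) > 1:
            n_multi += 1
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        g = np.asarray(rec.gt_types)
        calls = np.full(len(strains), MISSING, dtype=np.int8)
        calls[g == 0] = 0
        calls[g == 2] = 1
        loci.append(VariantLocus(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        rows.append(calls)
    if n_multi:
        logger.warning(
            "%d multi-allelic records: only the first alternate allele kept", n_multi
        )
    calls = (
        np.vstack(rows).T if rows else np.empty((len(strains), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix.from_loci(strains, loci, calls)
    return gm.loci, gm


# -- filters and joins --------------------------------------------------------


def filter_by_coverage(m: GenotypeMatrix, min_called: int) -> GenotypeMatrix:
    """Retain loci called in at least ``min_called`` strains (order preserved)."""
    if not 0 <= min_called <= m.n_strains:
        raise ValueError(f"min_called must be in [0, {m.n_strains}]")
    keep = np.flatnonzero(m.called_counts() >= min_called)
    if len(keep) == m.n_loci:
        return m
    return m.take_loci(keep)


def match_cross_variants(
    cross_loci: Sequence[VariantLocus], panel: GenotypeMatrix
) -> np.ndarray:
    """Flag which cross loci are shared with the panel.

    A cross locus is *shared* iff at least one panel strain carries the
    alternate allele at the same (chromosome, position).  Allele identity
    beyond position is not compared (extra alternate alleles are ignored).
    """
    alt_any = panel.alt_counts() > 0
    panel_keys = {
        (str(c), int(p))
        for c, p, a in zip(
            panel.variants["chrom"], panel.variants["pos"], alt_any
        )
        if a
    }
    return np.array(
        [(l.chromosome, l.position) in panel_keys for l in cross_loci], dtype=bool
    )


# -- strain metadata ----------------------------------------------------------


def read_strain_metadata(path) -> dict[str, StrainMetadata]:
    """Read strain metadata from a TSV with columns strain, niche[, clade]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "strain" not in cols or "niche" not in cols:
        raise ValueError(f"{path}: need 'strain' and 'niche' columns")
    out: dict[str, StrainMetadata] = {}
    for _, row in df.iterrows():
        name = row["strain"]
        if name in out:
            raise ValueError(f"{path}: duplicate strain {name!r}")
        out[name] = StrainMetadata(
            name=name, niche=row["niche"], clade=row.get("clade")
        )
    return out


def niche_map(meta: Mapping[str, StrainMetadata]) -> dict[str, str]:
    return {name: sm.niche for name, sm in meta.items()}
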