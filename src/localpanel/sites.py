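"""Ordered variant site maps shared by panels, genotype matrices and dosages.

A :class:`SiteMap` is the single source of truth for variant coordinates:
1-based physical positions (VCF convention), allele codes, cumulative genetic
position in centiMorgans, and the site flags (exomic target / array-typed /
multi-mapping) that drive ascertainment and QC downstream.  All matrices in
the package are column-aligned to a SiteMap; internal indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["SiteMap"]


@dataclass
class SiteMap:
    """Ordered biallelic variant records over one chromosome region.

    Parameters
    ----------
    chrom : array of str
        Chromosome label per site.
    pos : array of int
        1-based physical position; strictly increasing.
    ids : array of str
        Variant identifiers (unique within the map).
    ref, alt : array of str
        Reference / alternate allele strings; a length-mismatch or
        multi-base allele marks the site as an indel.
    cm : array of float
        Cumulative genetic position in centiMorgans; non-decreasing.
    is_exomic : bool array
        Site lies in a sequenced (exome-capture) window.
    is_array : bool array
        Site is typed on the genotyping array.
    is_multimapping : bool array
        Site maps to more than one homologous region (QC exclusion flag).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    cm: np.ndarray
    is_exomic: np.ndarray
    is_array: np.ndarray
    is_multimapping: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        self.is_exomic = np.asarray(self.is_exomic, dtype=bool)
        self.is_array = np.asarray(self.is_array, dtype=bool)
        self.is_multimapping = np.asarray(self.is_multimapping, dtype=bool)
        n = len(self.pos)
        for name in ("chrom", "ids", "ref", "alt", "cm", "is_exomic",
                     "is_array", "is_multimapping"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SiteMap field {name!r} has inconsistent length")
        if n and np.any(np.diff(self.pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if n and np.any(np.diff(self.cm) < 0):
            raise ValueError("genetic positions must be non-decreasing")
        if any(r == a for r, a in zip(self.ref, self.alt)):
            raise ValueError("ref and alt alleles must differ")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def is_indel(self) -> np.ndarray:
        return np.array([len(r) != 1 or len(a) != 1
                         for r, a in zip(self.ref, self.alt)], dtype=bool)

    @property
    def is_snv(self) -> np.ndarray:
        return ~self.is_indel

    @property
    def morgans(self) -> np.ndarray:
        """Cumulative genetic position in Morgans."""
        return self.cm / 100.0

    def interval_cm(self) -> np.ndarray:
        """Genetic length (cM) of the L-1 inter-site intervals."""
        return np.diff(self.cm)

    # -- selection ---------------------------------------------------------
    def take(self, index) -> "SiteMap":
        """Subset by boolean mask or integer index array (order-preserving)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SiteMap(
            chrom=self.chrom[index], pos=self.pos[index], ids=self.ids[index],
            ref=self.ref[index], alt=self.alt[index], cm=self.cm[index],
            is_exomic=self.is_exomic[index], is_array=self.is_array[index],
            is_multimapping=self.is_multimapping[index],
        )

    def with_flags(self, *, is_exomic=None, is_array=None,
                   is_multimapping=None) -> "SiteMap":
        """Copy with replaced flag vectors."""
        kw = {}
        if is_exomic is not None:
            kw["is_exomic"] = np.asarray(is_exomic, dtype=bool)
        if is_array is not None:
            kw["is_array"] = np.asarray(is_array, dtype=bool)
        if is_multimapping is not None:
            kw["is_multimapping"] = np.asarray(is_multimapping, dtype=bool)
        return replace(self, **kw)

    # -- keying ------------------------------------------------------------
    def keys(self) -> list[tuple[int, str, str]]:
        """(position, ref, alt) identity keys, the unit of cross-dataset matching."""
        return list(zip(self.pos.tolist(), self.ref.tolist(), self.alt.tolist()))

    def key_index(self) -> dict[tuple[int, str, str], int]:
        return {k: i for i, k in enumerate(self.keys())}

    def equals(self, other: "SiteMap") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.pos == other.pos))
            and all(a == b for a, b in zip(self.ref, other.ref))
            and all(a == b for a, b in zip(self.alt, other.alt))
            and bool(np.allclose(self.cm, other.cm))
        )
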