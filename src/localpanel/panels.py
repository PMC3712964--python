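"""In-memory containers: phased haplotype panels, genotype calls, dosages.

Allele / genotype encodings
---------------------------
* Haplotype alleles: int8, 0 = ref, 1 = alt, ``MISSING`` (-1) = unknown.
* Diploid calls: int8 count of alt alleles in {0, 1, 2}, ``MISSING`` (-1).
* Dosages: float64 expected alt-allele count in [0, 2].

Haplotypes are paired into diploid subjects via an explicit per-haplotype
subject id, so leave-one-out removal and genotype collapsing never rely on
column order conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sites import SiteMap

__all__ = ["MISSING", "HaplotypePanel", "GenotypeMatrix", "DosageMatrix"]

MISSING: int = -1


@dataclass
class HaplotypePanel:
    """Phased haplotype alleles for H haplotypes over a shared SiteMap."""

    hap_ids: np.ndarray
    subject_ids: np.ndarray
    sites: SiteMap
    alleles: np.ndarray  # int8 (H, L)

    def __post_init__(self) -> None:
        self.hap_ids = np.asarray(self.hap_ids, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (H, L) array")
        h, l = self.alleles.shape
        if len(self.hap_ids) != h or len(self.subject_ids) != h:
            raise ValueError("hap_ids/subject_ids length must equal haplotype count")
        if l != len(self.sites):
            raise ValueError("allele columns must match SiteMap length")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("haplotype alleles must be 0, 1 or missing")

    @property
    def n_haps(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def subjects(self) -> list:
        """Distinct subject ids in first-appearance order."""
        seen: dict = {}
        for s in self.subject_ids:
            seen.setdefault(s, None)
        return list(seen)

    def haps_of(self, subject_id) -> np.ndarray:
        """Row indices of a subject's haplotypes."""
        idx = np.flatnonzero(self.subject_ids == subject_id)
        if idx.size == 0:
            raise KeyError(f"unknown subject {subject_id!r}")
        return idx

    def frequencies(self) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing alleles (NaN if none)."""
        a = self.alleles
        known = a != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(known.sum(0) > 0,
                            np.where(a == 1, 1, 0).sum(0) / np.maximum(known.sum(0), 1),
                            np.nan)

    def maf(self) -> np.ndarray:
        f = self.frequencies()
        return np.minimum(f, 1.0 - f)

    def take_sites(self, index) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypePanel(self.hap_ids, self.subject_ids,
                              self.sites.take(index), self.alleles[:, index])

    def drop_subject(self, subject_id) -> "HaplotypePanel":
        idx = self.haps_of(subject_id)
        keep = np.setdiff1d(np.arange(self.n_haps), idx)
        return HaplotypePanel(self.hap_ids[keep], self.subject_ids[keep],
                              self.sites, self.alleles[keep])

    def to_genotypes(self, gq: float = 99.0, qual: float = 99.0) -> "GenotypeMatrix":
        """Collapse haplotype pairs to diploid calls (perfect qualities)."""
        subjects = self.subjects
        n, l = len(subjects), self.n_sites
        calls = np.empty((n, l), dtype=np.int8)
        for i, s in enumerate(subjects):
            rows = self.haps_of(s)
            if rows.size != 2:
                raise ValueError(f"subject {s!r} does not have exactly 2 haplotypes")
            pair = self.alleles[rows]
            g = pair.sum(0)
            g[np.any(pair == MISSING, axis=0)] = MISSING
            calls[i] = g
        return GenotypeMatrix(
            subjects=np.asarray(subjects, dtype=object), sites=self.sites,
            calls=calls,
            gq=np.full((n, l), gq, dtype=np.float32),
            site_qual=np.full(l, qual, dtype=np.float64),
        )

    @staticmethod
    def concatenate(a: "HaplotypePanel", b: "HaplotypePanel") -> "HaplotypePanel":
        """Stack two panels sharing the same SiteMap (haplotype-wise)."""
        if not a.sites.equals(b.sites):
            raise ValueError("panels must share an identical SiteMap")
        return HaplotypePanel(
            np.concatenate([a.hap_ids, b.hap_ids]),
            np.concatenate([a.subject_ids, b.subject_ids]),
            a.sites, np.vstack([a.alleles, b.alleles]),
        )

    def align_to(self, sites: SiteMap) -> "HaplotypePanel":
        """Re-express the panel on another site grid; absent sites are missing."""
        idx = self.sites.key_index()
        l = len(sites)
        alleles = np.full((self.n_haps, l), MISSING, dtype=np.int8)
        for j, key in enumerate(sites.keys()):
            i = idx.get(key)
            if i is not None:
                alleles[:, j] = self.alleles[:, i]
        return HaplotypePanel(self.hap_ids, self.subject_ids, sites, alleles)


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls with per-call GQ and per-site QUAL (phred)."""

    subjects: np.ndarray
    sites: SiteMap
    calls: np.ndarray      # int8 (N, L)
    gq: np.ndarray         # float32 (N, L)
    site_qual: np.ndarray  # float64 (L,)

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.gq = np.asarray(self.gq, dtype=np.float32)
        self.site_qual = np.asarray(self.site_qual, dtype=np.float64)
        n, l = self.calls.shape
        if len(self.subjects) != n:
            raise ValueError("subject count must match call rows")
        if l != len(self.sites):
            raise ValueError("call columns must match SiteMap length")
        if self.gq.shape != (n, l):
            raise ValueError("gq must match calls shape")
        if self.site_qual.shape != (l,):
            raise ValueError("site_qual must have one entry per site")
        if not np.isin(self.calls, (0, 1, 2, MISSING)).all():
            raise ValueError("calls must be 0, 1, 2 or missing")
        if (self.gq < 0).any() or (self.site_qual < 0).any():
            raise ValueError("phred qualities must be non-negative")

    @property
    def n_subjects(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def site_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def subject_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """(L, 3) counts of hom-ref / het / hom-alt among non-missing calls."""
        out = np.empty((self.n_sites, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.calls == g).sum(axis=0)
        return out

    def alt_frequency(self) -> np.ndarray:
        """Alt-allele frequency over non-missing calls (NaN where all missing)."""
        known = ~self.missing_mask()
        alt = np.where(known, self.calls, 0).sum(axis=0)
        denom = 2 * known.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, alt / np.maximum(denom, 1), np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(self.subjects, self.sites.take(index),
                              self.calls[:, index], self.gq[:, index],
                              self.site_qual[index])

    def take_subjects(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(self.subjects[index], self.sites,
                              self.calls[index], self.gq[index], self.site_qual)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.subjects.copy(), self.sites,
                              self.calls.copy(), self.gq.copy(),
                              self.site_qual.copy())


@dataclass
class DosageMatrix:
    """Imputed expected alt-allele dosages in [0, 2] per subject per site."""

    subjects: np.ndarray
    sites: SiteMap
    dosage: np.ndarray  # float64 (N, L)

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        n, l = self.dosage.shape
        if len(self.subjects) != n:
            raise ValueError("subject count must match dosage rows")
        if l != len(self.sites):
            raise ValueError("dosage columns must match SiteMap length")
        if np.nanmin(self.dosage, initial=0.0) < -1e-9 or \
           np.nanmax(self.dosage, initial=0.0) > 2.0 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]
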