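"""Sequence-data QC cascade, array-sequence merging and concordance checks.

The cascade applies, in order: site-quality filtering (QUAL >= 40), GQ
masking (calls with GQ < 20 set missing), site call-rate (>= 50%), minor
allele frequency (>= 0.75% of non-missing alleles — with ~100 diploid
subjects this means at least two minor alleles), an exact Hardy-Weinberg
test (p >= 1e-4), removal of multi-mapping sites and of non-SNV sites.
Array and sequence data for the same subjects are then merged, with
subjects/variants showing more than 50/30 mismatching calls excluded, and
the result is restricted to sites present (with matching allele codes) in
the global reference panel.  Each stage logs its removals in a QcReport.

Filters only mask or drop: a retained call's value is never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .panels import MISSING, GenotypeMatrix, HaplotypePanel

__all__ = [
    "QcThresholds", "QcStage", "QcReport",
    "hwe_exact_test", "apply_sequence_qc", "merge_array_sequence",
    "restrict_to_global_panel", "filter_subject_call_rate",
]


@dataclass
class QcThresholds:
    """Default thresholds of the sequence QC cascade."""

    min_site_qual: float = 40.0
    min_call_gq: float = 20.0
    min_call_rate: float = 0.5
    min_maf: float = 0.0075
    min_hwe_p: float = 1e-4
    drop_multimapping: bool = True
    snv_only: bool = True


@dataclass
class QcStage:
    stage: str
    n_removed_sites: int = 0
    n_removed_subjects: int = 0
    n_retained_sites: int = 0
    n_retained_subjects: int = 0
    detail: str = ""


@dataclass
class QcReport:
    """Ordered log of filter stages plus concordance summaries."""

    stages: list[QcStage] = field(default_factory=list)
    concordance: dict = field(default_factory=dict)

    def log(self, stage: str, *, removed_sites: int = 0, removed_subjects: int = 0,
            retained_sites: int = 0, retained_subjects: int = 0,
            detail: str = "") -> None:
        self.stages.append(QcStage(stage, removed_sites, removed_subjects,
                                   retained_sites, retained_subjects, detail))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage, s.n_removed_sites, s.n_removed_subjects,
              s.n_retained_sites, s.n_retained_subjects, s.detail)
             for s in self.stages],
            columns=["stage", "n_removed_sites", "n_removed_subjects",
                     "n_retained_sites", "n_retained_subjects", "detail"])

    def removed_at(self, stage: str) -> QcStage:
        for s in self.stages:
            if s.stage == stage:
                return s
        raise KeyError(stage)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

# Relative slack when comparing probability masses for the two-sided p-value;
# masses equal up to float rounding must count as "as extreme".
_HWE_REL_TOL = 1e-12


@lru_cache(maxsize=100_000)
def _hwe_pvalues(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional p-values for all heterozygote counts.

    Given ``n`` diploid genotypes carrying ``n_minor`` copies of the minor
    allele, the heterozygote count ``h`` has an exact conditional
    distribution under Hardy-Weinberg proportions.  Returns (het_counts,
    p_values), the two-sided p-value for each attainable ``h`` (sum of the
    conditional probabilities of all outcomes no more probable than ``h``).

    The distribution is built with the standard ratio recurrence
    P(h+2)/P(h) = 4*hom_minor*hom_major / ((h+2)*(h+1)).
    """
    h_min = n_minor % 2
    h_max = min(n_minor, 2 * n - n_minor)
    hets = np.arange(h_min, h_max + 1, 2)
    probs = np.empty(len(hets), dtype=np.float64)
    probs[0] = 1.0
    for i in range(len(hets) - 1):
        h = hets[i]
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        probs[i + 1] = probs[i] * 4.0 * hom_minor * hom_major / ((h + 2) * (h + 1))
        # renormalise on the fly to keep the recurrence in range
        if probs[i + 1] > 1e250:
            probs[: i + 2] /= 1e250
    probs /= probs.sum()
    pvals = np.array([probs[probs <= p * (1.0 + _HWE_REL_TOL)].sum()
                      for p in probs])
    np.minimum(pvals, 1.0, out=pvals)
    return hets, pvals


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    The p-value is the total conditional probability (given the allele
    counts and sample size) of all heterozygote counts whose probability
    does not exceed that of the observed count.  Monomorphic samples have a
    single attainable outcome and return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype is required")
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    hets, pvals = _hwe_pvalues(n, n_minor)
    i = np.searchsorted(hets, n_het)
    return float(pvals[i])


# ---------------------------------------------------------------------------
# sequence QC cascade


def apply_sequence_qc(gm: GenotypeMatrix,
                      thresholds: QcThresholds | None = None
                      ) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the ordered sequence-QC cascade; returns (filtered, report).

    Stage order: site QUAL, GQ masking, call rate, MAF, HWE, multi-mapping,
    non-SNV.  Masking precedes call-rate, call-rate precedes MAF, MAF
    precedes HWE; the report logs each stage in execution order.
    """
    if gm.n_sites == 0 or gm.n_subjects == 0:
        raise ValueError("empty genotype matrix")
    t = thresholds or QcThresholds()
    report = QcReport()
    out = gm.copy()

    def _keep_sites(mask: np.ndarray, stage: str, detail: str = "") -> None:
        nonlocal out
        removed = int((~mask).sum())
        out = out.take_sites(mask)
        report.log(stage, removed_sites=removed, retained_sites=out.n_sites,
                   retained_subjects=out.n_subjects, detail=detail)

    _keep_sites(out.site_qual >= t.min_site_qual, "site_qual",
                f"QUAL >= {t.min_site_qual:g}")

    mask_low = (out.gq < t.min_call_gq) & (out.calls != MISSING)
    out.calls[mask_low] = MISSING
    report.log("gq_mask", retained_sites=out.n_sites,
               retained_subjects=out.n_subjects,
               detail=f"{int(mask_low.sum())} calls with GQ < "
                      f"{t.min_call_gq:g} set missing")

    _keep_sites(out.site_call_rate() >= t.min_call_rate, "call_rate",
                f"call rate >= {t.min_call_rate:g}")

    maf = out.maf()
    _keep_sites(np.nan_to_num(maf, nan=-1.0) >= t.min_maf, "maf",
                f"MAF >= {t.min_maf:g} of non-missing alleles")

    counts = out.genotype_counts()
    hwe_p = np.array([hwe_exact_test(*c) if c.sum() > 0 else 1.0
                      for c in counts])
    _keep_sites(hwe_p >= t.min_hwe_p, "hwe", f"exact HWE p >= {t.min_hwe_p:g}")

    if t.drop_multimapping:
        _keep_sites(~out.sites.is_multimapping, "multimapping",
                    "multi-homologous-region sites removed")
    if t.snv_only:
        _keep_sites(out.sites.is_snv, "snv_only",
                    "non-single-base substitutions removed")
    return out, report


# ---------------------------------------------------------------------------
# array-sequence merge


def merge_array_sequence(array_gm: GenotypeMatrix, seq_gm: GenotypeMatrix,
                         max_subject_mismatches: int = 50,
                         max_variant_mismatches: int = 30
                         ) -> tuple[GenotypeMatrix, QcReport]:
    """Merge array and sequence calls for the shared subjects.

    Mismatching calls on overlapping sites are counted per subject and per
    variant BEFORE any exclusion; subjects with more than
    ``max_subject_mismatches`` and variants with more than
    ``max_variant_mismatches`` mismatches are dropped (values exactly at
    the threshold are retained).  The merged matrix covers the union of
    site sets; where both sources retain a call the sequence call wins.
    The report carries overall and minor-allele concordance by MAF band.
    """
    common = [s for s in seq_gm.subjects if s in set(array_gm.subjects)]
    if not common:
        raise ValueError("array and sequence data share no subjects")
    a_order = {s: i for i, s in enumerate(array_gm.subjects)}
    s_order = {s: i for i, s in enumerate(seq_gm.subjects)}
    arr = array_gm.take_subjects(np.array([a_order[s] for s in common]))
    seq = seq_gm.take_subjects(np.array([s_order[s] for s in common]))

    report = QcReport()
    a_keys = arr.sites.key_index()
    s_keys = seq.sites.key_index()
    overlap = [(a_keys[k], s_keys[k]) for k in s_keys if k in a_keys]
    mism_subj = np.zeros(len(common), dtype=np.int64)
    mism_var: dict[tuple[int, int], int] = {}
    n_compared = 0
    n_mismatch = 0
    minor_band_stats: dict[str, list[int]] = {}
    seq_maf = seq.maf()
    for ai, si in overlap:
        a_col, s_col = arr.calls[:, ai], seq.calls[:, si]
        both = (a_col != MISSING) & (s_col != MISSING)
        mm = both & (a_col != s_col)
        mism_subj += mm
        mism_var[(ai, si)] = int(mm.sum())
        n_compared += int(both.sum())
        n_mismatch += int(mm.sum())
        # minor-allele concordance: call pairs where either source carries at
        # least one minor allele, i.e. is not homozygous for the major allele
        maf = seq_maf[si]
        major_geno = 2 if seq.alt_frequency()[si] > 0.5 else 0
        involves = both & ((a_col != major_geno) | (s_col != major_geno))
        band = _maf_band(maf)
        st = minor_band_stats.setdefault(band, [0, 0])
        st[0] += int(involves.sum())
        st[1] += int((involves & mm).sum())

    bad_subj = mism_subj > max_subject_mismatches
    seq_keys_list = seq.sites.keys()
    bad_var_keys = {seq_keys_list[si] for (ai, si), c in mism_var.items()
                    if c > max_variant_mismatches}

    report.concordance["n_overlapping_variants"] = len(overlap)
    report.concordance["n_compared_calls"] = n_compared
    report.concordance["n_mismatching_calls"] = n_mismatch
    report.concordance["overall_pct"] = (
        100.0 * (1 - n_mismatch / n_compared) if n_compared else float("nan"))
    report.concordance["minor_allele_by_maf_band"] = {
        band: {"n_calls": c, "n_discrepant": d,
               "concordance_pct": 100.0 * (1 - d / c) if c else float("nan")}
        for band, (c, d) in sorted(minor_band_stats.items())}

    # drop bad subjects from both sources
    keep_subj = ~bad_subj
    arr = arr.take_subjects(keep_subj)
    seq = seq.take_subjects(keep_subj)
    report.log("merge_subject_mismatch",
               removed_subjects=int(bad_subj.sum()),
               retained_subjects=int(keep_subj.sum()),
               detail=f"> {max_subject_mismatches} array/sequence mismatches")

    # union of sites minus bad variants, sequence call wins at overlaps
    union: dict[tuple[int, str, str], tuple[str, int]] = {}
    for k, i in a_keys.items():
        union[k] = ("array", i)
    for k, i in s_keys.items():
        union[k] = ("seq", i)          # sequence wins
    removed_vars = [k for k in union if k in bad_var_keys]
    for k in removed_vars:
        del union[k]
    keys_sorted = sorted(union, key=lambda k: k[0])

    n = arr.n_subjects
    l = len(keys_sorted)
    calls = np.full((n, l), MISSING, dtype=np.int8)
    gq = np.zeros((n, l), dtype=np.float32)
    qual = np.zeros(l, dtype=np.float64)
    meta = {"chrom": [], "pos": [], "ids": [], "ref": [], "alt": [], "cm": [],
            "is_exomic": [], "is_array": [], "is_multimapping": []}
    for j, k in enumerate(keys_sorted):
        src, i = union[k]
        gsrc = seq if src == "seq" else arr
        col = gsrc.calls[:, i].copy()
        gq_col = gsrc.gq[:, i].copy()
        if src == "seq" and k in a_keys:
            # fill sequence-missing calls from the array where available
            ai = a_keys[k]
            fill = (col == MISSING) & (arr.calls[:, ai] != MISSING)
            col[fill] = arr.calls[fill, ai]
            gq_col[fill] = arr.gq[fill, ai]
        calls[:, j] = col
        gq[:, j] = gq_col
        qual[j] = gsrc.site_qual[i]
        sm = gsrc.sites
        meta["chrom"].append(sm.chrom[i])
        meta["pos"].append(sm.pos[i])
        meta["ids"].append(sm.ids[i])
        meta["ref"].append(sm.ref[i])
        meta["alt"].append(sm.alt[i])
        meta["cm"].append(sm.cm[i])
        meta["is_exomic"].append(sm.is_exomic[i])
        meta["is_array"].append(bool(k in a_keys))
        meta["is_multimapping"].append(sm.is_multimapping[i])
    from .sites import SiteMap
    sites = SiteMap(**meta)
    merged = GenotypeMatrix(arr.subjects, sites, calls, gq, qual)
    report.log("merge_variant_mismatch", removed_sites=len(removed_vars),
               retained_sites=merged.n_sites,
               retained_subjects=merged.n_subjects,
               detail=f"> {max_variant_mismatches} array/sequence mismatches")
    return merged, report


def _maf_band(maf: float) -> str:
    if not np.isfinite(maf) or maf < 0.01:
        return "<1%"
    if maf < 10 ** -1.5:
        return "1-3.2%"
    if maf < 0.1:
        return "3.2-10%"
    if maf < 10 ** -0.5:
        return "10-32%"
    return ">32%"


# ---------------------------------------------------------------------------
# panel intersection and subject call rate


def restrict_to_global_panel(gm: GenotypeMatrix, panel: HaplotypePanel
                             ) -> tuple[GenotypeMatrix, QcReport]:
    """Keep only sites present in the reference panel with matching alleles.

    A site at a panel position with different allele codes is excluded and
    logged separately from a site absent from the panel altogether.
    """
    report = QcReport()
    panel_keys = set(panel.sites.key_index())
    panel_pos = set(panel.sites.pos.tolist())
    keep = np.zeros(gm.n_sites, dtype=bool)
    n_absent = 0
    n_code_mismatch = 0
    for j, k in enumerate(gm.sites.keys()):
        if k in panel_keys:
            keep[j] = True
        elif k[0] in panel_pos:
            n_code_mismatch += 1
        else:
            n_absent += 1
    out = gm.take_sites(keep)
    report.log("panel_absent", removed_sites=n_absent,
               retained_sites=out.n_sites, retained_subjects=out.n_subjects,
               detail="not present in reference panel")
    report.log("panel_allele_mismatch", removed_sites=n_code_mismatch,
               retained_sites=out.n_sites, retained_subjects=out.n_subjects,
               detail="allele codes disagree with reference panel")
    return out, report


def filter_subject_call_rate(gm: GenotypeMatrix, min_rate: float = 0.8
                             ) -> tuple[GenotypeMatrix, QcReport]:
    """Drop subjects called at fewer than ``min_rate`` of sites.

    The threshold is exclusive ("fewer than"): a subject at exactly
    ``min_rate`` is retained.
    """
    if not 0.0 < min_rate <= 1.0:
        raise ValueError("min_rate must lie in (0, 1]")
    report = QcReport()
    keep = gm.subject_call_rate() >= min_rate
    out = gm.take_subjects(keep)
    report.log("subject_call_rate", removed_subjects=int((~keep).sum()),
               retained_sites=out.n_sites, retained_subjects=out.n_subjects,
               detail=f"subject call rate >= {min_rate:g}")
    return out, report
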