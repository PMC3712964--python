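"""Synthetic structured populations for imputation experiments.

The generator emulates the study design behind local-reference-panel
augmentation: a large "global" panel of phased haplotypes, and a small
sequenced cohort drawn from a drifted sister population whose allele
frequencies have diverged from the global panel.

Linkage disequilibrium is produced by founder-mosaic copying: every
haplotype is a mosaic of a founder pool, with copying switches occurring at
rate ``mosaic_switch_rate`` per Morgan along a genetic map.  The local
population is seeded from a subset of founders (a founding bottleneck) and
then drifts for ``drift_generations`` of haplotype resampling, which shifts
allele frequencies away from the global population while preserving block
LD — the regime in which adding a local reference panel to a global one
should help imputation most.

Site ascertainment mirrors practice: "array" sites are a random subset of
SNVs that are common in the GLOBAL panel (commercial arrays are designed on
cosmopolitan frequencies), while "exome" sites are all variants falling in
capture windows.  Called genotypes carry injected errors with phred-scaled
call (GQ) and site (QUAL) qualities so the QC cascade has real work to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .panels import MISSING, GenotypeMatrix, HaplotypePanel
from .sites import SiteMap

__all__ = [
    "SimConfig", "QualityModel", "TruthSet",
    "build_founder_pool", "sample_mosaic_haplotype", "simulate_populations",
    "inject_genotype_errors", "inject_switch_errors",
]


@dataclass
class QualityModel:
    """How phred qualities are assigned to simulated genotype calls.

    flag_prob
        Probability that an injected genotype error receives a low GQ
        (below ``low_gq``), so that GQ-masking at the usual threshold of 20
        catches a tunable share of errors.
    site_low_qual_frac
        Fraction of sites whose QUAL is drawn below ``low_qual_max`` —
        i.e. below any site-quality threshold chosen in that range.
    """

    flag_prob: float = 0.5
    low_gq: float = 10.0
    high_gq_min: float = 30.0
    high_gq_max: float = 99.0
    site_low_qual_frac: float = 0.02
    low_qual_min: float = 10.0
    low_qual_max: float = 39.0
    high_qual_min: float = 45.0
    high_qual_max: float = 99.0


@dataclass
class SimConfig:
    """All knobs of the population simulator (deterministic given ``seed``)."""

    n_founders: int = 120
    n_sites: int = 1200
    region_length: int = 3_000_000
    map_length: float = 3.0            # cM
    freq_spectrum_alpha: float = 1.0
    n_global_haps: int = 500
    n_local_subjects: int = 90
    local_founder_fraction: float = 0.3
    drift_generations: int = 10
    mosaic_switch_rate: float = 500.0  # switches per Morgan
    drift_switch_rate: float = 25.0    # switches per Morgan per drift epoch
    drift_pool_haps: int = 600         # haplotypes in the drifting population
    genotype_error_rate: float = 0.001
    phase_switch_rate: float = 0.0     # per het-interval
    array_ascertainment_maf: float = 0.10
    array_density: float = 0.5         # fraction of eligible common SNVs typed
    exome_fraction: float = 0.7
    indel_fraction: float = 0.02
    multimapping_fraction: float = 0.01
    quality_model: QualityModel = field(default_factory=QualityModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_sites", "region_length",
                     "n_global_haps", "n_local_subjects"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.map_length <= 0:
            raise ValueError("map_length must be positive")
        if self.mosaic_switch_rate < 0 or self.drift_switch_rate < 0:
            raise ValueError("switch rates must be non-negative")
        for name in ("genotype_error_rate", "phase_switch_rate",
                     "array_ascertainment_maf", "array_density",
                     "exome_fraction", "indel_fraction",
                     "multimapping_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.local_founder_fraction <= 1.0:
            raise ValueError("local_founder_fraction must lie in (0, 1]")
        if self.drift_generations < 0:
            raise ValueError("drift_generations must be >= 0")
        if self.drift_pool_haps < 2 * self.n_local_subjects:
            raise ValueError("drift_pool_haps must cover 2*n_local_subjects")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Gold-standard output of one simulation run.

    ``local_truth`` plays the role real QC'd sequence data play in a
    leave-one-out evaluation: both the local reference panel and the truth
    against which imputed dosages are scored.  ``local_called_genotypes`` is
    the error-injected, quality-annotated version the QC stage consumes.
    """

    global_panel: HaplotypePanel
    local_truth: HaplotypePanel
    local_called_genotypes: GenotypeMatrix
    site_map: SiteMap
    founder_segments: np.ndarray | None = None  # (H_global, L) copied founder idx
    local_array_calls: GenotypeMatrix | None = None
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        if not self.global_panel.sites.equals(self.site_map) or \
           not self.local_truth.sites.equals(self.site_map):
            raise ValueError("panels must share the TruthSet SiteMap")


# ---------------------------------------------------------------------------
# founders and site map


def _sample_spectrum(rng: np.random.Generator, n: int, alpha: float,
                     f_min: float) -> np.ndarray:
    """Draw n frequencies with density proportional to f^-alpha on [f_min, 0.5]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return f_min * (0.5 / f_min) ** u
    b = 1.0 - alpha
    lo, hi = f_min ** b, 0.5 ** b
    return (lo + u * (hi - lo)) ** (1.0 / b)


_BASES = np.array(list("ACGT"), dtype=object)


def _build_site_map(config: SimConfig, rng: np.random.Generator) -> SiteMap:
    n = config.n_sites
    if n == 0:
        raise ValueError("empty region: n_sites must be >= 1")
    pos = np.sort(rng.choice(np.arange(1, config.region_length + 1),
                             size=n, replace=False))
    # uniform recombination rate over the region
    cm = (pos - pos[0]) / max(pos[-1] - pos[0], 1) * config.map_length
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    ref = _BASES[ref_idx].copy()
    alt = _BASES[alt_idx].copy()
    is_indel = rng.random(n) < config.indel_fraction
    for i in np.flatnonzero(is_indel):
        alt[i] = str(ref[i]) + str(_BASES[rng.integers(0, 4)])
    is_multi = rng.random(n) < config.multimapping_fraction
    # exome capture windows covering ~exome_fraction of the region
    n_windows = 8
    edges = np.linspace(pos[0], pos[-1] + 1, n_windows + 1)
    covered = rng.permutation(n_windows) < round(config.exome_fraction * n_windows)
    window_of = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0,
                        n_windows - 1)
    is_exomic = covered[window_of]
    ids = np.array([f"snp{i:06d}" for i in range(n)], dtype=object)
    return SiteMap(chrom=np.full(n, "1", dtype=object), pos=pos, ids=ids,
                   ref=ref, alt=alt, cm=cm, is_exomic=is_exomic,
                   is_array=np.zeros(n, dtype=bool), is_multimapping=is_multi)


def build_founder_pool(config: SimConfig,
                       rng: np.random.Generator | None = None) -> HaplotypePanel:
    """Founder haplotypes with a rare-variant-heavy site frequency spectrum.

    Per-site founder allele frequencies are drawn from a density
    proportional to f^-alpha on [1/(2*n_founders), 0.5] and discretised to
    carrier counts.  Carriers of a variant form a contiguous block in a
    fixed circular ordering of the founders, emulating the clade structure
    of a genealogy: a common (old) variant is carried by a large block of
    similar founders and is therefore robustly tagged by nearby sites,
    while a rare (young) variant marks only a narrow clade.  LD along the
    genome is created later by mosaic copying.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    sites = _build_site_map(config, rng)
    nf, ns = config.n_founders, config.n_sites
    f = _sample_spectrum(rng, ns, config.freq_spectrum_alpha, 1.0 / (2 * nf))
    # stochastic rounding keeps E[carriers] = f * n_founders
    m = np.floor(f * nf).astype(np.int64)
    m += rng.random(ns) < (f * nf - m)
    offset = rng.integers(0, nf, size=ns)
    idx = np.arange(nf)[:, None]
    alleles = (((idx - offset[None, :]) % nf) < m[None, :]).astype(np.int8)
    hap_ids = np.array([f"founder{i}" for i in range(nf)], dtype=object)
    return HaplotypePanel(hap_ids, hap_ids.copy(), sites, alleles)


# ---------------------------------------------------------------------------
# mosaic copying


def _sample_mosaics(founder_alleles: np.ndarray, cm: np.ndarray,
                    switch_rate: float, n: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised mosaic sampler.

    Returns (alleles, copied_index) for ``n`` mosaics; the copied founder
    index changes between adjacent sites with probability
    1 - exp(-switch_rate * d_morgans); on a switch the new donor is uniform
    over the OTHER founders.
    """
    f, l = founder_alleles.shape
    d_m = np.diff(cm) / 100.0
    p_switch = 1.0 - np.exp(-switch_rate * d_m)
    idx = np.empty((n, l), dtype=np.int64)
    idx[:, 0] = rng.integers(0, f, size=n)
    if l > 1:
        switch = rng.random((n, l - 1)) < p_switch[None, :]
        # uniform over the f-1 other donors
        jump = rng.integers(1, max(f, 2), size=(n, l - 1))
        for j in range(1, l):
            prev = idx[:, j - 1]
            nxt = np.where(switch[:, j - 1], (prev + jump[:, j - 1]) % f, prev)
            idx[:, j] = nxt
    alleles = founder_alleles[idx, np.arange(l)[None, :]]
    return alleles.astype(np.int8), idx


def sample_mosaic_haplotype(founders: HaplotypePanel, site_map: SiteMap,
                            switch_rate: float,
                            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One mosaic haplotype over ``founders``; returns (alleles, copied_index)."""
    if founders.n_haps == 0:
        raise ValueError("founder panel is empty")
    if switch_rate < 0:
        raise ValueError("switch_rate must be non-negative")
    alleles, idx = _sample_mosaics(founders.alleles, site_map.cm, switch_rate,
                                   1, rng)
    return alleles[0], idx[0]


# ---------------------------------------------------------------------------
# populations


def simulate_populations(config: SimConfig) -> TruthSet:
    """Generate the full truth set: global panel, drifted local cohort, calls.

    The local population starts from a random founder subset of size
    ``ceil(local_founder_fraction * n_founders)`` (founding bottleneck) and
    then undergoes ``drift_generations`` rounds of re-mosaicking of the
    previous haplotype set at ``drift_switch_rate`` switches per Morgan
    per generation, so both allele-frequency divergence (resampling) and
    haplotype-structure divergence (novel segment junctions unseen in the
    global panel) grow with drift and with bottleneck severity.
    """
    ss = np.random.SeedSequence(config.seed)
    (r_founder, r_global, r_local, r_drift, r_array,
     r_geno, r_arraycall) = [np.random.default_rng(s) for s in ss.spawn(7)]

    founders = build_founder_pool(config, r_founder)
    sites = founders.sites

    g_alleles, g_idx = _sample_mosaics(founders.alleles, sites.cm,
                                       config.mosaic_switch_rate,
                                       config.n_global_haps, r_global)
    g_ids = np.array([f"g{i:04d}" for i in range(config.n_global_haps)],
                     dtype=object)
    g_subj = np.array([f"G{i // 2:04d}" for i in range(config.n_global_haps)],
                      dtype=object)

    n_local_founders = math.ceil(config.local_founder_fraction * config.n_founders)
    if n_local_founders < 1:
        raise ValueError("local founder subset is empty")
    subset = r_local.choice(config.n_founders, size=n_local_founders,
                            replace=False)
    # the whole isolate population drifts; the sequenced cohort is a sample
    n_local_haps = 2 * config.n_local_subjects
    pool = max(config.drift_pool_haps, n_local_haps)
    l_alleles, _ = _sample_mosaics(founders.alleles[subset], sites.cm,
                                   config.mosaic_switch_rate, pool, r_local)
    for _ in range(config.drift_generations):
        l_alleles, _ = _sample_mosaics(l_alleles, sites.cm,
                                       config.drift_switch_rate,
                                       pool, r_drift)
    l_alleles = l_alleles[r_drift.choice(pool, size=n_local_haps,
                                         replace=False)]

    l_ids = np.array([f"L{i // 2:03d}_{'AB'[i % 2]}" for i in range(n_local_haps)],
                     dtype=object)
    l_subj = np.array([f"L{i // 2:03d}" for i in range(n_local_haps)],
                      dtype=object)

    # array ascertainment on GLOBAL frequencies, SNVs only, sparse subset
    tmp_global = HaplotypePanel(g_ids, g_subj, sites, g_alleles)
    g_maf = tmp_global.maf()
    eligible = (g_maf >= config.array_ascertainment_maf) & sites.is_snv \
        & ~sites.is_multimapping
    is_array = eligible & (r_array.random(len(sites)) < config.array_density)
    sites = sites.with_flags(is_array=is_array)

    global_panel = HaplotypePanel(g_ids, g_subj, sites, g_alleles)
    local_truth = HaplotypePanel(l_ids, l_subj, sites, l_alleles)

    called = inject_genotype_errors(local_truth, config.genotype_error_rate,
                                    config.quality_model, r_geno)
    # independently assayed array genotypes for the concordance/merge stage
    array_calls = inject_genotype_errors(
        local_truth.take_sites(sites.is_array),
        config.genotype_error_rate / 2.0, config.quality_model, r_arraycall)

    return TruthSet(global_panel=global_panel, local_truth=local_truth,
                    local_called_genotypes=called, site_map=sites,
                    founder_segments=g_idx, local_array_calls=array_calls,
                    config=config)


# ---------------------------------------------------------------------------
# error injection


def inject_genotype_errors(truth: HaplotypePanel, rate: float,
                           quality_model: QualityModel,
                           rng: np.random.Generator) -> GenotypeMatrix:
    """Collapse haplotype pairs to calls and perturb them at ``rate``.

    Errors move one step in dosage (0<->1<->2); perturbed calls get a low GQ
    with probability ``quality_model.flag_prob`` so GQ-masking can recover a
    tunable share of them.  Site QUAL straddles the usual threshold of 40
    according to ``site_low_qual_frac``.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("error rate must lie in [0, 1)")
    gm = truth.to_genotypes()
    n, l = gm.calls.shape
    calls = gm.calls.copy()
    err = (rng.random((n, l)) < rate) & (calls != MISSING)
    if err.any():
        r, c = np.nonzero(err)
        g = calls[r, c]
        up = rng.random(len(r)) < 0.5
        new = np.where(g == 0, 1, np.where(g == 2, 1, np.where(up, 0, 2)))
        calls[r, c] = new.astype(np.int8)
    qm = quality_model
    gq = rng.uniform(qm.high_gq_min, qm.high_gq_max, size=(n, l)).astype(np.float32)
    flag = err & (rng.random((n, l)) < qm.flag_prob)
    gq[flag] = qm.low_gq
    site_qual = rng.uniform(qm.high_qual_min, qm.high_qual_max, size=l)
    low = rng.random(l) < qm.site_low_qual_frac
    site_qual[low] = rng.uniform(qm.low_qual_min, qm.low_qual_max, size=low.sum())
    return GenotypeMatrix(gm.subjects, truth.sites, calls, gq, site_qual)


def inject_switch_errors(haps: HaplotypePanel, rate: float,
                         rng: np.random.Generator) -> HaplotypePanel:
    """Introduce phasing switch errors; diploid genotypes are unchanged.

    Within each subject's haplotype pair, with probability ``rate`` per
    interval between consecutive heterozygous sites the parental assignment
    flips from that site onward.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("switch rate must lie in [0, 1)")
    alleles = haps.alleles.copy()
    for s in haps.subjects:
        rows = haps.haps_of(s)
        if rows.size != 2:
            raise ValueError(f"subject {s!r} does not have exactly 2 haplotypes")
        a, b = alleles[rows[0]], alleles[rows[1]]
        het = np.flatnonzero((a != b) & (a != MISSING) & (b != MISSING))
        if het.size < 2:
            continue
        flips = rng.random(het.size - 1) < rate
        orient = np.concatenate([[False], np.logical_xor.accumulate(flips)])
        swap_at = het[orient]
        a[swap_at], b[swap_at] = b[swap_at].copy(), a[swap_at].copy()
    return HaplotypePanel(haps.hap_ids.copy(), haps.subject_ids.copy(),
                          haps.sites, alleles)
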