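"""Haploid Li-Stephens haplotype-copying HMM for genotype imputation.

A target haplotype is modelled as an imperfect mosaic copy of the H
haplotypes of a reference panel.  Hidden state = the reference haplotype
currently copied; transitions between adjacent sites follow the standard
copying-model kernel with no-switch probability exp(-4*Ne*d/H) over genetic
distance d (Morgans), the switch mass spread uniformly over all H states
(self included).  Emissions allow miscopying with probability lambda,
derived from Watterson's theta: theta = 1/sum_{i<H}(1/i) and
lambda = theta / (2*(H + theta)).

The HMM runs over the FULL site grid of the panel; only typed (array)
sites emit, untyped sites are silent (emission 1 for every state), so the
posterior copying probabilities at untyped sites are exact rather than
interpolated.  The recursion is scaled (per-site normalisation) in linear
space.

Two reference panels — a large global panel and a small local one — are
combined by simple haplotype concatenation over the global panel's site
grid; sites absent from the local panel carry missing alleles, which emit
probability 0.5.  Lambda is recomputed for the combined haplotype count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .panels import MISSING, HaplotypePanel

__all__ = [
    "HmmParams", "LeaveOneOutViolation",
    "compute_lambda", "no_switch_prob", "forward_backward",
    "combine_panels", "impute_dosage",
]


class LeaveOneOutViolation(ValueError):
    """The subject being imputed is present in a reference panel."""


@dataclass
class HmmParams:
    """Tunable copying-model parameters.

    ne
        Effective population size scaling the recombination term (default
        20,000, the value used for human imputation at this panel scale).
    miscopy_lambda
        Mutation/miscopy probability; ``None`` derives it from the panel
        haplotype count via :func:`compute_lambda`.
    min_no_switch
        Floor on the per-interval no-switch probability (numerical guard
        against fully forgetting the chain over long gaps).
    """

    ne: float = 20_000.0
    miscopy_lambda: float | None = None
    min_no_switch: float = 1e-12

    def __post_init__(self) -> None:
        if self.ne < 1:
            raise ValueError("ne must be >= 1")
        if self.miscopy_lambda is not None and not (
                0.0 <= self.miscopy_lambda < 0.5):
            raise ValueError("miscopy_lambda must lie in [0, 0.5)")

    def lam(self, n_haps: int) -> float:
        return self.miscopy_lambda if self.miscopy_lambda is not None \
            else compute_lambda(n_haps)


def compute_lambda(n_haps: int) -> float:
    """Miscopy probability from Watterson's theta for an H-haplotype panel.

    theta = 1 / sum_{i=1}^{H-1} 1/i;  lambda = theta / (2*(H + theta)).
    Strictly decreasing in H; lambda(2) = 1/6.
    """
    if n_haps < 2:
        raise ValueError("panel must contain at least 2 haplotypes")
    theta = 1.0 / np.sum(1.0 / np.arange(1, n_haps))
    return float(theta / (2.0 * (n_haps + theta)))


def no_switch_prob(d_cm: float, ne: float, n_haps: int) -> float:
    """Probability of copying the same reference haplotype across d_cm.

    exp(-4*Ne*d/H) with d in Morgans; the complementary switch mass is
    distributed uniformly over all H states including the current one.
    """
    if np.any(np.asarray(d_cm) < 0):
        raise ValueError("genetic distance must be non-negative")
    return np.exp(-4.0 * ne * (np.asarray(d_cm, dtype=float) / 100.0) / n_haps)


def _emissions(obs: np.ndarray, panel_alleles: np.ndarray,
               lam: float) -> np.ndarray:
    """(T, H) emission probabilities at the typed sites.

    Match -> 1-lam, mismatch -> lam, missing panel allele -> 0.5, missing
    observation -> 1 (uninformative).
    """
    a = panel_alleles  # (H, T)
    e = np.where(a.T == obs[:, None], 1.0 - lam, lam)
    e[(a.T == MISSING)] = 0.5
    e[obs == MISSING, :] = 1.0
    return e


def forward_backward(obs: np.ndarray, typed_idx: np.ndarray,
                     panel: HaplotypePanel,
                     params: HmmParams | None = None) -> np.ndarray:
    """Posterior copying probabilities gamma (L, H) over the full site grid.

    Parameters
    ----------
    obs : int8 array over the typed sites (0/1, missing allowed).
    typed_idx : sorted 0-based indices of the typed sites within the grid.
    panel : reference haplotypes over the full grid.
    params : HMM parameters; defaults to :class:`HmmParams`.
    """
    params = params or HmmParams()
    H, L = panel.alleles.shape
    obs = np.asarray(obs, dtype=np.int8)
    typed_idx = np.asarray(typed_idx, dtype=np.int64)
    if obs.shape != typed_idx.shape:
        raise ValueError("obs and typed_idx must have equal length")
    if typed_idx.size and (typed_idx.min() < 0 or typed_idx.max() >= L):
        raise ValueError("typed site index outside the site grid")
    if typed_idx.size > 1 and np.any(np.diff(typed_idx) <= 0):
        raise ValueError("typed_idx must be strictly increasing")
    if H == 1:
        return np.ones((L, 1))
    lam = params.lam(H)
    if typed_idx.size == 0 or np.all(obs == MISSING):
        warnings.warn("all observations missing; returning uniform posteriors")
        return np.full((L, H), 1.0 / H)

    emit = np.ones((L, H))
    emit[typed_idx] = _emissions(obs, panel.alleles[:, typed_idx], lam)

    d_cm = panel.sites.interval_cm()
    p_ns = np.maximum(no_switch_prob(d_cm, params.ne, H), params.min_no_switch)

    fwd = np.empty((L, H))
    f = emit[0] / H
    fwd[0] = f / f.sum()
    for t in range(1, L):
        p = p_ns[t - 1]
        f = emit[t] * (p * fwd[t - 1] + (1.0 - p) / H)
        fwd[t] = f / f.sum()

    bwd = np.empty((L, H))
    b = np.ones(H)
    bwd[-1] = b
    for t in range(L - 2, -1, -1):
        p = p_ns[t]
        eb = emit[t + 1] * bwd[t + 1]
        b = p * eb + (1.0 - p) * eb.mean()
        bwd[t] = b / b.sum()

    gamma = fwd * bwd
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma


def combine_panels(primary: HaplotypePanel,
                   secondary: HaplotypePanel) -> HaplotypePanel:
    """Concatenate a secondary panel onto the primary panel's site grid.

    Secondary-panel sites are matched by (position, ref, alt); sites of the
    primary grid absent from the secondary panel are filled with missing
    alleles (which emit 0.5 in the HMM).  This mirrors supplying two
    reference panels without merging them into consensus haplotypes.
    """
    if secondary.sites.equals(primary.sites):
        aligned = secondary
    else:
        aligned = secondary.align_to(primary.sites)
    return HaplotypePanel.concatenate(primary, aligned)


def _allele_prob(gamma: np.ndarray, panel_alleles: np.ndarray,
                 lam: float) -> np.ndarray:
    """P(target allele = 1) per site from copying posteriors."""
    a = panel_alleles  # (H, L)
    e1 = np.where(a == 1, 1.0 - lam, lam)
    e1 = np.where(a == MISSING, 0.5, e1)
    return np.einsum("lh,hl->l", gamma, e1)


def impute_dosage(hap_a: np.ndarray, hap_b: np.ndarray,
                  typed_idx: np.ndarray,
                  panels: tuple[HaplotypePanel, ...],
                  params: HmmParams | None = None,
                  subject_id=None) -> np.ndarray:
    """Impute a diploid subject's expected alt-allele dosage at every site.

    ``hap_a``/``hap_b`` are the subject's phased alleles at the typed
    sites.  ``panels`` holds one (global) or two (global, local) reference
    panels; two panels are concatenated on the first panel's site grid and
    lambda recomputed for the combined haplotype count.  If ``subject_id``
    is given, its presence in any panel raises
    :class:`LeaveOneOutViolation` (anti-circularity guard).
    """
    params = params or HmmParams()
    if not panels:
        raise ValueError("at least one reference panel is required")
    if subject_id is not None:
        for p in panels:
            if np.any(p.subject_ids == subject_id):
                raise LeaveOneOutViolation(
                    f"subject {subject_id!r} present in a reference panel")
    panel = panels[0]
    for extra in panels[1:]:
        panel = combine_panels(panel, extra)
    lam = params.lam(panel.n_haps)
    dosage = np.zeros(panel.n_sites)
    for hap in (hap_a, hap_b):
        gamma = forward_backward(hap, typed_idx, panel, params)
        dosage += _allele_prob(gamma, panel.alleles, lam)
    return np.clip(dosage, 0.0, 2.0)
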