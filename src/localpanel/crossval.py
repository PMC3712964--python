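"""Leave-one-out evaluation of imputation accuracy with and without a
local reference panel.

Each sequenced subject is imputed twice from their phased array-site
haplotypes: (i) against the global panel alone, and (ii) against the global
panel plus the local panel with that subject's own two haplotypes removed
(drop-one-out, so the subject's imputation panel never contains their own
sequence).  Per SNP, the squared Pearson correlation (r^2) between imputed
dosage and gold-standard genotype across subjects measures accuracy; per-
MAF-bin summaries, the poor-to-well rescue crosstab, the local-by-global
MAF improvement grid, and the effective-sample-size conversion reproduce
the standard reporting layout for this design.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .lshmm import HmmParams, impute_dosage
from .panels import MISSING, HaplotypePanel
from .synthpop import TruthSet

__all__ = [
    "MAF_BIN_EDGES", "MAF_BIN_LABELS", "GLOBAL_BAND_LABELS",
    "leave_one_out_panel", "snp_r2", "assign_maf_bin", "run_crossval",
    "summarize_bins", "ess_increase", "poor_to_well_crosstab",
    "improvement_grid",
]

#: sqrt(10)-spaced MAF bin edges: 1%, 3.2%, 10%, 32%, 50%.
MAF_BIN_EDGES = (10 ** -2, 10 ** -1.5, 10 ** -1, 10 ** -0.5, 0.5)
MAF_BIN_LABELS = ("1-3.2%", "3.2-10%", "10-32%", ">32%")
BELOW_RANGE_LABEL = "<1%"
#: coarser bands used when stratifying by global-panel MAF
GLOBAL_BAND_EDGES = (0.0, 10 ** -2, 10 ** -1.5, 0.5)
GLOBAL_BAND_LABELS = ("<1%", "1-3.2%", ">3.2%")


def leave_one_out_panel(local: HaplotypePanel, subject_id) -> HaplotypePanel:
    """Local panel with one subject's two haplotypes removed."""
    rows = local.haps_of(subject_id)  # KeyError if unknown
    if rows.size != 2:
        raise ValueError(f"subject {subject_id!r} must have exactly 2 haplotypes")
    return local.drop_subject(subject_id)


def snp_r2(dosage: np.ndarray, truth_genotypes: np.ndarray) -> float | None:
    """Squared Pearson correlation of dosage vs truth across subjects.

    Pairs with missing truth are dropped (complete-case).  Returns ``None``
    when fewer than 2 complete pairs remain or either vector is constant.
    """
    dosage = np.asarray(dosage, dtype=float)
    truth = np.asarray(truth_genotypes, dtype=float)
    if dosage.shape != truth.shape:
        raise ValueError("dosage and truth vectors must have equal length")
    ok = np.isfinite(dosage) & np.isfinite(truth) & (truth != MISSING)
    d, t = dosage[ok], truth[ok]
    if d.size < 2 or np.ptp(d) == 0 or np.ptp(t) == 0:
        return None
    r = np.corrcoef(d, t)[0, 1]
    return float(r * r)


def assign_maf_bin(maf: float) -> str:
    """sqrt(10)-spaced MAF bin label; lower-inclusive, upper bin closed at 0.5."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("MAF must lie in (0, 0.5]")
    if maf < MAF_BIN_EDGES[0]:
        return BELOW_RANGE_LABEL
    for lo, hi, label in zip(MAF_BIN_EDGES[:-1], MAF_BIN_EDGES[1:],
                             MAF_BIN_LABELS):
        if lo <= maf < hi:
            return label
    return MAF_BIN_LABELS[-1]  # maf == 0.5


def _assign_global_band(maf: float) -> str:
    if not np.isfinite(maf):
        return BELOW_RANGE_LABEL
    if maf < GLOBAL_BAND_EDGES[1]:
        return GLOBAL_BAND_LABELS[0]
    if maf < GLOBAL_BAND_EDGES[2]:
        return GLOBAL_BAND_LABELS[1]
    return GLOBAL_BAND_LABELS[2]


# ---------------------------------------------------------------------------
# the evaluation itself


def run_crossval(truth: TruthSet, params: HmmParams | None = None,
                 local_panel: HaplotypePanel | None = None,
                 target_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Drop-one-out accuracy table over the exomic non-array target sites.

    For every local subject the expected dosage at all sites is imputed
    from the subject's phased array-site alleles under both panel
    configurations; per-site r^2 vs the gold-standard genotypes is then
    computed across subjects.  Returns one row per target SNP with columns
    ``site_id, pos, maf_local, maf_global, r2_one_panel, r2_two_panel,
    n_subjects_used``; sites monomorphic among the sequenced subjects get
    NaN r^2 and are excluded from downstream summaries.

    ``local_panel`` defaults to the truth haplotypes (use a switch-error-
    injected or QC-restricted panel to study those effects); the subject's
    observed array alleles always come from the truth haplotypes.
    """
    params = params or HmmParams()
    sm = truth.site_map
    gp = truth.global_panel
    lp = local_panel if local_panel is not None else truth.local_truth
    subjects = lp.subjects
    if len(subjects) < 3:
        raise ValueError("cross-validation requires at least 3 subjects")

    gfreq = gp.frequencies()
    polymorphic = (gfreq > 0) & (gfreq < 1)
    if target_mask is None:
        target_mask = (sm.is_exomic & ~sm.is_array & polymorphic
                       & sm.is_snv & ~sm.is_multimapping)
    target_idx = np.flatnonzero(target_mask)
    typed_idx = np.flatnonzero(sm.is_array)

    n = len(subjects)
    dos1 = np.empty((n, len(sm)))
    dos2 = np.empty((n, len(sm)))
    for i, s in enumerate(subjects):
        rows = truth.local_truth.haps_of(s)
        hap_a = truth.local_truth.alleles[rows[0], typed_idx]
        hap_b = truth.local_truth.alleles[rows[1], typed_idx]
        dos1[i] = impute_dosage(hap_a, hap_b, typed_idx, (gp,), params)
        loo = leave_one_out_panel(lp, s)
        dos2[i] = impute_dosage(hap_a, hap_b, typed_idx, (gp, loo), params,
                                subject_id=s)

    truth_gm = truth.local_truth.to_genotypes()
    order = {s: i for i, s in enumerate(truth_gm.subjects)}
    truth_calls = truth_gm.calls[[order[s] for s in subjects]]

    lfreq = truth_gm.alt_frequency()
    records = []
    for j in target_idx:
        g = truth_calls[:, j]
        r2_one = snp_r2(dos1[:, j], g)
        r2_two = snp_r2(dos2[:, j], g)
        n_used = int((g != MISSING).sum())
        f_l = lfreq[j]
        records.append((
            sm.ids[j], int(sm.pos[j]),
            float(min(f_l, 1 - f_l)) if np.isfinite(f_l) else np.nan,
            float(min(gfreq[j], 1 - gfreq[j])),
            np.nan if r2_one is None else r2_one,
            np.nan if r2_two is None else r2_two,
            n_used,
        ))
    return pd.DataFrame(records, columns=[
        "site_id", "pos", "maf_local", "maf_global",
        "r2_one_panel", "r2_two_panel", "n_subjects_used"])


# ---------------------------------------------------------------------------
# summaries


def _defined(table: pd.DataFrame) -> pd.DataFrame:
    return table.dropna(subset=["r2_one_panel", "r2_two_panel"])


def summarize_bins(table: pd.DataFrame, bin_by: str = "local") -> pd.DataFrame:
    """Per-MAF-bin accuracy summary (the Table-1-style layout).

    ``bin_by='local'`` bins on the gold-standard local MAF into the four
    sqrt(10)-spaced bins (records below 1% are excluded); ``bin_by='global'``
    stratifies on global-panel MAF into <1%, 1-3.2%, >3.2% bands.
    Columns include mean/median r^2 under each configuration, the mean,
    SD and SE of the per-SNP increase, the effective-sample-size increase
    (whole percent), a two-sided one-sample t-test of the increase against
    zero and a Welch test against the next bin.
    """
    if bin_by not in ("local", "global"):
        raise ValueError("bin_by must be 'local' or 'global'")
    df = _defined(table).copy()
    if bin_by == "local":
        df = df[(df["maf_local"] > 0) & (df["maf_local"] >= MAF_BIN_EDGES[0])]
        df["bin"] = [assign_maf_bin(m) for m in df["maf_local"]]
        labels = MAF_BIN_LABELS
    else:
        df["bin"] = [_assign_global_band(m) for m in df["maf_global"]]
        labels = GLOBAL_BAND_LABELS
    df["increase"] = df["r2_two_panel"] - df["r2_one_panel"]

    rows = []
    groups = {label: df[df["bin"] == label] for label in labels}
    for i, label in enumerate(labels):
        g = groups[label]
        n = len(g)
        if n == 0:
            rows.append({"bin": label, "n_snps": 0})
            continue
        inc = g["increase"].to_numpy()
        m1 = float(g["r2_one_panel"].mean())
        m2 = float(g["r2_two_panel"].mean())
        sd = float(np.std(inc, ddof=1)) if n > 1 else np.nan
        se = sd / math.sqrt(n) if n > 1 else np.nan
        p0 = float(stats.ttest_1samp(inc, 0.0).pvalue) if n > 1 else np.nan
        nxt = labels[i + 1] if i + 1 < len(labels) else None
        if nxt is not None and len(groups[nxt]) > 1 and n > 1:
            p_adj = float(stats.ttest_ind(
                inc, groups[nxt]["increase"].to_numpy(), equal_var=False).pvalue)
        else:
            p_adj = np.nan
        rows.append({
            "bin": label, "n_snps": n,
            "mean_r2_one": m1, "mean_r2_two": m2,
            "mean_increase": float(inc.mean()),
            "sd_increase": sd, "se_increase": se,
            "ess_increase_pct": round(ess_increase(m1, m2)) if m1 > 0 else np.nan,
            "t_p_vs_zero": p0, "t_p_vs_next_bin": p_adj,
            "median_r2_one": float(g["r2_one_panel"].median()),
            "median_r2_two": float(g["r2_two_panel"].median()),
        })
    return pd.DataFrame(rows)


def ess_increase(mean_r2_one: float, mean_r2_two: float) -> float:
    """Effective-sample-size increase, percent: 100*(r2_two/r2_one - 1).

    A proportionate increase in imputation r^2 acts on association power
    like the same proportionate increase in study size.
    """
    if mean_r2_one <= 0:
        raise ValueError("baseline mean r^2 must be positive")
    return 100.0 * (mean_r2_two / mean_r2_one - 1.0)


def poor_to_well_crosstab(table: pd.DataFrame, poor: float = 0.2,
                          well: float = 0.8) -> tuple[float, float | None]:
    """Fraction of SNPs imputed poorly one-panel, and the rescued share.

    Returns (fraction with one-panel r^2 < ``poor``, fraction of THOSE with
    two-panel r^2 > ``well``); the second is ``None`` when no SNP is poor.
    """
    if not (0.0 < poor < well < 1.0):
        raise ValueError("thresholds must satisfy 0 < poor < well < 1")
    df = _defined(table)
    if len(df) == 0:
        return 0.0, None
    poor_mask = df["r2_one_panel"] < poor
    frac_poor = float(poor_mask.mean())
    if poor_mask.sum() == 0:
        return frac_poor, None
    rescued = float((df.loc[poor_mask, "r2_two_panel"] > well).mean())
    return frac_poor, rescued


def improvement_grid(table: pd.DataFrame,
                     local_edges: tuple = (0.01, 10 ** -1.5, 0.1),
                     global_edges: tuple = (0.0, 0.01, 10 ** -1.5, 0.1, 0.5),
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2-D mean-improvement grid: local-sequence MAF x global-panel MAF.

    Default rows cover local MAF 1-10% (the range where augmentation
    matters most); columns include a global "<1%" band.  Returns aligned
    (mean_increase, counts) DataFrames; empty cells carry NaN means.
    """
    df = _defined(table).copy()
    df["increase"] = df["r2_two_panel"] - df["r2_one_panel"]
    row_labels = [f"{lo * 100:.3g}-{hi * 100:.3g}%"
                  for lo, hi in zip(local_edges[:-1], local_edges[1:])]
    col_labels = [f"{lo * 100:.3g}-{hi * 100:.3g}%" if lo > 0
                  else f"<{hi * 100:.3g}%"
                  for lo, hi in zip(global_edges[:-1], global_edges[1:])]
    means = pd.DataFrame(np.nan, index=row_labels, columns=col_labels)
    counts = pd.DataFrame(0, index=row_labels, columns=col_labels)
    for ri, (rlo, rhi) in enumerate(zip(local_edges[:-1], local_edges[1:])):
        for ci, (clo, chi) in enumerate(zip(global_edges[:-1], global_edges[1:])):
            cell = df[(df["maf_local"] >= rlo) & (df["maf_local"] < rhi)
                      & (df["maf_global"] >= clo) & (df["maf_global"] < chi)]
            counts.iat[ri, ci] = len(cell)
            if len(cell):
                means.iat[ri, ci] = float(cell["increase"].mean())
    return means, counts
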