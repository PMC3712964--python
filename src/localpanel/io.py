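"""Readers and writers for the formats the pipeline exchanges.

* VCF 4.2 with GT, GQ (FORMAT) and QUAL — written as plain text, parsed
  with cyvcf2.  Multi-allelic records are skipped with a counted warning.
* IMPUTE2 ``.hap`` / ``.legend`` / ``.sample`` reference-panel triplets.
* 3-column genetic maps (position, rate cM/Mb, cumulative cM).
* Tab-separated report tables.

Every file written starts with a comment header carrying the tool version,
a hash of the generating configuration and the seed, so outputs are
self-describing and diffable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .panels import MISSING, GenotypeMatrix, HaplotypePanel
from .sites import SiteMap

__all__ = [
    "config_hash", "meta_comment",
    "write_vcf", "read_vcf_genotypes", "read_vcf_panel",
    "write_impute2_panel", "read_impute2_panel",
    "write_genetic_map", "read_genetic_map", "genetic_positions",
    "write_tsv", "read_tsv",
]


def config_hash(config) -> str:
    """Short stable hash of a configuration mapping/dataclass."""
    if hasattr(config, "to_dict"):
        config = config.to_dict()
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def meta_comment(seed=None, config=None, prefix: str = "#") -> str:
    parts = [f"{prefix} localpanel v{__version__}"]
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# VCF


def _format_gt(call: int, phased_pair=None) -> str:
    if phased_pair is not None:
        a, b = phased_pair
        fa = "." if a == MISSING else str(int(a))
        fb = "." if b == MISSING else str(int(b))
        return f"{fa}|{fb}"
    if call == MISSING:
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(call)]


def write_vcf(obj, path, seed=None, config=None) -> Path:
    """Write a GenotypeMatrix (unphased GT/GQ/QUAL) or HaplotypePanel
    (phased GT) as a VCF 4.2 text file."""
    path = Path(path)
    is_panel = isinstance(obj, HaplotypePanel)
    sites = obj.sites
    if is_panel:
        subjects = obj.subjects
        pairs = {s: obj.haps_of(s) for s in subjects}
    else:
        subjects = list(obj.subjects)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(meta_comment(seed=seed, config=config, prefix="##source=")
                 .replace("##source= ", "##source=") + "\n")
        contigs = sorted(set(sites.chrom.tolist()))
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if not is_panel:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                     'Description="Phred-scaled genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in subjects) + "\n")
        for j in range(len(sites)):
            qual = "." if is_panel else f"{obj.site_qual[j]:g}"
            fields = [str(sites.chrom[j]), str(sites.pos[j]), str(sites.ids[j]),
                      str(sites.ref[j]), str(sites.alt[j]), qual, "PASS", ".",
                      "GT" if is_panel else "GT:GQ"]
            if is_panel:
                for s in subjects:
                    r = pairs[s]
                    fields.append(_format_gt(
                        None, (obj.alleles[r[0], j], obj.alleles[r[1], j])))
            else:
                for i in range(obj.n_subjects):
                    gt = _format_gt(obj.calls[i, j])
                    fields.append(f"{gt}:{int(round(obj.gq[i, j]))}")
            fh.write("\t".join(fields) + "\n")
    return path


class VcfGenotypes(NamedTuple):
    matrix: GenotypeMatrix
    n_multiallelic_skipped: int


class VcfPanel(NamedTuple):
    panel: HaplotypePanel
    n_multiallelic_skipped: int


def _load_vcf(path):
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    records = []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        try:
            gq = v.format("GQ")
        except KeyError:
            gq = None
        records.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}",
                        v.REF, v.ALT[0], v.QUAL, list(v.genotypes),
                        None if gq is None else np.asarray(gq).ravel()))
    if skipped:
        warnings.warn(f"skipped {skipped} multi-allelic record(s)")
    return subjects, records, skipped


def _sitemap_from_records(records) -> SiteMap:
    n = len(records)
    return SiteMap(
        chrom=np.array([r[0] for r in records], dtype=object),
        pos=np.array([r[1] for r in records], dtype=np.int64),
        ids=np.array([r[2] for r in records], dtype=object),
        ref=np.array([r[3] for r in records], dtype=object),
        alt=np.array([r[4] for r in records], dtype=object),
        cm=np.zeros(n), is_exomic=np.zeros(n, dtype=bool),
        is_array=np.zeros(n, dtype=bool),
        is_multimapping=np.zeros(n, dtype=bool))


def read_vcf_genotypes(path) -> VcfGenotypes:
    """Read a VCF into a GenotypeMatrix (GT + GQ + QUAL).

    Multi-allelic records are skipped and counted; a missing GQ field
    yields GQ 99 (treated as confident).
    """
    subjects, records, skipped = _load_vcf(path)
    n, l = len(subjects), len(records)
    calls = np.full((n, l), MISSING, dtype=np.int8)
    gq = np.full((n, l), 99.0, dtype=np.float32)
    qual = np.zeros(l)
    for j, (_, _, _, _, _, q, genos, gq_col) in enumerate(records):
        qual[j] = 0.0 if q is None else q
        for i, g in enumerate(genos):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                calls[i, j] = a + b
        if gq_col is not None:
            gq[:, j] = gq_col
    sites = _sitemap_from_records(records)
    return VcfGenotypes(GenotypeMatrix(np.array(subjects, dtype=object),
                                       sites, calls, gq, qual), skipped)


def read_vcf_panel(path) -> VcfPanel:
    """Read a phased VCF into a HaplotypePanel (errors on unphased calls)."""
    subjects, records, skipped = _load_vcf(path)
    n, l = len(subjects), len(records)
    alleles = np.full((2 * n, l), MISSING, dtype=np.int8)
    for j, (_, _, _, _, _, _, genos, _) in enumerate(records):
        for i, g in enumerate(genos):
            a, b, phased = g[0], g[1], g[2]
            if (a >= 0 or b >= 0) and not phased and a != b:
                raise ValueError(
                    f"unphased heterozygous call for sample {subjects[i]} "
                    f"at record {j}; a panel requires phased GT")
            alleles[2 * i, j] = a if a >= 0 else MISSING
            alleles[2 * i + 1, j] = b if b >= 0 else MISSING
    hap_ids = np.array([f"{s}_{x}" for s in subjects for x in "AB"],
                       dtype=object)
    subj_ids = np.array([s for s in subjects for _ in "AB"], dtype=object)
    sites = _sitemap_from_records(records)
    return VcfPanel(HaplotypePanel(hap_ids, subj_ids, sites, alleles), skipped)


# ---------------------------------------------------------------------------
# IMPUTE2 hap/legend/sample


def write_impute2_panel(panel: HaplotypePanel, prefix, seed=None,
                        config=None) -> tuple[Path, Path, Path]:
    """Write a panel as ``<prefix>.hap`` / ``.legend`` / ``.sample``."""
    hap_p, leg_p, sam_p = (Path(f"{prefix}.hap"), Path(f"{prefix}.legend"),
                           Path(f"{prefix}.sample"))
    with open(hap_p, "w") as fh:
        for j in range(panel.n_sites):
            row = ("?" if a == MISSING else str(int(a))
                   for a in panel.alleles[:, j])
            fh.write(" ".join(row) + "\n")
    with open(leg_p, "w") as fh:
        fh.write(meta_comment(seed=seed, config=config) + "\n")
        fh.write("id position a0 a1\n")
        for j in range(panel.n_sites):
            s = panel.sites
            fh.write(f"{s.ids[j]} {s.pos[j]} {s.ref[j]} {s.alt[j]}\n")
    with open(sam_p, "w") as fh:
        fh.write(meta_comment(seed=seed, config=config) + "\n")
        fh.write("hap_id subject_id\n")
        for h, s in zip(panel.hap_ids, panel.subject_ids):
            fh.write(f"{h} {s}\n")
    return hap_p, leg_p, sam_p


def read_impute2_panel(prefix) -> HaplotypePanel:
    """Read a ``.hap``/``.legend``/``.sample`` triplet back into a panel."""
    hap_p, leg_p, sam_p = (Path(f"{prefix}.hap"), Path(f"{prefix}.legend"),
                           Path(f"{prefix}.sample"))
    legend = []
    with open(leg_p) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("id "):
                continue
            vid, pos, a0, a1 = line.split()
            legend.append((vid, int(pos), a0, a1))
    positions = [p for _, p, _, _ in legend]
    if len(set(positions)) != len(positions):
        raise ValueError(f"{leg_p.name}: duplicated position in legend")
    haps = []
    with open(hap_p) as fh:
        for line in fh:
            haps.append([MISSING if tok == "?" else int(tok)
                         for tok in line.split()])
    if len(haps) != len(legend):
        raise ValueError(f"{hap_p.name}: row count does not match legend")
    alleles = np.array(haps, dtype=np.int8).T  # rows were sites
    sam = []
    with open(sam_p) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("hap_id"):
                continue
            h, s = line.split()
            sam.append((h, s))
    if len(sam) != alleles.shape[0]:
        raise ValueError(f"{sam_p.name}: haplotype count does not match .hap")
    n = len(legend)
    sites = SiteMap(
        chrom=np.full(n, "1", dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ids=np.array([v for v, _, _, _ in legend], dtype=object),
        ref=np.array([a for _, _, a, _ in legend], dtype=object),
        alt=np.array([a for _, _, _, a in legend], dtype=object),
        cm=np.zeros(n), is_exomic=np.zeros(n, dtype=bool),
        is_array=np.zeros(n, dtype=bool), is_multimapping=np.zeros(n, dtype=bool))
    return HaplotypePanel(
        np.array([h for h, _ in sam], dtype=object),
        np.array([s for _, s in sam], dtype=object), sites, alleles)


# ---------------------------------------------------------------------------
# genetic map


def write_genetic_map(sites: SiteMap, path, seed=None, config=None) -> Path:
    """3-column map: position, local rate (cM/Mb), cumulative cM."""
    path = Path(path)
    pos = sites.pos
    cm = sites.cm
    rate = np.zeros(len(pos))
    if len(pos) > 1:
        d_bp = np.diff(pos)
        rate[1:] = np.diff(cm) / np.maximum(d_bp, 1) * 1e6
        rate[0] = rate[1] if len(pos) > 1 else 0.0
    with open(path, "w") as fh:
        fh.write(meta_comment(seed=seed, config=config) + "\n")
        fh.write("position rate_cM_Mb cM\n")
        for p, r, c in zip(pos, rate, cm):
            fh.write(f"{p} {r:.8g} {c:.8g}\n")
    return path


def read_genetic_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    expected = ["position", "rate_cM_Mb", "cM"]
    if list(df.columns) != expected:
        df.columns = expected
    return df


def genetic_positions(map_df: pd.DataFrame, pos: np.ndarray) -> np.ndarray:
    """Interpolate cumulative cM at physical positions."""
    return np.interp(pos, map_df["position"].to_numpy(),
                     map_df["cM"].to_numpy())


# ---------------------------------------------------------------------------
# TSV reports


def write_tsv(df: pd.DataFrame, path, seed=None, config=None,
              index: bool = False) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(meta_comment(seed=seed, config=config) + "\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
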