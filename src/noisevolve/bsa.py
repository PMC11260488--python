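"""Bulk-segregant causal-mutation mapping via the ΔSNP index.

F1 haploid progeny of an evolved x ancestral cross are phenotyped for
expression noise in replicate, classified as ancestral-like or
evolved-like (only segregants consistent across all replicates are
used), and pooled (20 per bulk by default). Pooled sequencing gives
per-site read counts; the SNP index of a bulk is the fraction of reads
carrying the evolved-parent allele, and the ΔSNP index is the
evolved-bulk index minus the ancestral-bulk index. Sites with an SNP
index > 0.3 in at least one bulk pass the spurious-SNP filter, and a
ΔSNP index > 0.8 calls a causal mutation. A separate filter for
single-clone sequencing keeps variants with coverage > 30 and allele
frequency > 0.5. All four thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthio

ANCESTRAL_LIKE = "ancestral-like"
EVOLVED_LIKE = "evolved-like"
INCONSISTENT = "inconsistent"


# ---------------------------------------------------------------------------
# segregant classification and pooling
# ---------------------------------------------------------------------------

def classify_segregants(
    phenotypes: np.ndarray,
    ancestral_ref: float,
    evolved_ref: float,
) -> pd.DataFrame:
    """Classify segregants from replicate Fano measurements.

    Each replicate is called evolved-like iff its Fano exceeds the
    midpoint of the two parental reference values; a segregant's label
    requires all replicates to agree, otherwise it is ``inconsistent``
    and excluded from pooling.
    """
    pheno = np.asarray(phenotypes, dtype=float)
    if pheno.ndim != 2:
        raise ValueError("phenotypes must be (n_segregants, n_replicates)")
    if not np.all(np.isfinite(pheno)):
        raise ValueError("missing or non-finite replicate measurement")
    if evolved_ref <= ancestral_ref:
        raise ValueError("evolved_ref must exceed ancestral_ref")
    midpoint = 0.5 * (ancestral_ref + evolved_ref)
    evolved_call = pheno > midpoint
    all_evolved = evolved_call.all(axis=1)
    all_ancestral = (~evolved_call).all(axis=1)
    label = np.where(all_evolved, EVOLVED_LIKE,
                     np.where(all_ancestral, ANCESTRAL_LIKE, INCONSISTENT))
    return pd.DataFrame({
        "segregant": np.arange(pheno.shape[0]),
        "label": label,
        "mean_fano": pheno.mean(axis=1),
    })


def build_pools(
    classified: pd.DataFrame,
    pool_size: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded choice of ``pool_size`` consistent segregants per bulk.

    Returns (evolved pool indices, ancestral pool indices). Raises with
    the shortfall named if either class has too few consistent members.
    """
    rng = np.random.default_rng(seed)
    pools = []
    for want in (EVOLVED_LIKE, ANCESTRAL_LIKE):
        idx = classified.loc[classified["label"] == want, "segregant"].to_numpy()
        if len(idx) < pool_size:
            raise ValueError(
                f"only {len(idx)} consistent {want} segregants; need {pool_size}"
            )
        pools.append(np.sort(rng.choice(idx, size=pool_size, replace=False)))
    return pools[0], pools[1]


# ---------------------------------------------------------------------------
# SNP index and filters
# ---------------------------------------------------------------------------

def snp_index(ref_counts, alt_counts) -> np.ndarray:
    """Per-site alternate-read fraction alt/(ref+alt); NaN at zero depth."""
    ref = np.asarray(ref_counts, dtype=float)
    alt = np.asarray(alt_counts, dtype=float)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(depth > 0, alt / depth, np.nan)


@dataclass(frozen=True)
class DeltaReport:
    n_sites: int
    n_zero_depth_dropped: int
    n_passed_filter: int
    n_causal: int


def delta_and_filter(
    records: pd.DataFrame,
    min_index: float = 0.3,
    causal_threshold: float = 0.8,
) -> tuple[pd.DataFrame, DeltaReport]:
    """Compute ΔSNP index per site and apply the two strict filters.

    ``records`` must carry per-bulk counts
    (ref_count_evolved, alt_count_evolved, ref_count_ancestral,
    alt_count_ancestral) with the alternate allele oriented to the
    evolved parent. Sites with zero depth in either bulk are dropped
    (counted in the report). ``passed_index_filter`` requires an SNP
    index strictly above ``min_index`` in at least one bulk;
    ``called_causal`` additionally requires ΔSNP strictly above
    ``causal_threshold``.
    """
    out = records.copy()
    out["snp_index_evolved"] = snp_index(
        out["ref_count_evolved"], out["alt_count_evolved"])
    out["snp_index_ancestral"] = snp_index(
        out["ref_count_ancestral"], out["alt_count_ancestral"])
    defined = out["snp_index_evolved"].notna() & out["snp_index_ancestral"].notna()
    n_dropped = int((~defined).sum())
    out = out.loc[defined].reset_index(drop=True)
    out["delta_snp_index"] = out["snp_index_evolved"] - out["snp_index_ancestral"]
    out["passed_index_filter"] = (
        (out["snp_index_evolved"] > min_index)
        | (out["snp_index_ancestral"] > min_index)
    )
    out["called_causal"] = out["passed_index_filter"] & (
        out["delta_snp_index"] > causal_threshold
    )
    report = DeltaReport(
        n_sites=len(records),
        n_zero_depth_dropped=n_dropped,
        n_passed_filter=int(out["passed_index_filter"].sum()),
        n_causal=int(out["called_causal"].sum()),
    )
    return out, report


def clone_variant_filter(
    variants: pd.DataFrame,
    min_coverage: float = 30,
    min_af: float = 0.5,
) -> pd.DataFrame:
    """Keep clone variants with coverage > 30 AND allele frequency > 0.5.

    Both inequalities are strict: coverage exactly 30 or AF exactly 0.5
    is dropped.
    """
    for col in ("coverage", "allele_frequency"):
        if col not in variants.columns:
            raise ValueError(f"variant table missing column {col!r}")
    keep = (variants["coverage"] > min_coverage) & (
        variants["allele_frequency"] > min_af)
    return variants.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# end-to-end simulated mapping experiment
# ---------------------------------------------------------------------------

def run_cross_mapping(
    design: synthio.CrossDesign,
    seed: int,
    depth: int = 200,
    error_rate: float = 0.0,
    pool_size: int = 20,
    min_index: float = 0.3,
    causal_threshold: float = 0.8,
) -> tuple[pd.DataFrame, DeltaReport]:
    """Simulate cross -> classify -> pool -> sequence -> ΔSNP filter.

    The classification references are the parental Fano values implied
    by the design (the bench protocol phenotypes both parents alongside
    the segregants). Returns the per-site record table and filter
    report; the causal locus row is ``records.site == design.causal_index``.
    """
    rng = np.random.default_rng(seed)
    segs = synthio.gen_segregants(design, seed=int(rng.integers(2**31)))
    classified = classify_segregants(
        segs.phenotypes, design.ancestral_fano, design.evolved_fano)
    pool_evo, pool_anc = build_pools(classified, pool_size,
                                     seed=int(rng.integers(2**31)))
    counts_evo = synthio.gen_pool_reads(
        segs.genotypes[pool_evo], depth, error_rate, seed=int(rng.integers(2**31)))
    counts_anc = synthio.gen_pool_reads(
        segs.genotypes[pool_anc], depth, error_rate, seed=int(rng.integers(2**31)))
    records = pd.DataFrame({
        "site": counts_evo["site"],
        "ref_count_evolved": counts_evo["ref_count"],
        "alt_count_evolved": counts_evo["alt_count"],
        "ref_count_ancestral": counts_anc["ref_count"],
        "alt_count_ancestral": counts_anc["alt_count"],
    })
    return delta_and_filter(records, min_index, causal_threshold)


# ---------------------------------------------------------------------------
# I/O: VCF / TSV readers, TSV / BED writers
# ---------------------------------------------------------------------------

def read_bulk_vcf(
    path,
    evolved_bulk: str,
    ancestral_bulk: str,
    skip_multiallelic: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Read per-bulk allele depths (AD) from a two-sample VCF.

    Returns (records, n_multiallelic_skipped). Positions are 1-based as
    in the VCF. Multi-allelic sites are skipped (default) or split into
    one record per alternate allele against the reference depth.
    """
    import pysam

    rows = []
    n_multi = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for name in (evolved_bulk, ancestral_bulk):
            if name not in samples:
                raise ValueError(f"bulk sample {name!r} not in VCF samples {samples}")
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multi += len(alts) if not skip_multiallelic else 1
                if skip_multiallelic:
                    continue
            for ai, alt in enumerate(alts, start=1):
                ad_e = rec.samples[evolved_bulk].get("AD")
                ad_a = rec.samples[ancestral_bulk].get("AD")
                if ad_e is None or ad_a is None:
                    raise ValueError(f"missing AD field at {rec.chrom}:{rec.pos}")
                rows.append({
                    "chrom": rec.chrom, "pos": rec.pos,
                    "ref": rec.ref, "alt": alt,
                    "ref_count_evolved": int(ad_e[0]),
                    "alt_count_evolved": int(ad_e[ai]),
                    "ref_count_ancestral": int(ad_a[0]),
                    "alt_count_ancestral": int(ad_a[ai]),
                })
    return pd.DataFrame(rows), n_multi


def read_counts_tsv(path) -> pd.DataFrame:
    """Read the TSV pooled-count dialect written by :mod:`synthio`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "ref", "alt", "ref_count_evolved",
                "alt_count_evolved", "ref_count_ancestral", "alt_count_ancestral"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts TSV missing columns {sorted(missing)}")
    return df


def write_snp_index(records: pd.DataFrame, path,
                    header_comment: str | None = None) -> None:
    """Write the full per-site SNP-index record table as TSV."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        records.to_csv(fh, sep="\t", index=False)


def write_causal_bed(records: pd.DataFrame, path) -> None:
    """Write causal candidates as BED (0-based half-open intervals)."""
    causal = records.loc[records["called_causal"]]
    with open(path, "w") as fh:
        for _, row in causal.iterrows():
            chrom = row.get("chrom", "chrUn")
            pos = int(row.get("pos", row.get("site", 0) + 1))
            name = f"{row.get('ref', '.')}>{row.get('alt', '.')}"
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{name}\t"
                     f"{row['delta_snp_index']:.4f}\n")
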