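"""VCF ingestion: fill a genotype panel from VCF files over a position panel.

This is the converter stage between standard variant calls and the byte-level
comparison engine.  Per (sample, panel position):

* a diploid GT passing the configured quality thresholds is encoded to its
  IUPAC byte;
* a missing GT, a site below ``min_site_qual``, a sample below ``min_depth``,
  a non-SNV allele, or (optionally) a non-PASS FILTER yields NUL;
* a panel position with no record at all yields NUL under
  ``absent_policy="missing"`` or a reference homozygote under
  ``absent_policy="homref"`` (force-called inputs).

Variant-allele fractions for the contamination/CNV QC plots are extracted
from the per-sample AD field when present.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .encoding import NULL, GenotypePanel, RegionMap, encode_genotype
from .errors import MalformedRecordError, ManifestError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IngestConfig:
    """Conversion rules applied while reading VCFs.

    Attributes
    ----------
    min_site_qual
        Sites with QUAL below this are treated as missing; ``None`` disables
        (default — quality filtering is opt-in so defaults never drop data).
    min_depth
        Per-sample calls with FORMAT/DP below this are treated as missing;
        ``None`` disables.
    absent_policy
        ``"missing"`` (default, conservative for variants-only VCFs) or
        ``"homref"`` (for force-called inputs where absence of a record is
        informative).
    contig_normalization
        When True, ``chr``-prefix differences between BED and VCF contig
        names are harmonized; off by default so mismatches fail loudly via
        the zero-overlap warning instead of being silently renamed.
    pass_only
        When True, records whose FILTER is not PASS/``.`` are treated as
        missing.
    """

    min_site_qual: float | None = None
    min_depth: int | None = None
    absent_policy: str = "missing"
    contig_normalization: bool = False
    pass_only: bool = False

    def __post_init__(self) -> None:
        if self.absent_policy not in ("missing", "homref"):
            raise ValueError(f"unknown absent_policy {self.absent_policy!r}")
        if self.min_site_qual is not None and self.min_site_qual < 0:
            raise ValueError("min_site_qual must be >= 0")
        if self.min_depth is not None and self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class IngestStats:
    """Per-run bookkeeping: what was called, missing, filtered, duplicated."""

    called: Counter = field(default_factory=Counter)
    missing: Counter = field(default_factory=Counter)
    filtered: Counter = field(default_factory=Counter)
    duplicate_records: int = 0
    nondiploid_calls: int = 0

    def log_summary(self) -> None:
        for sample in sorted(set(self.called) | set(self.missing) | set(self.filtered)):
            logger.info(
                "sample %s: %d called, %d missing, %d filtered",
                sample,
                self.called[sample],
                self.missing[sample],
                self.filtered[sample],
            )
        if self.duplicate_records:
            logger.warning("%d duplicate panel-locus records ignored", self.duplicate_records)
        if self.nondiploid_calls:
            logger.warning("%d non-diploid calls encoded as missing", self.nondiploid_calls)


def _norm_contig(chrom: str, region_has_chr: bool) -> str:
    if region_has_chr and not chrom.startswith("chr"):
        return "chr" + chrom
    if not region_has_chr and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


def ingest_vcfs(
    paths: Sequence[str | Path],
    region: RegionMap,
    config: IngestConfig = IngestConfig(),
    reference: Mapping[tuple[str, int], str] | None = None,
    stats: IngestStats | None = None,
) -> GenotypePanel:
    """Read genotypes at the panel positions from one or more VCF files.

    Each file may carry one or many samples; sample names must be unique
    across files.  Returns a panel whose sample order is file order then
    within-file column order.

    Parameters
    ----------
    reference
        Optional ``(chrom, pos) -> ref base`` lookup used by
        ``absent_policy="homref"`` for loci never seen in any record; REF
        bases observed in the files take precedence.
    """
    if stats is None:
        stats = IngestStats()
    if len(region) == 0:
        raise ValueError("empty region map")
    region_has_chr = region.loci[0][0].startswith("chr")

    sample_names: list[str] = []
    rows: list[np.ndarray] = []
    covered: list[np.ndarray] = []
    seen_ref: dict[int, str] = {}

    for path in paths:
        vcf = VCF(str(path), gts012=False)
        file_samples = list(vcf.samples)
        dup = set(file_samples) & set(sample_names)
        if dup:
            raise ManifestError(f"duplicate sample names across VCFs: {sorted(dup)}")
        ns = len(file_samples)
        block = np.zeros((ns, len(region)), dtype=np.uint8)
        claimed = np.zeros(len(region), dtype=bool)
        n_hits = 0
        for variant in vcf:
            chrom = variant.CHROM
            if config.contig_normalization:
                chrom = _norm_contig(chrom, region_has_chr)
            offset = region.offset(chrom, variant.POS)
            if offset is None:
                continue
            n_hits += 1
            if claimed[offset]:
                stats.duplicate_records += 1
                continue
            claimed[offset] = True
            ref = variant.REF
            if len(ref) == 1 and ref.upper() in "ACGT":
                seen_ref.setdefault(offset, ref.upper())

            site_fail = (
                (
                    config.min_site_qual is not None
                    and (variant.QUAL is None or variant.QUAL < config.min_site_qual)
                )
                or (config.pass_only and variant.FILTER is not None)
            )
            if site_fail:
                for k, s in enumerate(file_samples):
                    stats.filtered[s] += 1
                    block[k, offset] = NULL
                continue

            depths = None
            if config.min_depth is not None:
                dp = variant.format("DP")
                if dp is not None:
                    depths = np.asarray(dp).reshape(ns)
            alts = variant.ALT or []
            for k, s in enumerate(file_samples):
                gt = variant.genotypes[k]
                alleles = gt[:-1]  # last element is the phased flag
                if depths is not None and (depths[k] < 0 or depths[k] < config.min_depth):
                    stats.filtered[s] += 1
                    continue
                if len(alleles) != 2:
                    stats.nondiploid_calls += 1
                    stats.missing[s] += 1
                    continue
                try:
                    code = encode_genotype(
                        ref, alts, [a if a >= 0 else None for a in alleles]
                    )
                except MalformedRecordError as exc:
                    raise MalformedRecordError(
                        f"{path}: {variant.CHROM}:{variant.POS} sample {s}: {exc}"
                    ) from None
                block[k, offset] = code
                if code == NULL:
                    stats.missing[s] += 1
                else:
                    stats.called[s] += 1
        if n_hits == 0:
            logger.warning(
                "VCF %s shares zero panel positions with the region map "
                "(contig-name mismatch between BED and VCF?)",
                path,
            )
        sample_names.extend(file_samples)
        rows.append(block)
        covered.append(np.tile(claimed, (ns, 1)))

    data = np.vstack(rows)
    claimed_all = np.vstack(covered)
    if config.absent_policy == "homref":
        absent = ~claimed_all
        for offset in range(len(region)):
            if not absent[:, offset].any():
                continue
            base = seen_ref.get(offset)
            if base is None and reference is not None:
                base = reference.get(region.loci[offset])
            if base is None:
                continue  # ref base unknown -> stays missing
            data[absent[:, offset], offset] = ord(base)
    stats.log_summary()
    return GenotypePanel(sample_names, data, region)


@dataclass
class AlleleFractionTable:
    """Per-sample variant-read fractions at covered panel positions.

    ``table`` has columns ``sample, chrom, pos, fraction, depth``; a row
    exists only where at least one informative read was observed.
    ``available`` is False when no input carried an AD field.
    """

    table: pd.DataFrame
    available: bool = True

    COLUMNS = ["sample", "chrom", "pos", "fraction", "depth"]

    def samples(self) -> list[str]:
        return sorted(self.table["sample"].unique()) if len(self.table) else []

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.table[self.table["sample"] == sample]


def extract_allele_fractions(
    paths: Sequence[str | Path],
    region: RegionMap,
    config: IngestConfig = IngestConfig(),
) -> AlleleFractionTable:
    """Variant-allele fraction per sample per covered panel locus.

    fraction = sum(ALT-supporting depths) / sum(all allele depths); loci with
    zero total depth are omitted.  If no file carries FORMAT/AD the result is
    flagged unavailable (plots are skipped, nothing aborts).
    """
    region_has_chr = region.loci[0][0].startswith("chr") if len(region) else False
    records: list[dict] = []
    any_ad = False
    for path in paths:
        vcf = VCF(str(path), gts012=False)
        file_samples = list(vcf.samples)
        for variant in vcf:
            chrom = variant.CHROM
            if config.contig_normalization:
                chrom = _norm_contig(chrom, region_has_chr)
            if (chrom, variant.POS) not in region:
                continue
            ad = variant.format("AD")
            if ad is None:
                continue
            any_ad = True
            ad = np.asarray(ad, dtype=float)
            ad[ad < 0] = 0  # cyvcf2 encodes missing AD entries as negatives
            for k, s in enumerate(file_samples):
                total = float(ad[k].sum())
                if total <= 0:
                    continue
                alt_depth = float(ad[k, 1:].sum())
                records.append(
                    {
                        "sample": s,
                        "chrom": chrom,
                        "pos": variant.POS,
                        "fraction": alt_depth / total,
                        "depth": total,
                    }
                )
    if not any_ad:
        logger.info("no FORMAT/AD field found in inputs; allele-fraction plots unavailable")
        return AlleleFractionTable(
            pd.DataFrame(columns=AlleleFractionTable.COLUMNS), available=False
        )
    table = pd.DataFrame(records, columns=AlleleFractionTable.COLUMNS)
    table = table.sort_values(["sample", "chrom", "pos"]).reset_index(drop=True)
    return AlleleFractionTable(table, available=True)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest TSV.

    Columns: ``sample_name``, ``vcf_path`` (resolved relative to the manifest
    location when not absolute), optional ``individual_id`` used only for
    plot annotation/grouping.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_name", "vcf_path"}
    if not required.issubset(df.columns):
        raise ManifestError(
            f"manifest {path} must have columns {sorted(required)}; got {list(df.columns)}"
        )
    if df["sample_name"].duplicated().any():
        dups = df.loc[df["sample_name"].duplicated(), "sample_name"].tolist()
        raise ManifestError(f"duplicate sample names in manifest: {dups}")
    base = path.parent
    df["vcf_path"] = [
        str(p) if Path(p).is_absolute() else str(base / p) for p in df["vcf_path"]
    ]
    return df


def ingest_manifest(
    manifest: pd.DataFrame | str | Path,
    region: RegionMap,
    config: IngestConfig = IngestConfig(),
    stats: IngestStats | None = None,
) -> GenotypePanel:
    """Ingest every VCF referenced by a manifest and order the panel rows by
    manifest order (the order the heatmap will use)."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    paths = list(dict.fromkeys(manifest["vcf_path"]))
    panel = ingest_vcfs(paths, region, config, stats=stats)
    wanted = list(manifest["sample_name"])
    missing = [s for s in wanted if s not in panel.sample_names]
    if missing:
        raise ManifestError(f"manifest samples not found in VCFs: {missing}")
    return panel.reorder(wanted)
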