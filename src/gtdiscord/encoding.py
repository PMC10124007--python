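"""Genotype encoding, position panel, and the in-memory genotype-string model.

A diploid single-nucleotide genotype is stored in ONE byte: the uppercase
IUPAC nucleotide code for a homozygote (``A C G T``) or the two-base
ambiguity code for a heterozygote (``R Y S W K M``), with the ASCII NUL byte
(value 0) reserved for missing or low-quality calls.  All uppercase letters
have bit 6 (value 64) set, so the bytewise AND of two *called* genotypes is
never zero — the property the comparison engine's missingness count relies
on.  A sample's genotypes across the whole position panel are concatenated
into a single byte string, one byte per panel position.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import BedFormatError, EmptyPanelError, MalformedRecordError, ManifestError

logger = logging.getLogger(__name__)

#: Byte value encoding a missing / low-quality genotype.
NULL = 0

#: IUPAC two-base ambiguity codes for unordered heterozygous allele pairs.
_HET_CODE = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

#: The ten valid non-NULL genotype byte values.
IUPAC_BYTES = frozenset(b"ACGTRYSWKM")

#: All valid panel byte values (the ten IUPAC codes plus NULL).
VALID_BYTES = IUPAC_BYTES | {NULL}

_CODE_TO_PAIR = {ord(b): (b, b) for b in "ACGT"}
_CODE_TO_PAIR.update({ord(c): tuple(sorted(pair)) for pair, c in _HET_CODE.items()})

_VALID_LOOKUP = np.zeros(256, dtype=bool)
for _b in VALID_BYTES:
    _VALID_LOOKUP[_b] = True

_BASES = frozenset("ACGT")


def encode_genotype(
    ref_allele: str,
    alt_alleles: Sequence[str],
    allele_indices: Sequence[int | None] | None,
) -> int:
    """Encode a diploid VCF genotype call as a single IUPAC byte.

    Parameters
    ----------
    ref_allele
        The site's REF allele.
    alt_alleles
        The site's ALT allele list (may be empty for force-called hom-ref
        records).
    allele_indices
        The two GT allele indices (``0`` = REF, ``1`` = first ALT, ...),
        phase-agnostic; ``None``, or a sequence containing ``None`` or a
        negative index, means a (half-)missing call.

    Returns
    -------
    int
        The genotype byte: the base itself for a homozygote, the IUPAC
        ambiguity code for a heterozygote, or :data:`NULL` for missing,
        non-diploid, or non-SNV calls.

    Raises
    ------
    MalformedRecordError
        If an allele index exceeds the site's allele list (the VCF ingest
        layer re-raises with chrom/pos/sample context).
    """
    if allele_indices is None:
        return NULL
    idx = list(allele_indices)
    if len(idx) != 2:
        # ploidy != 2 cannot be represented in one IUPAC byte
        return NULL
    if any(i is None or i < 0 for i in idx):
        return NULL
    alleles = [ref_allele, *alt_alleles]
    for i in idx:
        if i >= len(alleles):
            raise MalformedRecordError(
                f"GT allele index {i} out of range for {len(alleles)} alleles"
            )
    a, b = (alleles[i].upper() for i in idx)
    if ref_allele.upper() not in _BASES or a not in _BASES or b not in _BASES:
        # indel context, symbolic alleles, breakends, 'N': no identity signal
        return NULL
    if a == b:
        return ord(a)
    return ord(_HET_CODE[frozenset((a, b))])


def decode_genotype(code: int) -> tuple[str, str] | None:
    """Inverse of :func:`encode_genotype`: byte -> unordered allele pair.

    Returns ``None`` for :data:`NULL`.
    """
    if code == NULL:
        return None
    try:
        return _CODE_TO_PAIR[code]
    except KeyError:
        raise ValueError(f"invalid genotype byte {code!r}") from None


@dataclass(frozen=True)
class RegionMap:
    """Ordered panel of genomic positions defining byte offset <-> locus.

    ``loci[i]`` is the ``(chromosome, 1-based position)`` stored at byte
    offset ``i`` of every sample's genotype string.  Construction sorts by
    chromosome (lexicographic) then position and deduplicates, so two panels
    built from the same BED are byte-compatible.
    """

    loci: tuple[tuple[str, int], ...]
    _index: dict[tuple[str, int], int] = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {locus: i for i, locus in enumerate(self.loci)}
        )
        if len(self._index) != len(self.loci):
            raise ValueError("RegionMap loci must be unique")

    def __len__(self) -> int:
        return len(self.loci)

    def offset(self, chrom: str, pos: int) -> int | None:
        """Byte offset of ``(chrom, pos)`` or ``None`` if not in the panel."""
        return self._index.get((chrom, pos))

    def __contains__(self, locus: tuple[str, int]) -> bool:
        return locus in self._index

    @property
    def chromosomes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for chrom, _ in self.loci:
            seen.setdefault(chrom)
        return tuple(seen)


def build_region_map(
    bed_records: Iterable[tuple[str, int, int]],
) -> RegionMap:
    """Expand BED3 intervals (0-based, half-open) into a sorted locus panel.

    Intervals may be unsorted and may overlap; every covered base becomes one
    1-based locus, deduplicated and sorted by chromosome then position.
    """
    loci: set[tuple[str, int]] = set()
    for lineno, (chrom, start, end) in enumerate(bed_records, start=1):
        if end <= start:
            raise BedFormatError(
                f"BED record {lineno}: end ({end}) must exceed start ({start})"
            )
        for pos in range(start + 1, end + 1):
            loci.add((str(chrom), pos))
    return RegionMap(tuple(sorted(loci)))


def read_bed(path: str | Path) -> RegionMap:
    """Read a BED3+ file into a :class:`RegionMap`.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    """
    records: list[tuple[str, int, int]] = []
    with open(path) as fh:
        rows = [
            line.rstrip("\n")
            for line in fh
            if line.strip()
            and not line.startswith(("#", "track", "browser"))
        ]
    for lineno, row in enumerate(rows, start=1):
        fields = row.split("\t")
        if len(fields) < 3:
            raise BedFormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedFormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if end <= start:
            raise BedFormatError(
                f"{path}:{lineno}: end ({end}) must exceed start ({start})"
            )
        records.append((chrom, start, end))
    return build_region_map(records)


@dataclass
class GenotypePanel:
    """Per-sample fixed-length genotype byte strings over one position panel.

    ``data`` is an ``(n_samples, panel_length)`` uint8 array; row ``i`` is the
    concatenated genotype string of ``sample_names[i]``.  Sample order is
    input/manifest order and drives downstream heatmap ordering.
    """

    sample_names: list[str]
    data: np.ndarray
    region: RegionMap | None = None

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("panel data must be 2-D (samples x positions)")
        if len(self.sample_names) != self.data.shape[0]:
            raise ValueError("one genotype string per sample name required")
        if len(set(self.sample_names)) != len(self.sample_names):
            raise ManifestError("duplicate sample names in panel")
        if self.region is not None and len(self.region) != self.data.shape[1]:
            raise ValueError(
                f"panel length {self.data.shape[1]} != region size {len(self.region)}"
            )
        bad = ~_VALID_LOOKUP[self.data]
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype byte {int(self.data[i, j])} at sample "
                f"{self.sample_names[i]!r}, offset {int(j)}"
            )

    @classmethod
    def from_strings(
        cls,
        sample_names: Sequence[str],
        genotype_strings: Sequence[bytes],
        region: RegionMap | None = None,
    ) -> "GenotypePanel":
        lengths = {len(s) for s in genotype_strings}
        if len(lengths) > 1:
            raise ValueError(f"genotype strings differ in length: {sorted(lengths)}")
        if not genotype_strings or next(iter(lengths), 0) == 0:
            raise EmptyPanelError("empty genotype panel")
        data = np.frombuffer(b"".join(genotype_strings), dtype=np.uint8).reshape(
            len(genotype_strings), -1
        )
        return cls(list(sample_names), data.copy(), region)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def panel_length(self) -> int:
        return self.data.shape[1]

    def genotype_string(self, sample: str | int) -> bytes:
        """The raw concatenated genotype byte string of one sample."""
        if isinstance(sample, str):
            try:
                sample = self.sample_names.index(sample)
            except ValueError:
                raise KeyError(sample) from None
        return self.data[sample].tobytes()

    def missing_counts(self) -> pd.Series:
        """Per-sample count of NULL (missing) panel positions."""
        return pd.Series(
            (self.data == NULL).sum(axis=1), index=self.sample_names, name="n_missing"
        )

    def reorder(self, sample_names: Sequence[str]) -> "GenotypePanel":
        """Return a panel with rows in the given sample order."""
        missing = [s for s in sample_names if s not in self.sample_names]
        if missing:
            raise ManifestError(f"samples not in panel: {missing}")
        idx = [self.sample_names.index(s) for s in sample_names]
        return GenotypePanel(list(sample_names), self.data[idx].copy(), self.region)

    # -- optional cache serialization: JSON header + raw byte block ---------
    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.panel.json`` (names/shape) + ``<prefix>.panel.bin``
        (the raw concatenated genotype strings, row-major)."""
        prefix = Path(prefix)
        header = prefix.with_suffix(".panel.json")
        block = prefix.with_suffix(".panel.bin")
        header.write_text(
            json.dumps(
                {
                    "sample_names": self.sample_names,
                    "panel_length": self.panel_length,
                    "loci": [list(l) for l in self.region.loci] if self.region else None,
                },
                indent=0,
            )
        )
        block.write_bytes(self.data.tobytes())
        return header, block

    @classmethod
    def load(cls, prefix: str | Path) -> "GenotypePanel":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".panel.json").read_text())
        raw = prefix.with_suffix(".panel.bin").read_bytes()
        data = np.frombuffer(raw, dtype=np.uint8).reshape(
            len(meta["sample_names"]), meta["panel_length"]
        )
        region = (
            RegionMap(tuple((c, int(p)) for c, p in meta["loci"]))
            if meta.get("loci")
            else None
        )
        return cls(meta["sample_names"], data.copy(), region)
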