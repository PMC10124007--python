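"""Synthetic cohort generator: HWE genotypes, replicates, errors, swaps.

The generator emulates the data regime the comparison engine is meant for: a
panel of common biallelic SNVs, genotypes drawn per individual under
Hardy-Weinberg equilibrium (hom-ref q-squared, het 2pq, hom-alt p-squared at
minor-allele frequency p), technical replicates that copy an individual's
truth and then independently pick up genotyping errors and missingness, and
optional planted label swaps.  Output is standard, force-called per-sample
VCF 4.2 plus a BED3 panel, a sample manifest, and a JSON-lines truth record,
so every downstream module is testable without external data.

The analytic companions used by the tests:

* unrelated-pair discordance under HWE:
  ``E_p[1 - (q^4 + 4 p^2 q^2 + p^4)]`` — two independent HWE draws agree
  with probability ``q^4 + (2pq)^2 + p^4``;
* replicate-pair discordance under the symmetric error model (replace the
  genotype with one of the other two states, uniformly, with probability e):
  ``2e(1-e) + e^2/2`` — approximately ``2e`` for small e.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import integrate

from .errors import CohortSpecError

_GT_FIELD = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_ALT_OF = {"A": "G", "C": "T", "G": "A", "T": "C"}  # transition partner


@dataclass(frozen=True)
class MafDistribution:
    """Named minor-allele-frequency distribution for the site panel.

    Supported families: ``point`` (all sites at one MAF) and ``uniform``
    (MAF drawn uniformly from ``[low, high]``).  Support must lie in
    (0, 0.5] — these are minor-allele frequencies of polymorphic sites.
    """

    family: str
    params: tuple[float, ...]

    @classmethod
    def point(cls, p: float) -> "MafDistribution":
        return cls("point", (float(p),))

    @classmethod
    def uniform(cls, low: float, high: float) -> "MafDistribution":
        return cls("uniform", (float(low), float(high)))

    def __post_init__(self) -> None:
        if self.family == "point":
            (p,) = self.params
            if not 0 < p <= 0.5:
                raise CohortSpecError(f"point MAF {p} outside (0, 0.5]")
        elif self.family == "uniform":
            low, high = self.params
            if not (0 < low <= high <= 0.5):
                raise CohortSpecError(
                    f"uniform MAF support [{low}, {high}] outside (0, 0.5]"
                )
        else:
            raise CohortSpecError(f"unknown MAF family {self.family!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "point":
            return np.full(n, self.params[0])
        low, high = self.params
        return rng.uniform(low, high, size=n)

    def expect(self, f) -> float:
        """E[f(p)] under the distribution (exact for point, quadrature for
        uniform)."""
        if self.family == "point":
            return float(f(self.params[0]))
        low, high = self.params
        if low == high:
            return float(f(low))
        val, _ = integrate.quad(f, low, high)
        return val / (high - low)


def hwe_pair_discordance(p: float) -> float:
    """Probability two independent HWE genotypes at MAF p differ."""
    q = 1.0 - p
    return 1.0 - (q**4 + 4 * p**2 * q**2 + p**4)


def expected_unrelated_discordance(maf: MafDistribution) -> float:
    """Closed-form expected discordance between unrelated individuals,
    averaged over the MAF distribution."""
    return maf.expect(hwe_pair_discordance)


def expected_replicate_discordance(error_rate: float) -> float:
    """Expected discordance between two replicates of one individual when
    each genotype is independently replaced by one of the other two states
    with probability ``error_rate``."""
    e = error_rate
    return 2 * e * (1 - e) + 0.5 * e * e


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; the seed determines all output.

    ``replicate_plan`` maps individual index (0-based) to its number of
    samples (default 1 each); ``swap_plan`` lists sample-label pairs whose
    data are exchanged after generation, emulating a wet-lab swap.
    """

    n_individuals: int = 20
    n_sites: int = 10_000
    maf: MafDistribution = field(default_factory=lambda: MafDistribution.uniform(0.15, 0.30))
    replicate_plan: dict[int, int] = field(default_factory=dict)
    swap_plan: list[tuple[str, str]] = field(default_factory=list)
    genotype_error_rate: float = 0.01
    missing_rate: float = 0.02
    mean_depth: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_sites < 1:
            raise CohortSpecError("need >= 1 individual and >= 1 site")
        for name, rate in (
            ("genotype_error_rate", self.genotype_error_rate),
            ("missing_rate", self.missing_rate),
        ):
            if not 0 <= rate <= 1:
                raise CohortSpecError(f"{name}={rate} outside [0, 1]")
        for ind, count in self.replicate_plan.items():
            if not 0 <= ind < self.n_individuals:
                raise CohortSpecError(f"replicate_plan references individual {ind}")
            if count < 1:
                raise CohortSpecError("replicate counts must be >= 1")

    def sample_labels(self) -> list[str]:
        labels = []
        for ind in range(self.n_individuals):
            n_rep = self.replicate_plan.get(ind, 1)
            for r in range(n_rep):
                labels.append(f"IND{ind + 1:03d}_rep{r + 1}")
        return labels

    def individual_of(self) -> list[int]:
        owners = []
        for ind in range(self.n_individuals):
            owners.extend([ind] * self.replicate_plan.get(ind, 1))
        return owners


@dataclass
class Cohort:
    """In-memory synthetic cohort before/after file emission.

    ``dosages`` is (n_samples, n_sites) int8 with alt-allele dosage 0/1/2 or
    -1 for missing; ``truth_individual[k]`` is the individual whose genome
    sample k's *data* really came from (reflecting any planted swap).
    """

    spec: CohortSpec
    sample_names: list[str]
    labeled_individual: list[int]
    truth_individual: list[int]
    dosages: np.ndarray
    mafs: np.ndarray
    chroms: list[str]
    positions: np.ndarray
    ref: list[str]
    alt: list[str]
    error_counts: np.ndarray
    missing_counts: np.ndarray

    def truth_records(self) -> list[dict]:
        recs = []
        swapped = {s for pair in self.spec.swap_plan for s in pair}
        for k, name in enumerate(self.sample_names):
            recs.append(
                {
                    "sample": name,
                    "labeled_individual": int(self.labeled_individual[k]),
                    "true_individual": int(self.truth_individual[k]),
                    "n_errors": int(self.error_counts[k]),
                    "n_missing": int(self.missing_counts[k]),
                    "in_swap": name in swapped,
                }
            )
        return recs


def simulate_genotypes(spec: CohortSpec) -> Cohort:
    """Draw the cohort in memory: truth genotypes, per-sample errors and
    missingness, then apply the swap plan."""
    rng = np.random.default_rng(spec.seed)
    n_sites = spec.n_sites
    mafs = spec.maf.sample(rng, n_sites)

    # two synthetic chromosomes, evenly spaced sites
    half = (n_sites + 1) // 2
    chroms = ["chr1"] * half + ["chr2"] * (n_sites - half)
    positions = np.concatenate(
        [np.arange(1, half + 1), np.arange(1, n_sites - half + 1)]
    ) * 100
    ref = [str(b) for b in rng.choice(list("ACGT"), size=n_sites)]
    alt = [_ALT_OF[b] for b in ref]

    # per-individual HWE truth dosage: 0 wp q^2, 1 wp 2pq, 2 wp p^2
    u = rng.random((spec.n_individuals, n_sites))
    q = 1.0 - mafs
    truth = np.where(u < q**2, 0, np.where(u < q**2 + 2 * mafs * q, 1, 2)).astype(
        np.int8
    )

    labels = spec.sample_labels()
    owners = spec.individual_of()
    n_samples = len(labels)
    dosages = truth[owners].copy()

    err_mask = rng.random((n_samples, n_sites)) < spec.genotype_error_rate
    # symmetric error: replace with one of the other two states uniformly
    shift = rng.integers(1, 3, size=(n_samples, n_sites), dtype=np.int8)
    dosages = np.where(err_mask, (dosages + shift) % 3, dosages).astype(np.int8)
    miss_mask = rng.random((n_samples, n_sites)) < spec.missing_rate
    dosages[miss_mask] = -1

    truth_individual = list(owners)
    for a, b in spec.swap_plan:
        if a not in labels or b not in labels:
            raise CohortSpecError(f"swap plan references unknown sample(s): {a}, {b}")
        ia, ib = labels.index(a), labels.index(b)
        dosages[[ia, ib]] = dosages[[ib, ia]]
        truth_individual[ia], truth_individual[ib] = (
            truth_individual[ib],
            truth_individual[ia],
        )
        err_tmp = err_mask[ia].copy()
        err_mask[ia], err_mask[ib] = err_mask[ib], err_tmp
        miss_tmp = miss_mask[ia].copy()
        miss_mask[ia], miss_mask[ib] = miss_mask[ib], miss_tmp

    return Cohort(
        spec=spec,
        sample_names=labels,
        labeled_individual=owners,
        truth_individual=truth_individual,
        dosages=dosages,
        mafs=mafs,
        chroms=chroms,
        positions=positions,
        ref=ref,
        alt=alt,
        error_counts=(err_mask & ~miss_mask).sum(axis=1),
        missing_counts=miss_mask.sum(axis=1),
    )


def _write_sample_vcf(
    path: Path, cohort: Cohort, k: int, rng: np.random.Generator
) -> None:
    """Force-called single-sample VCF 4.2 with GT, DP, AD, QUAL at all sites."""
    spec = cohort.spec
    n = spec.n_sites
    depths = rng.poisson(spec.mean_depth, size=n)
    het_alt = rng.binomial(depths, 0.5)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=gtdiscord-simulate (seed={spec.seed})",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    for chrom in dict.fromkeys(cohort.chroms):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + cohort.sample_names[k]
    )
    dos = cohort.dosages[k]
    for i in range(n):
        d = int(depths[i])
        g = int(dos[i])
        if g == -1:
            gt, dp, ad = "./.", 0, "0,0"
        elif g == 0:
            gt, dp, ad = "0/0", d, f"{d},0"
        elif g == 1:
            a = int(het_alt[i])
            gt, dp, ad = "0/1", d, f"{d - a},{a}"
        else:
            gt, dp, ad = "1/1", d, f"0,{d}"
        qual = "0" if g == -1 else "60"
        lines.append(
            f"{cohort.chroms[i]}\t{int(cohort.positions[i])}\t.\t{cohort.ref[i]}\t"
            f"{cohort.alt[i]}\t{qual}\tPASS\t.\tGT:DP:AD\t{gt}:{dp}:{ad}"
        )
    path.write_text("\n".join(lines) + "\n")


@dataclass
class CohortPaths:
    """File layout written by :func:`simulate_cohort`."""

    out_dir: Path
    vcf_paths: list[Path]
    bed_path: Path
    manifest_path: Path
    truth_path: Path


def simulate_cohort(spec: CohortSpec, out_dir: str | Path) -> tuple[Cohort, CohortPaths]:
    """Generate the cohort and write VCFs + BED + manifest + truth JSONL.

    Identical spec (including seed) gives byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_genotypes(spec)

    bed_path = out_dir / "panel.bed"
    with open(bed_path, "w") as fh:
        for chrom, pos in zip(cohort.chroms, cohort.positions):
            fh.write(f"{chrom}\t{int(pos) - 1}\t{int(pos)}\n")

    vcf_paths = []
    for k, name in enumerate(cohort.sample_names):
        # per-sample depth stream keyed on (seed, k): stable under re-runs
        sub_rng = np.random.default_rng([spec.seed, k])
        path = out_dir / f"{name}.vcf"
        _write_sample_vcf(path, cohort, k, sub_rng)
        vcf_paths.append(path)

    manifest_path = out_dir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("sample_name\tvcf_path\tindividual_id\n")
        for k, name in enumerate(cohort.sample_names):
            fh.write(
                f"{name}\t{name}.vcf\tIND{cohort.labeled_individual[k] + 1:03d}\n"
            )

    truth_path = out_dir / "truth.jsonl"
    with open(truth_path, "w") as fh:
        for rec in cohort.truth_records():
            fh.write(json.dumps(rec) + "\n")

    return cohort, CohortPaths(out_dir, vcf_paths, bed_path, manifest_path, truth_path)


def cohort_panel(cohort: Cohort):
    """Encode the in-memory cohort directly into a GenotypePanel (bypassing
    VCF round-trip); used for fast in-process analyses."""
    from .encoding import GenotypePanel, RegionMap, encode_genotype

    n_sites = cohort.spec.n_sites
    codes = np.zeros((len(cohort.sample_names), n_sites), dtype=np.uint8)
    per_site = np.empty((3, n_sites), dtype=np.uint8)
    for i in range(n_sites):
        ref, alts = cohort.ref[i], [cohort.alt[i]]
        per_site[0, i] = encode_genotype(ref, alts, (0, 0))
        per_site[1, i] = encode_genotype(ref, alts, (0, 1))
        per_site[2, i] = encode_genotype(ref, alts, (1, 1))
    dos = cohort.dosages
    for g in (0, 1, 2):
        codes[dos == g] = np.broadcast_to(per_site[g], dos.shape)[dos == g]
    region = RegionMap(
        tuple(
            (c, int(p)) for c, p in sorted(zip(cohort.chroms, (int(x) for x in cohort.positions)))
        )
    )
    # region sorting must match the per-column order: rebuild columns sorted
    order = np.argsort(
        np.array([f"{c}\t{int(p):012d}" for c, p in zip(cohort.chroms, cohort.positions)])
    )
    return GenotypePanel(list(cohort.sample_names), codes[:, order], region)
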