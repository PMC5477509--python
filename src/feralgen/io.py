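"""Shared data model and readers/writers for VCF, BED and TSV inputs.

Coordinate convention: every interval in this package is 0-based half-open.
BED files are native; VCF POS is converted on read (``pos - 1``) and back on
write. Genotypes are stored as alternative-allele dosages in ``{0, 1, 2}``
with ``-1`` for missing; phase is discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

MISSING = -1

ROLES = ("weedy", "cultivated", "wild")

_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP-sites genotype matrix.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, in column order of the source VCF.
    chrom : ndarray of str, per site
    pos : ndarray of int, per site, 0-based
    ref, alt : ndarray of str, per site
    geno : int8 ndarray of shape (n_samples, n_sites)
        Count of alternative alleles per call; ``-1`` marks a missing or
        half-missing call.
    """

    samples: list
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray

    def __post_init__(self):
        self.samples = list(self.samples)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if len(self.samples) < 2:
            raise InputError("need at least 2 samples")
        n_sites = self.pos.shape[0]
        if self.geno.shape != (len(self.samples), n_sites):
            raise InputError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.samples)} samples x {n_sites} sites"
            )
        bad = ~np.isin(self.geno, (MISSING, 0, 1, 2))
        if bad.any():
            raise InputError("genotype codes must be in {-1, 0, 1, 2}")
        self._check_sorted()

    def _check_sorted(self):
        seen = set()
        prev_chrom = None
        prev_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != prev_chrom:
                if c in seen:
                    raise InputError(f"chromosome {c} is not contiguous")
                seen.add(c)
                prev_chrom, prev_pos = c, p
            else:
                if p <= prev_pos:
                    raise InputError(
                        f"positions not strictly increasing on {c} at {p + 1}"
                    )
                prev_pos = p

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    def chroms(self) -> list:
        """Chromosome names in first-appearance order."""
        out = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slice(self, chrom) -> slice:
        idx = np.nonzero(self.chrom == chrom)[0]
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as e:
            raise InputError(f"sample {e.args[0]!r} not in genotype matrix") from None

    def allele_counts(self, sample_idx=None):
        """Per-site (n_called_alleles, n_alt, n_het) over the given samples."""
        g = self.geno if sample_idx is None else self.geno[sample_idx]
        called = g >= 0
        n_called = 2 * called.sum(axis=0)
        n_alt = np.where(called, g, 0).sum(axis=0)
        n_het = (g == 1).sum(axis=0)
        return n_called.astype(np.int64), n_alt.astype(np.int64), n_het.astype(np.int64)

    def take_sites(self, site_idx) -> "GenotypeMatrix":
        site_idx = np.asarray(site_idx)
        return GenotypeMatrix(
            samples=self.samples,
            chrom=self.chrom[site_idx],
            pos=self.pos[site_idx],
            ref=self.ref[site_idx],
            alt=self.alt[site_idx],
            geno=self.geno[:, site_idx],
        )


@dataclass
class PopulationMap:
    """Assignment of samples to named groups with roles."""

    assignments: dict  # sample -> (group, role)

    def __post_init__(self):
        for s, (g, r) in self.assignments.items():
            if r not in ROLES:
                raise InputError(f"unknown role {r!r} for sample {s!r}")
        if not self.assignments:
            raise InputError("no samples in population map")

    def groups(self) -> dict:
        out = {}
        for s, (g, _r) in self.assignments.items():
            out.setdefault(g, []).append(s)
        return out

    def samples_in_group(self, group) -> list:
        out = [s for s, (g, _r) in self.assignments.items() if g == group]
        if not out:
            raise InputError(f"group {group!r} is empty or unknown")
        return out

    def samples_with_role(self, role) -> list:
        if role not in ROLES:
            raise InputError(f"unknown role {role!r}")
        return [s for s, (_g, r) in self.assignments.items() if r == role]

    def role_of_group(self, group) -> str:
        roles = {r for s, (g, r) in self.assignments.items() if g == group}
        if len(roles) != 1:
            raise InputError(f"group {group!r} has roles {sorted(roles)}")
        return roles.pop()

    def validate_against(self, matrix: GenotypeMatrix):
        present = set(matrix.samples)
        missing = [s for s in self.assignments if s not in present]
        if missing:
            raise InputError(f"samples not in genotype matrix: {missing[:5]}")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str
    is_te: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise InputError(
                f"interval {self.name!r}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom, start, end) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class AnnotationSet:
    """A set of named, possibly overlapping intervals (0-based half-open)."""

    intervals: list = field(default_factory=list)

    def __post_init__(self):
        names = [iv.name for iv in self.intervals]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate interval names: {dup[:5]}")

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_chrom(self) -> dict:
        out = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def overlapping(self, chrom, start, end) -> list:
        return [iv for iv in self.intervals if iv.overlaps(chrom, start, end)]


@dataclass
class WindowStat:
    """One sliding-window statistic record (0-based half-open window)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    value: float
    stat_name: str


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path, region=None) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF v4.x file.

    Multiallelic and non-SNP records are skipped (count logged). Half-missing
    and fully missing calls become missing; phased and unphased genotypes are
    treated identically.

    Parameters
    ----------
    region : tuple (chrom, start, end), optional
        0-based half-open filter applied while reading.
    """
    try:
        vcf = VCF(str(path), gts012=False)
    except OSError as e:
        raise InputError(f"cannot open VCF {path}: {e}") from None
    if "GT" not in vcf:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    chrom, pos, ref, alt, geno_cols = [], [], [], [], []
    n_skipped = 0
    seen = set()
    prev_chrom, prev_pos = None, -1
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_skipped += 1
            continue
        p0 = v.POS - 1  # to 0-based
        if v.CHROM != prev_chrom:
            if v.CHROM in seen:
                raise InputError(f"{path}: chromosome {v.CHROM} not contiguous")
            seen.add(v.CHROM)
            prev_chrom, prev_pos = v.CHROM, p0
        else:
            if p0 <= prev_pos:
                raise InputError(f"{path}: unsorted positions at {v.CHROM}:{v.POS}")
            prev_pos = p0
        if region is not None:
            rc, rs, re_ = region
            if v.CHROM != rc or not (rs <= p0 < re_):
                continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) < 2 or any(a < 0 for a in alleles):
                col[i] = MISSING
            else:
                col[i] = sum(1 for a in alleles if a == 1)
        chrom.append(v.CHROM)
        pos.append(p0)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        geno_cols.append(col)
    if n_skipped:
        logger.info("%s: skipped %d multiallelic/non-SNP records", path, n_skipped)
    if geno_cols:
        geno = np.stack(geno_cols, axis=1)
    else:
        geno = np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, chrom, pos, ref, alt, geno)


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path, chrom_lengths=None):
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=feralgen\n")
        for c in matrix.chroms():
            sl = matrix.chrom_slice(c)
            length = (
                chrom_lengths[c]
                if chrom_lengths and c in chrom_lengths
                else int(matrix.pos[sl][-1]) + 1
            )
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in range(matrix.n_sites):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.geno[:, j])
            fh.write(
                f"{matrix.chrom[j]}\t{int(matrix.pos[j]) + 1}\t.\t"
                f"{matrix.ref[j]}\t{matrix.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TSV / BED readers and writers
# ---------------------------------------------------------------------------


def read_population_map(path) -> PopulationMap:
    """Read a sample/group/role TSV (header required)."""
    assignments = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise InputError(f"{path}: no samples")
        cols = header.rstrip("\n").split("\t")
        if cols[:3] != ["sample", "group", "role"]:
            raise FormatError(
                f"{path}: expected header 'sample<TAB>group<TAB>role', got {cols[:3]}"
            )
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected 3 columns")
            sample, group, role = parts[0], parts[1], parts[2]
            if sample in assignments:
                raise InputError(f"{path}:{ln}: duplicate sample {sample!r}")
            if role not in ROLES:
                raise InputError(f"{path}:{ln}: unknown role {role!r}")
            assignments[sample] = (group, role)
    if not assignments:
        raise InputError(f"{path}: no samples")
    return PopulationMap(assignments)


def write_population_map(popmap: PopulationMap, path):
    with open(path, "w") as fh:
        fh.write("sample\tgroup\trole\n")
        for s, (g, r) in popmap.assignments.items():
            fh.write(f"{s}\t{g}\t{r}\n")


def read_bed(path) -> AnnotationSet:
    """Read a 3+ column BED file; optional name (col 4) and TE flag (col 5).

    The TE flag column takes the literal strings ``TE`` or ``non-TE``.
    Unnamed intervals are auto-named ``chrom:start-end``.
    """
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from None
            if start >= end:
                raise InputError(f"{path}:{ln}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 and parts[3] else f"{chrom}:{start}-{end}"
            is_te = False
            if len(parts) > 4 and parts[4]:
                if parts[4] not in ("TE", "non-TE"):
                    raise FormatError(f"{path}:{ln}: TE flag must be 'TE' or 'non-TE'")
                is_te = parts[4] == "TE"
            intervals.append(Interval(chrom, start, end, name, is_te))
    return AnnotationSet(intervals)


def write_bed(annotation: AnnotationSet, path):
    with open(path, "w") as fh:
        for iv in annotation:
            flag = "TE" if iv.is_te else "non-TE"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{flag}\n")


def read_chrom_lengths(path) -> dict:
    """Read a 'chrom<TAB>length' TSV into an ordered dict."""
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected chrom<TAB>length")
            try:
                length = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer length") from None
            if parts[0] in out:
                raise InputError(f"{path}:{ln}: duplicate chromosome {parts[0]!r}")
            if length < 0:
                raise InputError(f"{path}:{ln}: negative length")
            out[parts[0]] = length
    if not out:
        raise InputError(f"{path}: no chromosomes")
    return out


def write_window_stats(stats, path):
    """Write a list of WindowStat as TSV (one statistic per file)."""
    stats = list(stats)
    stat_name = stats[0].stat_name if stats else "value"
    with open(path, "w") as fh:
        fh.write(f"chrom\tstart\tend\tn_snps\t{stat_name}\n")
        for w in stats:
            val = "NA" if w.value is None or np.isnan(w.value) else f"{w.value:.10g}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_snps}\t{val}\n")


def read_window_stats(path) -> list:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 5 or header[:4] != ["chrom", "start", "end", "n_snps"]:
            raise FormatError(f"{path}: not a window-stat TSV")
        stat_name = header[4]
        for line in fh:
            if not line.strip():
                continue
            c, s, e, n, v = line.rstrip("\n").split("\t")
            value = float("nan") if v == "NA" else float(v)
            out.append(WindowStat(c, int(s), int(e), int(n), value, stat_name))
    return out
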