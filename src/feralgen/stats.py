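"""Per-site and windowed population-genetic statistics, and SFS machinery.

Statistics: nucleotide diversity (pi), Tajima's D, Weir & Cockerham (1984)
FST, observed heterozygosity; site-frequency spectra with hypergeometric
projection, minor-allele folding and singleton masking.

Missing data policy: sites are never dropped globally; every statistic uses
its own per-site called-sample count. The missing-value sentinel is NaN.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .errors import InputError, ParameterError
from .io import GenotypeMatrix, WindowStat

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Per-site quantities
# ---------------------------------------------------------------------------


@dataclass
class SiteCounts:
    """Per-site allele bookkeeping (vectorized over sites).

    n_called: called alleles (2 x called samples); n_alt: alternative allele
    count; n_het: heterozygous sample count.
    """

    n_called: np.ndarray
    n_alt: np.ndarray
    n_het: np.ndarray

    def __post_init__(self):
        self.n_called = np.atleast_1d(np.asarray(self.n_called, dtype=np.int64))
        self.n_alt = np.atleast_1d(np.asarray(self.n_alt, dtype=np.int64))
        self.n_het = np.atleast_1d(np.asarray(self.n_het, dtype=np.int64))
        if np.any(self.n_alt > self.n_called) or np.any(self.n_alt < 0):
            raise InputError("n_alt must be in [0, n_called]")
        if np.any(2 * self.n_het > self.n_called):
            raise InputError("n_het cannot exceed n_called / 2")

    @classmethod
    def from_matrix(cls, matrix: GenotypeMatrix, sample_idx=None) -> "SiteCounts":
        return cls(*matrix.allele_counts(sample_idx))


def site_pi(counts: SiteCounts) -> np.ndarray:
    """Unbiased per-site heterozygosity 2 j (n - j) / (n (n - 1)).

    Sites with fewer than 2 called alleles contribute 0 (logged).
    """
    n = counts.n_called.astype(float)
    j = counts.n_alt.astype(float)
    ok = n >= 2
    if not ok.all():
        logger.info("site_pi: %d sites with < 2 called alleles set to 0", (~ok).sum())
    out = np.zeros_like(n)
    np.divide(2.0 * j * (n - j), n * (n - 1.0), out=out, where=ok)
    return out


def observed_het(counts: SiteCounts) -> np.ndarray:
    """H_O = heterozygous samples / called samples, NaN where none called."""
    n_samples = counts.n_called / 2.0
    out = np.full(n_samples.shape, np.nan)
    np.divide(counts.n_het, n_samples, out=out, where=n_samples > 0)
    return out


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TajimaConstants:
    """Tajima (1989) normalizing constants for allele-sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise ParameterError(f"Tajima constants need n >= 2, got {n}")
    n = int(n)
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(S, pi_sum, n) -> float:
    """Tajima's D from segregating-site count S and summed per-site pi.

    Returns NaN when S == 0 (undefined); raises for n < 4.
    """
    if n < 4:
        raise ParameterError(f"Tajima's D needs n >= 4, got {n}")
    if S == 0:
        return float("nan")
    k = tajima_constants(int(n))
    var = k.e1 * S + k.e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi_sum - S / k.a1) / np.sqrt(var))


# ---------------------------------------------------------------------------
# Windowed statistics
# ---------------------------------------------------------------------------


def _window_site_ranges(matrix: GenotypeMatrix, windows):
    """Yield (window, lo, hi) site-index ranges, using per-chromosome slices."""
    slices = {c: matrix.chrom_slice(c) for c in matrix.chroms()}
    for w in windows:
        chrom, start, end = w[0], w[1], w[2]
        sl = slices.get(chrom)
        if sl is None:
            yield w, 0, 0
            continue
        pos = matrix.pos[sl]
        lo = int(np.searchsorted(pos, start, side="left")) + sl.start
        hi = int(np.searchsorted(pos, end, side="left")) + sl.start
        yield w, lo, hi


def window_pi(matrix: GenotypeMatrix, samples, windows) -> list:
    """Per-window nucleotide diversity: sum of site pi / window span (bp)."""
    idx = matrix.sample_indices(samples)
    pi = site_pi(SiteCounts.from_matrix(matrix, idx))
    cs = np.concatenate([[0.0], np.cumsum(pi)])
    out = []
    for (chrom, start, end), lo, hi in _window_site_ranges(matrix, windows):
        span = end - start
        val = (cs[hi] - cs[lo]) / span if span > 0 else 0.0
        out.append(WindowStat(chrom, start, end, hi - lo, float(val), "pi"))
    return out


def window_tajimas_d(matrix: GenotypeMatrix, samples, windows, min_snps=3) -> list:
    """Per-window Tajima's D.

    S counts sites segregating within the sample subset; n is the median
    called-allele number over those sites (single-n approximation). Windows
    with fewer than ``min_snps`` segregating sites get NaN.
    """
    idx = matrix.sample_indices(samples)
    counts = SiteCounts.from_matrix(matrix, idx)
    seg = (counts.n_alt > 0) & (counts.n_alt < counts.n_called) & (counts.n_called >= 4)
    pi = np.where(seg, site_pi(counts), 0.0)
    cs_pi = np.concatenate([[0.0], np.cumsum(pi)])
    cs_seg = np.concatenate([[0], np.cumsum(seg.astype(np.int64))])
    out = []
    for (chrom, start, end), lo, hi in _window_site_ranges(matrix, windows):
        S = int(cs_seg[hi] - cs_seg[lo])
        if S < min_snps:
            out.append(WindowStat(chrom, start, end, S, float("nan"), "tajimas_d"))
            continue
        n_med = int(np.median(counts.n_called[lo:hi][seg[lo:hi]]))
        if n_med < 4:
            out.append(WindowStat(chrom, start, end, S, float("nan"), "tajimas_d"))
            continue
        d = tajimas_d(S, float(cs_pi[hi] - cs_pi[lo]), n_med)
        out.append(WindowStat(chrom, start, end, S, d, "tajimas_d"))
    return out


def wc_variance_components(counts1: SiteCounts, counts2: SiteCounts):
    """Per-site Weir & Cockerham (1984) components (a, b, c) for 2 populations.

    Sites where either population has < 2 called samples are unusable and
    returned as (0, 0, 0) with usable=False.
    """
    n1 = counts1.n_called / 2.0  # individuals
    n2 = counts2.n_called / 2.0
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = counts1.n_alt / counts1.n_called
        p2 = counts2.n_alt / counts2.n_called
        h1 = counts1.n_het / n1
        h2 = counts2.n_het / n2
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        inner = pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 / 2.0 - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~usable] = 0.0
        np.nan_to_num(arr, copy=False)
    return a, b, c, usable


def wc_fst_window(matrix: GenotypeMatrix, pop1_samples, pop2_samples, windows) -> list:
    """Windowed Weir & Cockerham weighted FST: sum(a) / sum(a + b + c).

    Sites with a + b + c == 0 are skipped; negative estimates are retained.
    Windows with no usable sites get NaN.
    """
    c1 = SiteCounts.from_matrix(matrix, matrix.sample_indices(pop1_samples))
    c2 = SiteCounts.from_matrix(matrix, matrix.sample_indices(pop2_samples))
    a, b, c, usable = wc_variance_components(c1, c2)
    tot = a + b + c
    contributes = usable & (tot != 0)
    a = np.where(contributes, a, 0.0)
    tot = np.where(contributes, tot, 0.0)
    cs_a = np.concatenate([[0.0], np.cumsum(a)])
    cs_t = np.concatenate([[0.0], np.cumsum(tot)])
    cs_n = np.concatenate([[0], np.cumsum(contributes.astype(np.int64))])
    out = []
    for (chrom, start, end), lo, hi in _window_site_ranges(matrix, windows):
        n_use = int(cs_n[hi] - cs_n[lo])
        denom = cs_t[hi] - cs_t[lo]
        if n_use == 0 or denom == 0:
            val = float("nan")
        else:
            val = float((cs_a[hi] - cs_a[lo]) / denom)
        out.append(WindowStat(chrom, start, end, n_use, val, "wc_fst"))
    return out


def window_observed_het(matrix: GenotypeMatrix, samples, windows) -> list:
    """Per-window mean per-SNP observed heterozygosity (NaN if no SNPs)."""
    idx = matrix.sample_indices(samples)
    counts = SiteCounts.from_matrix(matrix, idx)
    ho = observed_het(counts)
    ok = ~np.isnan(ho)
    cs = np.concatenate([[0.0], np.cumsum(np.where(ok, ho, 0.0))])
    cs_n = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
    out = []
    for (chrom, start, end), lo, hi in _window_site_ranges(matrix, windows):
        n = int(cs_n[hi] - cs_n[lo])
        val = float((cs[hi] - cs[lo]) / n) if n else float("nan")
        out.append(WindowStat(chrom, start, end, n, val, "observed_het"))
    return out


def mean_observed_het(matrix: GenotypeMatrix, samples, chrom, start, end) -> float:
    """Mean per-SNP H_O over a genomic span for one sample set."""
    [w] = window_observed_het(matrix, samples, [(chrom, start, end)])
    return w.value


# ---------------------------------------------------------------------------
# Site-frequency spectra
# ---------------------------------------------------------------------------


def _default_mask(shape) -> np.ndarray:
    """Mask the absorbing corners (non-segregating cells) of a spectrum."""
    mask = np.zeros(shape, dtype=bool)
    if len(shape) == 1:
        mask[0] = mask[-1] = True
    else:
        mask[0, 0] = mask[-1, -1] = True
    return mask


@dataclass
class SFS:
    """A 1D or joint 2D site-frequency spectrum.

    ``counts`` is indexed by alternative-allele count per axis (length n+1
    per axis). ``mask`` flags entries excluded from likelihoods; the
    absorbing corners are masked at construction. Folded spectra are in
    minor-allele orientation with folded-away entries structurally zero.
    """

    counts: np.ndarray
    folded: bool = False
    mask: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim not in (1, 2):
            raise InputError("SFS must be 1D or 2D")
        if np.any(self.counts < 0):
            raise InputError("SFS counts must be non-negative")
        if self.mask is None:
            self.mask = _default_mask(self.counts.shape)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise InputError("mask shape must match counts shape")

    @property
    def dims(self) -> int:
        return self.counts.ndim

    @property
    def n(self) -> tuple:
        return tuple(s - 1 for s in self.counts.shape)

    def total(self) -> float:
        return float(self.counts.sum())

    def unmasked_counts(self) -> np.ndarray:
        return self.counts[~self.mask]

    def normalized(self) -> "SFS":
        """Probabilities over unmasked entries (masked entries zeroed)."""
        tot = self.counts[~self.mask].sum()
        if tot <= 0:
            raise InputError("cannot normalize an empty spectrum")
        counts = np.where(self.mask, 0.0, self.counts / tot)
        return SFS(counts, folded=self.folded, mask=self.mask.copy())


def _projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """Rows: allele count j in n_from; cols: hypergeometric weights at n_to."""
    j = np.arange(n_from + 1)[:, None]
    k = np.arange(n_to + 1)[None, :]
    return hypergeom.pmf(k, n_from, j, n_to)


def build_sfs(matrix: GenotypeMatrix, samples_axis1, samples_axis2=None,
              project_to=None) -> SFS:
    """Build an unfolded SFS of alternative-allele counts.

    Fully called sites increment integer cells. Sites with missing data are
    included via per-site hypergeometric projection when ``project_to`` is
    given (one size per axis); otherwise they are dropped with a logged count.
    """
    axes = [samples_axis1] + ([samples_axis2] if samples_axis2 is not None else [])
    counts_per_axis = [
        SiteCounts.from_matrix(matrix, matrix.sample_indices(s)) for s in axes
    ]
    full_n = [2 * len(s) for s in axes]
    if project_to is None:
        target = full_n
    else:
        target = [project_to] if np.isscalar(project_to) else list(project_to)
        if len(target) != len(axes):
            raise ParameterError("project_to must give one size per axis")
        for t, f in zip(target, full_n):
            if t > f:
                raise ParameterError(f"cannot project up: {t} > {f}")
    shape = tuple(t + 1 for t in target)
    sfs = np.zeros(shape)
    n_sites = matrix.n_sites
    n_dropped = 0
    proj_cache = {}

    def site_weights(ax, j, nc):
        t = target[ax]
        if nc < t:
            return None
        key = (nc, t)
        if key not in proj_cache:
            proj_cache[key] = _projection_matrix(nc, t)
        return proj_cache[key][j]

    for s in range(n_sites):
        ws = []
        ok = True
        for ax, cnt in enumerate(counts_per_axis):
            nc = int(cnt.n_called[s])
            j = int(cnt.n_alt[s])
            if project_to is None and nc < full_n[ax]:
                ok = False
                break
            w = site_weights(ax, j, nc)
            if w is None:
                ok = False
                break
            ws.append(w)
        if not ok:
            n_dropped += 1
            continue
        if len(ws) == 1:
            sfs += ws[0]
        else:
            sfs += np.outer(ws[0], ws[1])
    if n_dropped:
        logger.info("build_sfs: %d sites dropped (missing data)", n_dropped)
    return SFS(sfs)


def project_sfs(sfs: SFS, m) -> SFS:
    """Hypergeometric projection of a whole spectrum to smaller sample sizes.

    Conserves total mass. The mask is reset to the default (corners); apply
    folding/masking after projection.
    """
    if sfs.folded:
        raise ParameterError("project before folding, not after")
    targets = [m] if np.isscalar(m) else list(m)
    if len(targets) != sfs.dims:
        raise ParameterError("need one target size per axis")
    counts = sfs.counts
    for ax, (t, n) in enumerate(zip(targets, sfs.n)):
        if t > n:
            raise ParameterError(f"cannot project up on axis {ax}: {t} > {n}")
        P = _projection_matrix(n, t)
        counts = np.tensordot(counts, P, axes=([ax], [0]))
        counts = np.moveaxis(counts, -1, ax)
    return SFS(counts)


def fold_sfs(sfs: SFS) -> SFS:
    """Fold to minor-allele orientation (2D: fold on total minor count).

    Entry k is added to min(k, n - k); 2D cells with total count beyond the
    midpoint fold onto their complement. Idempotent.
    """
    if sfs.folded:
        return SFS(sfs.counts.copy(), folded=True, mask=sfs.mask.copy())
    counts = sfs.counts.copy()
    mask = sfs.mask.copy()
    fold_away = ~folded_support(counts.shape)
    rev = tuple(slice(None, None, -1) for _ in range(counts.ndim))
    kept = np.where(fold_away, 0.0, counts)
    moved = np.where(fold_away, counts, 0.0)[rev]
    new_mask = np.where(fold_away, False, mask | mask[rev])
    return SFS(kept + moved, folded=True, mask=new_mask)


def folded_support(shape) -> np.ndarray:
    """Boolean array of cells kept (not structurally zero) after folding."""
    if len(shape) == 1:
        n = shape[0] - 1
        tot = np.arange(n + 1)
        return ~(tot > n - tot)
    n1, n2 = shape[0] - 1, shape[1] - 1
    k1 = np.arange(n1 + 1)[:, None]
    k2 = np.arange(n2 + 1)[None, :]
    tot = k1 + k2
    n_tot = n1 + n2
    return ~((tot > n_tot - tot) | ((2 * tot == n_tot) & (k1 > n1 - k1)))


def mask_singletons(sfs: SFS) -> SFS:
    """Mask entries whose total minor-allele count equals 1."""
    counts = sfs.counts.copy()
    mask = sfs.mask.copy()
    if sfs.dims == 1:
        n = sfs.n[0]
        tot = np.arange(n + 1)
        n_tot = n
    else:
        n1, n2 = sfs.n
        tot = np.arange(n1 + 1)[:, None] + np.arange(n2 + 1)[None, :]
        n_tot = n1 + n2
    minor = np.minimum(tot, n_tot - tot)
    mask |= minor == 1
    return SFS(counts, folded=sfs.folded, mask=mask)


def write_sfs(sfs: SFS, tsv_path, json_path):
    """Serialize an SFS as TSV (counts) plus a JSON sidecar (metadata)."""
    if sfs.dims == 1:
        with open(tsv_path, "w") as fh:
            fh.write("allele_count\tsites\n")
            for k, v in enumerate(sfs.counts):
                fh.write(f"{k}\t{v:.10g}\n")
    else:
        np.savetxt(tsv_path, sfs.counts, delimiter="\t", fmt="%.10g")
    meta = {
        "dims": sfs.dims,
        "n": list(sfs.n),
        "folded": sfs.folded,
        "masked_entries": [list(map(int, idx)) for idx in np.argwhere(sfs.mask)],
    }
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_sfs(tsv_path, json_path) -> SFS:
    with open(json_path) as fh:
        meta = json.load(fh)
    if meta["dims"] == 1:
        counts = np.loadtxt(tsv_path, delimiter="\t", skiprows=1, ndmin=2)[:, 1]
    else:
        counts = np.loadtxt(tsv_path, delimiter="\t", ndmin=2)
    mask = np.zeros(counts.shape, dtype=bool)
    for idx in meta["masked_entries"]:
        mask[tuple(idx)] = True
    return SFS(counts, folded=meta["folded"], mask=mask)
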