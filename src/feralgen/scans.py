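"""Region calling on windowed statistics.

Z(FST) divergent-region detection with gene mapping, and the
balancing-selection region detector (top-quantile Tajima's D runs filtered
by the matched cultivated background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateComputationError, InputError
from .io import AnnotationSet, GenotypeMatrix, WindowStat
from .stats import SiteCounts, site_pi, tajimas_d, window_tajimas_d


@dataclass
class Region:
    """A merged run of qualifying windows (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_windows: int
    mean_stat: float
    max_stat: float
    genes: list = field(default_factory=list)
    cult_mean_stat: float = float("nan")
    pct_zfst_ge3: float = float("nan")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def make_windows(chrom_lengths: dict, size=100_000, step=10_000) -> list:
    """Sliding windows [k*step, k*step + size) per chromosome.

    Windows start while k*step < chromosome length and are truncated at the
    chromosome end.
    """
    if not (size >= step > 0):
        raise InputError(f"need size >= step > 0, got size={size} step={step}")
    windows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            windows.append((chrom, start, min(start + size, length)))
            start += step
    return windows


def zscore(values) -> np.ndarray:
    """(v - mean) / sd over non-missing entries (sd with n-1 denominator).

    NaN entries stay NaN. Raises DegenerateComputationError on zero variance.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise InputError("zscore needs >= 2 non-missing values")
    mean = v[ok].mean()
    sd = v[ok].std(ddof=1)
    # numerically-constant input leaves sd at rounding-noise level
    if sd <= 1e-12 * max(1.0, abs(mean)):
        raise DegenerateComputationError("zero variance in Z-transformation")
    out = np.full_like(v, np.nan)
    out[ok] = (v[ok] - mean) / sd
    return out


def _merge_runs(windows_sel, values):
    """Merge overlapping/abutting qualifying windows into maximal regions.

    ``windows_sel``: list of (chrom, start, end); ``values``: matched stats.
    Returns list of Region sorted by (chrom-first-appearance, start).
    """
    regions = []
    current = None
    cur_vals = []
    order = sorted(
        range(len(windows_sel)),
        key=lambda i: (windows_sel[i][0], windows_sel[i][1], windows_sel[i][2]),
    )
    for i in order:
        chrom, start, end = windows_sel[i]
        if current is not None and chrom == current[0] and start <= current[2]:
            current[2] = max(current[2], end)
            cur_vals.append(values[i])
        else:
            if current is not None:
                regions.append(_finish_region(current, cur_vals))
            current = [chrom, start, end]
            cur_vals = [values[i]]
    if current is not None:
        regions.append(_finish_region(current, cur_vals))
    return regions


def _finish_region(bounds, vals):
    return Region(
        chrom=bounds[0],
        start=bounds[1],
        end=bounds[2],
        n_windows=len(vals),
        mean_stat=float(np.mean(vals)),
        max_stat=float(np.max(vals)),
    )


def divergent_regions(fst_windows, z_threshold=3.0) -> list:
    """Call divergent regions from windowed FST via genome-wide Z >= threshold.

    Overlapping or abutting qualifying windows are merged into maximal
    regions; mean/max stats recorded are the Z values.
    """
    vals = np.array([w.value for w in fst_windows], dtype=float)
    z = zscore(vals)
    sel = [i for i in range(len(fst_windows)) if not math.isnan(z[i]) and z[i] >= z_threshold]
    windows_sel = [(fst_windows[i].chrom, fst_windows[i].start, fst_windows[i].end) for i in sel]
    return _merge_runs(windows_sel, [float(z[i]) for i in sel])


def map_genes(regions, annotation: AnnotationSet, non_te_only=False) -> list:
    """Attach overlapping (>= 1 bp) gene names to each region, in place."""
    by_chrom = annotation.by_chrom()
    for r in regions:
        genes = []
        for iv in by_chrom.get(r.chrom, []):
            if iv.is_te and non_te_only:
                continue
            if iv.overlaps(r.chrom, r.start, r.end):
                genes.append(iv.name)
        r.genes = sorted(set(genes))
    return regions


def scan_gene_set(regions, annotation: AnnotationSet, non_te_only=False) -> set:
    """De-duplicated union of gene names over all regions of one scan."""
    map_genes(regions, annotation, non_te_only=non_te_only)
    out = set()
    for r in regions:
        out.update(r.genes)
    return out


def overlap_rate(geneset: AnnotationSet, regions_b: AnnotationSet) -> float:
    """Percent of genes in ``geneset`` overlapping (>= 1 bp) any interval in b.

    Returns NaN for an empty gene set.
    """
    if len(geneset) == 0:
        return float("nan")
    by_chrom = regions_b.by_chrom()
    n_hit = 0
    for g in geneset:
        if any(iv.overlaps(g.chrom, g.start, g.end) for iv in by_chrom.get(g.chrom, [])):
            n_hit += 1
    return 100.0 * n_hit / len(geneset)


def shared_genes(gene_sets, min_groups=3) -> set:
    """Genes present in at least ``min_groups`` of the given sets."""
    if len(gene_sets) < min_groups:
        raise InputError(f"need >= {min_groups} gene sets, got {len(gene_sets)}")
    tally = {}
    for s in gene_sets:
        for g in s:
            tally[g] = tally.get(g, 0) + 1
    return {g for g, k in tally.items() if k >= min_groups}


def _same_grid(w1, w2):
    return len(w1) == len(w2) and all(
        a.chrom == b.chrom and a.start == b.start and a.end == b.end
        for a, b in zip(w1, w2)
    )


def top_quantile_threshold(values, q=0.95) -> float:
    """Empirical order-statistic quantile (type 1): an observed value such
    that at least q of the non-missing mass lies at or below it."""
    v = np.sort(np.asarray(values, dtype=float))
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise InputError("no non-missing values for quantile")
    idx = max(0, int(np.ceil(q * v.size)) - 1)
    return float(v[idx])


def balancing_regions(
    d_windows_weedy,
    d_windows_cult,
    top_quantile=0.95,
    min_len=500_000,
    cult_mean_max=1.0,
    cult_window_max=2.0,
    fst_windows=None,
    z_threshold=3.0,
) -> list:
    """Detect balancing-selection regions from weedy vs cultivated Tajima's D.

    1. threshold = empirical top-quantile of non-missing weedy D;
    2. qualifying windows merged into maximal runs (as in divergent_regions);
    3. regions with length <= min_len dropped;
    4. a region is removed if the cultivated windows over the same span have
       mean D > cult_mean_max or any window D > cult_window_max.

    If an FST scan on the same grid is supplied, the fraction of each
    region's weedy windows with Z(FST) >= z_threshold is reported.
    """
    if not _same_grid(d_windows_weedy, d_windows_cult):
        raise InputError("weedy and cultivated windows are on different grids")
    zf = None
    if fst_windows is not None:
        if not _same_grid(d_windows_weedy, fst_windows):
            raise InputError("FST windows are on a different grid")
        zf = zscore(np.array([w.value for w in fst_windows], dtype=float))
    weedy_vals = np.array([w.value for w in d_windows_weedy], dtype=float)
    thr = top_quantile_threshold(weedy_vals, top_quantile)
    sel = [i for i, v in enumerate(weedy_vals) if not math.isnan(v) and v >= thr]
    windows_sel = [
        (d_windows_weedy[i].chrom, d_windows_weedy[i].start, d_windows_weedy[i].end)
        for i in sel
    ]
    candidates = _merge_runs(windows_sel, [float(weedy_vals[i]) for i in sel])
    out = []
    for r in candidates:
        if r.length_bp <= min_len:
            continue
        span_idx = [
            i
            for i, w in enumerate(d_windows_cult)
            if w.chrom == r.chrom and w.start < r.end and r.start < w.end
        ]
        cult_vals = np.array(
            [d_windows_cult[i].value for i in span_idx], dtype=float
        )
        cult_vals = cult_vals[~np.isnan(cult_vals)]
        if cult_vals.size:
            r.cult_mean_stat = float(cult_vals.mean())
            if r.cult_mean_stat > cult_mean_max or np.any(cult_vals > cult_window_max):
                continue
        if zf is not None:
            zin = [
                zf[i]
                for i, w in enumerate(d_windows_weedy)
                if w.chrom == r.chrom and w.start < r.end and r.start < w.end
                and not math.isnan(zf[i])
            ]
            if zin:
                r.pct_zfst_ge3 = 100.0 * sum(z >= z_threshold for z in zin) / len(zin)
        out.append(r)
    return out


def per_gene_tajimas_d(matrix: GenotypeMatrix, samples, annotation: AnnotationSet) -> dict:
    """Tajima's D over the SNPs within each annotated gene interval.

    Genes with no segregating SNPs map to NaN.
    """
    idx = matrix.sample_indices(samples)
    counts = SiteCounts.from_matrix(matrix, idx)
    seg = (counts.n_alt > 0) & (counts.n_alt < counts.n_called) & (counts.n_called >= 4)
    pi = np.where(seg, site_pi(counts), 0.0)
    out = {}
    for iv in annotation:
        sl = matrix.chrom_slice(iv.chrom)
        pos = matrix.pos[sl]
        lo = int(np.searchsorted(pos, iv.start, side="left")) + sl.start
        hi = int(np.searchsorted(pos, iv.end, side="left")) + sl.start
        S = int(seg[lo:hi].sum())
        if S == 0:
            out[iv.name] = float("nan")
            continue
        n_med = int(np.median(counts.n_called[lo:hi][seg[lo:hi]]))
        if n_med < 4:
            out[iv.name] = float("nan")
            continue
        out[iv.name] = tajimas_d(S, float(pi[lo:hi].sum()), n_med)
    return out


def write_regions(regions, path):
    """Region TSV: coordinates, window count, stats, gene list."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tlength_bp\tn_windows\tmean_stat\tmax_stat\t"
            "cult_mean_stat\tpct_zfst_ge3\tgenes\n"
        )
        for r in regions:
            def fmt(x):
                return "NA" if math.isnan(x) else f"{x:.6g}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.length_bp}\t{r.n_windows}\t"
                f"{fmt(r.mean_stat)}\t{fmt(r.max_stat)}\t{fmt(r.cult_mean_stat)}\t"
                f"{fmt(r.pct_zfst_ge3)}\t{','.join(r.genes)}\n"
            )
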