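"""Standing-vs-new variant classification and allele-frequency differentiation.

A weedy-population SNP is *standing* if its alternative allele is observed at
least once among called cultivated samples, *new* otherwise. AFD is the
signed difference of alternative-allele frequencies, weedy minus cultivated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import AnnotationSet, GenotypeMatrix
from .stats import SiteCounts

logger = logging.getLogger(__name__)


@dataclass
class VariantClass:
    chrom: str
    pos: int
    origin: str  # standing | new
    afd: float
    in_selected_region: bool = False
    wild_flag: bool = False  # alt absent in cultivated, present in wild pool


def afd(weedy_alt_freq, cultivated_alt_freq) -> float:
    """Signed AFD: alt frequency in weedy minus alt frequency in cultivated."""
    if np.isnan(weedy_alt_freq) or np.isnan(cultivated_alt_freq):
        return float("nan")
    return float(weedy_alt_freq - cultivated_alt_freq)


def classify_variants(
    matrix: GenotypeMatrix,
    weedy_samples,
    cultivated_samples,
    wild_samples=None,
    regions: AnnotationSet = None,
) -> list:
    """Classify weedy SNPs as standing or new and compute per-site AFD.

    Only sites where the alternative allele is observed among called weedy
    samples are classified. Sites with no called cultivated samples are
    unclassifiable and excluded (logged). An optional wild panel flags
    variants absent in cultivated but present in the wild pool.
    """
    cw = SiteCounts.from_matrix(matrix, matrix.sample_indices(weedy_samples))
    cc = SiteCounts.from_matrix(matrix, matrix.sample_indices(cultivated_samples))
    wild = None
    if wild_samples is not None:
        wild = SiteCounts.from_matrix(matrix, matrix.sample_indices(wild_samples))

    weedy_poly = (cw.n_alt > 0) & (cw.n_called > 0)
    classifiable = cc.n_called > 0
    n_unclassifiable = int((weedy_poly & ~classifiable).sum())
    if n_unclassifiable:
        logger.info(
            "classify_variants: %d weedy SNPs unclassifiable "
            "(no called cultivated samples)",
            n_unclassifiable,
        )
    use = np.nonzero(weedy_poly & classifiable)[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        fw = cw.n_alt / cw.n_called
        fc = cc.n_alt / cc.n_called
    region_cache = regions.by_chrom() if regions is not None else {}

    out = []
    for i in use:
        chrom, pos = matrix.chrom[i], int(matrix.pos[i])
        origin = "standing" if cc.n_alt[i] > 0 else "new"
        in_region = any(
            iv.overlaps(chrom, pos, pos + 1) for iv in region_cache.get(chrom, [])
        )
        wild_flag = bool(
            origin == "new"
            and wild is not None
            and wild.n_called[i] > 0
            and wild.n_alt[i] > 0
        )
        out.append(
            VariantClass(chrom, pos, origin, afd(fw[i], fc[i]), in_region, wild_flag)
        )
    return out


def afd_distribution(
    classes, bin_width=0.1, thresholds=(0.7, 0.9), regions: AnnotationSet = None
) -> pd.DataFrame:
    """Per-class AFD percentage histograms and strict-threshold percentages.

    Rows cover each origin class for scope ``genome`` and, when regions were
    available at classification time (or are supplied here), scope
    ``selected``. Percentages are normalized within class and scope; empty
    classes yield NaN percentages.
    """
    if regions is not None:
        cache = regions.by_chrom()
        for v in classes:
            v.in_selected_region = any(
                iv.overlaps(v.chrom, v.pos, v.pos + 1) for iv in cache.get(v.chrom, [])
            )
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    rows = []
    for scope in ("genome", "selected"):
        for origin in ("standing", "new"):
            vals = np.array(
                [
                    v.afd
                    for v in classes
                    if v.origin == origin
                    and not np.isnan(v.afd)
                    and (scope == "genome" or v.in_selected_region)
                ]
            )
            n = vals.size
            if n == 0:
                hist = np.full(edges.size - 1, np.nan)
                pct_thr = {t: float("nan") for t in thresholds}
            else:
                counts, _ = np.histogram(vals, bins=edges)
                # histogram's last bin is closed; AFD = 1.0 belongs there
                hist = 100.0 * counts / n
                pct_thr = {t: 100.0 * float((vals > t).sum()) / n for t in thresholds}
            for lo, hi, pct in zip(edges[:-1], edges[1:], hist):
                rows.append(
                    {
                        "class": origin,
                        "scope": scope,
                        "kind": "bin",
                        "bin_low": float(lo),
                        "bin_high": float(hi),
                        "pct": float(pct),
                        "n": n,
                    }
                )
            for t, pct in pct_thr.items():
                rows.append(
                    {
                        "class": origin,
                        "scope": scope,
                        "kind": "threshold",
                        "bin_low": float(t),
                        "bin_high": float("nan"),
                        "pct": float(pct),
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


def pct_above(distribution: pd.DataFrame, origin, scope, threshold) -> float:
    """Convenience lookup of a threshold row in an afd_distribution table."""
    sel = distribution[
        (distribution["class"] == origin)
        & (distribution["scope"] == scope)
        & (distribution["kind"] == "threshold")
        & (np.isclose(distribution["bin_low"], threshold))
    ]
    if sel.empty:
        raise InputError(f"no threshold row for {origin}/{scope}/{threshold}")
    return float(sel["pct"].iloc[0])


def variant_table(classes) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in classes],
            "pos": [v.pos for v in classes],
            "origin": [v.origin for v in classes],
            "afd": [v.afd for v in classes],
            "in_selected_region": [v.in_selected_region for v in classes],
            "wild_flag": [v.wild_flag for v in classes],
        }
    )
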